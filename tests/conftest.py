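import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from exosnv.simulate import PILEUP_COLUMNS  # noqa: E402


def pileup_row(
    chrom="chr1",
    pos=1,
    ref="A",
    alt="C",
    ref_fwd=0,
    ref_rev=0,
    alt_fwd=0,
    alt_rev=0,
    max_alt_quality=0,
    homopolymer_len=1,
):
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "ref_fwd": ref_fwd,
        "ref_rev": ref_rev,
        "alt_fwd": alt_fwd,
        "alt_rev": alt_rev,
        "max_alt_quality": max_alt_quality,
        "homopolymer_len": homopolymer_len,
    }


def make_pileup(rows):
    return pd.DataFrame(list(rows), columns=PILEUP_COLUMNS)


@pytest.fixture
def tiny_cohort_config():
    """Small two-patient cohort config for end-to-end runs."""
    return {
        "seed": 11,
        "generator": {
            "n_sites": 1500,
            "heterozygosity_rate": 0.02,
            "somatic_rate": 0.01,
            "n_genes": 10,
            "bin_count": 120,
            "planted_segments": [[40, 59, 1.0]],
        },
        "patients": [
            {"id": "msi_case", "preset": "msi"},
            {"id": "mss_case", "preset": "mss"},
        ],
    }
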