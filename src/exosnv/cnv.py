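"""Read-depth copy-number analysis on genomic bins.

Per-bin tumor/normal counts are library-size normalized (each count
vector scaled to equal totals), converted to log2 ratios, and
median-centered so copy-neutral bins sit at zero.  Changepoints are
found by recursive circular binary segmentation: at each step the
contiguous arc maximizing the arc-versus-complement t-like statistic is
tested with a seeded permutation test, and the split (both arc
boundaries at once) is accepted when the permutation p-value falls
below ``alpha``.  Segment states (gain / loss / neutral)
follow the two-standard-deviation rule, with the SD estimated robustly
from bin-level residuals around segment means (MAD x 1.4826 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826

SEGMENT_COLUMNS = ["chrom", "start_bin", "end_bin", "n_bins", "mean_ratio"]


@dataclass
class SegmentationParams:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_segment_bins: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1 or self.min_segment_bins < 1:
            raise ValueError("n_permutations and min_segment_bins must be >= 1")


def compute_ratios(bins: pd.DataFrame) -> pd.DataFrame:
    """Add a median-centered ``log2_ratio`` column to a bin-count table.

    Bins where either count is zero are masked (NaN) and excluded from
    the centering median.  The result is invariant to global scaling of
    either count vector.
    """
    required = {"chrom", "bin_start", "tumor_count", "normal_count"}
    missing = required - set(bins.columns)
    if missing:
        raise ValueError(f"bin table missing columns: {sorted(missing)}")
    if bins.duplicated(["chrom", "bin_start"]).any():
        raise ValueError("duplicate (chrom, bin_start) rows: tumor/normal grids must match")
    out = bins.copy()
    t = out["tumor_count"].to_numpy(float)
    n = out["normal_count"].to_numpy(float)
    if (t < 0).any() or (n < 0).any():
        raise ValueError("negative bin counts")
    mask = (t > 0) & (n > 0)
    scale = n.sum() / t.sum() if t.sum() > 0 else 1.0
    ratio = np.full(len(out), np.nan)
    ratio[mask] = np.log2(t[mask] * scale / n[mask])
    ratio[mask] -= np.median(ratio[mask])
    out["log2_ratio"] = ratio
    return out


def _arc_maxima(X: np.ndarray, min_seg: int) -> np.ndarray:
    """Maximum circular-segmentation statistic per profile row.

    For each row, the statistic is max over contiguous arcs [i, j) of
    |mean(arc) - mean(rest)| / sqrt(1/d + 1/(n-d)) with d = j - i; both
    the arc and its complement must span >= min_seg bins, and a non-empty
    prefix or suffix of the complement must itself be >= min_seg so that
    every segment produced by the split is admissible.  The segment's
    standard deviation is a permutation-invariant constant, so it cancels
    from the permutation test and is omitted.
    """
    R, n = X.shape
    C = np.concatenate([np.zeros((R, 1)), np.cumsum(X, axis=1)], axis=1)
    total = C[:, -1:]
    best = np.full(R, -np.inf)
    for d in range(min_seg, n - min_seg + 1):
        s = C[:, d:] - C[:, :-d]  # arc sums for starts i = 0 .. n-d
        stat = np.abs(s / d - (total - s) / (n - d)) / np.sqrt(1.0 / d + 1.0 / (n - d))
        i = np.arange(n - d + 1)
        suffix = n - d - i
        valid = ((i == 0) | (i >= min_seg)) & ((suffix == 0) | (suffix >= min_seg))
        stat[:, ~valid] = -np.inf
        np.maximum(best, stat.max(axis=1), out=best)
    return best


def _best_arc(x: np.ndarray, min_seg: int) -> tuple[int, int, float] | None:
    """Best (start, end, statistic) arc of a single profile, or None when
    the segment is too short to split."""
    n = len(x)
    if n < 2 * min_seg:
        return None
    C = np.concatenate([[0.0], np.cumsum(x)])
    total = C[-1]
    best: tuple[int, int, float] | None = None
    for d in range(min_seg, n - min_seg + 1):
        s = C[d:] - C[:-d]
        stat = np.abs(s / d - (total - s) / (n - d)) / np.sqrt(1.0 / d + 1.0 / (n - d))
        i = np.arange(n - d + 1)
        suffix = n - d - i
        valid = ((i == 0) | (i >= min_seg)) & ((suffix == 0) | (suffix >= min_seg))
        stat[~valid] = -np.inf
        k = int(np.argmax(stat))
        if best is None or stat[k] > best[2]:
            best = (k, k + d, float(stat[k]))
    return best


def _arc_is_significant(
    x: np.ndarray,
    observed: float,
    min_seg: int,
    B: int,
    alpha: float,
    rng: np.random.Generator,
    chunk: int = 250,
) -> bool:
    """Permutation test for the best-arc statistic.

    The split is accepted when (1 + #exceedances) / (B + 1) < alpha.
    Permutations are drawn in chunks with early rejection once the
    exceedance budget is exhausted.
    """
    budget = int(np.floor(alpha * (B + 1))) - 1  # max exceedances still significant
    if budget < 0:
        return False
    exceed = 0
    done = 0
    while done < B:
        m = min(chunk, B - done)
        perms = rng.permuted(np.tile(x, (m, 1)), axis=1)
        exceed += int(np.sum(_arc_maxima(perms, min_seg) >= observed))
        if exceed > budget:
            return False
        done += m
    return exceed <= budget


def _segment_array(
    x: np.ndarray, params: SegmentationParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive circular binary segmentation; returns half-open index
    intervals covering [0, len(x))."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        arc = _best_arc(seg, params.min_segment_bins)
        if arc is not None and np.isfinite(arc[2]) and arc[2] > 0:
            i, j, stat = arc
            if _arc_is_significant(
                seg, stat, params.min_segment_bins, params.n_permutations, params.alpha, rng
            ):
                for child in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                    if child[1] > child[0]:
                        stack.append(child)
                continue
        out.append((lo, hi))
    return sorted(out)


def segment_ratios(profile: pd.DataFrame, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment a centered log2-ratio profile per chromosome.

    Masked (NaN) bins are skipped; segment boundaries are reported in
    bin-index space (``start_bin`` inclusive, ``end_bin`` exclusive),
    each segment spanning from its first to one past its last unmasked
    bin.
    """
    p = params or SegmentationParams()
    rng = np.random.default_rng([int(p.seed), 61])
    rows = []
    for chrom, grp in profile.groupby("chrom", sort=True):
        grp = grp.sort_values("bin_start", kind="mergesort").reset_index(drop=True)
        unmasked = grp["log2_ratio"].notna().to_numpy()
        if not unmasked.any():
            continue
        idx = np.flatnonzero(unmasked)
        x = grp.loc[unmasked, "log2_ratio"].to_numpy()
        for lo, hi in _segment_array(x, p, rng):
            rows.append(
                {
                    "chrom": chrom,
                    "start_bin": int(idx[lo]),
                    "end_bin": int(idx[hi - 1]) + 1,
                    "n_bins": hi - lo,
                    "mean_ratio": float(np.mean(x[lo:hi])),
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_states(
    segments: pd.DataFrame,
    profile: pd.DataFrame,
    k: float = 2.0,
    sd_method: str = "mad",
) -> pd.DataFrame:
    """Assign gain / loss / neutral states by the k-standard-deviation rule.

    The SD is estimated from bin-level residuals (each unmasked bin minus
    its segment mean) across the whole profile: robustly via
    MAD x 1.4826 (default) or the plain standard deviation.
    """
    if sd_method not in ("mad", "std"):
        raise ValueError("sd_method must be 'mad' or 'std'")
    out = segments.copy()
    if out.empty:
        out["state"] = pd.Series(dtype=object)
        return out
    residuals = []
    prof = profile.copy()
    prof["_bin_index"] = prof.groupby("chrom")["bin_start"].rank(method="first").astype(int) - 1
    for _, seg in out.iterrows():
        sel = (
            (prof["chrom"] == seg["chrom"])
            & (prof["_bin_index"] >= seg["start_bin"])
            & (prof["_bin_index"] < seg["end_bin"])
        )
        vals = prof.loc[sel, "log2_ratio"].dropna().to_numpy()
        residuals.append(vals - seg["mean_ratio"])
    res = np.concatenate(residuals) if residuals else np.array([])
    if sd_method == "mad":
        sd = MAD_SCALE * float(np.median(np.abs(res - np.median(res)))) if res.size else 0.0
    else:
        sd = float(np.std(res)) if res.size else 0.0
    means = out["mean_ratio"].to_numpy()
    out["state"] = np.where(means > k * sd, "gain", np.where(means < -k * sd, "loss", "neutral"))
    return out
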