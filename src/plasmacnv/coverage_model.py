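"""Depth-of-coverage model: window ratio values and copy-number priors.

The genome is tiled with non-overlapping windows, each containing exactly one
SNP, with breakpoints midway between adjacent SNPs.  The coverage measure for
window W_i is the *window ratio value*

    WRV_i = N_{W_i} / sum of N_W over the 200 windows with GC content
            closest to W_i

which is invariant to both sequencing depth and GC bias.  Counts are first
scaled to a 1 kb equivalent (N * 1000 / |W|) so windows of different lengths
are comparable.

A fetal CNV changes the expected plasma fragment count of the affected
windows by a factor 1 + (|PP| - 2) * r/2 (one extra or missing fetal
haplotype out of the ~2/r haplotypes contributing molecules).  Comparing the
sample WRV against a scaled reference-plasma WRV under each copy count and
modelling the residual as zero-mean Gaussian noise with empirically estimated
scale sigma_noise yields, after normalisation, a per-window prior over fetal
copy count {1, 2, 3} that the HMM injects into its transition probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6
UNIFORM_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

WINDOW_TABLE_COLUMNS = ["chrom", "start", "end", "n_sample", "n_ref", "gc"]


@dataclass
class WindowRecord:
    """A genomic window with fragment counts for sample and reference plasma.

    Coordinates are 0-based half-open (BED convention).
    """

    chrom: str
    start: int
    end: int
    n_fragments_sample: float
    n_fragments_ref: float
    gc_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoveragePrior:
    """Normalised probabilities over fetal copy count (1, 2, 3) for a window."""

    probs: Tuple[float, float, float]
    sigma_noise: float

    def __post_init__(self) -> None:
        total = sum(self.probs)
        if not np.isclose(total, 1.0):
            raise ValueError(f"copy-number prior must sum to 1, got {total}")


class CoverageError(ValueError):
    pass


def scale_to_1kb(count: float, window_length: int) -> float:
    """Scale a fragment count to its 1 kb-window equivalent."""
    if window_length <= 0:
        raise CoverageError(f"window length must be positive, got {window_length}")
    return count * 1000.0 / window_length


def windows_to_frame(windows: Sequence[WindowRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_sample": w.n_fragments_sample, "n_ref": w.n_fragments_ref,
                "gc": w.gc_fraction,
            }
            for w in windows
        ],
        columns=WINDOW_TABLE_COLUMNS,
    )


def frame_to_windows(df: pd.DataFrame) -> List[WindowRecord]:
    return [
        WindowRecord(str(r.chrom), int(r.start), int(r.end),
                     float(r.n_sample), float(r.n_ref), float(r.gc))
        for r in df.itertuples(index=False)
    ]


def gc_neighbors(
    window: WindowRecord, all_windows: Sequence[WindowRecord], k: int = 200
) -> List[WindowRecord]:
    """The k windows (excluding the query) with GC content closest to it.

    Ties in |delta GC| are broken deterministically by genomic order.  Raises
    if fewer than k other windows are available rather than silently
    shrinking the neighbourhood.
    """
    others = [w for w in all_windows if w is not window]
    if len(others) < k:
        raise CoverageError(
            f"need {k} GC neighbours but only {len(others)} other windows available"
        )
    ranked = sorted(
        others,
        key=lambda w: (abs(w.gc_fraction - window.gc_fraction),
                       w.chrom, w.start),
    )
    return ranked[:k]


def compute_wrv(
    window: WindowRecord, neighbors: Sequence[WindowRecord], use_ref: bool = False
) -> float:
    """Window ratio value: 1 kb-scaled count over the summed neighbour counts."""
    if use_ref:
        num = scale_to_1kb(window.n_fragments_ref, window.length)
        den = sum(scale_to_1kb(w.n_fragments_ref, w.length) for w in neighbors)
    else:
        num = scale_to_1kb(window.n_fragments_sample, window.length)
        den = sum(scale_to_1kb(w.n_fragments_sample, w.length) for w in neighbors)
    if den <= 0:
        raise CoverageError("zero neighbour fragment sum; region unanalyzable")
    return num / den


def scaled_reference_wrv(
    window: WindowRecord,
    neighbors: Sequence[WindowRecord],
    copy_count: int,
    r: float,
) -> float:
    """Reference WRV rescaled to the expectation under fetal copy count |PP|."""
    if copy_count not in (1, 2, 3):
        raise CoverageError(f"copy count must be 1, 2 or 3, got {copy_count}")
    return compute_wrv(window, neighbors, use_ref=True) * (
        1.0 + (copy_count - 2) * r / 2.0
    )


def robust_sigma(residuals: np.ndarray, floor: float = SIGMA_FLOOR) -> float:
    """1.4826 x median absolute deviation, floored away from zero."""
    res = np.asarray(residuals, dtype=float)
    res = res[np.isfinite(res)]
    if res.size == 0:
        return floor
    mad = np.median(np.abs(res - np.median(res)))
    return max(1.4826 * float(mad), floor)


# ---------------------------------------------------------------------------
# bulk WRV computation
# ---------------------------------------------------------------------------

def wrv_table(df: pd.DataFrame, k: int = 200) -> pd.DataFrame:
    """Compute sample and reference WRVs for every window in a table.

    Neighbourhoods are found on the GC-sorted axis (the k nearest-GC windows
    form a contiguous run there), which makes the whole computation
    O(n log n).  Returns a copy of ``df`` with ``wrv_sample`` and ``wrv_ref``
    columns; windows whose neighbour sum is zero get NaN.
    """
    n = len(df)
    if n < k + 1:
        raise CoverageError(
            f"need {k} GC neighbours but only {n - 1} other windows available"
        )
    length = (df["end"] - df["start"]).to_numpy(dtype=float)
    if np.any(length <= 0):
        raise CoverageError("zero-length window in table")
    scaled_s = df["n_sample"].to_numpy(dtype=float) * 1000.0 / length
    scaled_r = df["n_ref"].to_numpy(dtype=float) * 1000.0 / length
    gc = df["gc"].to_numpy(dtype=float)

    order = np.argsort(gc, kind="stable")
    gc_s = gc[order]
    ps = np.concatenate([[0.0], np.cumsum(scaled_s[order])])
    pr = np.concatenate([[0.0], np.cumsum(scaled_r[order])])

    denom_s = np.empty(n)
    denom_r = np.empty(n)
    lo = 0  # left edge of the (k+1)-wide run; monotone in i
    for i in range(n):
        lo = max(lo, i - k)
        hi = min(i, n - k - 1)
        if lo > hi:
            lo = hi
        # slide right while that brings the run closer in GC to gc_s[i]
        while lo < hi and (gc_s[i] - gc_s[lo]) > (gc_s[lo + k + 1] - gc_s[i]):
            lo += 1
        denom_s[i] = ps[lo + k + 1] - ps[lo] - scaled_s[order[i]]
        denom_r[i] = pr[lo + k + 1] - pr[lo] - scaled_r[order[i]]

    out = df.copy()
    wrv_s = np.full(n, np.nan)
    wrv_r = np.full(n, np.nan)
    inv = np.empty(n, dtype=np.int64)
    inv[order] = np.arange(n)
    ds = denom_s[inv]
    dr = denom_r[inv]
    ok_s = ds > 0
    ok_r = dr > 0
    wrv_s[ok_s] = scaled_s[ok_s] / ds[ok_s]
    wrv_r[ok_r] = scaled_r[ok_r] / dr[ok_r]
    out["wrv_sample"] = wrv_s
    out["wrv_ref"] = wrv_r
    return out


def estimate_sigma_noise(
    df: pd.DataFrame,
    k: int = 200,
    min_windows: int = 1000,
    floor: float = SIGMA_FLOOR,
) -> float:
    """Robust scale of the genome-wide copy-2 WRV residuals (ref - sample).

    True CNVs and the heavy coverage tail of plasma cfDNA inflate a naive
    standard deviation, so a MAD-based estimate is used.
    """
    if len(df) < min_windows:
        raise CoverageError(
            f"need at least {min_windows} windows to estimate sigma_noise, "
            f"got {len(df)}"
        )
    tab = df if "wrv_sample" in df.columns else wrv_table(df, k=k)
    res = (tab["wrv_ref"] - tab["wrv_sample"]).to_numpy(dtype=float)
    return robust_sigma(res, floor=floor)


def copy_number_prior(
    window: WindowRecord,
    neighbors_sample: Sequence[WindowRecord],
    neighbors_ref: Sequence[WindowRecord],
    r: float,
    sigma: float,
) -> CoveragePrior:
    """Normalised prior over fetal copy count {1,2,3} for one window.

    Evaluates the zero-mean Gaussian noise density at the residual between
    the copy-count-scaled reference WRV and the sample WRV.  On any WRV
    failure the window falls back to the uninformative prior.
    """
    try:
        wrv_s = compute_wrv(window, neighbors_sample, use_ref=False)
        dens = np.array([
            norm.pdf(scaled_reference_wrv(window, neighbors_ref, cc, r) - wrv_s,
                     loc=0.0, scale=sigma)
            for cc in (1, 2, 3)
        ])
    except CoverageError as exc:
        logger.warning("window %s:%d-%d unanalyzable (%s); uninformative prior",
                       window.chrom, window.start, window.end, exc)
        return CoveragePrior(UNIFORM_PRIOR, sigma)
    total = dens.sum()
    if not np.isfinite(total) or total <= 0:
        logger.warning("degenerate prior densities for window %s:%d-%d; "
                       "uninformative prior", window.chrom, window.start, window.end)
        return CoveragePrior(UNIFORM_PRIOR, sigma)
    p = dens / total
    return CoveragePrior((float(p[0]), float(p[1]), float(p[2])), sigma)


def coverage_priors(
    df: pd.DataFrame,
    r: float,
    sigma: Optional[float] = None,
    k: int = 200,
) -> Tuple[np.ndarray, float]:
    """Copy-number priors for every window, shape (n, 3); also returns sigma.

    Densities are computed in log space for numerical safety; windows with
    undefined WRVs fall back to the uniform prior (with a logged count).
    """
    tab = df if "wrv_sample" in df.columns else wrv_table(df, k=k)
    if sigma is None:
        sigma = estimate_sigma_noise(tab, k=k)
    wrv_s = tab["wrv_sample"].to_numpy(dtype=float)
    wrv_r = tab["wrv_ref"].to_numpy(dtype=float)
    res = np.stack(
        [wrv_r * (1.0 + (cc - 2) * r / 2.0) - wrv_s for cc in (1, 2, 3)], axis=1
    )
    logdens = -0.5 * (res / sigma) ** 2  # shared normalisation constant drops
    logdens -= logdens.max(axis=1, keepdims=True)
    dens = np.exp(logdens)
    priors = dens / dens.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(priors).all(axis=1)
    if bad.any():
        logger.warning("%d windows with undefined WRVs get the uniform prior",
                       int(bad.sum()))
        priors[bad] = np.array(UNIFORM_PRIOR)
    return priors, float(sigma)


def rebin_windows(df: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Re-tile per-SNP windows into fixed-size bins (for the coverage-only
    baseline).  Fragment counts are split by overlap fraction; GC is the
    length-weighted mean."""
    if bin_size <= 0:
        raise CoverageError("bin size must be positive")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        start = int(sub["start"].min())
        end = int(sub["end"].max())
        first = (start // bin_size) * bin_size
        edges = np.arange(first, end + bin_size, bin_size)
        nbins = len(edges) - 1
        ns = np.zeros(nbins)
        nr = np.zeros(nbins)
        gc_w = np.zeros(nbins)
        length = np.zeros(nbins)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        cs = sub["n_sample"].to_numpy(dtype=float)
        cr = sub["n_ref"].to_numpy(dtype=float)
        gc = sub["gc"].to_numpy(dtype=float)
        for ws, we, a, b, g in zip(s, e, cs, cr, gc):
            b0 = max(0, (ws - first) // bin_size)
            b1 = min(nbins - 1, (we - 1 - first) // bin_size)
            for bi in range(int(b0), int(b1) + 1):
                lo = max(ws, edges[bi])
                hi = min(we, edges[bi + 1])
                if hi <= lo:
                    continue
                frac = (hi - lo) / (we - ws)
                ns[bi] += a * frac
                nr[bi] += b * frac
                gc_w[bi] += g * (hi - lo)
                length[bi] += hi - lo
        keep = length > 0
        for bi in np.nonzero(keep)[0]:
            rows.append({
                "chrom": chrom,
                "start": int(edges[bi]),
                "end": int(edges[bi + 1]),
                "n_sample": ns[bi],
                "n_ref": nr[bi],
                "gc": gc_w[bi] / length[bi],
            })
    return pd.DataFrame(rows, columns=WINDOW_TABLE_COLUMNS)
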