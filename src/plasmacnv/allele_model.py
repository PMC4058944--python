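"""Plasma allele-distribution model at SNP loci.

Maternal plasma cfDNA is a mixture of maternal DNA (fraction ``1 - r``) and
fetal DNA (fraction ``r``).  At a biallelic SNP the nucleotide counts observed
in plasma reads therefore reflect both the two maternal haplotypes and the
fetal haplotypes the fetus actually inherited.  Conditional on a phased
inheritance pattern PP this module computes the expected nucleotide
distribution and the probability of an observed count vector, modelling the
four counts as independent Gaussians with variance equal to the mean (a
Poisson approximation that is more robust to noisy plasma coverage than the
exact multinomial).

The fetal copy count |PP| changes the local fetal fraction: an extra fetal
copy contributes extra fetal molecules, a deletion removes them, so ``r`` is
first adjusted to

    r' = (|PP| r / 2) / (|PP| r / 2 + (1 - r))

and each fetal haplotype contributes ``r'/|PP|`` of the molecules while
maternal haplotype ``i`` contributes ``m_i (1 - r')``, where ``m_i`` are the
maternal haplotype weights observed in maternal-only sequencing (with a
pseudocount ``alpha`` for regularisation; this also absorbs maternal CNVs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .patterns import PhasedPattern, enumerate_patterns

NUCLEOTIDES = ("A", "C", "G", "T")
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: floor applied to every expected count before evaluating the Gaussian, so
#: sequencing-error reads on nucleotides carried by no haplotype get a finite
#: log-density instead of -inf.
MU_FLOOR = 0.5


@dataclass(frozen=True)
class AdmixtureParams:
    """Fetal cfDNA fraction ``r`` and maternal-weight pseudocount ``alpha``."""

    r: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"fetal fraction r must be in (0, 1), got {self.r}")
        if self.alpha < 0:
            raise ValueError(f"pseudocount alpha must be >= 0, got {self.alpha}")


@dataclass
class SnpSite:
    """A SNP locus with phased parental alleles and observed counts.

    ``maternal_counts`` are nucleotide counts from the maternal-only sample
    (used for the haplotype weights m_i); ``plasma_counts`` are the
    nucleotide counts k_x from the plasma sample.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    maternal_haps: Tuple[str, str]  # alleles of (M_A, M_B)
    paternal_haps: Tuple[str, str]  # alleles of (P_A, P_B)
    maternal_counts: Dict[str, int] = field(default_factory=dict)
    plasma_counts: Dict[str, int] = field(default_factory=dict)

    def plasma_total(self) -> int:
        return sum(self.plasma_counts.get(n, 0) for n in NUCLEOTIDES)

    @property
    def is_uninformative(self) -> bool:
        """True when both parents are homozygous for the same allele.

        Such sites carry no allelic-ratio signal (every pattern predicts the
        same distribution); they remain HMM positions so the coverage prior
        can still act there.
        """
        a = self.maternal_haps[0]
        return (
            self.maternal_haps[1] == a
            and self.paternal_haps[0] == a
            and self.paternal_haps[1] == a
        )


class InvalidPatternError(ValueError):
    pass


class FetalFractionError(ValueError):
    pass


def adjust_fetal_fraction(r: float, copy_count: int) -> float:
    """Local fetal fraction r' given the fetal copy count |PP|.

    Strictly increasing in ``copy_count``; the identity at |PP| = 2.
    """
    if copy_count not in (1, 2, 3):
        raise InvalidPatternError(f"copy count must be 1, 2 or 3, got {copy_count}")
    if not 0.0 < r < 1.0:
        raise ValueError(f"fetal fraction r must be in (0, 1), got {r}")
    fetal = copy_count * r / 2.0
    return fetal / (fetal + (1.0 - r))


def maternal_allele_weights(site: SnpSite, alpha: float) -> Tuple[float, float]:
    """Pseudocounted weights (m_A, m_B) of the two maternal haplotypes.

    For a heterozygous mother the weights are the allele fractions observed
    in the maternal-only sample, smoothed by ``alpha``.  For a homozygous
    mother reads cannot be assigned to a haplotype, so both weights are 0.5
    (the shared allele then correctly receives the full maternal mass).
    """
    a1, a2 = site.maternal_haps
    if a1 == a2:
        return (0.5, 0.5)
    c1 = site.maternal_counts.get(a1, 0)
    c2 = site.maternal_counts.get(a2, 0)
    denom = 2.0 * alpha + c1 + c2
    if denom == 0.0:
        return (0.5, 0.5)
    return ((alpha + c1) / denom, (alpha + c2) / denom)


def _resolve(site: SnpSite, label: str) -> str:
    if label == "M_A":
        return site.maternal_haps[0]
    if label == "M_B":
        return site.maternal_haps[1]
    if label == "P_A":
        return site.paternal_haps[0]
    if label == "P_B":
        return site.paternal_haps[1]
    raise InvalidPatternError(f"unknown haplotype label {label!r}")


def expected_allele_probs(
    site: SnpSite, pattern: PhasedPattern, params: AdmixtureParams
) -> Dict[str, float]:
    """Expected plasma nucleotide probabilities p_x under ``pattern``.

    Each maternal haplotype i contributes ``m_i (1 - r')`` to its allele and
    each fetal haplotype in PP contributes ``r'/|PP|``; the four values sum
    to 1 exactly (before any floor applied downstream).
    """
    r_adj = adjust_fetal_fraction(params.r, pattern.copy_count)
    weights = maternal_allele_weights(site, params.alpha)
    p = {n: 0.0 for n in NUCLEOTIDES}
    for m_allele, w in zip(site.maternal_haps, weights):
        p[m_allele] += w * (1.0 - r_adj)
    share = r_adj / pattern.copy_count
    for label in pattern.fetal_haplotypes:
        p[_resolve(site, label)] += share
    return p


def expected_counts(probs: Mapping[str, float], total_reads: int) -> Dict[str, float]:
    """Expected read counts mu_x = p_x * total mapped reads."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    return {n: probs.get(n, 0.0) * total_reads for n in NUCLEOTIDES}


def _gaussian_logpdf(k: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """log N(k; mean=mu, var=mu), evaluated as a continuous density."""
    return -0.5 * (np.log(2.0 * math.pi * mu) + (k - mu) ** 2 / mu)


def _floor_and_renormalize(mu: np.ndarray, total: float) -> np.ndarray:
    """Apply the MU_FLOOR and rescale so the floored mu still sum to total."""
    mu = np.maximum(mu, MU_FLOOR)
    if total > 0:
        mu = mu * (total / mu.sum(axis=-1, keepdims=True))
        mu = np.maximum(mu, MU_FLOOR)
    return mu


def emission_logprob(
    site: SnpSite, pattern: PhasedPattern, params: AdmixtureParams
) -> float:
    """Log-probability of the observed plasma counts under ``pattern``.

    Sum over the four nucleotides of the log Gaussian density with mean and
    variance mu_x evaluated at k_x, after flooring mu_x at ``MU_FLOOR``.
    Finite for any finite counts.
    """
    probs = expected_allele_probs(site, pattern, params)
    total = site.plasma_total()
    mu = np.array([probs[n] * total for n in NUCLEOTIDES])
    mu = _floor_and_renormalize(mu, float(total))
    k = np.array([site.plasma_counts.get(n, 0) for n in NUCLEOTIDES], dtype=float)
    return float(_gaussian_logpdf(k, mu).sum())


# ---------------------------------------------------------------------------
# vectorized bulk interface over SNP tables
# ---------------------------------------------------------------------------

SNP_TABLE_COLUMNS = [
    "chrom", "pos", "mA", "mB", "pA", "pB",
    "mat_A", "mat_C", "mat_G", "mat_T",
    "pla_A", "pla_C", "pla_G", "pla_T",
]


def sites_to_frame(sites: Sequence[SnpSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "chrom": s.chrom, "pos": s.pos,
            "mA": s.maternal_haps[0], "mB": s.maternal_haps[1],
            "pA": s.paternal_haps[0], "pB": s.paternal_haps[1],
        }
        for n in NUCLEOTIDES:
            row[f"mat_{n}"] = s.maternal_counts.get(n, 0)
            row[f"pla_{n}"] = s.plasma_counts.get(n, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=SNP_TABLE_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> List[SnpSite]:
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            SnpSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                maternal_haps=(row.mA, row.mB),
                paternal_haps=(row.pA, row.pB),
                maternal_counts={n: int(getattr(row, f"mat_{n}")) for n in NUCLEOTIDES},
                plasma_counts={n: int(getattr(row, f"pla_{n}")) for n in NUCLEOTIDES},
            )
        )
    return sites


def _allele_indices(df: pd.DataFrame, col: str) -> np.ndarray:
    return df[col].map(_NUC_INDEX).to_numpy(dtype=np.int64)


def default_alpha(df: pd.DataFrame, factor: float = 1.0) -> float:
    """Default pseudocount: genome-wide mean per-site maternal depth.

    A pseudocount of this size shrinks the per-site maternal haplotype
    weights roughly half-way toward 1/2, which suppresses the binomial
    measurement noise of the maternal-only sample (otherwise absorbed by
    the more flexible duplication states as spurious signal) while still
    letting large genuine imbalances (maternal CNVs) shift the weights.
    """
    mat = df[[f"mat_{n}" for n in NUCLEOTIDES]].to_numpy(dtype=float)
    depth = mat.sum(axis=1).mean() if len(df) else 0.0
    return factor * depth


def emission_matrix(df: pd.DataFrame, params: AdmixtureParams) -> np.ndarray:
    """Per-site log emission for all 20 canonical states, shape (n, 20).

    Sites where both parents are homozygous for the same allele carry no
    allelic-ratio information; their emission row is constant (0) so only
    the coverage prior acts there.
    """
    n = len(df)
    patterns = enumerate_patterns()
    out = np.zeros((n, len(patterns)))
    if n == 0:
        return out

    idx = {lab: _allele_indices(df, col)
           for lab, col in (("M_A", "mA"), ("M_B", "mB"), ("P_A", "pA"), ("P_B", "pB"))}
    onehot = {lab: np.eye(4)[v] for lab, v in idx.items()}  # (n, 4) each

    mat = df[[f"mat_{n_}" for n_ in NUCLEOTIDES]].to_numpy(dtype=float)
    pla = df[[f"pla_{n_}" for n_ in NUCLEOTIDES]].to_numpy(dtype=float)
    total = pla.sum(axis=1)

    # maternal haplotype weights (Eq-4-style pseudocounted fractions)
    cA = np.take_along_axis(mat, idx["M_A"][:, None], axis=1)[:, 0]
    cB = np.take_along_axis(mat, idx["M_B"][:, None], axis=1)[:, 0]
    het = idx["M_A"] != idx["M_B"]
    denom = 2.0 * params.alpha + cA + cB
    wA = np.full(n, 0.5)
    wB = np.full(n, 0.5)
    ok = het & (denom > 0)
    wA[ok] = (params.alpha + cA[ok]) / denom[ok]
    wB[ok] = (params.alpha + cB[ok]) / denom[ok]

    uninformative = (
        (idx["M_A"] == idx["M_B"])
        & (idx["P_A"] == idx["P_B"])
        & (idx["M_A"] == idx["P_A"])
    )

    for j, pattern in enumerate(patterns):
        r_adj = adjust_fetal_fraction(params.r, pattern.copy_count)
        p = (1.0 - r_adj) * (wA[:, None] * onehot["M_A"] + wB[:, None] * onehot["M_B"])
        share = r_adj / pattern.copy_count
        for label in pattern.fetal_haplotypes:
            p = p + share * onehot[label]
        mu = np.maximum(p * total[:, None], MU_FLOOR)
        pos = total > 0
        mu[pos] *= (total[pos] / mu[pos].sum(axis=1))[:, None]
        mu = np.maximum(mu, MU_FLOOR)
        out[:, j] = _gaussian_logpdf(pla, mu).sum(axis=1)

    out[uninformative, :] = 0.0
    return out


def estimate_fetal_fraction(
    sites: Iterable[SnpSite] | pd.DataFrame, min_sites: int = 50
) -> float:
    """Estimate the fetal cfDNA fraction r from opposite-homozygote sites.

    At loci where the mother is homozygous for one allele and the father
    homozygous for a different one, every plasma read carrying the paternal
    allele is fetal; its expected fraction is r/2.  The estimate is twice
    the median per-site paternal-allele fraction (median for robustness),
    clamped to (0.005, 0.5).
    """
    if isinstance(sites, pd.DataFrame):
        df = sites
    else:
        df = sites_to_frame(list(sites))
    if len(df) == 0:
        raise FetalFractionError("no sites supplied (0 informative)")
    mA = _allele_indices(df, "mA")
    mB = _allele_indices(df, "mB")
    pA = _allele_indices(df, "pA")
    pB = _allele_indices(df, "pB")
    pla = df[[f"pla_{n}" for n in NUCLEOTIDES]].to_numpy(dtype=float)
    total = pla.sum(axis=1)
    informative = (mA == mB) & (pA == pB) & (mA != pA) & (total > 0)
    n_inf = int(informative.sum())
    if n_inf < min_sites:
        raise FetalFractionError(
            f"only {n_inf} informative opposite-homozygote sites with coverage; "
            f"need at least {min_sites}"
        )
    pat_count = np.take_along_axis(
        pla[informative], pA[informative][:, None], axis=1
    )[:, 0]
    frac = pat_count / total[informative]
    r_hat = 2.0 * float(np.median(frac))
    return float(np.clip(r_hat, 0.005, 0.5))
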