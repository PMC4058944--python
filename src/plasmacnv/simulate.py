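"""Synthetic trio + plasma data generator and in-silico CNV spike-in.

The generator emulates the statistical structure of a deeply sequenced
pregnancy trio: SNP loci at ~1 kb mean spacing, phased parental haplotypes
drawn from a population allele-frequency model, fetal haplotypes inherited
with rare recombination, plasma nucleotide counts at ~78x total depth mixing
maternal (fraction 1-r) and fetal (fraction r) molecules, and per-window
fragment counts for the studied plasma and an independent reference plasma
with GC-dependent mean bias and variance wider than Poisson (cfDNA coverage
is strongly overdispersed).

CNVs are introduced *after* generation by editing allele-count units with
the same per-read removal/addition probabilities a read-level pipeline would
use: a duplication adds counts matching one extra fetal haplotype's expected
depth; a deletion removes each count unit with the probability that the
underlying read is fetal and from the deleted haplotype,

    r/2 / (N_m (1-r)/2 + N_f r/2)

where N_m, N_f count the maternal/fetal haplotypes carrying the allele (and
r/2 for alleles carried by no haplotype, i.e. error reads).  Down-sampling
the fetal fraction from r to r' removes each count unit with probability
r_del * p_f, where r_del = 1 - ((1-r)/r) * (r'/(1-r')) is the fraction of
fetal reads to drop and p_f is the probability the read is fetal given its
allele.  Bernoulli thinning of counts reproduces the first and second
moments of the read-level procedure exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .allele_model import NUCLEOTIDES, SNP_TABLE_COLUMNS
from .coverage_model import WINDOW_TABLE_COLUMNS
from .patterns import IpClass

_NUC = np.array(list(NUCLEOTIDES))


@dataclass(frozen=True)
class TrioSimConfig:
    """Study conditions for the synthetic trio.

    Defaults follow the deep-plasma setting the model targets: 78x plasma
    depth, 32x maternal WGS, 13% fetal fraction, ~1 kb SNP spacing.
    """

    n_snps: int = 20000
    mean_spacing_bp: float = 1000.0
    plasma_depth: float = 78.0
    maternal_depth: float = 32.0
    ref_plasma_depth: float = 78.0
    r: float = 0.13
    recomb_rate: float = 1e-8  # per bp per meiosis (~1 event / 100 Mb)
    overdispersion: float = 3.0  # variance/mean of window fragment counts
    fragment_length: float = 166.0  # typical cfDNA fragment size
    gc_bias_strength: float = 0.3
    coverage_wave_sd: float = 0.025  # sd of the per-sample segmental bias
    coverage_wave_length_bp: float = 200_000.0  # its correlation length
    error_rate: float = 0.002  # per-base sequencing error
    beta_af: float = 0.8  # symmetric Beta shape for population allele freqs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError("fetal fraction r must be in (0, 1)")
        for name in ("n_snps", "mean_spacing_bp", "plasma_depth",
                     "maternal_depth", "overdispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PlantedCnv:
    """A CNV to introduce into a simulated dataset.

    ``target_hap`` names the parental haplotype involved.  The default
    ``"transmitted"`` is the haplotype the fetus actually inherited from the
    event's parent: a de novo CNV arises on the gamete's (recombined)
    chromosome, so a duplication copies the transmitted material and a
    deletion removes it.  An explicit label (M_A/M_B/P_A/P_B) forces a
    particular parental haplotype instead; duplicating a non-transmitted
    haplotype yields allele ratios close to those of the opposite-type
    event (e.g. maternal duplication of the untransmitted haplotype mimics
    a maternal deletion), which only the coverage signal can separate.
    """

    ip_class: Union[IpClass, str]
    start: int
    end: int
    target_hap: str = "transmitted"
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        cls = IpClass(self.ip_class) if not isinstance(self.ip_class, IpClass) else self.ip_class
        if not cls.is_cnv:
            raise ValueError("planted CNV class must be one of the four CNV classes")
        if self.target_hap not in ("transmitted", "M_A", "M_B", "P_A", "P_B"):
            raise ValueError(f"unknown haplotype {self.target_hap!r}")
        if self.end <= self.start:
            raise ValueError("empty CNV interval")

    @property
    def cls(self) -> IpClass:
        return IpClass(self.ip_class)


@dataclass
class TrioTruth:
    """Ground truth of a simulated dataset.

    ``fetal_m``/``fetal_p`` give, per SNP, which parental haplotype (0 = A,
    1 = B) the fetus inherited from each parent; ``cnvs`` lists planted
    events.
    """

    fetal_m: np.ndarray
    fetal_p: np.ndarray
    cnvs: List[PlantedCnv] = field(default_factory=list)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _overdispersed_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = dispersion * mean."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1.0:
        return rng.poisson(mean)
    size = mean / (dispersion - 1.0)  # NB shape: var = m + m^2/size
    lam = rng.gamma(shape=np.maximum(size, 1e-9), scale=mean / np.maximum(size, 1e-9))
    return rng.poisson(lam)


def _with_error(p: np.ndarray, eps: float) -> np.ndarray:
    """Perturb true base probabilities by a uniform substitution error."""
    return p * (1.0 - eps) + (1.0 - p) * (eps / 3.0)


def _multinomial_rows(rng, totals: np.ndarray, probs: np.ndarray) -> np.ndarray:
    out = np.zeros_like(probs, dtype=np.int64)
    for i in range(probs.shape[1] - 1):
        rem = probs[:, i:].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(rem > 0, probs[:, i] / rem, 0.0)
        out[:, i] = rng.binomial(totals, np.clip(q, 0.0, 1.0))
        totals = totals - out[:, i]
    out[:, -1] = totals
    return out


def _inherit(rng, n: int, pos: np.ndarray, recomb_rate: float) -> np.ndarray:
    hap = np.zeros(n, dtype=np.int64)
    hap[0] = rng.integers(0, 2)
    gaps = np.diff(pos)
    switch = rng.random(n - 1) < -np.expm1(-recomb_rate * gaps)
    hap[1:] = (hap[0] + np.cumsum(switch)) % 2
    return hap


def _gc_track(rng, n: int) -> np.ndarray:
    """Spatially smooth GC fractions around 0.42 (rolling-mean AR noise)."""
    raw = rng.normal(0.0, 1.0, n + 60)
    kernel = np.ones(61) / 61.0
    smooth = np.convolve(raw, kernel, mode="valid")[:n]
    sd = smooth.std() or 1.0
    return np.clip(0.42 + 0.06 * smooth / sd, 0.25, 0.65)


def _coverage_wave(
    rng: np.random.Generator, n: int, sd: float, length_windows: int
) -> np.ndarray:
    """Smooth library-specific multiplicative coverage bias.

    Plasma cfDNA libraries show regional coverage waves that do not average
    out over large bins and differ between samples, so the studied and
    reference plasma each get an independent field.  Without this component
    fixed-size-bin coverage would become unrealistically clean as bins grow.
    """
    if sd <= 0:
        return np.ones(n)
    half = max(int(length_windows), 1)
    raw = rng.normal(0.0, 1.0, n + 2 * half)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    smooth = np.convolve(raw, kernel, mode="valid")[:n]
    scale = smooth.std()
    field = sd * smooth / scale if scale > 0 else np.zeros(n)
    return np.clip(1.0 + field, 0.2, None)


def _gc_bias(gc: np.ndarray, strength: float) -> np.ndarray:
    """Smooth unimodal mean multiplier peaking near 45% GC."""
    b = np.exp(-0.5 * ((gc - 0.45) / 0.12) ** 2)
    b = 1.0 - strength + strength * b / b.max()
    return b / b.mean()


def simulate_trio(
    config: TrioSimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, TrioTruth]:
    """Generate a synthetic trio dataset under normal fetal inheritance.

    Returns the SNP table, the per-SNP window table (sample + reference
    plasma fragment counts with GC) and the inheritance truth.  Fully
    deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    chrom = "chr1"

    spacing = rng.exponential(config.mean_spacing_bp, n)
    pos = np.maximum(1, np.ceil(np.cumsum(spacing))).astype(np.int64)
    pos = np.unique(pos)
    while len(pos) < n:  # rare collisions after rounding
        extra = np.maximum(1, np.ceil(
            pos[-1] + np.cumsum(rng.exponential(config.mean_spacing_bp, n - len(pos)))
        )).astype(np.int64)
        pos = np.unique(np.concatenate([pos, extra]))
    pos = pos[:n]

    # population allele frequencies and parental haplotypes
    freq = rng.beta(config.beta_af, config.beta_af, n)
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    haps = {}
    for name in ("mA", "mB", "pA", "pB"):
        is_alt = rng.random(n) < freq
        haps[name] = np.where(is_alt, alt_idx, ref_idx)

    fetal_m = _inherit(rng, n, pos, config.recomb_rate)
    fetal_p = _inherit(rng, n, pos, config.recomb_rate)
    fm_allele = np.where(fetal_m == 0, haps["mA"], haps["mB"])
    fp_allele = np.where(fetal_p == 0, haps["pA"], haps["pB"])

    onehot = np.eye(4)

    # maternal-only sample: the mother's two haplotypes at equal weight
    p_mat = 0.5 * onehot[haps["mA"]] + 0.5 * onehot[haps["mB"]]
    mat_tot = rng.poisson(config.maternal_depth, n)
    mat_counts = _multinomial_rows(
        rng, mat_tot, _with_error(p_mat, config.error_rate))

    # plasma: maternal fraction (1-r) over both maternal haplotypes, fetal
    # fraction r split over the two inherited haplotypes
    r = config.r
    p_pla = (1.0 - r) * p_mat + (r / 2.0) * (onehot[fm_allele] + onehot[fp_allele])
    pla_tot = _overdispersed_counts(
        rng, np.full(n, config.plasma_depth), config.overdispersion)
    pla_counts = _multinomial_rows(
        rng, pla_tot, _with_error(p_pla, config.error_rate))

    snp = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "mA": _NUC[haps["mA"]], "mB": _NUC[haps["mB"]],
        "pA": _NUC[haps["pA"]], "pB": _NUC[haps["pB"]],
    })
    for i, nuc in enumerate(NUCLEOTIDES):
        snp[f"mat_{nuc}"] = mat_counts[:, i]
    for i, nuc in enumerate(NUCLEOTIDES):
        snp[f"pla_{nuc}"] = pla_counts[:, i]
    snp = snp[SNP_TABLE_COLUMNS]

    # windows: breakpoints midway between adjacent SNPs
    mid = (pos[:-1] + pos[1:]) // 2
    starts = np.concatenate([[max(0, pos[0] - 1 - int(config.mean_spacing_bp // 2))], mid])
    ends = np.concatenate([mid, [pos[-1] + int(config.mean_spacing_bp // 2)]])
    lengths = (ends - starts).astype(float)

    gc = _gc_track(rng, n)
    bias = _gc_bias(gc, config.gc_bias_strength)
    wave_windows = config.coverage_wave_length_bp / config.mean_spacing_bp
    wave_s = _coverage_wave(rng, n, config.coverage_wave_sd, wave_windows)
    wave_r = _coverage_wave(rng, n, config.coverage_wave_sd, wave_windows)
    frag_per_kb_s = config.plasma_depth * 1000.0 / config.fragment_length
    frag_per_kb_r = config.ref_plasma_depth * 1000.0 / config.fragment_length
    mean_s = frag_per_kb_s * (lengths / 1000.0) * bias * wave_s
    mean_r = frag_per_kb_r * (lengths / 1000.0) * bias * wave_r
    n_sample = _overdispersed_counts(rng, mean_s, config.overdispersion)
    n_ref = _overdispersed_counts(rng, mean_r, config.overdispersion)

    win = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": ends,
        "n_sample": n_sample, "n_ref": n_ref, "gc": gc,
    })[WINDOW_TABLE_COLUMNS]

    return snp, win, TrioTruth(fetal_m=fetal_m, fetal_p=fetal_p)


# ---------------------------------------------------------------------------
# CNV spike-in and admixture down-sampling (count level)
# ---------------------------------------------------------------------------

def _check_region(snp: pd.DataFrame, win: pd.DataFrame, cnv: PlantedCnv) -> None:
    lo = int(win["start"].min())
    hi = int(win["end"].max())
    if cnv.start < lo or cnv.end > hi:
        raise ValueError(
            f"CNV {cnv.start}-{cnv.end} outside simulated region {lo}-{hi}"
        )


def _site_mask(snp: pd.DataFrame, cnv: PlantedCnv) -> np.ndarray:
    pos0 = snp["pos"].to_numpy() - 1  # 0-based SNP coordinate
    return (snp["chrom"].to_numpy() == cnv.chrom) & (pos0 >= cnv.start) & (pos0 < cnv.end)


def _window_overlap_frac(win: pd.DataFrame, cnv: PlantedCnv) -> np.ndarray:
    s = win["start"].to_numpy()
    e = win["end"].to_numpy()
    ov = np.clip(np.minimum(e, cnv.end) - np.maximum(s, cnv.start), 0, None)
    frac = ov / (e - s)
    frac[win["chrom"].to_numpy() != cnv.chrom] = 0.0
    return frac


def _allele_matrix(snp: pd.DataFrame, cols) -> np.ndarray:
    """(n, len(cols)) nucleotide indices for parental-haplotype columns."""
    lut = {n: i for i, n in enumerate(NUCLEOTIDES)}
    return np.stack([snp[c].map(lut).to_numpy() for c in cols], axis=1)


_HAP_COL = {"M_A": "mA", "M_B": "mB", "P_A": "pA", "P_B": "pB"}


def _duplicated_alleles(
    snp: pd.DataFrame, truth: TrioTruth, cnv: PlantedCnv
) -> np.ndarray:
    """Per-site nucleotide (letter) of the duplicated haplotype."""
    if cnv.target_hap != "transmitted":
        return snp[_HAP_COL[cnv.target_hap]].to_numpy()
    if cnv.cls is IpClass.MATERNAL_DUP:
        a = snp["mA"].to_numpy()
        b = snp["mB"].to_numpy()
        return np.where(truth.fetal_m == 0, a, b)
    a = snp["pA"].to_numpy()
    b = snp["pB"].to_numpy()
    return np.where(truth.fetal_p == 0, a, b)


def spike_duplication(
    snp: pd.DataFrame,
    win: pd.DataFrame,
    truth: TrioTruth,
    cnv: PlantedCnv,
    r: float,
    seed_or_rng=0,
) -> Tuple[pd.DataFrame, pd.DataFrame, TrioTruth]:
    """Add a fetal duplication of ``cnv.target_hap`` to a simulated dataset.

    Inside the event each SNP gains Poisson(regional depth * r/2) extra
    plasma counts on the duplicated haplotype's allele (one extra fetal
    haplotype's worth of molecules), and overlapping window counts are
    inflated by the factor 1 + r/2 in expectation.
    """
    if cnv.cls not in (IpClass.MATERNAL_DUP, IpClass.PATERNAL_DUP):
        raise ValueError("spike_duplication requires a duplication class")
    _check_region(snp, win, cnv)
    rng = _rng(seed_or_rng)
    snp = snp.copy()
    win = win.copy()

    mask = _site_mask(snp, cnv)
    pla_cols = [f"pla_{n}" for n in NUCLEOTIDES]
    if r > 0 and mask.any():
        depth_regional = snp.loc[mask, pla_cols].to_numpy().sum(axis=1).mean()
        extra = rng.poisson(depth_regional * r / 2.0, int(mask.sum()))
        alleles = _duplicated_alleles(snp, truth, cnv)[mask]
        idx = np.nonzero(mask)[0]
        pla = snp[pla_cols].to_numpy(copy=True)
        lut = {n: i for i, n in enumerate(NUCLEOTIDES)}
        for i, a, x in zip(idx, alleles, extra):
            pla[i, lut[a]] += x
        snp[pla_cols] = pla

        frac = _window_overlap_frac(win, cnv)
        add = rng.poisson(win["n_sample"].to_numpy(dtype=float) * frac * r / 2.0)
        win["n_sample"] = win["n_sample"].to_numpy() + add

    new_truth = TrioTruth(truth.fetal_m, truth.fetal_p, truth.cnvs + [cnv])
    return snp, win, new_truth


def _haplotype_membership(
    snp: pd.DataFrame, truth: TrioTruth
) -> Tuple[np.ndarray, np.ndarray]:
    """Per site and nucleotide: N_m (maternal haplotypes carrying it, 0-2)
    and N_f (fetal haplotypes carrying it, 0-2) under normal inheritance."""
    m = _allele_matrix(snp, ["mA", "mB"])  # (n, 2)
    p = _allele_matrix(snp, ["pA", "pB"])
    fm = np.where(truth.fetal_m == 0, m[:, 0], m[:, 1])
    fp = np.where(truth.fetal_p == 0, p[:, 0], p[:, 1])
    eye = np.eye(4, dtype=np.int64)
    n_m = eye[m[:, 0]] + eye[m[:, 1]]  # (n, 4)
    n_f = eye[fm] + eye[fp]
    return n_m, n_f


def spike_deletion(
    snp: pd.DataFrame,
    win: pd.DataFrame,
    truth: TrioTruth,
    cnv: PlantedCnv,
    r: float,
    seed_or_rng=0,
) -> Tuple[pd.DataFrame, pd.DataFrame, TrioTruth]:
    """Delete the fetal haplotype inherited from ``cnv``'s parent.

    Each plasma count unit is removed with the probability that the
    underlying read is fetal and comes from the deleted haplotype: alleles
    carried by the deleted haplotype are thinned with probability
    (r/2) / (N_m (1-r)/2 + N_f r/2); alleles carried by no maternal or
    fetal haplotype (error reads) with probability r/2; all other alleles
    are kept.  Window counts are deflated by r/2 over the event.
    """
    if cnv.cls not in (IpClass.MATERNAL_DEL, IpClass.PATERNAL_DEL):
        raise ValueError("spike_deletion requires a deletion class")
    _check_region(snp, win, cnv)
    rng = _rng(seed_or_rng)
    snp = snp.copy()
    win = win.copy()

    mask = _site_mask(snp, cnv)
    if mask.any():
        n_m, n_f = _haplotype_membership(snp, truth)
        m = _allele_matrix(snp, ["mA", "mB"])
        p = _allele_matrix(snp, ["pA", "pB"])
        if cnv.cls is IpClass.MATERNAL_DEL:
            deleted_allele = np.where(truth.fetal_m == 0, m[:, 0], m[:, 1])
        else:
            deleted_allele = np.where(truth.fetal_p == 0, p[:, 0], p[:, 1])
        eye_del = np.eye(4, dtype=bool)[deleted_allele]  # (n, 4)

        denom = n_m * (1.0 - r) / 2.0 + n_f * r / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            p_target = np.where(denom > 0, (r / 2.0) / denom, 0.0)
        p_remove = np.where(eye_del, p_target, 0.0)
        p_remove = np.where((n_m + n_f) == 0, r / 2.0, p_remove)
        p_remove = np.clip(p_remove, 0.0, 1.0)

        pla_cols = [f"pla_{n}" for n in NUCLEOTIDES]
        pla = snp[pla_cols].to_numpy(copy=True)
        removed = rng.binomial(pla[mask], p_remove[mask])
        pla[mask] -= removed
        snp[pla_cols] = pla

        frac = _window_overlap_frac(win, cnv)
        drop = rng.binomial(win["n_sample"].to_numpy(dtype=np.int64),
                            np.clip(frac * r / 2.0, 0.0, 1.0))
        win["n_sample"] = win["n_sample"].to_numpy() - drop

    new_truth = TrioTruth(truth.fetal_m, truth.fetal_p, truth.cnvs + [cnv])
    return snp, win, new_truth


def plant_cnv(snp, win, truth, cnv: PlantedCnv, r: float, seed_or_rng=0):
    """Dispatch to the duplication or deletion spike-in."""
    if cnv.cls in (IpClass.MATERNAL_DUP, IpClass.PATERNAL_DUP):
        return spike_duplication(snp, win, truth, cnv, r, seed_or_rng)
    return spike_deletion(snp, win, truth, cnv, r, seed_or_rng)


def fetal_deletion_fraction(r: float, r_target: float) -> float:
    """Fraction r_del of fetal-origin reads to remove to reach ``r_target``.

    Zero at ``r_target == r`` (nothing to remove); raising the target above
    the current fraction is impossible by thinning and errors.
    """
    if not 0.0 < r_target <= r:
        raise ValueError(f"target fraction must be in (0, r={r}], got {r_target}")
    return 1.0 - ((1.0 - r) / r) * (r_target / (1.0 - r_target))


def downsample_fetal_fraction(
    snp: pd.DataFrame,
    win: pd.DataFrame,
    truth: TrioTruth,
    r: float,
    r_target: float,
    seed_or_rng=0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Thin fetal-origin plasma counts so the admixture drops from r to r_target.

    Each count unit is removed with probability r_del * p_f, where p_f is
    the probability that a read with that allele is fetal:
    N_f r/2 / (N_m (1-r)/2 + N_f r/2), or r when no haplotype carries the
    allele.  Window counts lose the same overall fraction r_del * r.
    """
    r_del = fetal_deletion_fraction(r, r_target)
    rng = _rng(seed_or_rng)
    snp = snp.copy()
    win = win.copy()

    n_m, n_f = _haplotype_membership(snp, truth)
    denom = n_m * (1.0 - r) / 2.0 + n_f * r / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p_f = np.where(denom > 0, n_f * (r / 2.0) / denom, r)
    p_remove = np.clip(r_del * p_f, 0.0, 1.0)

    pla_cols = [f"pla_{n}" for n in NUCLEOTIDES]
    pla = snp[pla_cols].to_numpy(copy=True)
    pla -= rng.binomial(pla, p_remove)
    snp[pla_cols] = pla

    win["n_sample"] = win["n_sample"].to_numpy() - rng.binomial(
        win["n_sample"].to_numpy(dtype=np.int64), r_del * r
    )
    return snp, win
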