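"""Readers and writers for the SNP, window, call and VCF formats.

Coordinate conventions: VCF and the SNP table use 1-based positions; window
tables and BED output are 0-based half-open.  All tabular formats are plain
TSV with a header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .allele_model import NUCLEOTIDES, SNP_TABLE_COLUMNS, SnpSite
from .coverage_model import WINDOW_TABLE_COLUMNS
from .hmm import CnvCall

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run-level configuration; defaults match the model's fixed constants."""

    mode: str = "combined"
    fetal_fraction: Optional[float] = None
    alpha: Optional[float] = None
    within_class_p: float = 0.01
    cnv_start_p: float = 0.0001
    cnv_end_p: float = 0.001
    split_start: bool = False
    sigma_floor: float = 1e-6
    k_neighbors: int = 200
    bin_size: int = 100000
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("within_class_p", "cnv_start_p", "cnv_end_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_snp_table(path) -> pd.DataFrame:
    df = _read_tsv(path, SNP_TABLE_COLUMNS)
    count_cols = [c for c in SNP_TABLE_COLUMNS if c.startswith(("mat_", "pla_"))]
    bad = df[count_cols].isna().any(axis=1) | (df[count_cols] < 0).any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise FormatError(f"{path}: malformed counts at line {line}")
    return df[SNP_TABLE_COLUMNS]


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[SNP_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_window_table(path) -> pd.DataFrame:
    df = _read_tsv(path, WINDOW_TABLE_COLUMNS)
    bad = (df["end"] <= df["start"]) | df["gc"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: malformed window at line {line}")
    return df[WINDOW_TABLE_COLUMNS]


def write_window_table(df: pd.DataFrame, path) -> None:
    df[WINDOW_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_calls_bed(calls: Sequence[CnvCall], path) -> None:
    """BED6: chrom, start, end, name=ip_class, score, strand '.'."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.ip_class}\t"
                     f"{c.score:.4f}\t.\n")


def read_calls_bed(path) -> List[CnvCall]:
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln}: expected >=4 BED columns")
            chrom, start, end, name = parts[:4]
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            calls.append(CnvCall(chrom, int(start), int(end), name, score=score))
    return calls


def read_trio_vcf(
    path, mother: str, father: str
) -> Tuple[List[SnpSite], int]:
    """SNP site skeletons from a trio VCF with phased parental genotypes.

    Only phased ("|") biallelic SNP records are used; unphased, multiallelic
    or non-SNP records are skipped and counted.  Count fields are left zero
    for later population from count tables.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (mother, father):
        if name not in samples:
            raise FormatError(f"sample {name!r} not found in {path} "
                              f"(has: {', '.join(samples)})")
    i_m = samples.index(mother)
    i_f = samples.index(father)
    sites: List[SnpSite] = []
    skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        alleles = (rec.REF, alts[0])
        gts = rec.genotypes  # [allele_a, allele_b, phased]
        gm, gf = gts[i_m], gts[i_f]
        if not (gm[2] and gf[2]) or min(gm[0], gm[1], gf[0], gf[1]) < 0:
            skipped += 1
            continue
        sites.append(SnpSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            maternal_haps=(alleles[gm[0]], alleles[gm[1]]),
            paternal_haps=(alleles[gf[0]], alleles[gf[1]]),
            maternal_counts={n: 0 for n in NUCLEOTIDES},
            plasma_counts={n: 0 for n in NUCLEOTIDES},
        ))
    if skipped:
        logger.warning("%s: skipped %d unphased/multiallelic/non-SNP records",
                       path, skipped)
    return sites, skipped
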