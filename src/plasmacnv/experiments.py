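"""Reusable simulation experiments: spike-in recall and false-call runs.

Each replicate simulates an independent synthetic trio over a ~20 Mb region
(20 000 SNPs at ~1 kb spacing, 78x plasma, 13% fetal fraction), plants one
CNV with class cycling over the four CNV classes and length drawn uniformly
from the requested range, runs a caller, and scores it under the same-type
>=50%-span rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caller import CoverageOnlyCnvCaller, HmmCnvCaller
from .hmm import CnvCall, collapse_parent_of_origin, evaluate_calls
from .patterns import CNV_CLASSES
from .simulate import PlantedCnv, TrioSimConfig, plant_cnv, simulate_trio

DEFAULT_N_SNPS = 20_000
DEFAULT_R = 0.13
EDGE_MARGIN = 1_000_000  # keep events away from region ends


@dataclass
class ReplicateResult:
    seed: int
    cnv: Optional[PlantedCnv]
    calls: List[CnvCall]
    recalled: Optional[bool]


def simulate_with_cnv(
    seed: int,
    size_range: Tuple[int, int],
    cls_index: int,
    n_snps: int = DEFAULT_N_SNPS,
    r: float = DEFAULT_R,
) -> Tuple[pd.DataFrame, pd.DataFrame, PlantedCnv]:
    """One replicate dataset with a single planted CNV."""
    rng = np.random.default_rng(seed)
    cfg = TrioSimConfig(n_snps=n_snps, r=r, seed=seed)
    snp, win, truth = simulate_trio(cfg)
    region_end = int(win["end"].max())
    cls = CNV_CLASSES[cls_index % len(CNV_CLASSES)]
    length = int(rng.uniform(*size_range))
    start = int(rng.uniform(EDGE_MARGIN, region_end - EDGE_MARGIN - length))
    cnv = PlantedCnv(cls.value, start, start + length)
    snp, win, truth = plant_cnv(snp, win, truth, cnv, r, rng)
    return snp, win, cnv


def _truth_call(cnv: PlantedCnv) -> CnvCall:
    return CnvCall(cnv.chrom, cnv.start, cnv.end, cnv.cls.value)


def recall_experiment(
    seeds: Sequence[int],
    size_range: Tuple[int, int],
    mode: str = "combined",
    bin_size: int = 100_000,
    n_snps: int = DEFAULT_N_SNPS,
    r: float = DEFAULT_R,
    k_bins: int = 30,
) -> dict:
    """Plant one CNV per replicate; report recall under the >=50%-span rule.

    ``mode`` is "combined", "ratios_only" or "coverage_only" (the latter
    scores dup/del only, since a 3-state depth model cannot see parental
    origin).
    """
    results: List[ReplicateResult] = []
    truth_calls: List[CnvCall] = []
    for i, seed in enumerate(seeds):
        snp, win, cnv = simulate_with_cnv(seed, size_range, i, n_snps=n_snps, r=r)
        if mode == "coverage_only":
            caller = CoverageOnlyCnvCaller(
                fetal_fraction=r, bin_size=bin_size, k_neighbors=k_bins
            ).fit(win)
            calls = caller.call(win)
            truth = collapse_parent_of_origin([_truth_call(cnv)])
        else:
            caller = HmmCnvCaller(fetal_fraction=r, mode=mode).fit(snp, win)
            calls = caller.call(snp, win)
            truth = [_truth_call(cnv)]
        ev = evaluate_calls(truth, calls)
        recalled = ev["per_class"][truth[0].ip_class]["recall"] == 1.0
        results.append(ReplicateResult(seed, cnv, calls, recalled))
        truth_calls.append(truth[0])
    per_class: dict = {}
    for res, t in zip(results, truth_calls):
        d = per_class.setdefault(t.ip_class, {"n": 0, "recalled": 0})
        d["n"] += 1
        d["recalled"] += int(res.recalled)
    return {
        "recall": float(np.mean([r_.recalled for r_ in results])),
        "per_class": {
            c: d["recalled"] / d["n"] for c, d in sorted(per_class.items())
        },
        "n": len(results),
        "replicates": results,
    }


def false_call_experiment(
    seeds: Sequence[int],
    n_snps: int = DEFAULT_N_SNPS,
    r: float = DEFAULT_R,
) -> dict:
    """Combined-mode calls on CNV-free genomes (false-call control)."""
    counts = []
    for seed in seeds:
        cfg = TrioSimConfig(n_snps=n_snps, r=r, seed=seed)
        snp, win, _ = simulate_trio(cfg)
        caller = HmmCnvCaller(fetal_fraction=r).fit(snp, win)
        counts.append(len(caller.call(snp, win)))
    return {
        "per_genome": counts,
        "mean": float(np.mean(counts)),
        "n": len(seeds),
    }
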