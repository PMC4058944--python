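"""The 20-state CNV inference HMM and its coverage-only 3-state baseline.

States are the 20 phased inheritance patterns in canonical order.  Emissions
at each SNP are the plasma nucleotide counts scored by the allele model.
The transition structure encodes three fixed rates:

* 0.01 between distinct states of the same inheritance class (recombination
  or phasing errors within a haplotype block),
* 0.0001 from any normal state into each CNV state (a CNV starts about once
  in ten thousand SNP loci),
* 0.001 from any CNV state back into each normal state (CNVs span about a
  thousand SNP loci).

Direct transitions between two CNV classes are forbidden: two CNVs cannot be
adjacent, so every switch goes through normal inheritance.  The depth-of-
coverage signal enters as a position-specific prior over fetal copy count:
every transition probability *into* a state is multiplied by the prior of
that state's copy count and rows are renormalised, giving one transition
matrix per SNP position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .allele_model import AdmixtureParams, emission_matrix
from .coverage_model import CoveragePrior, rebin_windows, robust_sigma, wrv_table
from .patterns import (
    CLASS_SLICES,
    N_STATES,
    IpClass,
    state_classes,
    state_copy_counts,
)

logger = logging.getLogger(__name__)

WITHIN_CLASS_P = 0.01
CNV_START_P = 0.0001
CNV_END_P = 0.001

NORMAL_STATES = np.arange(4)


@dataclass
class CnvCall:
    """A called (or true) CNV interval; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    ip_class: str
    n_snps: int = 1
    score: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.ip_class, IpClass):
            self.ip_class = self.ip_class.value
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def base_transitions(
    within_class_p: float = WITHIN_CLASS_P,
    cnv_start_p: float = CNV_START_P,
    cnv_end_p: float = CNV_END_P,
    split_start: bool = False,
) -> np.ndarray:
    """The 20x20 base transition matrix from the three fixed rates.

    ``split_start`` divides the CNV-start mass across the 16 CNV states
    instead of assigning it per target state (an alternative reading of the
    one-in-ten-thousand rate); default is per-state.
    """
    classes = state_classes()
    start_p = cnv_start_p / 16.0 if split_start else cnv_start_p
    T = np.zeros((N_STATES, N_STATES))
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            if i == j:
                continue
            if ci == cj:
                T[i, j] = within_class_p
            elif ci == IpClass.NORMAL and cj.is_cnv:
                T[i, j] = start_p
            elif ci.is_cnv and cj == IpClass.NORMAL:
                T[i, j] = cnv_end_p
            # CNV class -> different CNV class stays 0
        T[i, i] = 1.0 - T[i].sum()
    return T


_CC_TO_COL = {1: 0, 2: 1, 3: 2}


def _prior_array(
    priors: Union[np.ndarray, Sequence[CoveragePrior]], n: Optional[int] = None
) -> np.ndarray:
    if isinstance(priors, np.ndarray):
        arr = priors
    else:
        arr = np.array([p.probs for p in priors], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("priors must have shape (n_sites, 3)")
    if n is not None and len(arr) != n:
        raise ValueError(f"{len(arr)} priors for {n} sites; they must align 1:1")
    return arr


def inject_coverage_priors(
    base: np.ndarray, prior: Union[CoveragePrior, np.ndarray]
) -> np.ndarray:
    """Multiply transitions into each state by its copy-count prior; renormalise.

    A uniform (1/3, 1/3, 1/3) prior reproduces the base matrix exactly.
    """
    w = np.asarray(prior.probs if isinstance(prior, CoveragePrior) else prior,
                   dtype=float)
    cc_cols = np.array([_CC_TO_COL[c] for c in state_copy_counts()])
    M = base * w[cc_cols][None, :]
    return M / M.sum(axis=1, keepdims=True)


def _viterbi(
    log_emissions: np.ndarray,
    log_init: np.ndarray,
    base: np.ndarray,
    prior_arr: Optional[np.ndarray],
) -> Tuple[np.ndarray, float]:
    """Max-probability path in log space; ties go to the lowest state index."""
    n, S = log_emissions.shape
    cc_cols = np.array([_CC_TO_COL[c] for c in state_copy_counts()]) if S == N_STATES else None
    with np.errstate(divide="ignore"):
        log_base = np.log(base)
    back = np.zeros((n, S), dtype=np.int8)
    delta = log_init + log_emissions[0]
    for t in range(1, n):
        if prior_arr is not None:
            M = base * prior_arr[t][cc_cols][None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                logM = np.log(M / M.sum(axis=1, keepdims=True))
        else:
            logM = log_base
        cand = delta[:, None] + logM
        back[t] = np.argmax(cand, axis=0)  # first max = lowest index
        delta = cand[back[t], np.arange(S)] + log_emissions[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(delta[path[-1]])


def viterbi_decode(
    sites: pd.DataFrame,
    priors: Optional[Union[np.ndarray, Sequence[CoveragePrior]]],
    params: AdmixtureParams,
    mode: str = "combined",
    base: Optional[np.ndarray] = None,
    emissions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Decode the most likely phased-pattern path over ordered SNP sites.

    ``mode="ratios_only"`` ignores the coverage priors; ``"combined"``
    injects them into every position's transition matrix.  The initial
    distribution is uniform over the 4 normal states.
    """
    if mode not in ("combined", "ratios_only"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(sites)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = sites["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("sites must be sorted by position")
    if emissions is None:
        emissions = emission_matrix(sites, params)
    prior_arr = None
    if mode == "combined":
        if priors is None:
            raise ValueError("combined mode requires coverage priors")
        prior_arr = _prior_array(priors, n)
    if base is None:
        base = base_transitions()
    log_init = np.full(N_STATES, -np.inf)
    log_init[NORMAL_STATES] = -np.log(len(NORMAL_STATES))
    path, _ = _viterbi(emissions, log_init, base, prior_arr)
    return path


def calls_from_path(
    path: np.ndarray,
    sites: pd.DataFrame,
    emissions: Optional[np.ndarray] = None,
) -> List[CnvCall]:
    """Collapse a decoded state path into CNV calls.

    Maximal runs of states sharing a CNV class become one call each (phase
    switches within the class do not split a run).  Call boundaries are the
    midpoints to the flanking SNPs, matching the coverage-window breakpoints.
    The score is the mean per-SNP emission log-odds of the decoded state
    versus the best normal state (0 if emissions are not supplied).
    """
    n = len(path)
    if n != len(sites):
        raise ValueError("path and sites must align")
    if n == 0:
        return []
    classes = state_classes()
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    calls: List[CnvCall] = []
    i = 0
    while i < n:
        cls = classes[path[i]]
        j = i
        while j + 1 < n and classes[path[j + 1]] == cls and chroms[j + 1] == chroms[i]:
            j += 1
        if cls.is_cnv:
            start = int((pos[i - 1] + pos[i]) // 2) if i > 0 and chroms[i - 1] == chroms[i] else int(pos[i] - 1)
            end = int((pos[j] + pos[j + 1]) // 2) if j + 1 < n and chroms[j + 1] == chroms[j] else int(pos[j])
            score = 0.0
            if emissions is not None:
                seg = np.arange(i, j + 1)
                best_normal = emissions[seg][:, CLASS_SLICES[IpClass.NORMAL]].max(axis=1)
                score = float(np.mean(emissions[seg, path[seg]] - best_normal))
            calls.append(CnvCall(str(chroms[i]), start, end, cls.value,
                                 n_snps=j - i + 1, score=score))
        i = j + 1
    return calls


# ---------------------------------------------------------------------------
# evaluation under the >=50 %-span rule
# ---------------------------------------------------------------------------

def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _union_coverage(truth: CnvCall, preds: Sequence[CnvCall]) -> int:
    """Total truth-interval length covered by the union of predictions."""
    segs = sorted(
        (max(truth.start, p.start), min(truth.end, p.end))
        for p in preds
        if p.chrom == truth.chrom and _overlap(truth.start, truth.end, p.start, p.end) > 0
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def evaluate_calls(
    truth: Sequence[CnvCall], predicted: Sequence[CnvCall]
) -> dict:
    """Recall/precision under the same-type >=50 %-span rule.

    A truth event is recalled iff the union of same-class predictions covers
    at least half of its length; a predicted call is correct iff it overlaps
    a same-class truth event.  Reported per class and overall.
    """
    classes = sorted({c.ip_class for c in truth} | {c.ip_class for c in predicted})
    per_class = {}
    tot_recalled = tot_truth = tot_correct = tot_pred = 0
    for cls in classes:
        t_cls = [t for t in truth if t.ip_class == cls]
        p_cls = [p for p in predicted if p.ip_class == cls]
        recalled = sum(
            1 for t in t_cls if _union_coverage(t, p_cls) * 2 >= t.length
        )
        correct = sum(
            1 for p in p_cls
            if any(p.chrom == t.chrom and _overlap(t.start, t.end, p.start, p.end) > 0
                   for t in t_cls)
        )
        per_class[cls] = {
            "n_truth": len(t_cls),
            "n_calls": len(p_cls),
            "recall": recalled / len(t_cls) if t_cls else float("nan"),
            "precision": correct / len(p_cls) if p_cls else float("nan"),
        }
        tot_recalled += recalled
        tot_truth += len(t_cls)
        tot_correct += correct
        tot_pred += len(p_cls)
    return {
        "per_class": per_class,
        "overall": {
            "n_truth": tot_truth,
            "n_calls": tot_pred,
            "recall": tot_recalled / tot_truth if tot_truth else float("nan"),
            "precision": tot_correct / tot_pred if tot_pred else float("nan"),
        },
    }


def collapse_parent_of_origin(calls: Sequence[CnvCall]) -> List[CnvCall]:
    """Map the four parent-of-origin classes onto 'dup'/'del' (for comparing
    against the 3-state coverage-only baseline, which cannot see parental
    origin)."""
    out = []
    for c in calls:
        cls = "dup" if c.ip_class.endswith("dup") or c.ip_class == "dup" else "del"
        out.append(CnvCall(c.chrom, c.start, c.end, cls, c.n_snps, c.score))
    return out


def coverage_only_hmm(
    windows: pd.DataFrame,
    bin_size: int,
    r: float,
    sigma: Optional[float] = None,
    k: int = 30,
    cnv_start_p: float = CNV_START_P,
    cnv_end_p: float = CNV_END_P,
) -> List[CnvCall]:
    """Coverage-only baseline: a 3-state HMM over fixed-size bins.

    States are normal / duplication / deletion; the per-bin emission is the
    zero-mean Gaussian noise density of the residual between the copy-count-
    scaled reference WRV and the sample WRV.  Transition constants reuse the
    main model's start/end rates.  Calls carry class 'dup' or 'del'.
    """
    bins = rebin_windows(windows, bin_size)
    tab = wrv_table(bins, k=k)
    wrv_s = tab["wrv_sample"].to_numpy(dtype=float)
    wrv_r = tab["wrv_ref"].to_numpy(dtype=float)
    if sigma is None:
        sigma = robust_sigma(wrv_r - wrv_s)
    # emission per state: normal (cc2), dup (cc3), del (cc1)
    res = np.stack(
        [wrv_r - wrv_s,
         wrv_r * (1.0 + r / 2.0) - wrv_s,
         wrv_r * (1.0 - r / 2.0) - wrv_s],
        axis=1,
    )
    log_emis = -0.5 * (res / sigma) ** 2 - np.log(sigma)
    log_emis[~np.isfinite(log_emis).all(axis=1)] = 0.0
    T = np.array([
        [1.0 - 2 * cnv_start_p, cnv_start_p, cnv_start_p],
        [cnv_end_p, 1.0 - cnv_end_p, 0.0],
        [cnv_end_p, 0.0, 1.0 - cnv_end_p],
    ])
    log_init = np.array([0.0, -np.inf, -np.inf])
    path, _ = _viterbi(log_emis, log_init, T, None)
    labels = {1: "dup", 2: "del"}
    calls: List[CnvCall] = []
    starts = tab["start"].to_numpy()
    ends = tab["end"].to_numpy()
    chroms = tab["chrom"].to_numpy()
    i = 0
    n = len(path)
    while i < n:
        j = i
        while j + 1 < n and path[j + 1] == path[i] and chroms[j + 1] == chroms[i]:
            j += 1
        if path[i] in labels:
            calls.append(CnvCall(str(chroms[i]), int(starts[i]), int(ends[j]),
                                 labels[path[i]], n_snps=j - i + 1))
        i = j + 1
    return calls
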