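"""Estimator-style front ends for the CNV callers.

``HmmCnvCaller`` wraps the full pipeline (fetal-fraction estimation,
coverage priors, 20-state Viterbi decoding, call extraction) behind the
scikit-learn estimator protocol: hyperparameters in ``__init__``, data-
derived quantities estimated in ``fit`` and stored with trailing
underscores, per-site labels from ``predict``.  ``CoverageOnlyCnvCaller``
is the 3-state depth-only baseline over fixed-size bins.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import hmm
from .allele_model import (
    AdmixtureParams,
    default_alpha,
    emission_matrix,
    estimate_fetal_fraction,
)
from .coverage_model import coverage_priors, estimate_sigma_noise, wrv_table
from .hmm import CnvCall, base_transitions, calls_from_path, viterbi_decode
from .patterns import state_classes


class HmmCnvCaller(BaseEstimator):
    """De novo fetal CNV caller over maternal-plasma SNP allele counts.

    Parameters
    ----------
    fetal_fraction : float or None
        Fetal cfDNA fraction r; estimated from opposite-homozygote sites
        when None.
    alpha : float or None
        Maternal-weight pseudocount; 0.1 x mean maternal depth when None.
    mode : {"combined", "ratios_only"}
        Whether the coverage prior is injected into the transitions.
    sigma_noise : float or None
        WRV noise scale; robustly estimated from the window table when None.
    k_neighbors : int
        Number of GC-nearest windows in the WRV denominator.
    within_class_p, cnv_start_p, cnv_end_p : float
        The fixed transition rates of the 20-state model.
    split_start : bool
        Spread the CNV-start rate across the 16 CNV states instead of
        applying it per state.
    """

    def __init__(
        self,
        fetal_fraction: Optional[float] = None,
        alpha: Optional[float] = None,
        mode: str = "combined",
        sigma_noise: Optional[float] = None,
        k_neighbors: int = 200,
        within_class_p: float = hmm.WITHIN_CLASS_P,
        cnv_start_p: float = hmm.CNV_START_P,
        cnv_end_p: float = hmm.CNV_END_P,
        split_start: bool = False,
    ):
        self.fetal_fraction = fetal_fraction
        self.alpha = alpha
        self.mode = mode
        self.sigma_noise = sigma_noise
        self.k_neighbors = k_neighbors
        self.within_class_p = within_class_p
        self.cnv_start_p = cnv_start_p
        self.cnv_end_p = cnv_end_p
        self.split_start = split_start

    def fit(self, sites: pd.DataFrame, windows: Optional[pd.DataFrame] = None):
        """Estimate data-derived parameters (r, alpha, sigma_noise)."""
        if self.mode not in ("combined", "ratios_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.fetal_fraction_ = (
            self.fetal_fraction
            if self.fetal_fraction is not None
            else estimate_fetal_fraction(sites)
        )
        self.alpha_ = self.alpha if self.alpha is not None else default_alpha(sites)
        self.params_ = AdmixtureParams(r=self.fetal_fraction_, alpha=self.alpha_)
        self.base_transitions_ = base_transitions(
            self.within_class_p, self.cnv_start_p, self.cnv_end_p, self.split_start
        )
        if self.mode == "combined":
            if windows is None:
                raise ValueError("combined mode requires a window table")
            tab = wrv_table(windows, k=self.k_neighbors)
            self.sigma_noise_ = (
                self.sigma_noise
                if self.sigma_noise is not None
                else estimate_sigma_noise(tab, k=self.k_neighbors)
            )
        else:
            self.sigma_noise_ = self.sigma_noise
        return self

    def _decode(self, sites, windows):
        priors = None
        if self.mode == "combined":
            if windows is None:
                raise ValueError("combined mode requires a window table")
            if len(windows) != len(sites):
                raise ValueError("window table must align 1:1 with SNP sites")
            priors, _ = coverage_priors(
                windows, self.fetal_fraction_, sigma=self.sigma_noise_,
                k=self.k_neighbors,
            )
        emissions = emission_matrix(sites, self.params_)
        path = viterbi_decode(
            sites, priors, self.params_, mode=self.mode,
            base=self.base_transitions_, emissions=emissions,
        )
        return path, emissions

    def predict(
        self, sites: pd.DataFrame, windows: Optional[pd.DataFrame] = None
    ) -> np.ndarray:
        """Per-site inheritance-class labels along the Viterbi path."""
        path, _ = self._decode(sites, windows)
        classes = state_classes()
        return np.array([classes[s].value for s in path])

    def predict_path(
        self, sites: pd.DataFrame, windows: Optional[pd.DataFrame] = None
    ) -> np.ndarray:
        """Per-site canonical state indices (0-19) along the Viterbi path."""
        return self._decode(sites, windows)[0]

    def call(
        self, sites: pd.DataFrame, windows: Optional[pd.DataFrame] = None
    ) -> List[CnvCall]:
        """Decode and collapse the path into CNV calls."""
        path, emissions = self._decode(sites, windows)
        return calls_from_path(path, sites, emissions)


class CoverageOnlyCnvCaller(BaseEstimator):
    """Depth-of-coverage-only baseline: 3-state HMM over fixed-size bins.

    Cannot distinguish parental origin; calls carry class 'dup' or 'del'.
    """

    def __init__(
        self,
        fetal_fraction: float = 0.13,
        bin_size: int = 100_000,
        sigma_noise: Optional[float] = None,
        k_neighbors: int = 30,
    ):
        self.fetal_fraction = fetal_fraction
        self.bin_size = bin_size
        self.sigma_noise = sigma_noise
        self.k_neighbors = k_neighbors

    def fit(self, windows: pd.DataFrame, y=None):
        self.sigma_noise_ = self.sigma_noise  # estimated per run when None
        return self

    def call(self, windows: pd.DataFrame) -> List[CnvCall]:
        return hmm.coverage_only_hmm(
            windows, self.bin_size, self.fetal_fraction,
            sigma=getattr(self, "sigma_noise_", self.sigma_noise),
            k=self.k_neighbors,
        )
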