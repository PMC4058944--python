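import itertools

import numpy as np
import pandas as pd
import pytest

from plasmacnv.allele_model import AdmixtureParams
from plasmacnv.hmm import (
    CNV_END_P,
    CNV_START_P,
    WITHIN_CLASS_P,
    CnvCall,
    base_transitions,
    calls_from_path,
    collapse_parent_of_origin,
    coverage_only_hmm,
    evaluate_calls,
    inject_coverage_priors,
    viterbi_decode,
)
from plasmacnv.patterns import CLASS_SLICES, IpClass, state_classes, state_copy_counts


def sites_frame(positions, chrom="chr1"):
    n = len(positions)
    df = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "mA": "A", "mB": "A", "pA": "A", "pB": "A",
    })
    for c in ("mat_A", "mat_C", "mat_G", "mat_T",
              "pla_A", "pla_C", "pla_G", "pla_T"):
        df[c] = 0
    df["mat_A"] = 30
    df["pla_A"] = 78
    return df


class TestBaseTransitions:
    def test_rows_sum_to_one(self):
        T = base_transitions()
        np.testing.assert_allclose(T.sum(axis=1), 1.0)
        assert (T >= 0).all()

    def test_stated_constants(self):
        T = base_transitions()
        classes = state_classes()
        i_norm = 0
        i_mdup = next(i for i, c in enumerate(classes) if c is IpClass.MATERNAL_DUP)
        j_mdup2 = i_mdup + 1
        i_pdel = next(i for i, c in enumerate(classes) if c is IpClass.PATERNAL_DEL)
        assert T[i_norm, i_mdup] == CNV_START_P
        assert T[i_mdup, i_norm] == CNV_END_P
        assert T[i_mdup, j_mdup2] == WITHIN_CLASS_P
        assert T[i_norm, 1] == WITHIN_CLASS_P  # normal <-> normal inner edge
        # no adjacent CNVs: cross-class CNV transitions are impossible
        assert T[i_mdup, i_pdel] == 0.0

    def test_cross_cnv_block_is_zero(self):
        T = base_transitions()
        classes = state_classes()
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                if ci.is_cnv and cj.is_cnv and ci != cj:
                    assert T[i, j] == 0.0

    def test_split_start_divides_mass(self):
        T = base_transitions(split_start=True)
        i_mdup = CLASS_SLICES[IpClass.MATERNAL_DUP].start
        assert T[0, i_mdup] == pytest.approx(CNV_START_P / 16)
        np.testing.assert_allclose(T.sum(axis=1), 1.0)


class TestPriorInjection:
    def test_uniform_prior_reproduces_base(self):
        T = base_transitions()
        out = inject_coverage_priors(T, np.array([1 / 3, 1 / 3, 1 / 3]))
        np.testing.assert_allclose(out, T, atol=1e-12)

    def test_degenerate_prior_zeroes_cnv_entries(self):
        T = base_transitions()
        out = inject_coverage_priors(T, np.array([0.0, 1.0, 0.0]))
        cc = np.array(state_copy_counts())
        assert (out[:, cc != 2] == 0.0).all()
        np.testing.assert_allclose(out.sum(axis=1), 1.0)

    def test_rows_normalized_for_random_priors(self, rng):
        T = base_transitions()
        for _ in range(25):
            w = rng.dirichlet([1, 1, 1])
            out = inject_coverage_priors(T, w)
            np.testing.assert_allclose(out.sum(axis=1), 1.0)


def brute_force_best_score(log_emis, log_init, base, priors):
    """Exhaustive enumeration over all state paths (oracle)."""
    n, S = log_emis.shape
    mats = []
    for t in range(1, n):
        M = inject_coverage_priors(base, priors[t]) if priors is not None else base
        with np.errstate(divide="ignore"):
            mats.append(np.log(M))
    best = -np.inf
    for path in itertools.product(range(S), repeat=n):
        s = log_init[path[0]] + log_emis[0, path[0]]
        for t in range(1, n):
            s += mats[t - 1][path[t - 1], path[t]] + log_emis[t, path[t]]
        best = max(best, s)
    return best


def path_score(path, log_emis, log_init, base, priors):
    s = log_init[path[0]] + log_emis[0, path[0]]
    for t in range(1, len(path)):
        M = inject_coverage_priors(base, priors[t]) if priors is not None else base
        s += np.log(M[path[t - 1], path[t]]) + log_emis[t, path[t]]
    return s


class TestViterbi:
    def test_agrees_with_exhaustive_enumeration_small(self, rng):
        base = base_transitions()
        log_init = np.full(20, -np.inf)
        log_init[:4] = -np.log(4)
        for trial in range(12):
            n = int(rng.integers(2, 4))
            log_emis = rng.normal(0, 3, (n, 20))
            priors = rng.dirichlet([1, 1, 1], size=n)
            df = sites_frame(np.arange(1, n + 1) * 1000)
            path = viterbi_decode(df, priors, AdmixtureParams(0.13, 1.0),
                                  emissions=log_emis)
            got = path_score(path, log_emis, log_init, base, priors)
            want = brute_force_best_score(log_emis, log_init, base, priors)
            assert got == pytest.approx(want, rel=1e-10)

    def test_single_site_equal_emissions_starts_normal(self):
        df = sites_frame([1000])
        path = viterbi_decode(df, np.full((1, 3), 1 / 3),
                              AdmixtureParams(0.13, 1.0),
                              emissions=np.zeros((1, 20)))
        assert state_classes()[path[0]] is IpClass.NORMAL
        assert path[0] == 0  # tie broken to lowest canonical index

    def test_uninformative_priors_match_ratios_only(self, rng):
        n = 60
        log_emis = rng.normal(0, 2, (n, 20))
        df = sites_frame(np.arange(1, n + 1) * 1000)
        params = AdmixtureParams(0.13, 1.0)
        p_comb = viterbi_decode(df, np.full((n, 3), 1 / 3), params,
                                mode="combined", emissions=log_emis)
        p_ratio = viterbi_decode(df, None, params, mode="ratios_only",
                                 emissions=log_emis)
        np.testing.assert_array_equal(p_comb, p_ratio)

    def test_deterministic_given_identical_inputs(self, rng):
        n = 40
        log_emis = rng.normal(0, 2, (n, 20))
        priors = rng.dirichlet([1, 1, 1], size=n)
        df = sites_frame(np.arange(1, n + 1) * 1000)
        params = AdmixtureParams(0.13, 1.0)
        a = viterbi_decode(df, priors, params, emissions=log_emis)
        b = viterbi_decode(df, priors.copy(), params, emissions=log_emis.copy())
        np.testing.assert_array_equal(a, b)

    def test_empty_sites_empty_path(self):
        df = sites_frame([]).iloc[0:0]
        path = viterbi_decode(df, None, AdmixtureParams(0.13, 1.0),
                              mode="ratios_only")
        assert len(path) == 0

    def test_misaligned_priors_error(self):
        df = sites_frame([1000, 2000])
        with pytest.raises(ValueError, match="1:1"):
            viterbi_decode(df, np.full((3, 3), 1 / 3),
                           AdmixtureParams(0.13, 1.0),
                           emissions=np.zeros((2, 20)))


class TestCallsFromPath:
    def test_all_normal_no_calls(self):
        df = sites_frame(np.arange(1, 51) * 1000)
        assert calls_from_path(np.zeros(50, dtype=int), df) == []

    def test_single_run_with_midpoint_boundaries(self):
        pos = np.arange(1, 51) * 1000
        df = sites_frame(pos)
        path = np.zeros(50, dtype=int)
        path[10:40] = 4  # a maternal_dup state for SNPs 11..40
        calls = calls_from_path(path, df)
        assert len(calls) == 1
        c = calls[0]
        assert c.ip_class == "maternal_dup"
        assert c.n_snps == 30
        assert c.start == (pos[9] + pos[10]) // 2
        assert c.end == (pos[39] + pos[40]) // 2

    def test_phase_switches_within_class_stay_one_call(self):
        df = sites_frame(np.arange(1, 31) * 1000)
        path = np.zeros(30, dtype=int)
        path[5:25] = [4, 5] * 10  # alternating maternal_dup states
        calls = calls_from_path(path, df)
        assert len(calls) == 1
        assert calls[0].ip_class == "maternal_dup"
        assert calls[0].n_snps == 20


class TestEvaluateCalls:
    def test_majority_span_recalls_truth(self):
        truth = [CnvCall("chr1", 0, 1_000_000, "maternal_del")]
        pred = [CnvCall("chr1", 100_000, 700_000, "maternal_del")]
        ev = evaluate_calls(truth, pred)
        assert ev["per_class"]["maternal_del"]["recall"] == 1.0
        assert ev["per_class"]["maternal_del"]["precision"] == 1.0

    def test_wrong_class_is_not_recall(self):
        truth = [CnvCall("chr1", 0, 1_000_000, "maternal_del")]
        pred = [CnvCall("chr1", 100_000, 700_000, "maternal_dup")]
        ev = evaluate_calls(truth, pred)
        assert ev["per_class"]["maternal_del"]["recall"] == 0.0

    def test_union_of_abutting_calls_counts(self):
        truth = [CnvCall("chr1", 0, 1_000_000, "paternal_dup")]
        pred = [
            CnvCall("chr1", 0, 250_000, "paternal_dup"),
            CnvCall("chr1", 250_000, 500_000, "paternal_dup"),
        ]
        ev = evaluate_calls(truth, pred)
        assert ev["per_class"]["paternal_dup"]["recall"] == 1.0
        assert ev["per_class"]["paternal_dup"]["precision"] == 1.0

    def test_under_half_union_is_missed(self):
        truth = [CnvCall("chr1", 0, 1_000_000, "paternal_dup")]
        pred = [CnvCall("chr1", 0, 499_999, "paternal_dup")]
        ev = evaluate_calls(truth, pred)
        assert ev["per_class"]["paternal_dup"]["recall"] == 0.0
        assert ev["per_class"]["paternal_dup"]["precision"] == 1.0

    def test_collapse_parent_of_origin(self):
        calls = [CnvCall("chr1", 0, 10, "maternal_dup"),
                 CnvCall("chr1", 20, 30, "paternal_del")]
        got = [c.ip_class for c in collapse_parent_of_origin(calls)]
        assert got == ["dup", "del"]


class TestCoverageOnlyHmm:
    @staticmethod
    def _window_frame(n, rng, dup_span=None, r=0.13):
        starts = np.arange(n) * 1000
        gc = np.clip(rng.normal(0.42, 0.03, n), 0.3, 0.6)
        mean = 470.0
        n_ref = rng.poisson(mean, n).astype(float)
        mult = np.ones(n)
        if dup_span:
            mult[dup_span[0] // 1000: dup_span[1] // 1000] = 1 + r / 2
        n_sample = rng.poisson(mean * mult, n).astype(float)
        return pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + 1000,
            "n_sample": n_sample, "n_ref": n_ref, "gc": gc,
        })

    def test_identical_samples_yield_no_calls(self, rng):
        df = self._window_frame(3000, rng)
        df["n_sample"] = df["n_ref"]
        calls = coverage_only_hmm(df, bin_size=100_000, r=0.13, k=20)
        assert calls == []

    def test_large_duplication_is_called(self):
        rng = np.random.default_rng(1234)
        df = self._window_frame(20_000, rng, dup_span=(8_000_000, 11_000_000))
        calls = coverage_only_hmm(df, bin_size=100_000, r=0.13, k=30)
        dup_calls = [c for c in calls if c.ip_class == "dup"]
        assert any(c.start < 11_000_000 and c.end > 8_000_000 for c in dup_calls)

    def test_dup_and_del_calls_never_abut(self):
        rng = np.random.default_rng(99)
        df = self._window_frame(20_000, rng, dup_span=(5_000_000, 8_000_000))
        calls = coverage_only_hmm(df, bin_size=100_000, r=0.13, k=30)
        calls = sorted(calls, key=lambda c: c.start)
        for a, b in zip(calls, calls[1:]):
            if a.end == b.start:
                assert a.ip_class == b.ip_class
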