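import itertools

import numpy as np
import pytest

from dualtf import role_analysis as ra
from dualtf.role_analysis import (
    CCMatrix,
    MethodSummary,
    ROLE_ACT,
    ROLE_NA,
    ROLE_REP,
    RoleCall,
    best_n,
    bonferroni,
    build_cc_matrix,
    bundled_pvalue_table,
    classify_enrichment_table,
    ensemble_vote,
    enrichment_call,
    minimum_config_cover,
    sensitivity,
    smallest_optimal,
    summarize_tf_roles,
)
from dualtf.sa_optimizer import SASchedule
from dualtf import synthetic_data as sd


def matrix(cc, n_tfs=None):
    cc = np.asarray(cc, dtype=float)
    n = int(np.log2(cc.shape[1])) if n_tfs is None else n_tfs
    crms = tuple(f"c{i}" for i in range(cc.shape[0]))
    return CCMatrix(crms, n, cc)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_best_n(cc, n):
    best = (-np.inf, None)
    for combo in itertools.combinations(range(cc.shape[1]), n):
        total = cc[:, list(combo)].max(axis=1).sum()
        if total > best[0] + 1e-15:
            best = (total, combo)
    return best


def brute_min_cover(optimal_sets):
    configs = sorted(set().union(*optimal_sets))
    for size in range(1, len(configs) + 1):
        for combo in itertools.combinations(configs, size):
            s = set(combo)
            if all(o & s for o in optimal_sets):
                return combo
    raise AssertionError


def brute_sensitivity(cc, n_tfs, tf, na=0.1):
    out = []
    for row in cc:
        best = 0.0
        for k in range(cc.shape[1]):
            if (k >> tf) & 1:
                continue
            diff = row[k | (1 << tf)] - row[k]
            if abs(diff) > abs(best):
                best = diff
        if abs(best) <= na:
            out.append(ROLE_NA)
        else:
            out.append(ROLE_ACT if best > 0 else ROLE_REP)
    return out


# ---------------------------------------------------------------------------


class TestCCMatrix:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="must be"):
            CCMatrix(("a",), 2, np.zeros((1, 3)))

    def test_range_validation(self):
        with pytest.raises(ValueError, match="-1, 1"):
            matrix([[2.0, 0.0]], n_tfs=1)

    def test_column_count_two_tfs(self):
        m = matrix(np.zeros((3, 4)))
        assert m.n_configs == 4


class TestSmallestOptimal:
    def test_identical_unique_optima(self):
        cc = np.zeros((3, 4))
        cc[:, 2] = 0.9
        res = smallest_optimal(matrix(cc))
        assert res.chosen_configs == (2,)

    def test_disjoint_singleton_optima(self):
        cc = np.zeros((2, 4))
        cc[0, 1] = 0.9
        cc[1, 3] = 0.9
        res = smallest_optimal(matrix(cc))
        assert set(res.chosen_configs) == {1, 3}

    def test_cover_matches_brute_force(self, rng):
        for _ in range(50):
            cc = rng.uniform(-1, 1, size=(6, 8))
            # quantize so ties actually occur
            cc = np.round(cc, 1)
            m = matrix(cc)
            optimal = ra._optimal_sets(m, 1e-9)
            got = minimum_config_cover(optimal)
            want = brute_min_cover(optimal)
            assert len(got) == len(want)
            assert got == want  # lexicographic tie-break as well

    def test_na_when_tf_never_matters(self):
        # columns identical across the TF-0 bit: TF0 is NA everywhere
        base = np.array([[0.1, 0.5], [0.3, 0.2]])
        cc = np.zeros((2, 4))
        for k in range(4):
            cc[:, k] = base[:, (k >> 1) & 1]
        res = smallest_optimal(matrix(cc), tf_names=["t0", "t1"])
        assert all(c.role == ROLE_NA for c in res.calls if c.tf == "t0")
        assert all(not c.strong for c in res.calls if c.tf == "t0")

    def test_cover_never_exceeds_crm_count(self, rng):
        cc = rng.uniform(-1, 1, size=(5, 16))
        res = smallest_optimal(matrix(cc))
        assert len(res.chosen_configs) <= 5


class TestBestN:
    def test_n1_is_best_column_sum(self, rng):
        cc = rng.uniform(-1, 1, size=(5, 8))
        res = best_n(matrix(cc), 1)
        assert res.chosen_configs == (int(cc.sum(axis=0).argmax()),)

    def test_full_set_equals_row_max_sum(self, rng):
        cc = rng.uniform(-1, 1, size=(4, 4))
        res = best_n(matrix(cc), 4)
        total = sum(cc[i, res.per_crm_config[c]] for i, c in enumerate(matrix(cc).crms))
        assert total == pytest.approx(cc.max(axis=1).sum())

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            cc = rng.uniform(-1, 1, size=(5, 8))
            m = matrix(cc)
            res = best_n(m, 2)
            total = cc[:, list(res.chosen_configs)].max(axis=1).sum()
            want_total, want_combo = brute_best_n(cc, 2)
            assert total == pytest.approx(want_total)
            assert res.chosen_configs == want_combo

    def test_monotone_in_n(self, rng):
        cc = rng.uniform(-1, 1, size=(6, 16))
        m = matrix(cc)
        totals = []
        for n in (1, 2, 3, 4):
            res = best_n(m, n)
            totals.append(cc[:, list(res.chosen_configs)].max(axis=1).sum())
        assert np.all(np.diff(totals) >= -1e-12)

    def test_all_calls_strong(self, rng):
        cc = rng.uniform(-1, 1, size=(3, 8))
        res = best_n(matrix(cc), 2)
        assert all(c.strong for c in res.calls)

    def test_n_out_of_range(self, rng):
        with pytest.raises(ValueError):
            best_n(matrix(np.zeros((2, 8))), 5)


class TestSensitivity:
    def test_matches_brute_force(self, rng):
        for _ in range(50):
            cc = rng.uniform(-1, 1, size=(4, 16))
            m = matrix(cc)
            res = sensitivity(m)
            for t in range(4):
                want = brute_sensitivity(cc, 4, t)
                got = [c.role for c in res.calls if c.tf == f"TF{t}"]
                assert got == want

    def test_identical_columns_na(self):
        # flipping TF0's bit (bit 0) never changes a cell: NA everywhere for TF0
        cc = np.tile(np.array([[0.3, 0.3, 0.5, 0.5]]), (3, 1))
        res = sensitivity(matrix(cc))
        assert all(c.role == ROLE_NA for c in res.calls if c.tf == "TF0")
        assert all(c.role == ROLE_ACT for c in res.calls if c.tf == "TF1")

    def test_single_tf_panel(self):
        cc = np.array([[0.1, 0.6]])  # rep, act columns
        res = sensitivity(matrix(cc))
        (call,) = res.calls
        assert call.role == ROLE_ACT
        assert call.strong
        assert call.delta_cc == pytest.approx(0.5)

    def test_strong_threshold(self):
        cc = np.array([[0.5, 0.58]])
        res = sensitivity(matrix(cc), na_threshold=0.05, strong_threshold=0.1)
        (call,) = res.calls
        assert call.role == ROLE_ACT and not call.strong


class TestSummaries:
    def _result(self, calls):
        return ra.MethodResult("x", (), {}, calls)

    def test_unanimous_activator(self):
        calls = [RoleCall(f"c{i}", "t", ROLE_ACT, True) for i in range(10)]
        summ = summarize_tf_roles(self._result(calls), ["t"])
        assert summ["t"].label == "+"

    def test_even_split_switches(self):
        calls = [RoleCall(f"c{i}", "t", ROLE_ACT if i < 5 else ROLE_REP, True)
                 for i in range(10)]
        assert summarize_tf_roles(self._result(calls), ["t"])["t"].label == "s"

    def test_seven_three_with_theta_two_thirds(self):
        calls = [RoleCall(f"c{i}", "t", ROLE_ACT if i < 7 else ROLE_REP, True)
                 for i in range(10)]
        summ = summarize_tf_roles(self._result(calls), ["t"], theta=2 / 3)
        assert summ["t"].label == "+"  # 0.7 > 2/3

    def test_all_na_switches_with_zero_confidence(self):
        calls = [RoleCall(f"c{i}", "t", ROLE_NA, False) for i in range(4)]
        summ = summarize_tf_roles(self._result(calls), ["t"])
        assert summ["t"].label == "s"
        assert summ["t"].n_strong_act == summ["t"].n_strong_rep == 0

    def test_theta_validation(self):
        with pytest.raises(ValueError):
            summarize_tf_roles(self._result([]), ["t"], theta=0.4)


class TestEnsemble:
    def _summ(self, label, ns=1):
        return MethodSummary("t", label, 1, 1, ns, ns)

    def test_two_of_three(self):
        out = ensemble_vote([{"t": self._summ("+")}, {"t": self._summ("+")},
                             {"t": self._summ("-")}])
        assert out.roles["t"] == "+"

    def test_no_majority(self):
        out = ensemble_vote([{"t": self._summ("+")}, {"t": self._summ("-")},
                             {"t": self._summ("s")}])
        assert out.roles["t"] == "s"

    def test_all_switch(self):
        out = ensemble_vote([{"t": self._summ("s")}] * 3)
        assert out.roles["t"] == "s"

    def test_requires_three(self):
        with pytest.raises(ValueError):
            ensemble_vote([{"t": self._summ("+")}] * 2)


class TestEnrichment:
    def test_differential_over_vs_background(self):
        call = enrichment_call("Hsf", 0.0, 0.231)
        assert call.status_act == "over" and call.status_rep == "background"
        assert call.differential

    def test_both_over_not_differential(self):
        call = enrichment_call("Abd-B", 0.0, 0.0)
        assert call.status_act == call.status_rep == "over"
        assert not call.differential

    def test_small_gap_not_differential(self):
        call = enrichment_call("Deaf1", 0.079, 0.005)
        assert call.status_rep == "over"
        assert not call.differential  # |0.079 - 0.005| <= 0.2

    def test_untested(self):
        call = enrichment_call("x", None, 0.5)
        assert call.status_act == "untested"
        assert not call.differential

    def test_bundled_table_counts(self):
        """3 differentially enriched pairs; 12 TFs over-represented somewhere."""
        table = bundled_pvalue_table()
        calls = classify_enrichment_table(table)
        diff = sorted(c.tf for c in calls if c.differential)
        assert diff == ["Br-Z4:Kr", "Hsf:Kr", "Kni:Kr"]
        over_tfs = {
            c.tf.split(":")[0]
            for c in calls
            if "over" in (c.status_act, c.status_rep)
        }
        assert len(over_tfs) == 12

    def test_bonferroni(self):
        assert bonferroni(0.001, 76) == pytest.approx(0.076)
        assert bonferroni(0.5, 76) == 1.0
        with pytest.raises(ValueError):
            bonferroni(-0.1, 10)


class TestBuildMatrix:
    def test_panel_guard(self, rng):
        from dualtf.thermo_model import Configuration, TFPanel

        names = tuple(f"T{i}" for i in range(11))
        panel = TFPanel(names, Configuration(tuple([1] * 11)))
        with pytest.raises(ValueError, match="restrict"):
            build_cc_matrix(None, panel, SASchedule())

    def test_two_tf_panel_four_columns_and_planted_argmax(self):
        spec = sd.default_spec(n_tfs=2, n_crms=2, seed=21, dual_tf=None,
                              crm_length=300, n_positions=30)
        synth = sd.generate(spec)
        ds = synth.to_dataset()
        sched = SASchedule(T0=0.03, alpha=0.99, iterations=400, repeats=3, seed=21)
        ccm = build_cc_matrix(ds, synth.panel, sched, d=synth.params.d)
        assert ccm.n_configs == 4
        for ci, crm in enumerate(ds.crm_ids):
            assert ccm.cc[ci].argmax() == synth.per_crm_configs[crm].index

    def test_deterministic(self):
        spec = sd.default_spec(n_tfs=2, n_crms=1, seed=5, dual_tf=None,
                              crm_length=200, n_positions=20)
        synth = sd.generate(spec)
        ds = synth.to_dataset()
        sched = SASchedule(iterations=50, repeats=2, seed=5)
        a = build_cc_matrix(ds, synth.panel, sched, d=synth.params.d)
        b = build_cc_matrix(ds, synth.panel, sched, d=synth.params.d)
        np.testing.assert_array_equal(a.cc, b.cc)
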