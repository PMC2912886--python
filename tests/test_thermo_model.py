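import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualtf.io_formats import ProfileSet
from dualtf.site_scanner import TFBS
from dualtf import thermo_model as tm
from dualtf.thermo_model import (
    ACT,
    REP,
    Configuration,
    ExpressionProfile,
    GAP_GENE_PANEL,
    ModelParams,
    TFPanel,
)


def make_params(names=("a", "b"), K=2.0, E_act=1.5, E_rep=0.8, G0=0.0, R0=1.0, d=50.0,
                dual_tfs=frozenset()):
    n = len(names)
    return ModelParams(
        names=tuple(names), K=np.full(n, K), E_act=np.full(n, E_act),
        E_rep=np.full(n, E_rep), G0=G0, R0=R0, d=d, dual_tfs=dual_tfs,
    )


class TestConfiguration:
    def test_index_round_trip(self):
        for idx in range(16):
            cfg = Configuration.from_index(idx, 4)
            assert cfg.index == idx

    def test_bit_meaning(self):
        cfg = Configuration.from_index(0b0101, 4)
        assert cfg.roles == (ACT, REP, ACT, REP)

    def test_invalid_role(self):
        with pytest.raises(ValueError):
            Configuration((1, 0))

    def test_panel_literature_roles(self):
        panel = GAP_GENE_PANEL
        roles = dict(zip(panel.names, panel.literature_roles.roles))
        assert roles["Bcd"] == ACT and roles["Cad"] == ACT and roles["TorRE"] == ACT
        for rep in ("Hb", "Gt", "Kni", "Kr", "Tll"):
            assert roles[rep] == REP

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            TFPanel(("x", "x"), Configuration((ACT, REP)))


class TestSiteOccupancy:
    def test_zero_concentration(self):
        assert tm.site_occupancy(0.5, 0.0, 3.0) == 0.0

    def test_half_saturation(self):
        assert tm.site_occupancy(1.0, 0.5, 2.0) == pytest.approx(0.5)

    def test_three_quarters(self):
        # K*v*q = 3
        assert tm.site_occupancy(1.0, 1.0, 3.0) == pytest.approx(0.75)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.site_occupancy(0.5, -1.0, 2.0)
        with pytest.raises(ValueError):
            tm.site_occupancy(0.5, 1.0, -2.0)

    @given(st.floats(0.01, 1.0), st.floats(0.0, 10.0), st.floats(0.01, 100.0))
    def test_bounded_below_one(self, q, v, K):
        f = tm.site_occupancy(q, v, K)
        assert 0.0 <= f < 1.0


class TestTotalActivation:
    def test_no_sites(self):
        p = make_params()
        assert tm.total_activation([], {}, p, Configuration((ACT, REP))) == 0.0

    def test_single_activator(self):
        p = make_params(K=1.0, E_act=2.0)
        site = TFBS(0, "a", "+", 10.0, 1.0, 4)
        cfg = Configuration((ACT, REP))
        f = tm.site_occupancy(1.0, 1.0, 1.0)
        assert tm.total_activation([site], {"a": 1.0, "b": 0.0}, p, cfg) == pytest.approx(2.0 * f)

    def test_full_quench(self):
        # repressor at full occupancy and effectiveness 1 cancels the activator
        n = 2
        p = ModelParams(("a", "b"), K=np.array([1.0, 1e6]), E_act=np.array([2.0, 0.0]),
                        E_rep=np.array([0.0, 1.0]), G0=0.0, R0=1.0, d=100.0)
        act = TFBS(0, "a", "+", 10.0, 1.0, 4)
        rep = TFBS(20, "b", "+", 10.0, 1.0, 4)
        total = tm.total_activation([act, rep], {"a": 1.0, "b": 1e6}, p, Configuration((ACT, REP)))
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_repressor_outside_d_ignored(self):
        p = make_params(d=10.0)
        act = TFBS(0, "a", "+", 10.0, 1.0, 4)
        rep = TFBS(100, "b", "+", 10.0, 1.0, 4)
        cfg = Configuration((ACT, REP))
        conc = {"a": 1.0, "b": 1.0}
        with_rep = tm.total_activation([act, rep], conc, p, cfg)
        without = tm.total_activation([act], conc, p, cfg)
        assert with_rep == pytest.approx(without)


class TestPredictExpression:
    def test_no_sites_basal(self, profile_set):
        p = make_params(G0=1.0, R0=2.0)
        prof = tm.predict_expression([], profile_set, p, Configuration((ACT, REP)))
        np.testing.assert_allclose(prof.values, 2.0 / (1.0 + np.exp(1.0)))

    def test_hand_case(self):
        # one activator site, q=1, K*v=1, E_act=2, G0=0, R0=1 -> 1/(1+exp(-1))
        axis = np.array([0.0, 1.0])
        conc = ProfileSet(axis, {"a": np.array([1.0, 1.0]), "b": np.zeros(2)})
        p = make_params(K=1.0, E_act=2.0, G0=0.0, R0=1.0)
        site = TFBS(0, "a", "+", 10.0, 1.0, 4)
        prof = tm.predict_expression([site], conc, p, Configuration((ACT, REP)))
        assert prof.values[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))

    def test_saturation_limit(self):
        axis = np.array([0.0])
        conc = ProfileSet(axis, {"a": np.array([1e9]), "b": np.zeros(1)})
        p = make_params(K=1e6, E_act=1e3, G0=0.0, R0=3.0)
        site = TFBS(0, "a", "+", 10.0, 1.0, 4)
        prof = tm.predict_expression([site], conc, p, Configuration((ACT, REP)))
        assert prof.values[0] == pytest.approx(3.0, rel=1e-6)

    def test_missing_track_raises(self):
        conc = ProfileSet(np.array([0.0]), {"a": np.array([1.0])})
        p = make_params()
        site = TFBS(0, "b", "+", 10.0, 1.0, 4)
        with pytest.raises(KeyError, match="'b'"):
            tm.predict_expression([site], conc, p, Configuration((ACT, REP)))

    def test_matches_per_position_reference(self, rng):
        """Vectorized prediction equals the per-position reference loop."""
        names = ("a", "b", "c")
        axis = np.linspace(0, 100, 11)
        conc = ProfileSet(axis, {n: rng.uniform(0, 1, 11) for n in names})
        p = ModelParams(names, K=rng.uniform(0.5, 5, 3), E_act=rng.uniform(0, 3, 3),
                        E_rep=rng.uniform(0, 1, 3), G0=0.5, R0=2.0, d=60.0)
        sites = [
            TFBS(int(rng.integers(0, 300)), names[int(rng.integers(0, 3))], "+",
                 10.0, float(rng.uniform(0.5, 1.0)), 8)
            for _ in range(10)
        ]
        cfg = Configuration((ACT, REP, ACT))
        prof = tm.predict_expression(sites, conc, p, cfg)
        for i, x in enumerate(axis):
            conc_at_x = {n: conc[n][i] for n in names}
            sigma = tm.total_activation(sites, conc_at_x, p, cfg)
            assert prof.values[i] == pytest.approx(tm.transcription_rate(sigma, p.G0, p.R0))

    def test_zero_repressor_effectiveness_is_repressor_free(self, rng):
        names = ("a", "b")
        axis = np.linspace(0, 100, 9)
        conc = ProfileSet(axis, {n: rng.uniform(0, 1, 9) for n in names})
        p_zero = ModelParams(names, K=np.array([2.0, 2.0]), E_act=np.array([2.0, 0.0]),
                             E_rep=np.array([0.0, 0.0]), G0=0.0, R0=1.0, d=1e6)
        sites = [TFBS(0, "a", "+", 10.0, 1.0, 4), TFBS(10, "b", "+", 10.0, 1.0, 4)]
        cfg = Configuration((ACT, REP))
        with_rep = tm.predict_expression(sites, conc, p_zero, cfg)
        without = tm.predict_expression([sites[0]], conc, p_zero, cfg)
        np.testing.assert_allclose(with_rep.values, without.values)

    def test_monotone_in_activator_concentration(self):
        names = ("a", "b")
        axis = np.array([0.0, 1.0])
        p = make_params()
        sites = [TFBS(0, "a", "+", 10.0, 1.0, 4), TFBS(5, "b", "+", 10.0, 1.0, 4)]
        cfg = Configuration((ACT, REP))
        lo = tm.predict_expression(
            sites, ProfileSet(axis, {"a": np.array([0.2, 0.2]), "b": np.array([0.5, 0.5])}),
            p, cfg)
        hi = tm.predict_expression(
            sites, ProfileSet(axis, {"a": np.array([0.9, 0.9]), "b": np.array([0.5, 0.5])}),
            p, cfg)
        assert np.all(hi.values >= lo.values)

    def test_monotone_in_repressor_concentration(self):
        names = ("a", "b")
        axis = np.array([0.0, 1.0])
        p = make_params()
        sites = [TFBS(0, "a", "+", 10.0, 1.0, 4), TFBS(5, "b", "+", 10.0, 1.0, 4)]
        cfg = Configuration((ACT, REP))
        lo = tm.predict_expression(
            sites, ProfileSet(axis, {"a": np.array([0.5, 0.5]), "b": np.array([0.2, 0.2])}),
            p, cfg)
        hi = tm.predict_expression(
            sites, ProfileSet(axis, {"a": np.array([0.5, 0.5]), "b": np.array([0.9, 0.9])}),
            p, cfg)
        assert np.all(hi.values <= lo.values)

    def test_large_d_quenches_everything(self, rng):
        """d beyond the CRM length means every repressor hits every activator."""
        names = ("a", "b")
        axis = np.linspace(0, 100, 7)
        conc = ProfileSet(axis, {n: rng.uniform(0.2, 1, 7) for n in names})
        sites = [TFBS(0, "a", "+", 10.0, 1.0, 4), TFBS(490, "b", "+", 10.0, 1.0, 4)]
        cfg = Configuration((ACT, REP))
        p_big = make_params(d=10_000.0)
        prof = tm.predict_expression(sites, conc, p_big, cfg)
        # oracle: fold the repressor factor in by hand at each position
        for i in range(7):
            fa = tm.site_occupancy(1.0, conc["a"][i], 2.0)
            fr = tm.site_occupancy(1.0, conc["b"][i], 2.0)
            sigma = 1.5 * fa * (1 - 0.8 * fr)
            assert prof.values[i] == pytest.approx(tm.transcription_rate(sigma, 0.0, 1.0))


class TestPearson:
    def _prof(self, values):
        return ExpressionProfile(np.arange(len(values), dtype=float), np.asarray(values, float))

    def test_identity(self):
        p = self._prof([1.0, 2.0, 3.0])
        assert tm.pearson_cc(p, p) == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        a = self._prof([1.0, 2.0, 3.0])
        b = self._prof([5.0, 3.0, 1.0])
        assert tm.pearson_cc(a, b) == pytest.approx(-1.0)

    def test_constant_prediction_zero(self):
        a = self._prof([1.0, 2.0, 3.0])
        b = self._prof([2.0, 2.0, 2.0])
        assert tm.pearson_cc(a, b) == 0.0

    def test_axis_mismatch(self):
        a = self._prof([1.0, 2.0])
        b = ExpressionProfile(np.array([5.0, 6.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            tm.pearson_cc(a, b)

    def test_invariant_under_positive_affine(self, rng):
        obs = self._prof(rng.uniform(0, 1, 20))
        pred = rng.uniform(0, 1, 20)
        cc1 = tm.pearson_cc(obs, self._prof(pred))
        cc2 = tm.pearson_cc(obs, self._prof(3.5 * pred + 0.7))
        assert cc1 == pytest.approx(cc2)


class TestParameterCount:
    def test_baseline_eight_tfs(self):
        assert tm.count_free_parameters("reinitz", 8) == 18

    def test_two_dual(self):
        assert tm.count_free_parameters("reinitz", 8, dual_tfs=("Hb", "Kr")) == 20

    def test_one_tf(self):
        assert tm.count_free_parameters("reinitz", 1) == 4

    def test_segal_formula(self):
        assert tm.count_free_parameters("segal", 8, pwm_total_width=92, n_crms=44) == 344

    def test_segal_requires_widths(self):
        with pytest.raises(ValueError):
            tm.count_free_parameters("segal", 8)
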