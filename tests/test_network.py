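"""Mixed-ODE regression design, group LASSO and edge extraction."""

import numpy as np
import pytest

from idopnet.basis import LogisticParams, logistic_curve
from idopnet.io import AnalysisConfig
from idopnet.network import (
    ODEDecomposition,
    build_entanglement,
    build_regressors,
    decompose,
    decompose_trait_pair,
    extract_edges,
    group_lasso_fit,
    kkt_violation,
    lambda_max,
    select_lambda,
)

TIMES = np.linspace(0.0, 28.0, 15)


def curves(seed=0, n=4):
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        p = LogisticParams(a=rng.uniform(8, 15), b=rng.uniform(2, 50),
                           r=rng.uniform(0.3, 0.6))
        out[(f"s{i}", "HT")] = logistic_curve(p, TIMES)
    return out


@pytest.fixture
def simple_reg():
    cs = curves()
    focal = cs.pop(("s0", "HT"))
    return build_regressors(focal, cs, TIMES, node=("s0", "HT"))


class TestDesign:
    def test_column_counts_follow_orders(self):
        cs = curves(n=2)
        focal = cs.pop(("s0", "HT"))
        cfg = AnalysisConfig(lop_order_independent=2, lop_order_dependent=2,
                             independent_form="lop")
        reg = build_regressors(focal, cs, TIMES, config=cfg, node=("s0", "HT"))
        # linear-in-time column + 3 basis-times-curve integrals
        assert reg.self_block.shape == (15, 4)
        assert reg.groups[("s1", "HT")].shape == (15, 3)

    def test_logistic_self_block_has_two_columns(self, simple_reg):
        assert simple_reg.self_block.shape[1] == 2

    def test_response_anchored_at_first_time(self, simple_reg):
        assert simple_reg.response[0] == 0.0

    def test_zero_candidate_gives_zero_group(self):
        cs = curves(n=2)
        focal = cs.pop(("s0", "HT"))
        cs[("s1", "HT")] = np.zeros_like(TIMES)
        reg = build_regressors(focal, cs, TIMES, node=("s0", "HT"))
        assert np.all(reg.groups[("s1", "HT")] == 0.0)
        fit = group_lasso_fit(reg, 0.1 * lambda_max(reg))
        assert ("s1", "HT") not in fit.active

    def test_grid_mismatch_rejected(self):
        cs = curves(n=2)
        focal = cs.pop(("s0", "HT"))
        cs[("s1", "HT")] = cs[("s1", "HT")][:-1]
        with pytest.raises(ValueError, match="grid"):
            build_regressors(focal, cs, TIMES, node=("s0", "HT"))

    def test_focal_among_candidates_rejected(self):
        cs = curves(n=2)
        with pytest.raises(ValueError, match="own candidates"):
            build_regressors(cs[("s0", "HT")], cs, TIMES, node=("s0", "HT"))


class TestGroupLasso:
    def test_huge_penalty_zeroes_all_groups(self, simple_reg):
        fit = group_lasso_fit(simple_reg, 10.0 * lambda_max(simple_reg))
        assert fit.active == []
        # self block alone equals its own least squares
        b0, *_ = np.linalg.lstsq(simple_reg.self_block, simple_reg.response,
                                 rcond=None)
        assert np.allclose(fit.coef_self, b0, atol=1e-6)

    def test_zero_penalty_equals_least_squares(self, simple_reg):
        fit = group_lasso_fit(simple_reg, 0.0)
        X = np.hstack([simple_reg.self_block]
                      + [simple_reg.groups[g] for g in simple_reg.group_names])
        coef, *_ = np.linalg.lstsq(X, simple_reg.response, rcond=None)
        assert np.allclose(fit.fitted, X @ coef, atol=1e-6)

    @pytest.mark.parametrize("frac", [0.5, 0.1, 0.02])
    def test_kkt_conditions_hold(self, simple_reg, frac):
        lam = frac * lambda_max(simple_reg)
        fit = group_lasso_fit(simple_reg, lam)
        scale = max(np.max(np.abs(fit._X.T @ fit._z)), 1.0)
        assert kkt_violation(fit) <= 1e-5 * scale

    def test_negative_penalty_rejected(self, simple_reg):
        with pytest.raises(ValueError):
            group_lasso_fit(simple_reg, -1.0)


class TestSelection:
    def test_pure_noise_candidates_rejected(self):
        rng = np.random.default_rng(1)
        p = LogisticParams(a=12.0, b=9.0, r=0.45)
        focal = logistic_curve(p, TIMES)
        cands = {(f"n{i}", "HT"): rng.normal(0, 1, TIMES.size)
                 for i in range(3)}
        reg = build_regressors(focal, cands, TIMES, node=("f", "HT"))
        _, fit = select_lambda(reg)
        assert fit.support_ == []

    def test_single_true_regulator_selected(self):
        # focal trajectory generated by a logistic ODE driven by s1's curve
        from scipy.integrate import solve_ivp
        from scipy.interpolate import CubicSpline

        cs = curves(seed=3, n=4)
        cs.pop(("s0", "HT"))
        driver = CubicSpline(TIMES, cs[("s1", "HT")])

        def rhs(t, y):
            return 0.45 * y[0] * (1 - y[0] / 12.0) + 0.15 * driver(t)

        sol = solve_ivp(rhs, (0, 28), [1.2], t_eval=TIMES, rtol=1e-10)
        reg = build_regressors(sol.y[0], cs, TIMES, node=("s0", "HT"))
        _, fit = select_lambda(reg)
        assert fit.support_ == [("s1", "HT")]

    def test_active_count_monotone_along_path(self, simple_reg):
        _, fit = select_lambda(simple_reg)
        counts = fit.path_active_counts
        # traversed sparse -> dense: sizes non-decreasing up to rare
        # solver-tolerance exceptions
        violations = sum(b < a for a, b in zip(counts, counts[1:]))
        assert violations <= 1


class TestDecomposition:
    def test_additivity_machine_precision(self, simple_reg):
        _, fit = select_lambda(simple_reg)
        from idopnet.network import group_lasso_fit as glf

        fit0 = glf(simple_reg, 0.02 * lambda_max(simple_reg))
        dec = decompose(simple_reg, fit0)
        total = dec.independent.copy()
        for dep in dec.dependent.values():
            total = total + dep
        assert np.allclose(dec.overall, total, rtol=0, atol=1e-12)

    def test_empty_active_set_overall_equals_independent(self, simple_reg):
        fit = group_lasso_fit(simple_reg, 10.0 * lambda_max(simple_reg))
        dec = decompose(simple_reg, fit)
        assert dec.dependent == {}
        assert np.array_equal(dec.overall, dec.independent)


class TestEdges:
    def make_dec(self, dep_curve):
        t = TIMES
        return ODEDecomposition(
            node=("a", "HT"),
            times=t,
            overall=np.ones_like(t),
            independent=np.ones_like(t) - dep_curve,
            dependent={("b", "HT"): dep_curve},
            residual=np.zeros_like(t),
        )

    def test_positive_component_gives_positive_edge(self):
        net = extract_edges([self.make_dec(np.ones_like(TIMES))])
        (e,) = net.edges
        assert e.sign == 1 and np.isclose(e.weight, 1.0)

    def test_constant_negative_component(self):
        net = extract_edges([self.make_dec(-0.5 * np.ones_like(TIMES))])
        (e,) = net.edges
        assert e.sign == -1 and np.isclose(e.weight, 0.5)

    def test_zero_integral_tie_is_positive(self):
        x = np.linspace(-1, 1, TIMES.size)
        net = extract_edges([self.make_dec(x)])  # odd: integral 0, tie
        (e,) = net.edges
        assert e.sign == 1


class TestTraitPair:
    def test_uncoupled_traits_have_tiny_dependent_parts(self):
        a = logistic_curve(LogisticParams(10, 9, 0.5), TIMES)
        b = logistic_curve(LogisticParams(14, 3, 0.35), TIMES)
        da, db = decompose_trait_pair(a, b, TIMES)
        for dec, y in ((da, a), (db, b)):
            dep = sum(dec.dependent.values())
            assert np.linalg.norm(dep) / np.linalg.norm(y) < 0.05

    def test_mutual_promotion_gives_positive_integrals(self):
        from scipy.integrate import solve_ivp

        def rhs(t, y):
            return [
                0.4 * y[0] * (1 - y[0] / 10.0) + 0.1 * y[1],
                0.3 * y[1] * (1 - y[1] / 14.0) + 0.1 * y[0],
            ]

        sol = solve_ivp(rhs, (0, 28), [1.0, 1.5], t_eval=TIMES, rtol=1e-9)
        da, db = decompose_trait_pair(sol.y[0], sol.y[1], TIMES)
        for dec in (da, db):
            dep = sum(dec.dependent.values())
            assert np.trapezoid(dep, TIMES) > 0

    def test_additivity_exact(self):
        a = logistic_curve(LogisticParams(10, 9, 0.5), TIMES)
        b = logistic_curve(LogisticParams(14, 3, 0.35), TIMES)
        da, _ = decompose_trait_pair(a, b, TIMES)
        total = da.independent + sum(da.dependent.values())
        assert np.allclose(da.overall, total, atol=1e-12)


class TestEntanglement:
    def test_pleiotropic_edges_connect_identical_snps(self):
        from idopnet.simulate import SimScenario, default_topology, simulate_system

        topo = default_topology()
        times, clean, _ = simulate_system(topo, SimScenario(T=11, sigma2=0.0), 0)
        net, _ = build_entanglement(clean, times)
        for e in net.edges:
            if e.edge_type == "pleiotropic":
                assert e.source == e.target
                assert e.layer_source != e.layer_target

    def test_network_invariant_under_snp_relabeling(self):
        from idopnet.simulate import SimScenario, default_topology, simulate_system

        topo = default_topology()
        times, clean, _ = simulate_system(topo, SimScenario(T=15, sigma2=0.0), 0)
        net1, _ = build_entanglement(clean, times)
        mapping = {"1": "x1", "2": "x2", "3": "x3", "4": "x4", "5": "x5"}
        relabeled = {
            layer: {mapping[s]: v for s, v in d.items()}
            for layer, d in clean.items()
        }
        net2, _ = build_entanglement(relabeled, times)
        e1 = {(mapping[e.source], e.layer_source, mapping[e.target],
               e.layer_target, e.edge_type, e.sign) for e in net1.edges}
        e2 = {(e.source, e.layer_source, e.target, e.layer_target,
               e.edge_type, e.sign) for e in net2.edges}
        assert e1 == e2

    def test_mismatched_snp_sets_rejected(self):
        trait_curves = {
            "HT": {"a": np.ones(15), "b": np.ones(15)},
            "DIA": {"a": np.ones(15)},
        }
        with pytest.raises(ValueError, match="same SNPs"):
            build_entanglement(trait_curves, TIMES)
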