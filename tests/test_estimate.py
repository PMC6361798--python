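"""Tests for the marginal likelihood, model comparison, and fitting engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gradedrt.estimate import (
    DesignSummary,
    FitOptions,
    InvalidComparisonError,
    QuadratureSpec,
    count_free_parameters,
    dataset_loglik,
    deviance_test,
    deviance_test_from_values,
    fit_mml,
    information_criteria,
    person_loglik,
    standard_errors,
)
from gradedrt.model_core import ModelVariant, PopulationStructure
from tests.conftest import simulate_single_batch, small_config

V = ModelVariant


def _one_person(toy_items, responses, rts):
    return pd.DataFrame({
        "person_id": "p1",
        "item_id": [it.item_id for it in toy_items],
        "response": responses,
        "rt": rts,
        "interviewer_id": "iv1",
        "batch_id": "b1",
    })


def _mc_loglik(items, structure, responses, rts, n_draws, seed=0):
    """Brute-force Monte Carlo integration of one person's likelihood."""
    rng = np.random.default_rng(seed)
    H = structure.H
    L = np.linalg.cholesky(structure.R_theta)
    theta = rng.standard_normal((n_draws, H)) @ L.T
    tau = rng.standard_normal(n_draws)
    like = np.ones(n_draws)
    for it, y, t in zip(items, responses, rts):
        th = theta[:, it.domain - 1]
        if y is not None:
            upper = expit(it.a * (th[:, None] - it.thresholds))
            bounds = np.concatenate(
                [np.ones((n_draws, 1)), upper, np.zeros((n_draws, 1))], axis=1
            )
            like *= -np.diff(bounds, axis=1)[:, y - 1]
        if t is not None:
            rho = structure.rho[it.domain - 1]
            mu = it.lam + it.phi * tau - it.phi * rho * th
            like *= np.exp(
                -((np.log(t) - mu) ** 2) / (2 * it.sigma_omega**2)
            ) / (t * it.sigma_omega * np.sqrt(2 * np.pi))
    return float(np.log(like.mean()))


class TestPersonLoglik:
    def test_empty_person_is_zero(self, toy_items, structure_1d):
        empty = _one_person(toy_items, [1, 1, 1], [5, 5, 5]).iloc[:0]
        assert person_loglik(empty, toy_items, structure_1d) == 0.0

    def test_quadrature_matches_monte_carlo(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        quad = QuadratureSpec(nodes_per_dim=41)
        ll = person_loglik(rec, toy_items, structure_1d, quad=quad)
        mc = _mc_loglik(toy_items, structure_1d, [2, 1, 3], [7.0, 10.5, 5.0],
                        n_draws=10**6)
        assert abs((ll - mc) / mc) < 1e-3

    def test_analytic_tau_matches_numeric_tau(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        qa = QuadratureSpec(nodes_per_dim=41, tau_integration="analytic")
        qn = QuadratureSpec(nodes_per_dim=41, tau_integration="numeric",
                            tau_nodes=41)
        la = person_loglik(rec, toy_items, structure_1d, quad=qa)
        ln = person_loglik(rec, toy_items, structure_1d, quad=qn)
        assert la == pytest.approx(ln, abs=1e-6)

    def test_quadrature_converges_with_nodes(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        ref = person_loglik(rec, toy_items, structure_1d,
                            quad=QuadratureSpec(nodes_per_dim=61))
        errs = [
            abs(person_loglik(rec, toy_items, structure_1d,
                              quad=QuadratureSpec(nodes_per_dim=n)) - ref)
            for n in (5, 11, 31)
        ]
        assert errs[0] >= errs[1] >= errs[2] - 1e-12 and errs[2] < 1e-6

    def test_missing_entries_drop_out(self, toy_items, structure_1d):
        # a person with one missing response and one missing RT equals the
        # likelihood computed from the reduced record set
        rec = _one_person(toy_items, [2, np.nan, 3], [7.0, 10.5, np.nan])
        ll = person_loglik(rec, toy_items, structure_1d)
        manual = (
            _mc_loglik(toy_items, structure_1d, [2, None, 3],
                       [7.0, 10.5, None], n_draws=2 * 10**6)
        )
        assert ll == pytest.approx(manual, abs=5e-3)


class TestDatasetLoglik:
    def test_single_person_equals_person_loglik(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        assert dataset_loglik(rec, toy_items, structure_1d) == pytest.approx(
            person_loglik(rec, toy_items, structure_1d)
        )

    def test_duplicated_person_doubles(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        dup = pd.concat([rec, rec.assign(person_id="p2")], ignore_index=True)
        assert dataset_loglik(dup, toy_items, structure_1d) == pytest.approx(
            2 * dataset_loglik(rec, toy_items, structure_1d)
        )

    def test_order_invariance(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        two = pd.concat(
            [rec, rec.assign(person_id="p2", response=[1, 2, 2])],
            ignore_index=True,
        )
        shuffled = two.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert dataset_loglik(two, toy_items, structure_1d) == pytest.approx(
            dataset_loglik(shuffled, toy_items, structure_1d), rel=1e-12
        )

    def test_permuted_item_list_identical(self, toy_items, structure_1d):
        rec = _one_person(toy_items, [2, 1, 3], [7.0, 10.5, 5.0])
        ll1 = dataset_loglik(rec, toy_items, structure_1d)
        ll2 = dataset_loglik(rec, toy_items[::-1], structure_1d)
        assert ll1 == pytest.approx(ll2, rel=1e-12)


class TestParameterCounting:
    # category-count buckets as printed for the two internally consistent
    # batch designs, H = 3 dimensions
    batch1 = DesignSummary({2: 1, 3: 31, 4: 77}, H=3, P=6, J=109)
    batch4 = DesignSummary({3: 23, 4: 72}, H=3, P=5, J=95)

    @pytest.mark.parametrize("design,variant,expected", [
        (batch1, V.MODEL0, 736),
        (batch1, V.MODEL1, 1281),
        (batch1, V.MODEL3, 741),
        (batch1, V.MODEL2, 741),
        (batch4, V.MODEL0, 648),
        (batch4, V.MODEL1, 1028),
        (batch4, V.MODEL3, 652),
        (batch4, V.MODEL2, 652),
    ])
    def test_published_design_counts(self, design, variant, expected):
        assert count_free_parameters(design, variant) == expected

    def test_mgrm_only_drops_rt_terms(self):
        d = DesignSummary({4: 10}, H=3, P=5, J=10)
        assert count_free_parameters(d, V.MGRM_ONLY) == 10 * 4 + 3
        assert count_free_parameters(d, V.MODEL0) == 10 * 4 + 3 + 30 + 3


class TestInformationCriteria:
    @pytest.mark.parametrize("m2ll,k,n,aic,bic", [
        (132094, 736, 563, 133566, 136755),
        (107060, 652, 507, 108364, 111121),
    ])
    def test_published_values(self, m2ll, k, n, aic, bic):
        a, b = information_criteria(m2ll, k, n)
        assert round(a) == aic and round(b) == bic

    def test_zero_parameters(self):
        a, b = information_criteria(100.0, 0, 50)
        assert a == b == 100.0


class TestDevianceTest:
    def test_from_printed_deviances(self):
        # main-effect variant against the item-interaction variant
        delta, df, p = deviance_test_from_values(130612, 1281, 131926, 741)
        assert delta == 1314 and df == 540
        assert p < 1e-6

    def test_identical_fits(self):
        delta, df, p = deviance_test_from_values(500.0, 10, 500.0, 10)
        assert delta == 0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self):
        class Dummy:
            def __init__(self, v, k):
                self.variant, self.n_free_params = v, k
                self.minus2ll, self.n_persons = 100.0, 50

        with pytest.raises(InvalidComparisonError):
            deviance_test(Dummy(V.MODEL2, 10), Dummy(V.MODEL3, 10))


@pytest.fixture(scope="module")
def fitted_1d():
    """A converged 1-D joint fit reused by several invariance tests."""
    cfg = small_config(seed=21, N=250, J=8, H=1)
    table, bank, *_ = simulate_single_batch(cfg, V.MODEL0)
    dom = {it.item_id: it.domain for it in bank}
    opts = FitOptions(max_iter=400, tol=1e-8,
                      quad=QuadratureSpec(nodes_per_dim=21))
    fit = fit_mml(table, V.MODEL0, H=1, domains=dom, options=opts)
    return cfg, table, bank, dom, opts, fit


class TestFitting:
    def test_em_matches_direct_engine(self, fitted_1d):
        cfg, table, bank, dom, opts, fit = fitted_1d
        direct = fit_mml(
            table, V.MODEL0, H=1, domains=dom,
            options=FitOptions(engine="direct", max_iter=300, tol=1e-10,
                               quad=QuadratureSpec(nodes_per_dim=21)),
        )
        assert fit.minus2ll == pytest.approx(direct.minus2ll, abs=0.05)
        a_em = np.array([it.a for it in fit.items])
        a_dir = np.array([it.a for it in direct.items])
        np.testing.assert_allclose(a_em, a_dir, atol=0.02)

    def test_rt_rescaling_shifts_only_lambda(self, fitted_1d):
        cfg, table, bank, dom, opts, fit = fitted_1d
        c = 3.0
        scaled = table.assign(rt=table["rt"] * c)
        fit2 = fit_mml(scaled, V.MODEL0, H=1, domains=dom, options=opts)
        lam1 = np.array([it.lam for it in fit.items])
        lam2 = np.array([it.lam for it in fit2.items])
        np.testing.assert_allclose(lam2 - lam1, np.log(c), atol=1e-3)
        for attr in ("a", "phi", "sigma_omega"):
            v1 = np.array([getattr(it, attr) for it in fit.items])
            v2 = np.array([getattr(it, attr) for it in fit2.items])
            np.testing.assert_allclose(v1, v2, atol=1e-3)
        np.testing.assert_allclose(fit.structure.rho, fit2.structure.rho,
                                   atol=1e-3)

    def test_mgrm_only_ignores_rts(self, fitted_1d):
        cfg, table, bank, dom, opts, fit = fitted_1d
        shuffled = table.copy()
        rng = np.random.default_rng(0)
        shuffled["rt"] = rng.permutation(shuffled["rt"].to_numpy())
        f1 = fit_mml(table, V.MGRM_ONLY, H=1, domains=dom, options=opts)
        f2 = fit_mml(shuffled, V.MGRM_ONLY, H=1, domains=dom, options=opts)
        np.testing.assert_allclose(
            [it.a for it in f1.items], [it.a for it in f2.items], rtol=1e-12
        )

    def test_null_cross_relation_recovered(self):
        cfg = small_config(seed=23, N=300, J=8, H=1, rho=(0.0,))
        table, bank, *_ = simulate_single_batch(cfg, V.MODEL0)
        fit = fit_mml(
            table, V.MODEL0, H=1,
            domains={it.item_id: it.domain for it in bank},
            options=FitOptions(max_iter=300, tol=1e-8,
                               quad=QuadratureSpec(nodes_per_dim=15)),
        )
        assert abs(fit.structure.rho[0]) < 0.1  # ~2 x sampling SE at N=300

    def test_nonconvergence_flagged(self, fitted_1d):
        cfg, table, bank, dom, _, _ = fitted_1d
        with pytest.warns(UserWarning):
            fit = fit_mml(
                table, V.MODEL0, H=1, domains=dom,
                options=FitOptions(max_iter=2, tol=1e-12,
                                   quad=QuadratureSpec(nodes_per_dim=11)),
            )
        assert not fit.converged


class TestStandardErrors:
    def test_positive_finite_and_scaling(self, fitted_1d):
        cfg, table, bank, dom, opts, fit = fitted_1d
        quad = QuadratureSpec(nodes_per_dim=15)
        se = standard_errors(fit, table, quad=quad)
        vals = np.array(list(se.values()))
        assert np.all(np.isfinite(vals)) and np.all(vals > 0)
        # information additivity: duplicating the sample shrinks SEs by 1/sqrt 2
        dup = pd.concat(
            [table, table.assign(person_id=table["person_id"] + "_dup")],
            ignore_index=True,
        )
        se2 = standard_errors(fit, dup, quad=quad)
        ratio = np.array([se2[k] / se[k] for k in se])
        np.testing.assert_allclose(ratio, 1 / np.sqrt(2), atol=1e-6)

    def test_constrained_parameters_absent(self, fitted_1d):
        cfg, table, bank, dom, opts, fit = fitted_1d
        se = standard_errors(fit, table, quad=QuadratureSpec(nodes_per_dim=11))
        assert not any(k.startswith("R[") for k in se)  # H=1: no correlations
        assert all("gamma" not in k for k in se)  # MODEL0: no interviewers
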