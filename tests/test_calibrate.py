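"""Tests for batch stacking, concurrent and fixed-parameter calibration."""

import numpy as np
import pandas as pd
import pytest

from gradedrt.calibrate import (
    BatchedDataset,
    FixedParameterSet,
    StructuralError,
    concurrent_calibrate,
    fixed_parameter_calibrate,
    linking_diagnostics,
    stack_batches,
)
from gradedrt.estimate import FitOptions, QuadratureSpec, dataset_loglik, fit_mml
from gradedrt.model_core import ModelVariant
from gradedrt.synthetic_data import SimulationConfig, make_linked_batches

V = ModelVariant


def _tiny_batched(seed=31, n=10, unique=8, linking=4, n_batches=2):
    cfg = SimulationConfig(
        seed=seed,
        n_per_batch=(n,) * n_batches,
        unique_per_batch=(unique,) * n_batches,
        n_linking=linking,
        H=1, R_theta=((1.0,),), rho=(0.45,),
        category_fractions=(0.0, 0.3, 0.7),
        P_per_batch=(1,) * n_batches,
        gamma_per_batch=((0.0,),) * n_batches,
        contamination_fraction=0.0,
        missing_response_rate=0.0,
    )
    batched, bank, truth = make_linked_batches(cfg)
    return cfg, batched, bank, truth


class TestBatchedStructure:
    def test_stacked_row_count(self):
        # 2 batches x 10 persons x (8 unique + 4 linking) items
        _, batched, *_ = _tiny_batched()
        stacked = stack_batches(batched)
        assert len(stacked) == 2 * 10 * 12
        assert stacked["person_id"].nunique() == 20
        assert stacked["item_id"].nunique() == 4 + 2 * 8

    def test_single_batch_identity(self):
        _, batched, *_ = _tiny_batched(n_batches=1)
        only = next(iter(batched.batches.values()))
        pd.testing.assert_frame_equal(stack_batches(batched), only)

    def test_duplicate_person_rejected(self):
        _, batched, *_ = _tiny_batched()
        b1, b2 = batched.batches["b1"], batched.batches["b2"]
        clash = b2.copy()
        clash["person_id"] = b1["person_id"].iloc[0]
        with pytest.raises(StructuralError):
            BatchedDataset(batches={"b1": b1, "b2": clash},
                           linking_item_ids=batched.linking_item_ids)

    def test_missing_linking_item_rejected(self):
        _, batched, *_ = _tiny_batched()
        b2 = batched.batches["b2"]
        lid = sorted(batched.linking_item_ids)[0]
        with pytest.raises(StructuralError):
            BatchedDataset(
                batches={"b1": batched.batches["b1"],
                         "b2": b2[b2["item_id"] != lid]},
                linking_item_ids=batched.linking_item_ids,
            )

    def test_unlinked_batches_rejected(self):
        _, batched, *_ = _tiny_batched()
        with pytest.raises(StructuralError):
            concurrent_calibrate(
                BatchedDataset(batches=batched.batches, linking_item_ids=set()),
                V.MODEL0,
            )

    def test_missing_by_design_likelihood_separates(self):
        # with zero linking items and shared population parameters, the
        # stacked likelihood is exactly the sum of per-batch likelihoods
        cfg, batched, bank, _ = _tiny_batched(n=25)
        b1 = batched.batches["b1"]
        b2 = batched.batches["b2"]
        only = {it for it in b2["item_id"].unique()} - batched.linking_item_ids
        b2u = b2[b2["item_id"].isin(only)]
        stacked = pd.concat([b1, b2u], ignore_index=True)
        st = cfg.structure()
        quad = QuadratureSpec(nodes_per_dim=15)
        ids1 = set(b1["item_id"])
        items1 = [it for it in bank if it.item_id in ids1]
        items2 = [it for it in bank if it.item_id in only]
        ll = dataset_loglik(stacked, items1 + items2, st, quad=quad)
        ll1 = dataset_loglik(b1, items1, st, quad=quad)
        ll2 = dataset_loglik(b2u, items2, st, quad=quad)
        assert ll == pytest.approx(ll1 + ll2, rel=1e-10)


@pytest.fixture(scope="module")
def calibrated_pair():
    """Two linked batches from one bank, concurrently calibrated."""
    cfg = SimulationConfig(
        seed=37, n_per_batch=(200, 200), unique_per_batch=(6, 6), n_linking=6,
        H=1, R_theta=((1.0,),), rho=(0.45,),
        category_fractions=(0.0, 0.3, 0.7),
        P_per_batch=(1, 1), gamma_per_batch=((0.0,), (0.0,)),
        contamination_fraction=0.0, missing_response_rate=0.0,
    )
    batched, bank, truth = make_linked_batches(cfg)
    dom = {it.item_id: it.domain for it in bank}
    opts = FitOptions(max_iter=400, tol=1e-8,
                      quad=QuadratureSpec(nodes_per_dim=15))
    fit = concurrent_calibrate(batched, V.MODEL0, H=1, domains=dom,
                               options=opts, min_linking_fraction=0.2)
    return cfg, batched, bank, dom, opts, fit


class TestConcurrentCalibration:
    def test_recovers_unique_items_on_common_scale(self, calibrated_pair):
        cfg, batched, bank, dom, opts, fit = calibrated_pair
        assert fit.converged
        a_true = {it.item_id: it.a for it in bank}
        lam_true = {it.item_id: it.lam for it in bank}
        a_err = [fit.item(i).a - a_true[i] for i in a_true]
        lam_err = [fit.item(i).lam - lam_true[i] for i in lam_true]
        assert abs(np.mean(a_err)) < 0.12
        assert abs(np.mean(lam_err)) < 0.05
        assert fit.structure.rho[0] == pytest.approx(0.45, abs=0.12)

    def test_single_batch_equals_fit_mml(self):
        cfg, batched, bank, truth = _tiny_batched(n=40, n_batches=1)
        dom = {it.item_id: it.domain for it in bank}
        opts = FitOptions(max_iter=60, tol=1e-6,
                          quad=QuadratureSpec(nodes_per_dim=11))
        f1 = concurrent_calibrate(batched, V.MODEL0, H=1, domains=dom,
                                  options=opts)
        f2 = fit_mml(stack_batches(batched), V.MODEL0, H=1, domains=dom,
                     options=opts)
        assert f1.minus2ll == pytest.approx(f2.minus2ll, rel=1e-12)

    def test_low_linking_fraction_warns(self):
        _, batched, bank, _ = _tiny_batched(n=15, unique=8, linking=1)
        dom = {it.item_id: it.domain for it in bank}
        with pytest.warns(UserWarning, match="linking fraction"):
            concurrent_calibrate(
                batched, V.MGRM_ONLY, H=1, domains=dom,
                options=FitOptions(max_iter=3, tol=1e-3,
                                   quad=QuadratureSpec(nodes_per_dim=5)),
            )


class TestFixedParameterCalibration:
    def test_frozen_values_bit_identical(self, calibrated_pair):
        cfg, batched, bank, dom, opts, fit = calibrated_pair
        anchors = sorted(batched.linking_item_ids)
        fixed = FixedParameterSet(
            items={i: fit.item(i) for i in anchors}, source="stage1"
        )
        new = batched.batches["b2"]
        refit = fixed_parameter_calibrate(
            new, fixed, V.MODEL0, H=1, domains=dom,
            options=FitOptions(max_iter=100, tol=1e-7,
                               quad=QuadratureSpec(nodes_per_dim=15)),
        )
        for i in anchors:
            assert refit.item(i).a == fit.item(i).a  # bit-exact
            assert np.array_equal(refit.item(i).thresholds,
                                  fit.item(i).thresholds)
            assert refit.item(i).lam == fit.item(i).lam
            assert refit.item(i).phi == fit.item(i).phi
        diag = linking_diagnostics(fit, refit, anchors)
        deltas = diag[diag["item_id"] == "max_abs"].drop(columns="item_id")
        assert float(deltas.to_numpy().max()) == 0.0
        # two-stage scale transfer: the held-out batch's unique items are
        # recovered against the frozen anchors, near their generating values
        unique2 = sorted(set(new["item_id"]) - set(anchors))
        a_true = {it.item_id: it.a for it in bank}
        lam_true = {it.item_id: it.lam for it in bank}
        a_err = [refit.item(i).a - a_true[i] for i in unique2]
        lam_err = [refit.item(i).lam - lam_true[i] for i in unique2]
        assert abs(np.mean(a_err)) < 0.2
        assert abs(np.mean(lam_err)) < 0.06

    def test_free_items_recovered_against_frozen_truth(self):
        cfg, batched, bank, truth = _tiny_batched(seed=41, n=250, unique=8,
                                                  linking=8, n_batches=1)
        table = batched.batches["b1"]
        dom = {it.item_id: it.domain for it in bank}
        anchors = sorted(batched.linking_item_ids)
        fixed = FixedParameterSet(
            items={i: next(it for it in bank if it.item_id == i)
                   for i in anchors},
            source="truth",
        )
        fit = fixed_parameter_calibrate(
            table, fixed, V.MODEL0, H=1, domains=dom,
            options=FitOptions(max_iter=300, tol=1e-8,
                               quad=QuadratureSpec(nodes_per_dim=15)),
        )
        free = [it for it in bank if it.item_id not in anchors]
        a_err = [fit.item(it.item_id).a - it.a for it in free]
        lam_err = [fit.item(it.item_id).lam - it.lam for it in free]
        assert abs(np.mean(a_err)) < 0.15
        assert abs(np.mean(lam_err)) < 0.06

    def test_freeze_all_items_estimates_population_only(self):
        cfg, batched, bank, truth = _tiny_batched(seed=43, n=200, unique=4,
                                                  linking=8, n_batches=1)
        table = batched.batches["b1"]
        dom = {it.item_id: it.domain for it in bank}
        fixed = FixedParameterSet(items={it.item_id: it for it in bank})
        fit = fixed_parameter_calibrate(
            table, fixed, V.MODEL0, H=1, domains=dom,
            options=FitOptions(max_iter=200, tol=1e-8,
                               quad=QuadratureSpec(nodes_per_dim=15)),
        )
        for it in bank:
            assert fit.item(it.item_id).a == it.a
        # population cross-relation still estimated, near truth
        assert fit.structure.rho[0] == pytest.approx(0.45, abs=0.15)

    def test_anchor_with_collapsed_categories(self, calibrated_pair):
        # the new batch observed one fewer category for an anchor: only the
        # matching upper thresholds are imposed
        cfg, batched, bank, dom, opts, fit = calibrated_pair
        anchors = sorted(batched.linking_item_ids)
        target = next(i for i in anchors if fit.item(i).n_categories == 4)
        new = batched.batches["b2"].copy()
        sel = new["item_id"] == target
        # collapse bottom two observed categories: codes 1..4 -> 1..3
        new.loc[sel, "response"] = np.maximum(new.loc[sel, "response"] - 1, 1)
        fixed = FixedParameterSet(items={target: fit.item(target)})
        refit = fixed_parameter_calibrate(
            new, fixed, V.MODEL0, H=1, domains=dom,
            options=FitOptions(max_iter=30, tol=1e-5,
                               quad=QuadratureSpec(nodes_per_dim=11)),
        )
        got = refit.item(target)
        assert got.thresholds.size == 2
        np.testing.assert_array_equal(got.thresholds,
                                      fit.item(target).thresholds[-2:])

    def test_absent_frozen_item_rejected(self, calibrated_pair):
        cfg, batched, bank, dom, opts, fit = calibrated_pair
        fixed = FixedParameterSet(items={"nonexistent": bank[0]})
        with pytest.raises(Exception):
            fixed_parameter_calibrate(batched.batches["b2"], fixed, V.MODEL0,
                                      H=1, domains=dom)


class TestLinkingDiagnostics:
    def test_no_shared_ids_rejected(self, calibrated_pair):
        *_, fit = calibrated_pair
        with pytest.raises(Exception):
            linking_diagnostics(fit, fit, [])

    def test_identical_fits_zero_deltas(self, calibrated_pair):
        cfg, batched, bank, dom, opts, fit = calibrated_pair
        diag = linking_diagnostics(fit, fit, sorted(batched.linking_item_ids))
        num = diag.drop(columns="item_id").to_numpy(dtype=float)
        assert np.nanmax(np.abs(num)) == 0.0
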