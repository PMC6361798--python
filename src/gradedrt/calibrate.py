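"""Placing items from multiple collection batches on a common scale.

Concurrent calibration stacks every batch into one long table whose
structural missingness (each person saw only their batch's items) is
handled by the marginal likelihood, so the shared linking items receive a
single parameter set and all unique items land on that scale in one fit.
Fixed-parameter calibration instead freezes previously estimated anchor
parameters and estimates only the new items and population parameters, so
no post-hoc linking transformation is ever needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import FitOptions, FitResult, fit_mml
from .model_core import InvalidInputError, ItemParameters, ModelVariant


class StructuralError(ValueError):
    """Raised when the batch/linking structure violates its invariants."""


@dataclass
class BatchedDataset:
    """Per-batch long tables plus the shared linking item ids."""

    batches: dict  # batch_id -> DataFrame
    linking_item_ids: set

    def __post_init__(self) -> None:
        self.linking_item_ids = set(self.linking_item_ids)
        items_by_batch = {
            b: set(t["item_id"].unique()) for b, t in self.batches.items()
        }
        for b, items in items_by_batch.items():
            missing = self.linking_item_ids - items
            if missing:
                raise StructuralError(
                    f"linking items {sorted(missing)[:3]}... absent from batch {b}"
                )
        seen: dict = {}
        for b, items in items_by_batch.items():
            for it in items - self.linking_item_ids:
                if it in seen:
                    raise StructuralError(
                        f"non-linking item {it} appears in batches {seen[it]} and {b}"
                    )
                seen[it] = b
        persons: dict = {}
        for b, t in self.batches.items():
            for p in t["person_id"].unique():
                if p in persons:
                    raise StructuralError(
                        f"person {p} appears in batches {persons[p]} and {b}"
                    )
                persons[p] = b

    @property
    def linking_fraction(self) -> float:
        sizes = [t["item_id"].nunique() for t in self.batches.values()]
        return len(self.linking_item_ids) / min(sizes)


@dataclass
class FixedParameterSet:
    """Anchor parameters frozen during fixed-parameter calibration."""

    items: dict  # item_id -> ItemParameters with (a, thresholds, lam, phi)
    source: str = ""

    def __post_init__(self) -> None:
        self.items = {k: v for k, v in self.items.items()}


def stack_batches(batched: BatchedDataset) -> pd.DataFrame:
    """Concatenate batches into one long table.

    Structural missingness needs no explicit rows: a person simply has no
    row for items outside their batch, which the likelihood treats as
    missing by design.
    """
    if not batched.batches:
        return pd.DataFrame(
            columns=["person_id", "item_id", "response", "rt",
                     "interviewer_id", "batch_id"]
        )
    return pd.concat(batched.batches.values(), ignore_index=True)


def concurrent_calibrate(
    batched: BatchedDataset,
    variant: ModelVariant,
    items: list | None = None,
    H: int = 3,
    domains: dict | None = None,
    options: FitOptions | None = None,
    min_linking_fraction: float = 0.20,
) -> FitResult:
    """One joint fit over all stacked batches.

    Warns (does not fail) when the shared-anchor fraction falls below the
    conventional 20% floor for linking designs.
    """
    if len(batched.batches) > 1 and not batched.linking_item_ids:
        raise StructuralError("batches share no linking items")
    if batched.linking_fraction < min_linking_fraction:
        warnings.warn(
            f"linking fraction {batched.linking_fraction:.2f} below "
            f"{min_linking_fraction:.2f}; the common scale may be weakly linked"
        )
    stacked = stack_batches(batched)
    return fit_mml(stacked, variant, items=items, H=H, domains=domains,
                   options=options)


def _match_frozen_to_data(
    fixed: FixedParameterSet, table: pd.DataFrame
) -> dict:
    """Align frozen anchors to the categories observed in the new data.

    When the new batch observed fewer categories than the anchor was
    calibrated with (its sparse bottom categories collapsed upward), only
    the corresponding upper thresholds and the discrimination are imposed:
    for K' observed categories, the last K'-1 frozen thresholds.
    """
    out = {}
    obs_k = (
        table.dropna(subset=["response"])
        .groupby("item_id")["response"]
        .max()
        .astype(int)
    )
    for item_id, fz in fixed.items.items():
        if item_id not in obs_k.index:
            raise InvalidInputError(f"frozen item {item_id} absent from dataset")
        K_obs = max(int(obs_k[item_id]), 2)
        if K_obs - 1 < fz.thresholds.size:
            out[item_id] = ItemParameters(
                item_id=fz.item_id, domain=fz.domain, a=fz.a,
                thresholds=fz.thresholds[-(K_obs - 1):].copy(),
                lam=fz.lam, phi=fz.phi, sigma_omega=fz.sigma_omega,
            )
        else:
            out[item_id] = fz
    return out


def fixed_parameter_calibrate(
    table: pd.DataFrame,
    fixed: FixedParameterSet,
    variant: ModelVariant,
    items: list | None = None,
    H: int = 3,
    domains: dict | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Estimate new items with anchors frozen at previously fitted values.

    Frozen (a, thresholds, lam, phi) are bit-identical in the output; the
    anchors' residual RT variances and all population and interviewer
    parameters are re-estimated against the frozen values.
    """
    frozen = _match_frozen_to_data(fixed, table)
    return fit_mml(table, variant, items=items, H=H, domains=domains,
                   options=options, frozen_items=frozen)


def linking_diagnostics(
    stage1: FitResult, stage2: FitResult, linking_ids
) -> pd.DataFrame:
    """Per-anchor parameter deltas (stage2 - stage1) with a max |delta| row.

    All deltas are exactly zero after fixed-parameter calibration; after
    two independent concurrent fits they reflect optimizer and sampling
    noise.
    """
    linking_ids = list(linking_ids)
    if not linking_ids:
        raise InvalidInputError("no shared linking ids")
    rows = []
    for iid in linking_ids:
        it1 = stage1.item(iid)
        it2 = stage2.item(iid)
        n = min(it1.thresholds.size, it2.thresholds.size)
        row = {
            "item_id": iid,
            "delta_a": it2.a - it1.a,
            "delta_lam": it2.lam - it1.lam,
            "delta_phi": it2.phi - it1.phi,
        }
        for k in range(n):
            row[f"delta_b{k + 1}"] = (
                it2.thresholds[-(n - k)] - it1.thresholds[-(n - k)]
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    num = df.drop(columns="item_id")
    summary = {"item_id": "max_abs", **num.abs().max().to_dict()}
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
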