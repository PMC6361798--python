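"""File formats: long-format CSV tables, parameter CSVs, JSON summaries.

The interchange format is deliberately plain CSV: one row per person-item
encounter with columns person_id, item_id, response, rt, interviewer_id,
batch_id (missing values empty).  Parameter tables use one row per item
with columns item_id, domain, a, b1..b3 (blank when the item has fewer
categories), lam, phi, sigma_omega; population structure and interviewer
effects travel as a JSON document.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import FitResult, information_criteria
from .model_core import (
    InterviewerDesign,
    ItemParameters,
    ModelVariant,
    PopulationStructure,
)
from .preprocess import REQUIRED_COLUMNS


class FormatError(ValueError):
    pass


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format dataset CSV with validation.

    Raises :class:`FormatError` on missing columns or duplicated
    (person_id, item_id) keys (named in the message); warns on an
    empty-but-headered file.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "item_id": str,
                                  "interviewer_id": str, "batch_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty dataset")
        return df
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    df["rt"] = pd.to_numeric(df["rt"], errors="coerce")
    dup = df.duplicated(subset=["person_id", "item_id"], keep=False)
    if dup.any():
        first = df.loc[dup, ["person_id", "item_id"]].iloc[0]
        raise FormatError(
            f"duplicate (person_id, item_id) key: "
            f"({first['person_id']}, {first['item_id']}) "
            f"at line {int(df.index[dup][0]) + 2}"
        )
    bad_rt = df["rt"].notna() & (df["rt"] <= 0)
    if bad_rt.any():
        raise FormatError(
            f"non-positive rt at line {int(df.index[bad_rt][0]) + 2}"
        )
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def items_to_frame(items) -> pd.DataFrame:
    kmax = max(it.n_categories for it in items)
    rows = []
    for it in items:
        row = {"item_id": it.item_id, "domain": it.domain, "a": it.a}
        for k in range(kmax - 1):
            row[f"b{k + 1}"] = (
                it.thresholds[k] if k < it.thresholds.size else np.nan
            )
        row.update(lam=it.lam, phi=it.phi, sigma_omega=it.sigma_omega)
        rows.append(row)
    return pd.DataFrame(rows)


def write_item_parameters(items, path) -> None:
    items_to_frame(items).to_csv(path, index=False)


def read_item_parameters(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    items = []
    bcols = sorted(c for c in df.columns if c.startswith("b") and c[1:].isdigit())
    for _, row in df.iterrows():
        thr = np.array([row[c] for c in bcols if np.isfinite(row[c])])
        items.append(ItemParameters(
            item_id=str(row["item_id"]), domain=int(row["domain"]),
            a=float(row["a"]), thresholds=thr,
            lam=float(row.get("lam", np.nan)),
            phi=float(row.get("phi", np.nan)),
            sigma_omega=float(row.get("sigma_omega", np.nan)),
        ))
    return items


def structure_to_dict(structure: PopulationStructure,
                      design: InterviewerDesign | None = None) -> dict:
    out = {
        "H": structure.H,
        "R_theta": structure.R_theta.tolist(),
        "rho": structure.rho.tolist(),
    }
    if design is not None:
        out["interviewer"] = {
            "P": design.P,
            "reference": design.reference,
            "gamma": np.asarray(design.gamma).tolist(),
            "roster": list(design.roster) if design.roster else None,
        }
    return out


def structure_from_dict(d: dict):
    structure = PopulationStructure(
        H=int(d["H"]), R_theta=np.asarray(d["R_theta"], float),
        rho=np.asarray(d["rho"], float),
    )
    design = None
    if d.get("interviewer"):
        iv = d["interviewer"]
        design = InterviewerDesign(
            P=int(iv["P"]), reference=int(iv["reference"]),
            gamma=np.asarray(iv["gamma"], float), roster=iv.get("roster"),
        )
    return structure, design


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_fit_result(fit: FitResult, out_dir, config: dict | None = None) -> dict:
    """Serialize a fit: parameter CSV, JSON summary, optional SE table.

    Returns the summary dict.  Outputs are deterministic for a given fit;
    the summary embeds the config hash and seed when a config is given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = fit.variant.value
    write_item_parameters(fit.items, out_dir / f"items_{tag}.csv")
    summary = {
        "variant": tag,
        "loglik": fit.loglik,
        "minus2LL": fit.minus2ll,
        "n_free_params": fit.n_free_params,
        "converged": bool(fit.converged),
        "n_iterations": fit.n_iterations,
        "n_persons": fit.n_persons,
        "structure": structure_to_dict(fit.structure, fit.design),
    }
    if config is not None:
        summary["config_hash"] = config_hash(config)
        summary["seed"] = config.get("seed")
    with open(out_dir / f"fit_{tag}.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    if fit.standard_errors:
        pd.DataFrame(
            sorted(fit.standard_errors.items()), columns=["parameter", "se"]
        ).to_csv(out_dir / f"se_{tag}.csv", index=False)
    return summary


def write_comparison_table(fits: list, n_persons: int, path) -> pd.DataFrame:
    """Model-comparison CSV: one row per variant, sorted by BIC."""
    rows = []
    for fit in fits:
        aic, bic = information_criteria(fit.minus2ll, fit.n_free_params, n_persons)
        rows.append({
            "model": fit.variant.value,
            "n_free_params": fit.n_free_params,
            "AIC": aic, "BIC": bic, "minus2LL": fit.minus2ll,
        })
    df = pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)
    df.to_csv(path, index=False)
    return df


def variant_from_string(s: str) -> ModelVariant:
    key = s.strip().lower().replace("-", "_").replace(" ", "_")
    aliases = {"mgrm": "mgrm_only", "0": "model0", "1": "model1",
               "2": "model2", "3": "model3"}
    key = aliases.get(key, key)
    return ModelVariant(key)
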