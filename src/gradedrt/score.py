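"""EAP scoring of latent traits and speed, with posterior-SD standard errors.

Scores are posterior means over the same Gauss-Hermite grid used in
estimation; the posterior SD serves as the reported standard error.
Scoring under an RT-bearing variant conditions on both the responses and
the response times, which is where the precision gain from RTs shows up;
under the response-only model the RT columns are ignored entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import QuadratureSpec, _Arrays, _loglik_components
from .model_core import (
    InterviewerDesign,
    InvalidInputError,
    ModelVariant,
    PopulationStructure,
)


@dataclass
class ScoreResult:
    """EAP estimates for one person."""

    person_id: str
    theta_hat: np.ndarray
    se_theta: np.ndarray
    tau_hat: float
    se_tau: float
    variant: ModelVariant
    prior_only: bool = False


def score_dataset(
    table: pd.DataFrame,
    params: list,
    structure: PopulationStructure,
    design: InterviewerDesign | None = None,
    variant: ModelVariant = ModelVariant.MODEL0,
    quad: QuadratureSpec | None = None,
) -> pd.DataFrame:
    """EAP score every person in a long table.

    Returns one row per person: theta1..H, tau, their posterior SDs, the
    variant label, and a flag for persons with no observed data (whose
    posterior is the prior: zero mean, unit SD).
    """
    quad = quad or QuadratureSpec()
    roster = list(design.roster) if design is not None and design.roster else None
    arrays = _Arrays(table, params, roster=roster)
    _, mom = _loglik_components(
        arrays, structure, design, variant, quad, want_moments=True
    )
    post = mom["post"]
    theta_nodes = mom["theta_nodes"]
    H = structure.H
    Eth = post @ theta_nodes
    Vth = post @ (theta_nodes * theta_nodes) - Eth**2
    if variant.uses_rt:
        m, v, tau_shift = mom["m"], mom["v"], mom["tau_shift"]
        Eeps = (post * m).sum(axis=1)
        Veps = (post * m * m).sum(axis=1) + v - Eeps**2
        tau_hat = tau_shift + Eeps
        se_tau = np.sqrt(np.clip(Veps, 0, None))
    else:
        tau_hat = np.full(len(arrays.persons), np.nan)
        se_tau = np.full(len(arrays.persons), np.nan)
    no_data = (arrays.resp >= 0).sum(axis=1) == 0
    if variant.uses_rt:
        no_data &= ~arrays.rt_mask.any(axis=1)
    out = {"person_id": arrays.persons}
    for d in range(H):
        out[f"theta{d + 1}"] = Eth[:, d]
    out["tau"] = tau_hat
    for d in range(H):
        out[f"se_theta{d + 1}"] = np.sqrt(np.clip(Vth[:, d], 0, None))
    out["se_tau"] = se_tau
    out["variant"] = variant.value
    out["prior_only"] = no_data
    return pd.DataFrame(out)


def eap_score(
    records: pd.DataFrame,
    params: list,
    structure: PopulationStructure,
    design: InterviewerDesign | None = None,
    variant: ModelVariant = ModelVariant.MODEL0,
    quad: QuadratureSpec | None = None,
) -> ScoreResult:
    """EAP estimate for a single person's records."""
    if records.empty:
        raise InvalidInputError("no records supplied")
    df = score_dataset(records, params, structure, design, variant, quad)
    row = df.iloc[0]
    H = structure.H
    return ScoreResult(
        person_id=row["person_id"],
        theta_hat=np.array([row[f"theta{d + 1}"] for d in range(H)]),
        se_theta=np.array([row[f"se_theta{d + 1}"] for d in range(H)]),
        tau_hat=float(row["tau"]),
        se_tau=float(row["se_tau"]),
        variant=variant,
        prior_only=bool(row["prior_only"]),
    )


def se_summary_compare(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> pd.DataFrame:
    """Compare scoring precision between two variants, person by person.

    Returns per-dimension mean and SD of the posterior SEs under each
    variant and a paired t-test of the SE difference (b - a): a negative
    mean difference means variant b is more precise.
    """
    a = scores_a.set_index("person_id").sort_index()
    b = scores_b.set_index("person_id").sort_index()
    if not a.index.equals(b.index):
        raise InvalidInputError("score tables cover different persons")
    dims = [c for c in a.columns if c.startswith("se_theta")]
    rows = []
    for c in dims:
        diff = b[c] - a[c]
        t, p = stats.ttest_rel(b[c], a[c])
        rows.append({
            "dimension": c.replace("se_", ""),
            "mean_se_a": a[c].mean(), "sd_se_a": a[c].std(),
            "mean_se_b": b[c].mean(), "sd_se_b": b[c].std(),
            "mean_diff": diff.mean(), "t": t, "p": p,
        })
    return pd.DataFrame(rows)
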