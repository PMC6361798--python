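"""Data-cleaning pipeline for interviewer-administered response + RT tables.

Four stages, mirroring how field data from batched computer-assisted
interviews are prepared for joint calibration:

1. respondent exclusion by count of missing item responses,
2. response-time trimming (floor in seconds plus an upper percentile cut
   on the pooled per-batch distribution),
3. per-item log-normality diagnostics (one-sample Kolmogorov-Smirnov
   against a normal with the item's moments, and Shapiro-Wilk),
4. collapsing sparse response categories and recoding to contiguous codes,
   with the matching remap of graded-model parameters.

Trimmed RTs become missing while the response itself is retained, so the
response likelihood keeps its full sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import InvalidInputError, ItemParameters

REQUIRED_COLUMNS = ["person_id", "item_id", "response", "rt", "interviewer_id", "batch_id"]


class DegenerateInputError(ValueError):
    pass


@dataclass
class CleanReport:
    """What a cleaning stage did: counts, trim fractions, cutpoints."""

    n_before: int = 0
    n_after: int = 0
    n_excluded_respondents: int = 0
    trimmed_rt_fraction: float = 0.0
    rt_cutpoints: dict = field(default_factory=dict)  # batch -> (low, high)
    skewness_before: dict = field(default_factory=dict)  # batch -> float
    skewness_after: dict = field(default_factory=dict)
    collapse_maps: dict = field(default_factory=dict)  # item_id -> CollapseMap

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_excluded_respondents": self.n_excluded_respondents,
            "trimmed_rt_fraction": self.trimmed_rt_fraction,
            "rt_cutpoints": {str(k): list(v) for k, v in self.rt_cutpoints.items()},
            "skewness_before": {str(k): v for k, v in self.skewness_before.items()},
            "skewness_after": {str(k): v for k, v in self.skewness_after.items()},
            "collapse_maps": {
                str(k): {
                    "old_to_new": {int(a): int(b) for a, b in m.old_to_new.items()},
                    "merged_pairs": [list(p) for p in m.merged_pairs],
                    "usable": m.usable,
                }
                for k, m in self.collapse_maps.items()
            },
        }


@dataclass
class CollapseMap:
    """Mapping from original ordinal codes to contiguous collapsed codes."""

    item_id: str
    old_to_new: dict  # original code -> new code (1..K')
    merged_pairs: list  # (source category, absorbing category) in merge order
    usable: bool = True

    @property
    def n_new_categories(self) -> int:
        return max(self.old_to_new.values()) if self.old_to_new else 0

    @property
    def is_identity(self) -> bool:
        return all(k == v for k, v in self.old_to_new.items())


def _missing_per_person(table: pd.DataFrame) -> pd.Series:
    """Missing-response count per person, relative to their batch's item set."""
    items_per_batch = table.groupby("batch_id")["item_id"].agg(lambda s: s.nunique())
    observed = (
        table[table["response"].notna()].groupby("person_id")["item_id"].nunique()
    )
    person_batch = table.drop_duplicates("person_id").set_index("person_id")["batch_id"]
    total = person_batch.map(items_per_batch)
    return (total - observed.reindex(total.index).fillna(0)).astype(int)


def filter_respondents(
    table: pd.DataFrame, max_missing_items: int
) -> tuple[pd.DataFrame, CleanReport]:
    """Drop respondents with ``max_missing_items`` or more missing responses.

    The threshold is inclusive ("at least"): a person missing exactly the
    threshold count is excluded.  Missingness is counted against the item
    set of the person's batch, so structurally unseen items from other
    batches never count.
    """
    if max_missing_items < 0:
        raise InvalidInputError("max_missing_items must be >= 0")
    report = CleanReport()
    if table.empty:
        return table.copy(), report
    missing = _missing_per_person(table)
    keep = missing[missing < max_missing_items].index
    out = table[table["person_id"].isin(keep)].reset_index(drop=True)
    report.n_before = int(missing.size)
    report.n_after = int(len(keep))
    report.n_excluded_respondents = report.n_before - report.n_after
    return out, report


def trim_rts(
    table: pd.DataFrame,
    min_seconds: float = 3.0,
    upper_percentile: float = 97.5,
    cutpoints: dict | None = None,
) -> tuple[pd.DataFrame, CleanReport]:
    """Set outlying response times to missing, keeping the responses.

    Both cutpoints are computed on each batch's pooled pre-trim RT
    distribution: RTs strictly below ``min_seconds`` and strictly above the
    ``upper_percentile`` value (linear-interpolation percentile) are
    removed.  Values exactly at the floor are retained.  Pass a previously
    reported ``cutpoints`` mapping to reapply identical cuts (reapplying a
    report's own cutpoints is a no-op, making the pipeline idempotent).
    """
    if not (0 < upper_percentile < 100):
        raise InvalidInputError("upper_percentile must be in (0, 100)")
    report = CleanReport(n_before=len(table), n_after=len(table))
    out = table.copy()
    rts = out["rt"]
    if rts.notna().sum() == 0:
        import warnings

        warnings.warn("no response times present; trim_rts is a no-op")
        return out, report
    n_removed = 0
    n_total = int(rts.notna().sum())
    for batch, idx in out.groupby("batch_id").groups.items():
        vals = out.loc[idx, "rt"].dropna()
        if vals.empty:
            continue
        if cutpoints is not None and batch in cutpoints:
            low, high = cutpoints[batch]
        else:
            low = min_seconds
            high = float(np.percentile(vals.to_numpy(), upper_percentile))
        report.rt_cutpoints[batch] = (low, high)
        report.skewness_before[batch] = float(stats.skew(vals.to_numpy()))
        mask = (out.loc[idx, "rt"] < low) | (out.loc[idx, "rt"] > high)
        mask = mask.fillna(False)
        n_removed += int(mask.sum())
        out.loc[idx[mask.to_numpy()], "rt"] = np.nan
        kept = out.loc[idx, "rt"].dropna()
        if len(kept) >= 3:
            report.skewness_after[batch] = float(stats.skew(kept.to_numpy()))
    report.trimmed_rt_fraction = n_removed / n_total if n_total else 0.0
    return out, report


def collapse_and_recode(counts, item_id: str = "") -> CollapseMap:
    """Derive the category-collapse map for one item from response counts.

    ``counts`` is the vector of response counts over original categories
    1..K.  Any category with at most one response is merged into the next
    higher category; a sparse top category merges downward into the next
    lower surviving group.  The merged groups are recoded to contiguous
    codes 1..K'.  If fewer than two groups survive, the item is flagged
    unusable.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InvalidInputError("category counts must be nonnegative")
    K = counts.size
    # group[k] = index of the group that original category k+1 belongs to;
    # groups are merged bottom-up with running counts.
    group_of = list(range(K))
    group_counts = counts.copy()
    merged_pairs: list[tuple[int, int]] = []
    for k in range(K - 1):
        if group_counts[k] <= 1 and group_of[k] == k:
            # merge group k upward into the next distinct group
            tgt = k + 1
            group_counts[tgt] += group_counts[k]
            group_counts[k] = -1  # consumed
            for i in range(K):
                if group_of[i] == k:
                    group_of[i] = tgt
            merged_pairs.append((k + 1, tgt + 1))
    # top group: merge downward if sparse
    top = group_of[K - 1]
    if group_counts[top] <= 1:
        lower_groups = sorted({g for g in group_of if g != top and group_counts[g] >= 0})
        if lower_groups:
            tgt = lower_groups[-1]
            group_counts[tgt] += group_counts[top]
            group_counts[top] = -1
            for i in range(K):
                if group_of[i] == top:
                    group_of[i] = tgt
            merged_pairs.append((top + 1, tgt + 1))
    surviving = sorted({g for g in group_of})
    new_code = {g: r + 1 for r, g in enumerate(surviving)}
    old_to_new = {k + 1: new_code[group_of[k]] for k in range(K)}
    usable = sum(1 for g in surviving if group_counts[g] >= 2) >= 2
    return CollapseMap(item_id=item_id, old_to_new=old_to_new,
                       merged_pairs=merged_pairs, usable=usable)


def apply_collapse(table: pd.DataFrame, maps: dict) -> pd.DataFrame:
    """Recode the ``response`` column using per-item collapse maps."""
    out = table.copy()
    for item_id, cmap in maps.items():
        sel = out["item_id"] == item_id
        if not sel.any() or cmap.is_identity:
            continue
        out.loc[sel, "response"] = out.loc[sel, "response"].map(
            lambda r: cmap.old_to_new.get(int(r), r) if pd.notna(r) else r
        )
    return out


def remap_collapsed_parameters(params: ItemParameters, cmap: CollapseMap) -> ItemParameters:
    """Drop thresholds whose boundaries vanished under a collapse map.

    Boundary k (between original categories k and k+1) survives iff the two
    categories map to different collapsed codes.  Discrimination and the
    RT parameters are unchanged — the graded model is a difference model,
    so the retained parameters keep their values.
    """
    K = params.n_categories
    if max(cmap.old_to_new) != K:
        raise InvalidInputError(
            f"collapse map covers {max(cmap.old_to_new)} categories, item has {K}"
        )
    keep = [
        k for k in range(1, K)
        if cmap.old_to_new[k] != cmap.old_to_new[k + 1]
    ]
    new_thresholds = params.thresholds[[k - 1 for k in keep]]
    return ItemParameters(
        item_id=params.item_id,
        domain=params.domain,
        a=params.a,
        thresholds=new_thresholds,
        lam=params.lam,
        phi=params.phi,
        sigma_omega=params.sigma_omega,
    )


def normality_diagnostics(log_rts) -> tuple[float, float, float, float]:
    """Log-normality diagnostics for one item's response times.

    Returns (ks_stat, ks_p, sw_stat, sw_p): a one-sample Kolmogorov-
    Smirnov test of the log-RTs against a normal distribution with the
    sample mean and variance (plain K-S, no small-sample correction), and
    the Shapiro-Wilk test on the same values.
    """
    x = np.asarray(log_rts, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise InvalidInputError("need at least 8 observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant log-RT vector")
    mu, sd = x.mean(), x.std(ddof=1)
    ks = stats.kstest(x, "norm", args=(mu, sd))
    sw = stats.shapiro(x)
    return float(ks.statistic), float(ks.pvalue), float(sw.statistic), float(sw.pvalue)


def diagnostics_table(table: pd.DataFrame, min_n: int = 8) -> pd.DataFrame:
    """Per-item log-normality diagnostics over a cleaned long table."""
    rows = []
    for item_id, grp in table.groupby("item_id"):
        rts = grp["rt"].dropna().to_numpy()
        if rts.size < min_n:
            continue
        ks_s, ks_p, sw_s, sw_p = normality_diagnostics(np.log(rts))
        rows.append({"item_id": item_id, "n": rts.size, "ks_stat": ks_s,
                     "ks_p": ks_p, "sw_stat": sw_s, "sw_p": sw_p})
    return pd.DataFrame(rows)


def preprocess(
    table: pd.DataFrame,
    max_missing_items: int = 20,
    min_seconds: float = 3.0,
    upper_percentile: float = 97.5,
    sparse_count: int = 1,
    rt_cutpoints: dict | None = None,
) -> tuple[pd.DataFrame, CleanReport]:
    """Run the full cleaning pipeline: filter, trim, collapse, recode.

    ``max_missing_items`` may be an int (applied to every batch) or a
    mapping batch_id -> threshold.  Categories with at most ``sparse_count``
    responses are collapsed.  Returns the cleaned table and a combined
    report whose ``rt_cutpoints`` allow an idempotent re-run.
    """
    if isinstance(max_missing_items, dict):
        parts, reports = [], []
        for batch in table["batch_id"].unique():
            sub = table[table["batch_id"] == batch]
            thr = max_missing_items.get(batch)
            if thr is None:
                parts.append(sub)
                reports.append(CleanReport(
                    n_before=sub["person_id"].nunique(),
                    n_after=sub["person_id"].nunique()))
                continue
            part, rep = filter_respondents(sub, thr)
            parts.append(part)
            reports.append(rep)
        filtered = pd.concat(parts, ignore_index=True) if parts else table.iloc[:0]
        filt_report = CleanReport(
            n_before=sum(r.n_before for r in reports),
            n_after=sum(r.n_after for r in reports),
            n_excluded_respondents=sum(r.n_excluded_respondents for r in reports),
        )
    else:
        filtered, filt_report = filter_respondents(table, max_missing_items)
    trimmed, trim_report = trim_rts(
        filtered, min_seconds, upper_percentile, cutpoints=rt_cutpoints
    )
    maps = {}
    for item_id, grp in trimmed.groupby("item_id"):
        resp = grp["response"].dropna().astype(int)
        if resp.empty:
            continue
        K = int(resp.max())
        counts = np.bincount(resp.to_numpy(), minlength=K + 1)[1:]
        cmap = collapse_and_recode(counts, item_id=item_id)
        if not cmap.is_identity or not cmap.usable:
            maps[item_id] = cmap
    cleaned = apply_collapse(trimmed, maps)
    report = CleanReport(
        n_before=filt_report.n_before,
        n_after=filt_report.n_after,
        n_excluded_respondents=filt_report.n_excluded_respondents,
        trimmed_rt_fraction=trim_report.trimmed_rt_fraction,
        rt_cutpoints=trim_report.rt_cutpoints,
        skewness_before=trim_report.skewness_before,
        skewness_after=trim_report.skewness_after,
        collapse_maps=maps,
    )
    return cleaned, report
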