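"""Marginal maximum likelihood estimation of the joint response + RT models.

The marginal likelihood of one respondent integrates the product of the
graded-response likelihood and the lognormal RT likelihood over the latent
trait vector theta (H correlated dimensions, Gauss-Hermite product grid)
and latent speed tau.  Given theta, the log-RTs are a one-factor linear
Gaussian model in tau, so tau (epsilon under Model 2) is integrated in
closed form via the Woodbury identity; a full numeric tau grid is retained
as a cross-check path.

Fitting uses an EM algorithm: the E-step computes posterior weights over
the theta grid together with the conditional Gaussian moments of tau; the
M-step updates each item's graded parameters by small per-item
optimizations of expected counts and the RT parameters by closed-form
weighted least squares, followed by closed-form updates of the
cross-relations, interviewer effects, and trait correlation matrix.
A direct quasi-Newton maximizer over the packed parameter vector is
available for small problems.

Identifiability: trait means 0 and variances 1, speed mean 0 and variance
1 (under Model 2 the residual speed variance is fixed at 1), and the
reference interviewer's effect fixed at 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .model_core import (
    InterviewerDesign,
    InvalidInputError,
    InvalidParameterError,
    ItemParameters,
    ModelVariant,
    PopulationStructure,
)

_LOG_2PI = math.log(2.0 * math.pi)
_PROB_FLOOR = 1e-12


# --------------------------------------------------------------------------
# configuration / result types


@dataclass
class QuadratureSpec:
    """Gauss-Hermite quadrature settings for the latent-trait integral."""

    nodes_per_dim: int = 11
    tau_integration: str = "analytic"  # or "numeric"
    tau_nodes: int = 21

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 3:
            raise InvalidParameterError("nodes_per_dim must be >= 3")
        if self.tau_integration not in ("analytic", "numeric"):
            raise InvalidParameterError("tau_integration must be analytic|numeric")


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_mml`."""

    engine: str = "em"  # "em" or "direct"
    max_iter: int = 500
    tol: float = 1e-5  # relative change in -2LL
    quad: QuadratureSpec = field(default_factory=QuadratureSpec)
    seed: int = 0
    compute_se: bool = False
    verbose: bool = False


@dataclass
class DesignSummary:
    """Shape of a calibration design, sufficient for parameter counting."""

    items_by_categories: dict  # K -> number of items with K categories
    H: int
    P: int
    J: int
    n_persons: int = 0

    def __post_init__(self) -> None:
        if sum(self.items_by_categories.values()) != self.J:
            raise InvalidParameterError("category buckets must sum to J")

    @classmethod
    def from_items(cls, items, H, P, n_persons=0):
        buckets: dict[int, int] = {}
        for it in items:
            buckets[it.n_categories] = buckets.get(it.n_categories, 0) + 1
        return cls(buckets, H=H, P=P, J=len(items), n_persons=n_persons)


@dataclass
class FitResult:
    """Estimates and fit statistics from one MML fit."""

    items: list
    structure: PopulationStructure
    design: InterviewerDesign | None
    variant: ModelVariant
    loglik: float
    n_free_params: int
    converged: bool
    n_iterations: int
    n_persons: int
    standard_errors: dict | None = None
    loglik_path: list = field(default_factory=list)

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik

    def item(self, item_id) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


# --------------------------------------------------------------------------
# internal array representation


class _Arrays:
    """Dense N x J views of a long table, aligned to an item list."""

    def __init__(self, table: pd.DataFrame, items: list, roster: list | None = None):
        self.items = items
        item_ids = [it.item_id for it in items]
        self.item_index = {iid: j for j, iid in enumerate(item_ids)}
        self.persons = np.array(sorted(table["person_id"].unique(), key=str))
        N, J = len(self.persons), len(items)
        pidx = {p: i for i, p in enumerate(self.persons)}
        self.resp = np.full((N, J), -1, dtype=np.int64)
        self.logt = np.full((N, J), np.nan)
        sub = table[table["item_id"].isin(self.item_index)]
        rows = sub["person_id"].map(pidx).to_numpy()
        cols = sub["item_id"].map(self.item_index).to_numpy()
        resp = pd.to_numeric(sub["response"], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(resp)
        self.resp[rows[ok], cols[ok]] = resp[ok].astype(np.int64) - 1  # 0-based
        rt = pd.to_numeric(sub["rt"], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(rt) & (rt > 0)
        self.logt[rows[ok], cols[ok]] = np.log(rt[ok])
        # one interviewer per person
        iv = table.groupby("person_id")["interviewer_id"].agg(
            lambda s: s.dropna().unique()
        )
        if roster is None:
            roster = sorted({v for arr in iv for v in arr}, key=str)
        self.roster = list(roster)
        rmap = {r: k for k, r in enumerate(self.roster)}
        self.interviewer = np.zeros(N, dtype=np.int64)
        for p, arr in iv.items():
            if len(arr) > 1:
                raise InvalidInputError(f"person {p} has multiple interviewers")
            if len(arr) == 1:
                self.interviewer[pidx[p]] = rmap[arr[0]]
        self.rt_mask = np.isfinite(self.logt)
        self.logt0 = np.where(self.rt_mask, self.logt, 0.0)

    # item parameter views
    def param_arrays(self):
        return _param_arrays(self.items)


def _param_arrays(items):
    a = np.array([it.a for it in items])
    ncat = np.array([it.n_categories for it in items])
    Kmax = int(ncat.max())
    thr = np.full((len(items), Kmax - 1), np.nan)
    for j, it in enumerate(items):
        thr[j, : it.n_categories - 1] = it.thresholds
    dom0 = np.array([it.domain - 1 for it in items])
    lam = np.array([it.lam for it in items])
    phi = np.array([it.phi for it in items])
    sig = np.array([it.sigma_omega for it in items])
    return a, thr, ncat, dom0, lam, phi, sig


def _theta_grid(structure: PopulationStructure, nodes_per_dim: int):
    """Product Gauss-Hermite grid transformed to the trait correlation."""
    x, w = np.polynomial.hermite.hermgauss(nodes_per_dim)
    z1 = x * math.sqrt(2.0)
    logw1 = np.log(w) - 0.5 * math.log(math.pi)
    H = structure.H
    grids = np.meshgrid(*([z1] * H), indexing="ij")
    z = np.stack([g.ravel() for g in grids], axis=1)  # (Q, H)
    lw = np.zeros(z.shape[0])
    for g in np.meshgrid(*([logw1] * H), indexing="ij"):
        lw = lw + g.ravel()
    theta = z @ structure.cholesky().T
    return theta, lw


def _response_loglik_grid(arrays: _Arrays, theta_nodes, D: float = 1.0):
    """log prod_j P(y_ij | theta_q): (N, Q)."""
    a, thr, ncat, dom0, *_ = arrays.param_arrays()
    N, J = arrays.resp.shape
    Q = theta_nodes.shape[0]
    logA = np.zeros((N, Q))
    for j in range(J):
        obs = arrays.resp[:, j] >= 0
        if not obs.any():
            continue
        K = ncat[j]
        th = theta_nodes[:, dom0[j]]
        upper = expit(D * a[j] * (th[:, None] - thr[j, : K - 1][None, :]))
        bounds = np.concatenate(
            [np.ones((Q, 1)), upper, np.zeros((Q, 1))], axis=1
        )
        probs = np.clip(-np.diff(bounds, axis=1), _PROB_FLOOR, None)  # (Q, K)
        logA[obs] += np.log(probs[:, arrays.resp[obs, j]]).T
    return logA


def _interviewer_offsets(arrays, phi, gamma, variant):
    """Additive log-RT offsets (N, J): Model 1 gamma_{j,p}, Model 3 gamma_p.

    Model 2's effect acts through latent speed and is handled separately.
    """
    N, J = arrays.logt0.shape
    if variant is ModelVariant.MODEL1:
        return gamma[:, arrays.interviewer].T  # gamma (J, P)
    if variant is ModelVariant.MODEL3:
        return np.broadcast_to(gamma[arrays.interviewer][:, None], (N, J))
    return np.zeros((N, J))


def _rt_loglik_grid(arrays, theta_nodes, rho, gamma, variant, want_moments=False):
    """Marginal log density of the observed log-RT vector given theta.

    tau (epsilon under Model 2) is integrated analytically: given theta the
    centered log-RTs x_j = phi_j tau + omega_j are jointly Gaussian with
    covariance phi phi' + diag(sigma^2); Woodbury gives the quadratic form
    and determinant in O(J).  Returns (N, Q) log densities and, optionally,
    the conditional posterior moments of tau given (theta, data).
    """
    _, _, _, dom0, lam, phi, sig = arrays.param_arrays()
    M = arrays.rt_mask
    N, J = M.shape
    if variant is ModelVariant.MODEL2:
        tau_shift = gamma[arrays.interviewer]  # E[tau] = gamma_p + epsilon
        g = phi[None, :] * tau_shift[:, None]
    else:
        tau_shift = np.zeros(N)
        g = _interviewer_offsets(arrays, phi, gamma, variant)
    r = np.where(M, arrays.logt0 - lam[None, :] - g, 0.0)  # (N, J)
    c = phi * rho[dom0]  # (J,)
    t = theta_nodes[:, dom0]  # (Q, J)
    inv_s2 = 1.0 / (sig * sig)
    Mw = M * inv_s2[None, :]
    S = (M * (phi * phi * inv_s2)[None, :]).sum(axis=1)  # (N,)
    v = 1.0 / (1.0 + S)
    # quadratic form sum x^2/s^2 with x = r + c * theta_d
    A0 = (r * r * Mw).sum(axis=1)  # (N,)
    A1 = (r * Mw * c[None, :]) @ t.T  # (N, Q)
    A2 = (M * (c * c * inv_s2)[None, :]) @ (t * t).T  # (N, Q)
    quad = A0[:, None] + 2.0 * A1 + A2
    # P = sum phi x / s^2
    B0 = (r * Mw * phi[None, :]).sum(axis=1)
    B1 = (M * (phi * c * inv_s2)[None, :]) @ t.T
    P = B0[:, None] + B1  # (N, Q)
    n_obs = M.sum(axis=1)
    logdet = (M * (2.0 * np.log(sig))[None, :]).sum(axis=1) + np.log1p(S)
    logB = -0.5 * (
        n_obs[:, None] * _LOG_2PI
        + logdet[:, None]
        + quad
        - v[:, None] * P * P
    )
    # density of t, not ln t: subtract sum of observed log t (Jacobian)
    logB = logB - (arrays.logt0 * M).sum(axis=1)[:, None]
    if want_moments:
        m = v[:, None] * P  # E[epsilon | theta, data]
        return logB, m, v, tau_shift
    return logB


def _rt_loglik_grid_numeric(arrays, theta_nodes, rho, gamma, variant, tau_nodes=21):
    """Numeric-tau counterpart of :func:`_rt_loglik_grid` (cross-check)."""
    _, _, _, dom0, lam, phi, sig = arrays.param_arrays()
    M = arrays.rt_mask
    if variant is ModelVariant.MODEL2:
        g = phi[None, :] * gamma[arrays.interviewer][:, None]
    else:
        g = _interviewer_offsets(arrays, phi, gamma, variant)
    r = np.where(M, arrays.logt0 - lam[None, :] - g, 0.0)
    c = phi * rho[dom0]
    t = theta_nodes[:, dom0]  # (Q, J)
    x, w = np.polynomial.hermite.hermgauss(tau_nodes)
    taus = x * math.sqrt(2.0)
    logw = np.log(w) - 0.5 * math.log(math.pi)
    N = M.shape[0]
    Q = theta_nodes.shape[0]
    acc = np.full((N, Q, tau_nodes), -np.inf)
    inv_s2 = 1.0 / (sig * sig)
    const = (M * (np.log(sig) + 0.5 * _LOG_2PI)[None, :]).sum(axis=1)
    for k, tau in enumerate(taus):
        # residual e_ijq = r_ij + c_j t_qj - phi_j tau
        e0 = r - phi[None, :] * tau  # (N, J)
        q0 = (e0 * e0 * M * inv_s2[None, :]).sum(axis=1)  # (N,)
        q1 = (e0 * M * (c * inv_s2)[None, :]) @ t.T  # (N, Q)
        q2 = (M * (c * c * inv_s2)[None, :]) @ (t * t).T
        acc[:, :, k] = -0.5 * (q0[:, None] + 2 * q1 + q2) - const[:, None] + logw[k]
    logB = logsumexp(acc, axis=2)
    return logB - (arrays.logt0 * M).sum(axis=1)[:, None]


def _loglik_components(arrays, structure, design, variant, quad, want_moments=False):
    theta_nodes, lw = _theta_grid(structure, quad.nodes_per_dim)
    logA = _response_loglik_grid(arrays, theta_nodes)
    gamma = design.gamma if design is not None else None
    if variant.uses_rt and arrays.rt_mask.any():
        if quad.tau_integration == "numeric":
            logB = _rt_loglik_grid_numeric(
                arrays, theta_nodes, structure.rho, gamma, variant, quad.tau_nodes
            )
            m = v = tau_shift = None
        else:
            logB, m, v, tau_shift = _rt_loglik_grid(
                arrays, theta_nodes, structure.rho, gamma, variant, want_moments=True
            )
    else:
        logB = np.zeros_like(logA)
        m = np.zeros_like(logA)
        v = np.ones(logA.shape[0])
        tau_shift = np.zeros(logA.shape[0])
    logpost = logA + logB + lw[None, :]
    ll_person = logsumexp(logpost, axis=1)
    if not want_moments:
        return ll_person, None
    post = np.exp(logpost - ll_person[:, None])
    return ll_person, {
        "post": post,
        "theta_nodes": theta_nodes,
        "m": m,
        "v": v,
        "tau_shift": tau_shift,
    }


def person_loglik(
    records: pd.DataFrame,
    params: list,
    structure: PopulationStructure,
    design: InterviewerDesign | None = None,
    variant: ModelVariant = ModelVariant.MODEL0,
    quad: QuadratureSpec | None = None,
) -> float:
    """Log marginal likelihood of one person's records.

    Missing responses and missing RTs contribute nothing (MAR); a person
    with no observed data has log-likelihood 0.
    """
    quad = quad or QuadratureSpec()
    if records.empty:
        return 0.0
    roster = list(design.roster) if design is not None and design.roster else None
    arrays = _Arrays(records, params, roster=roster)
    ll, _ = _loglik_components(arrays, structure, design, variant, quad)
    return float(ll.sum())


def dataset_loglik(
    table: pd.DataFrame,
    params: list,
    structure: PopulationStructure,
    design: InterviewerDesign | None = None,
    variant: ModelVariant = ModelVariant.MODEL0,
    quad: QuadratureSpec | None = None,
    per_person: bool = False,
):
    """Log marginal likelihood of a dataset (sum over independent persons)."""
    quad = quad or QuadratureSpec()
    roster = list(design.roster) if design is not None and design.roster else None
    arrays = _Arrays(table, params, roster=roster)
    ll, _ = _loglik_components(arrays, structure, design, variant, quad)
    if per_person:
        return pd.Series(ll, index=arrays.persons)
    return float(ll.sum())


# --------------------------------------------------------------------------
# parameter counting / information criteria / deviance


def count_free_parameters(design: DesignSummary, variant: ModelVariant) -> int:
    """Free-parameter count of one model variant for a calibration design.

    Per item: one discrimination plus K-1 thresholds; RT-bearing variants
    add per item a time intensity, a time discrimination, and a residual
    variance, plus H cross-relations.  All variants estimate the H(H-1)/2
    trait correlations.  Interviewer terms: J(P-1) for the item-specific
    interaction, P-1 for the proportional and main-effect variants.
    """
    k = sum(n * (1 + (K - 1)) for K, n in design.items_by_categories.items())
    k += design.H * (design.H - 1) // 2
    if variant.uses_rt:
        k += 3 * design.J + design.H
    if variant is ModelVariant.MODEL1:
        k += design.J * (design.P - 1)
    elif variant in (ModelVariant.MODEL2, ModelVariant.MODEL3):
        k += design.P - 1
    return k


def information_criteria(minus2ll: float, k: int, n: int) -> tuple[float, float]:
    """AIC and BIC from the deviance, parameter count, and number of
    respondents (the BIC sample size is the count of cleaned persons)."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    return minus2ll + 2.0 * k, minus2ll + k * math.log(n)


_NESTINGS = {
    (ModelVariant.MODEL1, ModelVariant.MODEL0),
    (ModelVariant.MODEL1, ModelVariant.MODEL2),
    (ModelVariant.MODEL1, ModelVariant.MODEL3),
    (ModelVariant.MODEL2, ModelVariant.MODEL0),
    (ModelVariant.MODEL3, ModelVariant.MODEL0),
    (ModelVariant.MODEL0, ModelVariant.MGRM_ONLY),
}


class InvalidComparisonError(ValueError):
    pass


def deviance_test_from_values(minus2ll_full, k_full, minus2ll_nested, k_nested):
    """Likelihood-ratio (deviance) test from deviances and parameter counts."""
    delta = minus2ll_nested - minus2ll_full
    df = k_full - k_nested
    if df < 0:
        raise InvalidComparisonError("full model has fewer parameters than nested")
    if df == 0:
        p = 1.0 if delta <= 0 else 0.0
    else:
        p = float(stats.chi2.sf(max(delta, 0.0), df))
    return delta, df, p


def deviance_test(fit_full: FitResult, fit_nested: FitResult):
    """Deviance test between two nested fits of the same dataset."""
    pair = (fit_full.variant, fit_nested.variant)
    if fit_full.variant is fit_nested.variant:
        pass  # identical variants: Δ should be ~0
    elif pair not in _NESTINGS:
        raise InvalidComparisonError(f"{pair[1].value} is not nested in {pair[0].value}")
    if fit_full.n_persons != fit_nested.n_persons:
        raise InvalidComparisonError("fits use different datasets")
    return deviance_test_from_values(
        fit_full.minus2ll, fit_full.n_free_params,
        fit_nested.minus2ll, fit_nested.n_free_params,
    )


# --------------------------------------------------------------------------
# starting values


def _cov2corr(S):
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _nearest_pd_corr(R, eps=1e-6):
    vals, vecs = np.linalg.eigh((R + R.T) / 2)
    vals = np.clip(vals, eps, None)
    S = vecs @ np.diag(vals) @ vecs.T
    return _cov2corr(S)


def _starting_values(arrays: _Arrays, H, P, variant, frozen_ids=frozenset()):
    """Heuristic starting values: thresholds from cumulative proportions at
    a = 1, time intensity from item mean log-RT, unit time discrimination
    and residual SD, zero cross-relations, trait correlations from domain
    sum-score correlations."""
    items = []
    a0, thr0, ncat, dom0, lam0, phi0, sig0 = arrays.param_arrays()
    N, J = arrays.resp.shape
    for j, it in enumerate(arrays.items):
        if it.item_id in frozen_ids:
            items.append(replace(it))
            continue
        K = it.n_categories
        obs = arrays.resp[:, j]
        obs = obs[obs >= 0]
        if obs.size:
            b = []
            for k in range(1, K):
                p = np.clip((obs >= k).mean(), 0.02, 0.98)
                b.append(-math.log(p / (1 - p)))
            b = np.array(b)
            for k in range(1, len(b)):  # enforce strict ordering
                b[k] = max(b[k], b[k - 1] + 1e-3)
        else:
            b = it.thresholds.copy()
        lt = arrays.logt[:, j]
        lam = float(np.nanmean(lt)) if np.isfinite(lt).any() else 2.0
        items.append(
            ItemParameters(
                item_id=it.item_id, domain=it.domain, a=1.0, thresholds=b,
                lam=lam, phi=1.0, sigma_omega=1.0,
            )
        )
    # domain sum-score correlations
    R = np.eye(H)
    if H > 1:
        scores = np.full((N, H), np.nan)
        for d in range(H):
            cols = np.where(dom0 == d)[0]
            if cols.size == 0:
                continue
            vals = np.where(arrays.resp[:, cols] >= 0, arrays.resp[:, cols], np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores[:, d] = np.nanmean(vals, axis=1)
        ok = np.all(np.isfinite(scores), axis=1)
        if ok.sum() > H + 2:
            R = np.corrcoef(scores[ok].T)
            R = _nearest_pd_corr(np.clip(R, -0.95, 0.95))
    structure = PopulationStructure(H=H, R_theta=R, rho=np.zeros(H))
    if variant is ModelVariant.MODEL1:
        gamma = np.zeros((J, P))
    else:
        gamma = np.zeros(P)
    design = InterviewerDesign(P=P, reference=0, gamma=gamma, roster=arrays.roster)
    return items, structure, design


# --------------------------------------------------------------------------
# EM engine


def _grm_item_update(a, b, counts, theta_d, D=1.0):
    """Maximize expected graded-response log-likelihood for one item.

    ``counts`` is (Q, K) expected category counts at the node values
    ``theta_d`` (Q,).  Parameterized as (log a, b1, log-gaps) to keep a > 0
    and thresholds strictly increasing.
    """
    K = counts.shape[1]

    def unpack(x):
        aa = math.exp(x[0])
        bb = np.empty(K - 1)
        bb[0] = x[1]
        if K > 2:
            bb[1:] = x[1] + np.cumsum(np.exp(x[2:]))
        return aa, bb

    def negq(x):
        aa, bb = unpack(x)
        upper = expit(D * aa * (theta_d[:, None] - bb[None, :]))
        bounds = np.concatenate(
            [np.ones((len(theta_d), 1)), upper, np.zeros((len(theta_d), 1))], axis=1
        )
        probs = np.clip(-np.diff(bounds, axis=1), _PROB_FLOOR, None)
        return -(counts * np.log(probs)).sum()

    x0 = np.empty(1 + (K - 1))
    x0[0] = math.log(max(a, 1e-3))
    x0[1] = b[0]
    if K > 2:
        gaps = np.maximum(np.diff(b), 1e-3)
        x0[2:] = np.log(gaps)
    res = optimize.minimize(negq, x0, method="L-BFGS-B")
    return unpack(res.x)


def _em_fit(arrays, items, structure, design, variant, options, frozen_ids):
    quad = options.quad
    H, P = structure.H, (design.P if design is not None else 1)
    N, J = arrays.resp.shape
    _, _, ncat, dom0, *_ = arrays.param_arrays()
    prev_m2ll = None
    converged = False
    it_count = 0
    ll_path = []
    for iteration in range(1, options.max_iter + 1):
        it_count = iteration
        arrays.items = items
        ll, mom = _loglik_components(
            arrays, structure, design, variant, quad, want_moments=True
        )
        m2ll = -2.0 * ll.sum()
        ll_path.append(-0.5 * m2ll)
        if options.verbose:
            print(f"  EM iter {iteration}: -2LL = {m2ll:.3f}")
        if prev_m2ll is not None and abs(prev_m2ll - m2ll) <= options.tol * abs(m2ll):
            converged = True
            break
        prev_m2ll = m2ll
        post = mom["post"]  # (N, Q)
        theta_nodes = mom["theta_nodes"]
        # ---- posterior moments
        Eth = post @ theta_nodes  # (N, H)
        Eth2 = post @ (theta_nodes * theta_nodes)  # (N, H)
        if variant.uses_rt:
            m, v, tau_shift = mom["m"], mom["v"], mom["tau_shift"]
            Eeps = (post * m).sum(axis=1)
            Eeps2 = (post * m * m).sum(axis=1) + v
            Eepsth = np.einsum("iq,iq,qd->id", post, m, theta_nodes)
            Es = tau_shift + Eeps  # E[tau]
            Es2 = tau_shift**2 + 2 * tau_shift * Eeps + Eeps2
            Esth = tau_shift[:, None] * Eth + Eepsth
        # ---- M-step: graded item parameters
        new_items = []
        a_arr, thr, _, _, lam_arr, phi_arr, sig_arr = arrays.param_arrays()
        for j, item in enumerate(items):
            frozen = item.item_id in frozen_ids
            K = item.n_categories
            a_j, b_j = item.a, item.thresholds
            if not frozen:
                obs = arrays.resp[:, j] >= 0
                if obs.any():
                    counts = np.zeros((post.shape[1], K))
                    for k in range(K):
                        sel = arrays.resp[:, j] == k
                        if sel.any():
                            counts[:, k] = post[sel].sum(axis=0)
                    a_j, b_j = _grm_item_update(
                        item.a, item.thresholds, counts, theta_nodes[:, dom0[j]]
                    )
            new_items.append(
                ItemParameters(
                    item_id=item.item_id, domain=item.domain, a=a_j, thresholds=b_j,
                    lam=item.lam, phi=item.phi, sigma_omega=item.sigma_omega,
                )
            )
        items = new_items
        # ---- M-step: RT item parameters (weighted least squares on moments)
        if variant.uses_rt and arrays.rt_mask.any():
            gamma = design.gamma
            offsets = _interviewer_offsets(arrays, phi_arr, gamma, variant)
            rho = structure.rho
            for j, item in enumerate(items):
                Mj = arrays.rt_mask[:, j]
                n = int(Mj.sum())
                if n < 3:
                    continue
                d = dom0[j]
                y = arrays.logt0[Mj, j] - offsets[Mj, j]
                Eu = Es[Mj] - rho[d] * Eth[Mj, d]
                Eu2 = Es2[Mj] - 2 * rho[d] * Esth[Mj, d] + rho[d] ** 2 * Eth2[Mj, d]
                frozen = (
                    item.item_id in frozen_ids
                    and frozen_ids[item.item_id].has_rt_params
                )
                if frozen:
                    lam_j, phi_j = item.lam, item.phi
                else:
                    A = np.array([[n, Eu.sum()], [Eu.sum(), Eu2.sum()]])
                    rhs = np.array([y.sum(), (y * Eu).sum()])
                    try:
                        lam_j, phi_j = np.linalg.solve(A, rhs)
                    except np.linalg.LinAlgError:
                        lam_j, phi_j = item.lam, item.phi
                    phi_j = max(phi_j, 0.05)
                s2 = (
                    (y * y).sum()
                    - 2 * lam_j * y.sum()
                    - 2 * phi_j * (y * Eu).sum()
                    + n * lam_j**2
                    + 2 * lam_j * phi_j * Eu.sum()
                    + phi_j**2 * Eu2.sum()
                ) / n
                item.lam = float(lam_j)
                item.phi = float(phi_j)
                item.sigma_omega = float(math.sqrt(max(s2, 1e-4)))
            # ---- cross-relations rho_d (closed form)
            _, _, _, _, lam_arr, phi_arr, sig_arr = _param_arrays(items)
            new_rho = structure.rho.copy()
            for d in range(H):
                num = 0.0
                den = 0.0
                for j in np.where(dom0 == d)[0]:
                    Mj = arrays.rt_mask[:, j]
                    if not Mj.any():
                        continue
                    w = phi_arr[j] / sig_arr[j] ** 2
                    y = arrays.logt0[Mj, j] - _interviewer_offsets(
                        arrays, phi_arr, design.gamma, variant
                    )[Mj, j]
                    resid_th = (y - lam_arr[j]) * Eth[Mj, d] - phi_arr[j] * Esth[Mj, d]
                    num += w * resid_th.sum()
                    den += w * phi_arr[j] * Eth2[Mj, d].sum()
                if den > 0:
                    new_rho[d] = float(np.clip(-num / den, -0.98, 0.98))
            structure = PopulationStructure(
                H=H, R_theta=structure.R_theta, rho=new_rho
            )
            # ---- interviewer effects
            if variant.uses_interviewer:
                gamma = design.gamma.copy()
                iv = arrays.interviewer
                if variant is ModelVariant.MODEL1:
                    for j in range(J):
                        Mj = arrays.rt_mask[:, j]
                        d = dom0[j]
                        e = (
                            arrays.logt0[:, j]
                            - lam_arr[j]
                            - phi_arr[j] * Es
                            + phi_arr[j] * structure.rho[d] * Eth[:, d]
                        )
                        for p in range(P):
                            if p == design.reference:
                                gamma[j, p] = 0.0
                                continue
                            sel = Mj & (iv == p)
                            gamma[j, p] = float(e[sel].mean()) if sel.any() else 0.0
                elif variant is ModelVariant.MODEL3:
                    num = np.zeros(P)
                    den = np.zeros(P)
                    for j in range(J):
                        Mj = arrays.rt_mask[:, j]
                        d = dom0[j]
                        e = (
                            arrays.logt0[:, j]
                            - lam_arr[j]
                            - phi_arr[j] * Es
                            + phi_arr[j] * structure.rho[d] * Eth[:, d]
                        )
                        w = 1.0 / sig_arr[j] ** 2
                        for p in range(P):
                            sel = Mj & (iv == p)
                            num[p] += w * e[sel].sum()
                            den[p] += w * sel.sum()
                    upd = np.divide(num, den, out=np.zeros(P), where=den > 0)
                    upd[design.reference] = 0.0
                    gamma = upd
                else:
                    # MODEL2 is hierarchical: tau_i ~ N(gamma_p, 1) at the
                    # second level, so the M-step for gamma_p is the group
                    # mean of posterior E[tau] (the speed-prior term is the
                    # only part of the complete-data loglik involving gamma).
                    upd = np.zeros(P)
                    for p in range(P):
                        sel = iv == p
                        if p != design.reference and sel.any():
                            upd[p] = float(Es[sel].mean())
                    gamma = upd
                design = InterviewerDesign(
                    P=P, reference=design.reference, gamma=gamma, roster=design.roster
                )
        # ---- trait correlation matrix
        if H > 1:
            Ett = np.einsum("iq,qa,qb->ab", post, theta_nodes, theta_nodes) / N
            R_new = _nearest_pd_corr(_cov2corr(Ett))
            structure = PopulationStructure(H=H, R_theta=R_new, rho=structure.rho)
    else:
        warnings.warn("EM did not converge within max_iter")
    arrays.items = items
    ll, _ = _loglik_components(arrays, structure, design, variant, quad)
    return items, structure, design, float(ll.sum()), converged, it_count, ll_path


# --------------------------------------------------------------------------
# direct engine (packed-vector quasi-Newton; intended for small problems)


def _corr_chol_from_z(z, H):
    """Cholesky factor of a correlation matrix from unconstrained partial
    correlations (canonical vine parameterization)."""
    pc = np.tanh(z)
    L = np.zeros((H, H))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, H):
        rem = 1.0
        for j in range(i):
            L[i, j] = pc[idx] * math.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = math.sqrt(max(rem, 1e-12))
    return L


class _Packer:
    """Pack/unpack free parameters to an unconstrained vector."""

    def __init__(self, items, structure, design, variant, frozen_ids):
        self.variant = variant
        self.frozen_ids = frozen_ids
        self.H = structure.H
        self.P = design.P if design is not None else 1
        self.reference = design.reference if design is not None else 0
        self.roster = design.roster if design is not None else None
        self.template = items

    def pack(self, items, structure, design):
        x = []
        for it in items:
            if it.item_id in self.frozen_ids:
                continue
            x.append(math.log(max(it.a, 1e-6)))
            x.append(it.thresholds[0])
            x.extend(np.log(np.maximum(np.diff(it.thresholds), 1e-6)))
            if self.variant.uses_rt:
                x.extend([it.lam, math.log(it.phi), math.log(it.sigma_omega)])
        if self.variant.uses_rt:
            x.extend(np.arctanh(np.clip(structure.rho, -0.97, 0.97)))
        if self.H > 1:
            L = structure.cholesky()
            for i in range(1, self.H):
                rem = 1.0
                for j in range(i):
                    x.append(np.arctanh(np.clip(L[i, j] / math.sqrt(rem), -0.99, 0.99)))
                    rem -= L[i, j] ** 2
        if self.variant.uses_interviewer:
            g = design.gamma
            if self.variant is ModelVariant.MODEL1:
                for j in range(len(items)):
                    for p in range(self.P):
                        if p != self.reference:
                            x.append(g[j, p])
            else:
                for p in range(self.P):
                    if p != self.reference:
                        x.append(g[p])
        return np.array(x)

    def unpack(self, x):
        items = []
        i = 0
        for it in self.template:
            if it.item_id in self.frozen_ids:
                items.append(replace(it))
                continue
            K = it.n_categories
            a = math.exp(x[i]); i += 1
            b = np.empty(K - 1)
            b[0] = x[i]; i += 1
            for k in range(1, K - 1):
                b[k] = b[k - 1] + math.exp(x[i]); i += 1
            lam, phi, sig = it.lam, it.phi, it.sigma_omega
            if self.variant.uses_rt:
                lam = x[i]; phi = math.exp(x[i + 1]); sig = math.exp(x[i + 2])
                i += 3
            items.append(ItemParameters(
                item_id=it.item_id, domain=it.domain, a=a, thresholds=b,
                lam=lam, phi=phi, sigma_omega=sig))
        rho = np.zeros(self.H)
        if self.variant.uses_rt:
            rho = np.tanh(x[i:i + self.H]); i += self.H
        if self.H > 1:
            n_off = self.H * (self.H - 1) // 2
            L = _corr_chol_from_z(x[i:i + n_off], self.H)
            R = L @ L.T
            np.fill_diagonal(R, 1.0)
            i += n_off
        else:
            R = np.eye(1)
        structure = PopulationStructure(H=self.H, R_theta=R, rho=rho)
        design = None
        if self.variant.uses_interviewer:
            if self.variant is ModelVariant.MODEL1:
                g = np.zeros((len(self.template), self.P))
                for j in range(len(self.template)):
                    for p in range(self.P):
                        if p != self.reference:
                            g[j, p] = x[i]; i += 1
            else:
                g = np.zeros(self.P)
                for p in range(self.P):
                    if p != self.reference:
                        g[p] = x[i]; i += 1
            design = InterviewerDesign(P=self.P, reference=self.reference,
                                       gamma=g, roster=self.roster)
        elif self.roster is not None:
            design = InterviewerDesign(P=self.P, reference=self.reference,
                                       gamma=np.zeros(self.P), roster=self.roster)
        return items, structure, design


def _direct_fit(arrays, items, structure, design, variant, options, frozen_ids):
    packer = _Packer(items, structure, design, variant, frozen_ids)
    quad = options.quad
    x0 = packer.pack(items, structure, design)
    n_eval = [0]

    def negll(x):
        n_eval[0] += 1
        its, st, de = packer.unpack(x)
        arrays.items = its
        ll, _ = _loglik_components(arrays, st, de, variant, quad)
        val = -ll.sum()
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        negll, x0, method="L-BFGS-B",
        options={"maxiter": options.max_iter, "ftol": options.tol},
    )
    items, structure, design = packer.unpack(res.x)
    arrays.items = items
    ll, _ = _loglik_components(arrays, structure, design, variant, quad)
    return items, structure, design, float(ll.sum()), bool(res.success), res.nit, []


# --------------------------------------------------------------------------
# public fitting API


def fit_mml(
    table: pd.DataFrame,
    variant: ModelVariant,
    items: list | None = None,
    H: int = 3,
    domains: dict | None = None,
    options: FitOptions | None = None,
    start: tuple | None = None,
    frozen_items: dict | None = None,
    roster: list | None = None,
    reference: int | None = None,
) -> FitResult:
    """Fit one model variant by marginal maximum likelihood.

    ``items`` may give template items (defining ids, domains, and category
    counts); alternatively ``domains`` maps item_id -> dimension (1-based)
    and category counts are inferred from the data.  ``frozen_items`` maps
    item_id -> ItemParameters whose (a, thresholds, lam, phi) are held
    fixed (fixed-parameter calibration); their residual SD is re-estimated.
    """
    options = options or FitOptions()
    if items is None:
        items = infer_items_from_data(table, domains or {}, H)
    frozen_items = frozen_items or {}
    # impose frozen values on templates
    merged = []
    for it in items:
        if it.item_id in frozen_items:
            fz = frozen_items[it.item_id]
            merged.append(ItemParameters(
                item_id=it.item_id, domain=fz.domain, a=fz.a,
                thresholds=fz.thresholds.copy(), lam=fz.lam, phi=fz.phi,
                sigma_omega=fz.sigma_omega if fz.has_rt_params else 1.0))
        else:
            merged.append(replace(it))
    arrays = _Arrays(table, merged, roster=roster)
    P = len(arrays.roster) if arrays.roster else 1
    frozen_ids = dict(frozen_items)  # membership + RT-freezing lookups
    if start is not None:
        s_items, s_structure, s_design = start
    else:
        s_items, s_structure, s_design = _starting_values(
            arrays, H, P, variant, frozen_ids
        )
        for j, it in enumerate(s_items):
            if it.item_id in frozen_ids:
                s_items[j] = merged[j]
        if reference is not None:
            s_design = InterviewerDesign(
                P=P, reference=reference, gamma=s_design.gamma,
                roster=arrays.roster)
    engine = _em_fit if options.engine == "em" else _direct_fit
    fitted_items, structure, design, ll, converged, n_iter, path = engine(
        arrays, s_items, s_structure, s_design, variant, options, frozen_ids
    )
    # restore frozen values bit-exactly
    for j, it in enumerate(fitted_items):
        if it.item_id in frozen_ids:
            fz = frozen_items[it.item_id]
            it.a = fz.a
            it.thresholds = fz.thresholds.copy()
            if variant.uses_rt and fz.has_rt_params:
                it.lam = fz.lam
                it.phi = fz.phi
    design_summary = DesignSummary.from_items(
        fitted_items, H=H, P=P, n_persons=len(arrays.persons)
    )
    result = FitResult(
        items=fitted_items,
        structure=structure,
        design=design,
        variant=variant,
        loglik=ll,
        n_free_params=count_free_parameters(design_summary, variant),
        converged=converged,
        n_iterations=n_iter,
        n_persons=len(arrays.persons),
        loglik_path=path,
    )
    if options.compute_se:
        result.standard_errors = standard_errors(result, table, quad=options.quad)
    return result


def infer_items_from_data(table, domains, H):
    """Build template items from observed data: category count per item from
    the maximum observed code, domain from the supplied mapping."""
    items = []
    for item_id, grp in table.groupby("item_id", sort=True):
        resp = pd.to_numeric(grp["response"], errors="coerce").dropna()
        K = int(resp.max()) if len(resp) else 2
        K = max(K, 2)
        dom = int(domains.get(item_id, 1))
        items.append(ItemParameters(
            item_id=item_id, domain=dom, a=1.0,
            thresholds=np.linspace(-1, 1, K - 1) if K > 2 else np.zeros(1),
            lam=2.0, phi=1.0, sigma_omega=1.0))
    return items


# --------------------------------------------------------------------------
# standard errors


def _free_param_refs(fit: FitResult):
    """(label, getter, setter) triples for every free natural parameter."""
    refs = []
    variant = fit.variant
    for it in fit.items:
        iid = it.item_id
        refs.append((f"a[{iid}]",
                     lambda it=it: it.a,
                     lambda v, it=it: setattr(it, "a", v)))
        for k in range(it.thresholds.size):
            def get_b(it=it, k=k):
                return it.thresholds[k]

            def set_b(v, it=it, k=k):
                it.thresholds[k] = v

            refs.append((f"b{k + 1}[{iid}]", get_b, set_b))
        if variant.uses_rt:
            refs.append((f"lam[{iid}]", lambda it=it: it.lam,
                         lambda v, it=it: setattr(it, "lam", v)))
            refs.append((f"phi[{iid}]", lambda it=it: it.phi,
                         lambda v, it=it: setattr(it, "phi", v)))
            refs.append((f"sigma[{iid}]", lambda it=it: it.sigma_omega,
                         lambda v, it=it: setattr(it, "sigma_omega", v)))
    if variant.uses_rt:
        for d in range(fit.structure.H):
            def get_r(d=d):
                return fit.structure.rho[d]

            def set_r(v, d=d):
                fit.structure.rho[d] = v

            refs.append((f"rho[{d + 1}]", get_r, set_r))
    if variant.uses_interviewer and fit.design is not None:
        g = fit.design.gamma
        if variant is ModelVariant.MODEL1:
            for j in range(g.shape[0]):
                for p in range(g.shape[1]):
                    if p == fit.design.reference:
                        continue
                    refs.append((f"gamma[{fit.items[j].item_id},{p}]",
                                 lambda j=j, p=p: g[j, p],
                                 lambda v, j=j, p=p: g.__setitem__((j, p), v)))
        else:
            for p in range(g.shape[0]):
                if p == fit.design.reference:
                    continue
                refs.append((f"gamma[{p}]",
                             lambda p=p: g[p],
                             lambda v, p=p: g.__setitem__(p, v)))
    return refs


def standard_errors(
    fit: FitResult,
    table: pd.DataFrame,
    quad: QuadratureSpec | None = None,
    h: float = 1e-4,
    frozen_ids: frozenset = frozenset(),
) -> dict:
    """Standard errors from the outer product of per-person score vectors.

    Scores are central finite differences of each person's marginal
    log-likelihood with respect to every free natural parameter; the
    information matrix is the sum of score outer products and SEs are the
    square roots of the diagonal of its inverse.  Parameters fixed by
    constraint (reference interviewer, frozen anchors) are excluded.
    """
    quad = quad or QuadratureSpec()

    def _item_of(label: str) -> str:
        return label.split("[", 1)[1].rstrip("]").split(",")[0]

    refs = [
        r for r in _free_param_refs(fit)
        if _item_of(r[0]) not in frozen_ids or r[0].startswith("sigma")
    ]
    roster = fit.design.roster if fit.design is not None else None
    arrays = _Arrays(table, fit.items, roster=roster)

    def per_person():
        arrays.items = fit.items
        ll, _ = _loglik_components(arrays, fit.structure, fit.design,
                                   fit.variant, quad)
        return ll

    npar = len(refs)
    N = len(arrays.persons)
    S = np.zeros((N, npar))
    for k, (_, get, set_) in enumerate(refs):
        v0 = get()
        step = h * max(1.0, abs(v0))
        set_(v0 + step)
        lp = per_person()
        set_(v0 - step)
        lm = per_person()
        set_(v0)
        S[:, k] = (lp - lm) / (2 * step)
    info = S.T @ S
    labels = [r[0] for r in refs]
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; using pseudo-inverse")
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return dict(zip(labels, se))
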