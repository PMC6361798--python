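"""Measurement models for graded responses and lognormal response times.

The response side is a multidimensional graded response model (MGRM) with
simple structure: item *j* loads on exactly one of *H* correlated latent
trait dimensions.  Category probabilities are differences of logistic
boundary response functions.

The response-time side is a lognormal model on log-seconds,

    ln t_ij = lambda_j + phi_j * tau_i - phi_j * rho_d * theta_id
              [+ interviewer effect] + omega_ij,

where ``lambda_j`` is the item time intensity (expected log-seconds),
``phi_j`` the time discrimination (loading of latent speed), ``tau_i`` the
person's latent speed, and ``rho_d`` a per-dimension cross-relation
coefficient that lets response times carry information about the ability
dimension the item measures.  Interviewer effects enter as additive shifts
in log time, dummy-coded against a reference interviewer, in one of three
forms (item-specific, proportional to phi_j, or a single main effect).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np


class ModelVariant(enum.Enum):
    """Which joint model is fit.

    MGRM_ONLY ignores response times entirely.  MODEL0 is the bivariate
    response + RT model without interviewer terms.  MODEL1 adds an
    item-by-interviewer interaction, MODEL2 a proportional (hierarchical)
    interviewer effect acting through latent speed, and MODEL3 an
    interviewer main effect constant across items.
    """

    MGRM_ONLY = "mgrm_only"
    MODEL0 = "model0"
    MODEL1 = "model1"
    MODEL2 = "model2"
    MODEL3 = "model3"

    @property
    def uses_rt(self) -> bool:
        return self is not ModelVariant.MGRM_ONLY

    @property
    def uses_interviewer(self) -> bool:
        return self in (ModelVariant.MODEL1, ModelVariant.MODEL2, ModelVariant.MODEL3)


RT_VARIANTS = (
    ModelVariant.MODEL0,
    ModelVariant.MODEL1,
    ModelVariant.MODEL2,
    ModelVariant.MODEL3,
)


class InvalidInputError(ValueError):
    """Raised when an operation receives non-finite or out-of-domain input."""


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


class UnsupportedOperationError(RuntimeError):
    """Raised when an operation is undefined for the requested model variant."""


@dataclass
class ItemParameters:
    """Per-item parameters for the joint response + RT model.

    ``domain`` is 1-based: the single trait dimension the item measures.
    ``thresholds`` are the K-1 ordered boundary locations b_j1 < ... <
    b_j,K-1.  ``lam``/``phi``/``sigma_omega`` are the lognormal RT
    parameters (time intensity in log-seconds, time discrimination, and
    residual SD); they may be NaN for response-only analyses.
    """

    item_id: str
    domain: int
    a: float
    thresholds: np.ndarray
    lam: float = math.nan
    phi: float = math.nan
    sigma_omega: float = math.nan

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if self.thresholds.size < 1:
            raise InvalidParameterError(f"item {self.item_id}: needs >= 1 threshold")
        if np.any(np.diff(self.thresholds) <= 0):
            raise InvalidParameterError(
                f"item {self.item_id}: thresholds must be strictly increasing"
            )
        if self.domain < 1:
            raise InvalidParameterError(f"item {self.item_id}: domain is 1-based")
        for name in ("phi", "sigma_omega"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise InvalidParameterError(f"item {self.item_id}: {name} must be > 0")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def has_rt_params(self) -> bool:
        return not (
            math.isnan(self.lam) or math.isnan(self.phi) or math.isnan(self.sigma_omega)
        )


@dataclass
class PopulationStructure:
    """Latent population: H trait dimensions with unit variances, zero means.

    ``R_theta`` is the freely estimated H x H trait correlation matrix.
    ``rho`` holds the per-dimension cross-relation coefficients linking
    each trait to the log-RTs of its items.  Latent speed tau has mean 0,
    variance 1, and is uncorrelated with every trait dimension by
    construction (the cross-relation term absorbs that association).
    """

    H: int
    R_theta: np.ndarray
    rho: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.R_theta = np.asarray(self.R_theta, dtype=float)
        if self.rho is None:
            self.rho = np.zeros(self.H)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.R_theta.shape != (self.H, self.H):
            raise InvalidParameterError("R_theta must be H x H")
        if not np.allclose(self.R_theta, self.R_theta.T):
            raise InvalidParameterError("R_theta must be symmetric")
        if not np.allclose(np.diag(self.R_theta), 1.0):
            raise InvalidParameterError("R_theta must have unit diagonal")
        try:
            np.linalg.cholesky(self.R_theta)
        except np.linalg.LinAlgError as exc:
            raise InvalidParameterError("R_theta must be positive definite") from exc
        if self.rho.shape != (self.H,):
            raise InvalidParameterError("rho must have length H")

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.R_theta)


@dataclass
class InterviewerDesign:
    """Interviewer dummy coding for Models 1-3.

    ``gamma`` holds effects for the P interviewers in roster order with the
    reference column identically zero: shape (J, P) for Model 1
    (item-specific), shape (P,) for Models 2-3.
    """

    P: int
    reference: int = 0
    gamma: np.ndarray = field(default=None)  # type: ignore[assignment]
    roster: list | None = None  # interviewer ids in column order

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = np.zeros(self.P)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape[-1] != self.P:
            raise InvalidParameterError("gamma last axis must have length P")
        if not (0 <= self.reference < self.P):
            raise InvalidParameterError("reference interviewer out of range")
        ref_col = self.gamma[..., self.reference]
        if not np.allclose(ref_col, 0.0):
            raise InvalidParameterError("reference interviewer effect must be 0")

    @property
    def item_specific(self) -> bool:
        return self.gamma.ndim == 2


@dataclass
class PersonState:
    """Latent state of one respondent: trait vector theta and speed tau.

    Under Model 2 ``tau`` is interpreted hierarchically as interviewer
    effect plus residual speed epsilon; ``tau`` here always denotes the
    total speed entering the RT mean.
    """

    theta: np.ndarray
    tau: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))


def boundary_prob(a, b, theta, D: float = 1.0):
    """Boundary response function: P(response in category k or above).

    Evaluates 1 / (1 + exp(-D a (theta - b))).  ``D`` defaults to the a-c
    convention (D = 1); D = 1.7 reproduces the normal-ogive-scaled
    convention.  Vectorized over all arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b)) and np.all(np.isfinite(theta))):
        raise InvalidInputError("boundary_prob requires finite inputs")
    from scipy.special import expit

    return expit(D * a * (theta - b))


def category_probs(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """Category probabilities of a graded item at trait vector ``theta``.

    ``theta`` may be a length-H vector (the item's domain component is
    used, simple structure) or a scalar.  Returns a vector of length K
    summing to one: successive differences of the boundary functions with
    the conventions P+_0 = 1 and P+_K = 0.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    th = theta[item.domain - 1] if theta.size > 1 else theta[0]
    upper = boundary_prob(item.a, item.thresholds, th, D=D)
    bounds = np.concatenate(([1.0], upper, [0.0]))
    return -np.diff(bounds)


def threshold_intercept_convert(a, b):
    """Convert a boundary location to the intercept of the a-c (slope-
    intercept) parameterization: c = -a * b."""
    return -np.asarray(a, dtype=float) * np.asarray(b, dtype=float)


def intercept_threshold_convert(a, c):
    """Inverse of :func:`threshold_intercept_convert`: b = -c / a."""
    a = np.asarray(a, dtype=float)
    if np.any(a == 0):
        raise InvalidParameterError("cannot recover threshold when a == 0")
    return -np.asarray(c, dtype=float) / a


def interviewer_shift(
    item_index: int,
    phi: float,
    interviewer: int,
    design: InterviewerDesign | None,
    variant: ModelVariant,
) -> float:
    """Additive interviewer contribution to expected log RT for one item."""
    if variant in (ModelVariant.MODEL0, ModelVariant.MGRM_ONLY) or design is None:
        return 0.0
    if variant is ModelVariant.MODEL1:
        return float(design.gamma[item_index, interviewer])
    g = float(design.gamma[interviewer])
    if variant is ModelVariant.MODEL2:
        return phi * g
    return g  # MODEL3


def predicted_log_rt(
    item: ItemParameters,
    person: PersonState,
    interviewer: int = 0,
    design: InterviewerDesign | None = None,
    structure: PopulationStructure | None = None,
    variant: ModelVariant = ModelVariant.MODEL0,
    item_index: int = 0,
) -> float:
    """Expected log response time for one person-item encounter.

    Model 0:  lambda + phi tau - phi rho_d theta_d
    Model 1:  ... + gamma_{j,p}        (item-by-interviewer interaction)
    Model 2:  ... + phi_j gamma_p      (proportional / hierarchical effect)
    Model 3:  ... + gamma_p            (interviewer main effect)

    The reference interviewer always contributes zero.
    """
    if variant is ModelVariant.MGRM_ONLY:
        raise UnsupportedOperationError("MGRM_ONLY has no response-time model")
    rho_d = 0.0
    if structure is not None:
        rho_d = float(structure.rho[item.domain - 1])
    theta_d = float(np.atleast_1d(person.theta)[item.domain - 1])
    mu = item.lam + item.phi * person.tau - item.phi * rho_d * theta_d
    mu += interviewer_shift(item_index, item.phi, interviewer, design, variant)
    return float(mu)


_LOG_2PI = math.log(2.0 * math.pi)


def rt_log_density(t, mu, sigma_omega):
    """Log density of a lognormal response time.

    ln f(t) = -ln t - ln sigma - 0.5 ln(2 pi) - (ln t - mu)^2 / (2 sigma^2).
    """
    t = np.asarray(t, dtype=float)
    sigma = np.asarray(sigma_omega, dtype=float)
    if np.any(t <= 0):
        raise InvalidInputError("response times must be positive")
    if np.any(sigma <= 0):
        raise InvalidInputError("sigma_omega must be positive")
    logt = np.log(t)
    z = (logt - mu) / sigma
    return -logt - np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z


def dispersion_form_convert(lam, sigma_omega, phi: float = 1.0):
    """Convert (lambda, sigma_omega) to the dispersion parameterization
    (alpha, beta) used when latent speed enters with unit loading.

    alpha = 1 / sigma_omega quantifies dispersion; beta = lambda.  Only
    defined for phi = 1, where the two lognormal forms coincide pointwise
    (reading the dispersion form's exponent as squared).
    """
    if phi != 1.0:
        raise UnsupportedOperationError(
            "dispersion parameterization is only defined for phi == 1"
        )
    sigma = np.asarray(sigma_omega, dtype=float)
    if np.any(sigma <= 0):
        raise InvalidInputError("sigma_omega must be positive")
    return 1.0 / sigma, np.asarray(lam, dtype=float)


def dispersion_form_invert(alpha, beta):
    """Inverse of :func:`dispersion_form_convert`."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise InvalidInputError("alpha must be positive")
    return np.asarray(beta, dtype=float), 1.0 / alpha
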