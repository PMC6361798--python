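"""Synthetic data with the structure of batched, interviewer-administered
health-measurement field data.

The generator emulates a large Likert-type item bank measuring three
correlated latent domains, administered in four batches that share a
common set of linking items.  Each respondent sees one batch, read aloud
by a single interviewer whose speed shifts the log response times.  Raw
response times are positively skewed lognormal draws, optionally
contaminated with implausibly fast taps and long interruptions, which is
what the trimming rules in :mod:`gradedrt.preprocess` exist to remove.

Default magnitudes mirror the field study this package is built around:
batch sizes near 500-560, 95-109 items per batch with 24 linking items
(eight per domain), 2-4 ordered categories, trait correlations around
(0.62, 0.47, 0.85), cross-relations around 0.42-0.46, and interviewer
effects of order one on the latent-speed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_core import (
    InterviewerDesign,
    InvalidParameterError,
    ItemParameters,
    ModelVariant,
    PopulationStructure,
)

_DEFAULT_R = (
    (1.0, 0.624, 0.468),
    (0.624, 1.0, 0.846),
    (0.468, 0.846, 1.0),
)


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic calibration study."""

    seed: int
    n_per_batch: tuple = (563, 490, 500, 507)
    unique_per_batch: tuple = (85, 72, 72, 71)
    n_linking: int = 24
    H: int = 3
    # fractions of items with 2, 3, 4 ordered categories
    category_fractions: tuple = (0.01, 0.27, 0.72)
    a_range: tuple = (0.9, 2.4)
    b1_mean: float = -1.2
    b1_sd: float = 0.6
    gap_range: tuple = (0.4, 1.2)
    # time parameters sized so raw RTs have mean ~8 s and SD ~4 s: total
    # log-RT SD = sqrt(phi^2 + sigma_omega^2) ~ 0.5 with unit-variance speed
    lam_range: tuple = (1.7, 2.3)
    phi_range: tuple = (0.25, 0.55)
    sigma_range: tuple = (0.30, 0.50)
    R_theta: tuple = _DEFAULT_R
    rho: tuple = (0.425, 0.458, 0.418)
    P_per_batch: tuple = (6, 5, 5, 5)
    # batch 1 has its own roster of six, three overlapping with the common five
    gamma_per_batch: tuple = (
        (0.0, 1.063, -0.286, 1.315, -0.135, 1.046),
        (0.0, 1.150, 1.053, 0.725, -0.911),
        (0.0, 1.150, 1.053, 0.725, -0.911),
        (0.0, 1.150, 1.053, 0.725, -0.911),
    )
    contamination_fraction: float = 0.04
    missing_response_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidParameterError("a seed is mandatory")
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise InvalidParameterError("category_fractions must sum to 1")
        R = np.asarray(self.R_theta, dtype=float)
        if np.any(np.linalg.eigvalsh(R) <= 0):
            raise InvalidParameterError("R_theta must be positive definite")
        if len(self.n_per_batch) != len(self.unique_per_batch):
            raise InvalidParameterError("batch size tuples must align")
        if self.n_linking > min(self.unique_per_batch) + self.n_linking:
            raise InvalidParameterError("n_linking exceeds batch size")

    @property
    def n_batches(self) -> int:
        return len(self.n_per_batch)

    @property
    def total_items(self) -> int:
        return sum(self.unique_per_batch) + self.n_linking

    def structure(self) -> PopulationStructure:
        return PopulationStructure(
            H=self.H, R_theta=np.asarray(self.R_theta, float),
            rho=np.asarray(self.rho, float),
        )


def _draw_categories(config: SimulationConfig, n: int, rng) -> np.ndarray:
    counts = np.floor(np.asarray(config.category_fractions) * n).astype(int)
    counts[-1] += n - counts.sum()  # remainder to the 4-category bucket
    ks = np.repeat([2, 3, 4], counts)
    rng.shuffle(ks)
    return ks


def generate_item_bank(config: SimulationConfig, rng=None) -> list:
    """Draw a reproducible item bank: domains in near-equal thirds,
    strictly increasing thresholds, lognormal RT parameters in range."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.total_items
    ks = _draw_categories(config, n, rng)
    items = []
    for i in range(n):
        K = int(ks[i])
        domain = i % config.H + 1  # near-equal thirds, round-robin
        b1 = rng.normal(config.b1_mean, config.b1_sd)
        gaps = rng.uniform(*config.gap_range, size=K - 2)
        thresholds = b1 + np.concatenate(([0.0], np.cumsum(gaps)))
        items.append(
            ItemParameters(
                item_id=f"i{i + 1:03d}",
                domain=domain,
                a=float(rng.uniform(*config.a_range)),
                thresholds=thresholds,
                lam=float(rng.uniform(*config.lam_range)),
                phi=float(rng.uniform(*config.phi_range)),
                sigma_omega=float(rng.uniform(*config.sigma_range)),
            )
        )
    return items


def generate_persons(
    config: SimulationConfig, N: int, P: int, rng=None, id_prefix: str = "p"
):
    """Draw latent states and interviewer assignment for one batch.

    theta ~ MVN(0, R_theta), tau ~ N(0, 1) independent of theta (the
    cross-relation in the RT model, not a latent covariance, carries the
    trait-speed association).  Interviewers take contiguous blocks of
    respondents, mimicking a field roster where one interviewer runs each
    session from start to finish.
    """
    rng = rng or np.random.default_rng(config.seed)
    L = np.linalg.cholesky(np.asarray(config.R_theta, float))
    theta = rng.standard_normal((N, config.H)) @ L.T
    tau = rng.standard_normal(N)
    edges = np.linspace(0, N, P + 1).astype(int)
    interviewer = np.zeros(N, dtype=int)
    for p in range(P):
        interviewer[edges[p]:edges[p + 1]] = p
    person_ids = [f"{id_prefix}{i + 1:04d}" for i in range(N)]
    return person_ids, theta, tau, interviewer


def simulate_dataset(
    bank: list,
    person_ids,
    theta,
    tau,
    interviewer,
    config: SimulationConfig,
    variant: ModelVariant = ModelVariant.MODEL0,
    gamma=None,
    interviewer_ids=None,
    batch_id: str = "b1",
    rng=None,
) -> pd.DataFrame:
    """Simulate a long-format table of responses and response times.

    Responses are drawn from the graded category probabilities at each
    person's theta; log-RTs are the variant's predicted mean plus
    N(0, sigma_omega) noise.  A ``contamination_fraction`` of RTs is
    replaced by fast taps (uniform 0.5-3 s) or interruption-length times
    (the generated RT times uniform 10-50), half and half; responses are
    deleted at random at ``missing_response_rate``.
    """
    rng = rng or np.random.default_rng(config.seed)
    N = len(person_ids)
    J = len(bank)
    theta = np.asarray(theta, float)
    tau = np.asarray(tau, float)
    rho = np.asarray(config.rho, float)
    dom0 = np.array([it.domain - 1 for it in bank])
    a = np.array([it.a for it in bank])
    lam = np.array([it.lam for it in bank])
    phi = np.array([it.phi for it in bank])
    sig = np.array([it.sigma_omega for it in bank])
    th_d = theta[:, dom0]  # (N, J)
    # responses
    resp = np.empty((N, J), dtype=int)
    u = rng.random((N, J))
    for j, it in enumerate(bank):
        upper = expit(it.a * (th_d[:, [j] * (it.n_categories - 1)] - it.thresholds))
        bounds = np.concatenate(
            [np.ones((N, 1)), upper, np.zeros((N, 1))], axis=1
        )
        probs = -np.diff(bounds, axis=1)
        cum = np.cumsum(probs, axis=1)
        resp[:, j] = 1 + (u[:, j:j + 1] > cum[:, :-1]).sum(axis=1)
    # response times
    if variant.uses_rt:
        mu = lam[None, :] + phi[None, :] * tau[:, None] - phi[None, :] * (
            rho[dom0][None, :] * th_d
        )
        if gamma is not None and variant.uses_interviewer:
            gamma = np.asarray(gamma, float)
            if variant is ModelVariant.MODEL1:
                mu = mu + gamma[:, interviewer].T
            elif variant is ModelVariant.MODEL2:
                mu = mu + phi[None, :] * gamma[interviewer][:, None]
            else:  # MODEL3
                mu = mu + gamma[interviewer][:, None]
        logt = mu + sig[None, :] * rng.standard_normal((N, J))
        t = np.exp(logt)
        if config.contamination_fraction > 0:
            bad = rng.random((N, J)) < config.contamination_fraction
            fast = rng.random((N, J)) < 0.5
            t = np.where(bad & fast, rng.uniform(0.5, 3.0, (N, J)), t)
            t = np.where(bad & ~fast, t * rng.uniform(10.0, 50.0, (N, J)), t)
    else:
        t = np.full((N, J), np.nan)
    if config.missing_response_rate > 0:
        miss = rng.random((N, J)) < config.missing_response_rate
    else:
        miss = np.zeros((N, J), dtype=bool)
    if interviewer_ids is None:
        interviewer_ids = [f"iv{p + 1}" for p in range(int(interviewer.max()) + 1)]
    rows = {
        "person_id": np.repeat(person_ids, J),
        "item_id": np.tile([it.item_id for it in bank], N),
        "response": np.where(miss, np.nan, resp.astype(float)).ravel(),
        "rt": t.ravel(),
        "interviewer_id": np.repeat(
            [interviewer_ids[p] for p in interviewer], J
        ),
        "batch_id": batch_id,
    }
    return pd.DataFrame(rows)


def make_linked_batches(
    config: SimulationConfig, variant: ModelVariant = ModelVariant.MODEL0
):
    """Generate a full multi-batch study from one common item bank.

    The first ``n_linking`` items of the bank (balanced over domains by
    round-robin construction) are shared verbatim by every batch; each
    batch adds its own unique items and a disjoint person sample.  Batch
    rosters come from ``P_per_batch``/``gamma_per_batch``; the first batch
    has a partially overlapping roster of its own, as in a field study
    where staffing changes between waves.

    Returns ``(BatchedDataset, bank, truth)`` where truth records the
    generating latent states per batch.
    """
    from .calibrate import BatchedDataset

    rng = np.random.default_rng(config.seed)
    bank = generate_item_bank(config, rng)
    linking = bank[: config.n_linking]
    linking_ids = {it.item_id for it in linking}
    # common roster of five for later batches; batch 1 gets three of them
    # plus three of its own (study-style overlap) when P_per_batch[0] == 6
    rosters = []
    for b, P in enumerate(config.P_per_batch):
        if b == 0 and P != config.P_per_batch[-1]:
            roster = [f"iv{k + 1}" for k in range(3)] + [
                f"ivA{k + 1}" for k in range(P - 3)
            ]
        else:
            roster = [f"iv{k + 1}" for k in range(P)]
        rosters.append(roster)
    batches = {}
    truth = {}
    offset = config.n_linking
    for b in range(config.n_batches):
        n_unique = config.unique_per_batch[b]
        items_b = linking + bank[offset:offset + n_unique]
        offset += n_unique
        P = config.P_per_batch[b]
        pid, theta, tau, iv = generate_persons(
            config, config.n_per_batch[b], P, rng, id_prefix=f"b{b + 1}_p"
        )
        gamma = np.asarray(config.gamma_per_batch[b], float)
        table = simulate_dataset(
            items_b, pid, theta, tau, iv, config, variant=variant,
            gamma=gamma if variant.uses_interviewer else None,
            interviewer_ids=rosters[b], batch_id=f"b{b + 1}", rng=rng,
        )
        batches[f"b{b + 1}"] = table
        truth[f"b{b + 1}"] = {
            "person_ids": pid, "theta": theta, "tau": tau,
            "interviewer": iv, "gamma": gamma, "roster": rosters[b],
        }
    return BatchedDataset(batches=batches, linking_item_ids=linking_ids), bank, truth


def interviewer_design_from_gamma(gamma, roster=None) -> InterviewerDesign:
    gamma = np.asarray(gamma, float)
    return InterviewerDesign(P=gamma.shape[-1], reference=0, gamma=gamma,
                             roster=roster)
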