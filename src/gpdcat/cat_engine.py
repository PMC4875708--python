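"""Adaptive administration of the item bank.

One simulated CAT session proceeds as in operational practice:

1. draw an initial trait value theta_0 ~ U(start_theta_low, start_theta_high)
   and select the first starter item there;
2. pick the remaining starter items (``n_start_items`` in total) with the
   configured selection rule evaluated at a Bayesian-modal interim estimate
   under a standard-normal prior — maximum likelihood is undefined on the
   short, often all-extreme starting patterns, so the starting portion is
   scored with the Bayesian interim scorer regardless of the cell's
   estimator (``start_scoring="fixed"`` keeps every starter at theta_0
   instead);  responses are stochastic at the simulee's true trait value;
3. alternate estimate -> select -> respond until the estimator's standard
   error of measurement (SEM) drops to the configured threshold or the bank
   is exhausted.  No termination check happens before all starter items are
   administered.

Estimators: maximum likelihood (MLE), Bayesian modal (BME, posterior mode
under a standard-normal or bounded-uniform prior) and expected a posteriori
(EAP, posterior mean by fixed-grid quadrature).  A uniform-prior BME is a
bounded MLE, so the two produce identical sessions under shared seeds.
Selection rules: unweighted Fisher information (UW-FI) and symmetrized
pointwise Kullback-Leibler divergence (FP-KL) between the response
distributions at theta_hat +/- delta.  Ties always break toward the lowest
bank index, and each session derives independent RNG streams for the
starting draw and the responses from one master seed, so the estimator
choice never perturbs the response stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from . import grm
from .item_bank import ItemBank, ItemIrtParams

__all__ = [
    "PriorSpec",
    "CatConfig",
    "ThetaEstimate",
    "CatSessionRecord",
    "BankExhaustedError",
    "estimate_mle",
    "estimate_bme",
    "estimate_eap",
    "select_uwfi",
    "select_fpkl",
    "run_cat_session",
    "SessionEngine",
]

#: Latent-trait support for bounded estimation and the uniform prior.
THETA_BOUNDS = (-6.0, 6.0)

#: Default EAP quadrature: equally spaced nodes on the trait support.
EAP_NODES = 61

#: Default half-width of the FP-KL evaluation interval.
KL_DELTA = 0.1

_XATOL = 1e-6


class BankExhaustedError(RuntimeError):
    """No unadministered item is left to select."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the latent trait for the Bayesian estimators.

    ``kind``: "normal_standard" (mean 0, sd 1), "uniform" (on
    ``(lower, upper)``, defaulting to the trait support) or "none"
    (valid only with MLE).
    """

    kind: str = "normal_standard"
    lower: float = THETA_BOUNDS[0]
    upper: float = THETA_BOUNDS[1]

    def __post_init__(self) -> None:
        if self.kind not in ("normal_standard", "uniform", "none"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.lower >= self.upper:
            raise ValueError("prior bounds must be ordered")

    @staticmethod
    def none() -> "PriorSpec":
        return PriorSpec(kind="none")


@dataclass(frozen=True)
class CatConfig:
    """Settings of one simulation cell."""

    estimator: str = "MLE"  # "MLE" | "BME" | "EAP"
    selector: str = "UW-FI"  # "UW-FI" | "FP-KL"
    prior: PriorSpec = field(default_factory=PriorSpec.none)
    sem_threshold: float = 0.32
    n_start_items: int = 3
    start_theta_low: float = -1.0
    start_theta_high: float = 1.0
    randomesque_pool: int = 1
    seed: int | None = None
    theta_bounds: tuple[float, float] = THETA_BOUNDS
    eap_nodes: int = EAP_NODES
    kl_delta: float = KL_DELTA
    start_scoring: str = "interim_bayes"  # "interim_bayes" | "fixed"

    def __post_init__(self) -> None:
        if self.estimator not in ("MLE", "BME", "EAP"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.selector not in ("UW-FI", "FP-KL"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.estimator == "MLE":
            if self.prior.kind != "none":
                raise ValueError("MLE does not take a prior")
        elif self.prior.kind == "none":
            raise ValueError(f"{self.estimator} requires a prior")
        if self.sem_threshold < 0:
            raise ValueError("sem_threshold must be nonnegative")
        if self.n_start_items < 1:
            raise ValueError("need at least one starting item")
        if self.randomesque_pool < 1:
            raise ValueError("randomesque_pool must be >= 1")
        if self.start_scoring not in ("interim_bayes", "fixed"):
            raise ValueError(f"unknown start_scoring {self.start_scoring!r}")

    def label(self) -> str:
        prior = {"normal_standard": "Normal", "uniform": "Uniform",
                 "none": "-"}[self.prior.kind]
        return f"{self.estimator}/{self.selector}/{prior}/{self.sem_threshold}"


@dataclass(frozen=True)
class ThetaEstimate:
    """A trait estimate with its standard error."""

    theta: float
    sem: float
    method: str
    converged: bool = True


@dataclass
class CatSessionRecord:
    """Complete trace of one adaptive administration."""

    theta_true: float
    administered: list[str]
    responses: list[int]
    estimates: list[ThetaEstimate]
    termination_reason: str  # "sem_met" | "bank_exhausted"
    theta_start: float

    @property
    def final_estimate(self) -> ThetaEstimate:
        return self.estimates[-1]

    @property
    def n_administered(self) -> int:
        return len(self.administered)


# ---------------------------------------------------------------------------
# Likelihood internals on administered-item arrays.
#
# For response r (0-based) of an item, the category probability is
# expit(alpha*theta - tlow) - expit(alpha*theta - thigh) with tlow = -inf for
# the bottom category and thigh = +inf for the top one.


def _response_bounds(
    tpad_row: np.ndarray, n_cat: int, r: int
) -> tuple[float, float]:
    tlow = -np.inf if r == 0 else tpad_row[r - 1]
    thigh = np.inf if r >= n_cat - 1 else tpad_row[r]
    return tlow, thigh


def _loglik(theta, alpha, tlow, thigh):
    """GRM log-likelihood; broadcasts over a theta grid in the last axis."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 0:
        p = expit(alpha * theta - tlow) - expit(alpha * theta - thigh)
    else:
        z = alpha[:, None] * theta[None, :]
        p = expit(z - tlow[:, None]) - expit(z - thigh[:, None])
    return np.log(np.maximum(p, 1e-300)).sum(axis=0)


def _fisher_info(theta: float, alpha: np.ndarray, tpad: np.ndarray) -> float:
    return float(grm.information_from_arrays(alpha, tpad, theta).sum())


def _mle_core(alpha, tlow, thigh, responses, n_cat, bounds):
    """Bounded ML estimate; all-extreme patterns return the relevant bound."""
    resp = np.asarray(responses)
    if np.all(resp == 0):
        return bounds[0], False
    if np.all(resp == np.asarray(n_cat) - 1):
        return bounds[1], False
    res = minimize_scalar(
        lambda th: -_loglik(th, alpha, tlow, thigh),
        bounds=bounds,
        method="bounded",
        options={"xatol": _XATOL},
    )
    return float(res.x), True


def _bme_normal_core(alpha, tlow, thigh, bounds):
    res = minimize_scalar(
        lambda th: -(_loglik(th, alpha, tlow, thigh) - 0.5 * th * th),
        bounds=bounds,
        method="bounded",
        options={"xatol": _XATOL},
    )
    return float(res.x)


def _eap_core(nodes, log_weights, alpha, tlow, thigh):
    logpost = log_weights + _loglik(nodes, alpha, tlow, thigh)
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    mean = float(np.dot(w, nodes))
    var = float(np.dot(w, (nodes - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


def _eap_grid(nodes: int, bounds, prior_kind: str):
    x = np.linspace(bounds[0], bounds[1], nodes)
    if prior_kind == "uniform":
        logw = np.zeros_like(x)
    else:
        logw = -0.5 * x * x
    return x, logw


def _admin_arrays(responses: Sequence[int], items: Sequence[ItemIrtParams]):
    if len(responses) != len(items):
        raise ValueError("responses and items must have equal length")
    alpha = np.array([it.alpha for it in items])
    n_cat = np.array([it.n_categories for it in items])
    tlow = np.empty(len(items))
    thigh = np.empty(len(items))
    tpad_rows = []
    kmax = max((it.n_categories for it in items), default=2) - 1
    for j, (it, r) in enumerate(zip(items, responses)):
        if not 0 <= r <= it.n_categories - 1:
            raise ValueError(
                f"response {r} outside categories of {it.item_id}"
            )
        row = np.full(kmax, np.inf)
        row[: len(it.t)] = it.t
        tpad_rows.append(row)
        tlow[j], thigh[j] = _response_bounds(row, it.n_categories, r)
    return alpha, n_cat, tlow, thigh, np.array(tpad_rows)


def estimate_mle(
    responses: Sequence[int], items: Sequence[ItemIrtParams]
) -> ThetaEstimate:
    """Maximum-likelihood trait estimate with SEM = 1/sqrt(I(theta_hat)).

    Response patterns with every item in the lowest (or highest) category
    have no interior maximum; the relevant trait bound is returned with
    ``converged=False``.
    """
    if len(responses) == 0:
        raise ValueError("MLE needs at least one response")
    alpha, n_cat, tlow, thigh, tpad = _admin_arrays(responses, items)
    theta, converged = _mle_core(
        alpha, tlow, thigh, responses, n_cat, THETA_BOUNDS
    )
    info = _fisher_info(theta, alpha, tpad)
    sem = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return ThetaEstimate(theta, sem, "MLE", converged)


def estimate_bme(
    responses: Sequence[int],
    items: Sequence[ItemIrtParams],
    prior: PriorSpec,
) -> ThetaEstimate:
    """Bayesian modal (posterior mode) trait estimate.

    With the standard-normal prior the penalty -theta^2/2 is added to the
    log-likelihood and the prior contributes unit precision to the SEM:
    ``sem = 1/sqrt(I + 1)``.  With a uniform prior the estimate is a
    bounded MLE on the prior support and the prior adds no curvature.
    """
    if prior.kind == "none":
        raise ValueError("BME requires a normal or uniform prior")
    if prior.kind == "uniform":
        if len(responses) == 0:
            raise ValueError("uniform-prior BME needs at least one response")
        alpha, n_cat, tlow, thigh, tpad = _admin_arrays(responses, items)
        bounds = (prior.lower, prior.upper)
        theta, converged = _mle_core(
            alpha, tlow, thigh, responses, n_cat, bounds
        )
        info = _fisher_info(theta, alpha, tpad)
        sem = 1.0 / math.sqrt(info) if info > 0 else math.inf
        return ThetaEstimate(theta, sem, "BME", converged)
    if len(responses) == 0:
        return ThetaEstimate(0.0, 1.0, "BME", True)
    alpha, n_cat, tlow, thigh, tpad = _admin_arrays(responses, items)
    theta = _bme_normal_core(alpha, tlow, thigh, THETA_BOUNDS)
    info = _fisher_info(theta, alpha, tpad)
    return ThetaEstimate(theta, 1.0 / math.sqrt(info + 1.0), "BME", True)


def estimate_eap(
    responses: Sequence[int],
    items: Sequence[ItemIrtParams],
    prior: PriorSpec,
    quadrature: tuple[int, float, float] | None = None,
) -> ThetaEstimate:
    """Expected-a-posteriori estimate via fixed-grid quadrature.

    ``quadrature`` is (number of nodes, lower, upper); the default is 61
    equally spaced nodes on the trait support.  The SEM is the posterior
    standard deviation.
    """
    if prior.kind == "none":
        raise ValueError("EAP requires a normal or uniform prior")
    if quadrature is None:
        quadrature = (EAP_NODES, *THETA_BOUNDS)
    n_nodes, lo, hi = quadrature
    nodes, logw = _eap_grid(n_nodes, (lo, hi), prior.kind)
    if len(responses) == 0:
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mean = float(np.dot(w, nodes))
        sd = math.sqrt(float(np.dot(w, (nodes - mean) ** 2)))
        return ThetaEstimate(mean, sd, "EAP", True)
    alpha, _, tlow, thigh, _ = _admin_arrays(responses, items)
    mean, sd = _eap_core(nodes, logw, alpha, tlow, thigh)
    return ThetaEstimate(mean, sd, "EAP", True)


# ---------------------------------------------------------------------------
# Item selection


def _kl_index(arrays: grm.ItemArrays, rows: np.ndarray, theta: float,
              delta: float) -> np.ndarray:
    """Symmetric pointwise KL divergence for the given item rows."""
    p_hi = arrays.category_probs(theta + delta)[rows]
    p_lo = arrays.category_probs(theta - delta)[rows]
    eps = grm.PROB_EPS
    mask = (p_hi > eps) & (p_lo > eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            mask,
            (p_hi - p_lo) * (np.log(np.maximum(p_hi, eps))
                             - np.log(np.maximum(p_lo, eps))),
            0.0,
        )
    return contrib.sum(axis=1)


def _select_index(
    arrays: grm.ItemArrays,
    candidate_rows: np.ndarray,
    theta: float,
    selector: str,
    delta: float,
) -> int:
    if candidate_rows.size == 0:
        raise BankExhaustedError("no unadministered items left")
    if selector == "UW-FI":
        crit = grm.information_from_arrays(
            arrays.alpha[candidate_rows], arrays.t[candidate_rows], theta
        )
    else:
        crit = _kl_index(arrays, candidate_rows, theta, delta)
    return int(candidate_rows[int(np.argmax(crit))])


def select_uwfi(
    candidates: Sequence[ItemIrtParams], theta_hat: float
) -> str:
    """Id of the candidate with maximal Fisher information at theta_hat."""
    arrays = grm.ItemArrays(candidates)
    rows = np.arange(arrays.n_items)
    idx = _select_index(arrays, rows, theta_hat, "UW-FI", KL_DELTA)
    return arrays.items[idx].item_id


def select_fpkl(
    candidates: Sequence[ItemIrtParams],
    theta_hat: float,
    delta: float = KL_DELTA,
) -> str:
    """Id of the candidate with maximal symmetric KL divergence between the
    response distributions at theta_hat +/- delta."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    arrays = grm.ItemArrays(candidates)
    rows = np.arange(arrays.n_items)
    idx = _select_index(arrays, rows, theta_hat, "FP-KL", delta)
    return arrays.items[idx].item_id


# ---------------------------------------------------------------------------
# Session loop


class SessionEngine:
    """Reusable per-cell engine: builds the bank arrays once and runs
    sessions cheaply."""

    def __init__(self, bank: ItemBank | Sequence[ItemIrtParams],
                 config: CatConfig) -> None:
        self.config = config
        self.arrays = grm.ItemArrays(bank)
        self.n_items = self.arrays.n_items
        if config.estimator == "EAP":
            lo, hi = (
                (config.prior.lower, config.prior.upper)
                if config.prior.kind == "uniform"
                else config.theta_bounds
            )
            self._nodes, self._logw = _eap_grid(
                config.eap_nodes, (lo, hi), config.prior.kind
            )

    def _estimate(self, alpha, tlow, thigh, responses, n_cat,
                  tpad) -> ThetaEstimate:
        cfg = self.config
        if cfg.estimator == "EAP":
            mean, sd = _eap_core(self._nodes, self._logw, alpha, tlow, thigh)
            return ThetaEstimate(mean, sd, "EAP", True)
        if cfg.estimator == "MLE" or cfg.prior.kind == "uniform":
            bounds = (
                (cfg.prior.lower, cfg.prior.upper)
                if cfg.estimator == "BME"
                else cfg.theta_bounds
            )
            theta, conv = _mle_core(alpha, tlow, thigh, responses, n_cat,
                                    bounds)
            info = _fisher_info(theta, alpha, tpad)
            sem = 1.0 / math.sqrt(info) if info > 0 else math.inf
            return ThetaEstimate(theta, sem, cfg.estimator, conv)
        theta = _bme_normal_core(alpha, tlow, thigh, cfg.theta_bounds)
        info = _fisher_info(theta, alpha, tpad)
        return ThetaEstimate(theta, 1.0 / math.sqrt(info + 1.0), "BME", True)

    def _pick(self, remaining: np.ndarray, theta: float,
              rng_sel: np.random.Generator) -> int:
        cfg = self.config
        rows = np.flatnonzero(remaining)
        if cfg.randomesque_pool <= 1:
            return _select_index(self.arrays, rows, theta, cfg.selector,
                                 cfg.kl_delta)
        if rows.size == 0:
            raise BankExhaustedError("no unadministered items left")
        if cfg.selector == "UW-FI":
            crit = grm.information_from_arrays(
                self.arrays.alpha[rows], self.arrays.t[rows], theta
            )
        else:
            crit = _kl_index(self.arrays, rows, theta, cfg.kl_delta)
        pool = min(cfg.randomesque_pool, rows.size)
        top = rows[np.argsort(-crit, kind="stable")[:pool]]
        return int(rng_sel.choice(top))

    def run(self, theta_true: float,
            seed: int | np.random.SeedSequence | None = None
            ) -> CatSessionRecord:
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        c_start, c_resp, c_sel = ss.spawn(3)
        rng_start = np.random.default_rng(c_start)
        rng_resp = np.random.default_rng(c_resp)
        rng_sel = np.random.default_rng(c_sel)

        theta0 = float(
            rng_start.uniform(cfg.start_theta_low, cfg.start_theta_high)
        )
        arrays = self.arrays
        remaining = np.ones(self.n_items, dtype=bool)
        adm_rows: list[int] = []
        responses: list[int] = []
        alpha_l: list[float] = []
        tlow_l: list[float] = []
        thigh_l: list[float] = []

        def administer(row: int) -> None:
            remaining[row] = False
            adm_rows.append(row)
            pstar = expit(arrays.alpha[row] * theta_true - arrays.t[row])
            r = int(np.sum(rng_resp.random() < pstar))
            responses.append(r)
            alpha_l.append(arrays.alpha[row])
            lo, hi = _response_bounds(
                arrays.t[row], int(arrays.n_categories[row]), r
            )
            tlow_l.append(lo)
            thigh_l.append(hi)

        n_start = min(cfg.n_start_items, self.n_items)
        administer(self._pick(remaining, theta0, rng_sel))
        for _ in range(n_start - 1):
            if cfg.start_scoring == "interim_bayes":
                at = _bme_normal_core(
                    np.array(alpha_l), np.array(tlow_l), np.array(thigh_l),
                    cfg.theta_bounds,
                )
            else:
                at = theta0
            administer(self._pick(remaining, at, rng_sel))

        estimates: list[ThetaEstimate] = []
        while True:
            alpha = np.array(alpha_l)
            tlow = np.array(tlow_l)
            thigh = np.array(thigh_l)
            n_cat = arrays.n_categories[adm_rows]
            tpad = arrays.t[adm_rows]
            est = self._estimate(alpha, tlow, thigh, responses, n_cat, tpad)
            estimates.append(est)
            if est.sem <= cfg.sem_threshold:
                reason = "sem_met"
                break
            if not remaining.any():
                reason = "bank_exhausted"
                break
            administer(self._pick(remaining, est.theta, rng_sel))

        ids = [arrays.items[r].item_id for r in adm_rows]
        return CatSessionRecord(
            theta_true=float(theta_true),
            administered=ids,
            responses=responses,
            estimates=estimates,
            termination_reason=reason,
            theta_start=theta0,
        )


def run_cat_session(
    theta_true: float,
    bank: ItemBank | Sequence[ItemIrtParams],
    config: CatConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> CatSessionRecord:
    """Simulate one adaptive administration; see module docstring."""
    return SessionEngine(bank, config).run(theta_true, seed)
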