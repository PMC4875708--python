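"""Simulation inputs: true trait values and full response matrices.

The Monte Carlo design draws simulees' true distress values either from the
standard normal N(0, 1) — the presumed population distribution of distress —
or from the uniform U(-3, 3), which removes the influence of the population
distribution on adaptive-testing performance.  Given a calibrated bank,
complete (non-adaptive) response matrices can also be generated for
fixed-form baselines and estimator tests.

Seed policy: the response stream of simulee ``i`` is a stable function of
``(seed, i)``, so taking a subset of simulees never reshuffles the data of
the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import grm
from .item_bank import ItemBank

__all__ = ["ThetaDistributionSpec", "sample_theta", "generate_response_matrix"]


@dataclass(frozen=True)
class ThetaDistributionSpec:
    """Distribution of true latent distress values.

    ``kind``: "standard_normal" or "uniform"; ``bounds`` apply to the
    uniform case only and default to (-3, 3).
    """

    kind: str = "standard_normal"
    n: int = 10_000
    bounds: tuple[float, float] = (-3.0, 3.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("standard_normal", "uniform"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("uniform bounds must be ordered")


def sample_theta(
    spec: ThetaDistributionSpec, seed: int | None = None
) -> np.ndarray:
    """Draw ``spec.n`` independent true trait values.

    No truncation or discretization is applied.  Reproducible under a fixed
    seed (``seed`` overrides ``spec.seed``).
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    if spec.kind == "standard_normal":
        return rng.standard_normal(spec.n)
    return rng.uniform(spec.bounds[0], spec.bounds[1], spec.n)


def generate_response_matrix(
    bank: ItemBank, thetas: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """Simulee x item matrix of 0-based GRM response categories.

    Row ``i`` holds simulee ``i``'s stochastic responses to all bank items
    at their true trait value, drawn independently across simulees and
    items.
    """
    arrays = grm.ItemArrays(bank)
    thetas = np.asarray(thetas, dtype=float)
    out = np.empty((thetas.size, arrays.n_items), dtype=np.int64)
    for i, th in enumerate(thetas):
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, i]))
        pstar = arrays.boundary_probs(th)  # (n_items, kmax)
        u = rng.random(arrays.n_items)
        out[i] = np.sum(u[:, None] < pstar, axis=1)
    return out
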