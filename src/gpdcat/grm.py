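"""Logistic graded response model (GRM): probabilities, information, SEM.

All functions work on the logistic metric produced by the factor-to-IRT
conversion in :mod:`gpdcat.item_bank`: the cumulative boundary probability
of reaching at least category ``k`` (k = 1..K-1, categories indexed 0..K-1)
is ``expit(alpha * theta - t_k)``.  Item and test information follow
Samejima's formula; the conditional standard error of measurement (SEM) is
``1 / sqrt(I(theta))``.

The module also houses the vectorized parameter arrays (:class:`ItemArrays`)
used by the adaptive-testing engine: items with different category counts
(GHQ: 4, Affectometer: 5) are padded with ``+inf`` thresholds, which makes
the phantom boundaries carry probability zero and drop out of every sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .item_bank import ItemBank, ItemIrtParams

__all__ = [
    "ItemArrays",
    "InformationCurve",
    "cumulative_prob",
    "category_probs",
    "item_information",
    "test_information",
    "best_k_subset_curve",
    "simulate_response",
    "default_theta_grid",
]

#: Category probabilities below this contribute zero information
#: (guarded division).
PROB_EPS = 1e-12

#: Default latent-trait grid for SEM curves: [-3.5, 3.5] in steps of 0.15.
DEFAULT_GRID = (-3.5, 3.5, 0.15)


def default_theta_grid(
    theta_min: float = DEFAULT_GRID[0],
    theta_max: float = DEFAULT_GRID[1],
    step: float = DEFAULT_GRID[2],
) -> np.ndarray:
    n = int(round((theta_max - theta_min) / step))
    return theta_min + step * np.arange(n + 1)


def _as_irt_items(items) -> list[ItemIrtParams]:
    if isinstance(items, ItemBank):
        return items.irt_items
    items = list(items)
    if not items:
        raise ValueError("empty item subset")
    return items


class ItemArrays:
    """Padded parameter arrays for a set of GRM items.

    ``alpha`` has shape (n,); ``t`` has shape (n, max_boundaries) and is
    padded with ``+inf`` beyond each item's last real boundary.
    """

    def __init__(self, items: Sequence[ItemIrtParams] | ItemBank) -> None:
        items = _as_irt_items(items)
        self.items = items
        self.n_items = len(items)
        self.n_categories = np.array([it.n_categories for it in items])
        kmax = int(self.n_categories.max()) - 1
        self.alpha = np.array([it.alpha for it in items])
        t = np.full((self.n_items, kmax), np.inf)
        for i, it in enumerate(items):
            t[i, : len(it.t)] = it.t
        self.t = t

    def boundary_probs(self, theta: float | np.ndarray) -> np.ndarray:
        """P(X >= k | theta) for k = 1..kmax; phantom boundaries give 0.

        For scalar ``theta`` the result has shape (n, kmax); for a grid of
        G points, (n, kmax, G).
        """
        theta = np.asarray(theta, dtype=float)
        if theta.ndim == 0:
            z = self.alpha[:, None] * theta - self.t
        else:
            z = (
                self.alpha[:, None, None] * theta[None, None, :]
                - self.t[:, :, None]
            )
        return expit(z)

    def category_probs(self, theta: float | np.ndarray) -> np.ndarray:
        """Per-category probabilities; padded categories carry 0."""
        pstar = self.boundary_probs(theta)
        shape = list(pstar.shape)
        shape[1] += 2
        full = np.zeros(shape)
        full[:, 0] = 1.0
        full[:, 1:-1] = pstar
        return full[:, :-1] - full[:, 1:]

    def information(self, theta: float | np.ndarray) -> np.ndarray:
        """Samejima item information for every item at ``theta``.

        I_i(theta) = alpha_i^2 * sum_k (Q_k - Q_{k+1})^2 / P_k with
        Q_k = P*_k (1 - P*_k), Q at the outer boundaries being 0.
        """
        return information_from_arrays(self.alpha, self.t, theta)


def information_from_arrays(
    alpha: np.ndarray, tpad: np.ndarray, theta: float | np.ndarray
) -> np.ndarray:
    """Samejima information on padded parameter arrays.

    ``alpha``: shape (n,); ``tpad``: shape (n, kmax), ``+inf``-padded.
    Scalar ``theta`` gives shape (n,); a grid of G points gives (n, G).
    Vanishing category probabilities contribute zero (guarded division).
    """
    theta_arr = np.asarray(theta, dtype=float)
    if theta_arr.ndim == 0:
        z = alpha[:, None] * theta_arr - tpad
    else:
        z = alpha[:, None, None] * theta_arr[None, None, :] - tpad[:, :, None]
    pstar = expit(z)
    shape = list(pstar.shape)
    shape[1] += 2
    full = np.zeros(shape)
    full[:, 0] = 1.0
    full[:, 1:-1] = pstar
    q = full * (1.0 - full)
    num = q[:, :-1] - q[:, 1:]
    pk = full[:, :-1] - full[:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            pk > PROB_EPS, num * num / np.maximum(pk, PROB_EPS), 0.0
        )
    alpha2 = alpha**2
    if terms.ndim == 3:
        return alpha2[:, None] * terms.sum(axis=1)
    return alpha2 * terms.sum(axis=1)


@dataclass(frozen=True)
class InformationCurve:
    """Fisher information and conditional SEM over a latent-trait grid.

    ``sem`` is ``1/sqrt(information)``; grid points with zero information
    get ``sem = inf`` (the SEM is undefined there).
    """

    theta_grid: np.ndarray
    information: np.ndarray
    sem: np.ndarray

    @staticmethod
    def from_information(
        theta_grid: np.ndarray, information: np.ndarray
    ) -> "InformationCurve":
        info = np.asarray(information, dtype=float)
        with np.errstate(divide="ignore"):
            sem = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
        return InformationCurve(np.asarray(theta_grid, dtype=float), info, sem)


def cumulative_prob(item: ItemIrtParams, k: int, theta: float) -> float:
    """P(response >= category k | theta) for boundary k = 1..K-1."""
    if not 1 <= k <= item.n_categories - 1:
        raise ValueError(
            f"boundary index {k} outside 1..{item.n_categories - 1}"
        )
    return float(expit(item.alpha * theta - item.t[k - 1]))


def category_probs(item: ItemIrtParams, theta: float) -> np.ndarray:
    """Probability of each of the K ordered categories at ``theta``."""
    pstar = np.concatenate(
        ([1.0], expit(item.alpha * theta - np.asarray(item.t)), [0.0])
    )
    return pstar[:-1] - pstar[1:]


def item_information(item: ItemIrtParams, theta: float) -> float:
    """Samejima GRM item information at ``theta``."""
    arr = ItemArrays([item])
    return float(arr.information(float(theta))[0])


def test_information(
    items: Sequence[ItemIrtParams] | ItemBank,
    theta_grid: Sequence[float] | np.ndarray,
) -> InformationCurve:
    """Pointwise sum of item information over a nonempty item subset."""
    arrays = ItemArrays(items)
    grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    info = arrays.information(grid).sum(axis=0)
    return InformationCurve.from_information(grid, info)


def best_k_subset_curve(
    bank: Sequence[ItemIrtParams] | ItemBank,
    k: int,
    theta_min: float = DEFAULT_GRID[0],
    theta_max: float = DEFAULT_GRID[1],
    step: float = DEFAULT_GRID[2],
) -> InformationCurve:
    """SEM curve of the locally optimal k-item subset.

    At each grid point the k items with the highest item information *at
    that point* are selected and their information summed — the item subset
    may change along the grid.  With ``k`` equal to the bank size this
    reduces to :func:`test_information` on the full bank.
    """
    arrays = ItemArrays(bank)
    if not 1 <= k <= arrays.n_items:
        raise ValueError(f"k={k} outside 1..{arrays.n_items}")
    if step <= 0:
        raise ValueError("step must be positive")
    grid = default_theta_grid(theta_min, theta_max, step)
    info_matrix = arrays.information(grid)  # (n_items, G)
    top = np.sort(info_matrix, axis=0)[-k:, :]
    return InformationCurve.from_information(grid, top.sum(axis=0))


def best_k_items_at(
    bank: Sequence[ItemIrtParams] | ItemBank, k: int, theta: float
) -> list[str]:
    """Ids of the k most informative items at a single trait value."""
    arrays = ItemArrays(bank)
    info = arrays.information(float(theta))
    order = np.argsort(-info, kind="stable")[:k]
    return [arrays.items[i].item_id for i in order]


def simulate_response(
    item: ItemIrtParams, theta: float, rng: np.random.Generator
) -> int:
    """Draw one 0-based response category from the GRM at ``theta``.

    Uses a single uniform draw against the cumulative boundary curve, which
    is distributionally identical to sampling from
    :func:`category_probs` and reproducible under a fixed generator state.
    """
    pstar = expit(item.alpha * theta - np.asarray(item.t))
    u = rng.random()
    return int(np.sum(u < pstar))
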