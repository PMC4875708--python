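"""The 52-item general psychological distress (GPD) item bank.

The bank pools the 12 GHQ-12 items (4 ordinal response levels each) with the
40 Affectometer-2 items (5 levels each).  Each item carries two parameter
sets:

* **factor-analytic parameters** from a bifactor model with a general
  distress factor plus two wording ("method") factors — one for positively
  worded GHQ items (posGHQ) and one for positively worded Affectometer items
  (posAff).  Negatively worded items load on the general factor only.
* **IRT parameters** of a logistic graded response model (GRM), obtained
  from the factor parameters through the classical normal-ogive-to-logistic
  conversion with scaling constant 1.7.

Both parameter sets ship with the package as transcribed tables; the
recomputed IRT parameters are also available (see
:meth:`ItemBank.recomputed_irt`) so the conversion can be audited.  The
adaptive-testing machinery consumes the transcribed IRT table, which was
produced from unrounded factor estimates and is therefore the operative
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemFactorParams",
    "ItemIrtParams",
    "ItemBank",
    "BankParameterError",
    "NonConvertibleItemError",
    "SCALING_CONSTANT",
    "convert_discrimination",
    "convert_thresholds",
    "convert_item",
    "load_item_bank",
    "load_default_bank",
    "omega_hierarchical",
]

#: Normal-ogive to logistic scaling constant.
SCALING_CONSTANT = 1.7


class BankParameterError(ValueError):
    """An item-bank table is malformed or internally inconsistent."""


class NonConvertibleItemError(ValueError):
    """Item communality >= 1: zero or negative uniqueness, no IRT conversion."""


@dataclass(frozen=True)
class ItemFactorParams:
    """Bifactor loadings and normal-ogive thresholds of one item.

    ``lambda_general`` is the loading on the general distress factor;
    ``lambda_specific`` is the loading on the item's wording method factor
    (posGHQ or posAff) and is ``None`` for negatively worded items.
    ``tau`` holds the ordered normal-ogive thresholds (3 for GHQ items,
    4 for Affectometer items).
    """

    item_id: str
    instrument: str  # "GHQ" | "AFF"
    wording: str  # "positive" | "negative"
    lambda_general: float
    lambda_specific: float | None
    tau: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.instrument not in ("GHQ", "AFF"):
            raise BankParameterError(
                f"{self.item_id}: unknown instrument {self.instrument!r}"
            )
        if self.wording not in ("positive", "negative"):
            raise BankParameterError(
                f"{self.item_id}: unknown wording {self.wording!r}"
            )
        if self.wording == "negative" and self.lambda_specific is not None:
            raise BankParameterError(
                f"{self.item_id}: negative-wording item must not have a "
                "specific loading"
            )
        if self.wording == "positive" and self.lambda_specific is None:
            raise BankParameterError(
                f"{self.item_id}: positive-wording item requires a specific "
                "loading"
            )
        tau = np.asarray(self.tau, dtype=float)
        if tau.size == 0 or np.any(np.diff(tau) <= 0):
            raise BankParameterError(
                f"{self.item_id}: thresholds must be strictly increasing, "
                f"got {self.tau}"
            )
        if self.communality >= 1.0:
            raise BankParameterError(
                f"{self.item_id}: communality {self.communality:.3f} >= 1"
            )

    @property
    def loadings(self) -> tuple[float, ...]:
        """All loadings, general factor first."""
        if self.lambda_specific is None:
            return (self.lambda_general,)
        return (self.lambda_general, self.lambda_specific)

    @property
    def communality(self) -> float:
        return float(sum(l * l for l in self.loadings))


@dataclass(frozen=True)
class ItemIrtParams:
    """Logistic-metric GRM parameters of one item.

    The model is parameterized in intercept form: the cumulative boundary
    probability is ``expit(alpha * theta - t[k])``.  The difficulty form
    ``b[k] = t[k] / alpha`` is exposed as a derived accessor only.
    """

    item_id: str
    n_categories: int
    alpha: float
    t: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise BankParameterError(
                f"{self.item_id}: need at least 2 categories"
            )
        if not self.alpha > 0:
            raise BankParameterError(
                f"{self.item_id}: discrimination must be positive, "
                f"got {self.alpha}"
            )
        t = np.asarray(self.t, dtype=float)
        if t.size != self.n_categories - 1:
            raise BankParameterError(
                f"{self.item_id}: expected {self.n_categories - 1} "
                f"thresholds, got {t.size}"
            )
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise BankParameterError(
                f"{self.item_id}: thresholds must be strictly increasing, "
                f"got {self.t}"
            )

    @property
    def difficulties(self) -> tuple[float, ...]:
        """Location parameters ``b_k = t_k / alpha``."""
        return tuple(tk / self.alpha for tk in self.t)


def convert_discrimination(lambdas: Sequence[float]) -> float:
    """Convert factor loadings to a logistic-metric discrimination.

    ``lambdas`` holds the item's loadings with the general-factor loading
    first; only that loading enters the numerator, while every loading
    contributes to the uniqueness in the denominator::

        alpha = 1.7 * lambda_general / sqrt(1 - sum(lambda**2))

    Raises :class:`NonConvertibleItemError` when the communality reaches 1.
    """
    lam = np.asarray(lambdas, dtype=float)
    ss = float(np.sum(lam * lam))
    if ss >= 1.0:
        raise NonConvertibleItemError(
            f"sum of squared loadings {ss:.3f} >= 1"
        )
    return float(SCALING_CONSTANT * lam[0] / np.sqrt(1.0 - ss))


def convert_thresholds(
    taus: Sequence[float], lambdas: Sequence[float]
) -> np.ndarray:
    """Convert normal-ogive thresholds to the logistic metric.

    Elementwise ``t_k = 1.7 * tau_k / sqrt(1 - sum(lambda**2))``; the order
    of the thresholds is preserved (the common positive factor cannot break
    monotonicity).
    """
    lam = np.asarray(lambdas, dtype=float)
    ss = float(np.sum(lam * lam))
    if ss >= 1.0:
        raise NonConvertibleItemError(
            f"sum of squared loadings {ss:.3f} >= 1"
        )
    tau = np.asarray(taus, dtype=float)
    return SCALING_CONSTANT * tau / np.sqrt(1.0 - ss)


def convert_item(fp: ItemFactorParams) -> ItemIrtParams:
    """Full factor-to-IRT conversion of one item."""
    alpha = convert_discrimination(fp.loadings)
    t = convert_thresholds(fp.tau, fp.loadings)
    return ItemIrtParams(
        item_id=fp.item_id,
        n_categories=len(fp.tau) + 1,
        alpha=alpha,
        t=tuple(float(x) for x in t),
    )


class ItemBank:
    """Ordered collection of the 52 calibrated items.

    Enforces the bank invariants: 52 items, exactly 12 GHQ and 40 AFF,
    matching ids between the factor and IRT parameter sets, and category
    counts consistent with the threshold counts (4 levels for GHQ, 5 for
    AFF).
    """

    EXPECTED_SIZE = 52
    EXPECTED_GHQ = 12

    def __init__(
        self, items: Sequence[tuple[ItemFactorParams, ItemIrtParams]]
    ) -> None:
        items = list(items)
        if len(items) != self.EXPECTED_SIZE:
            raise BankParameterError(
                f"expected {self.EXPECTED_SIZE} items, got {len(items)}"
            )
        seen: set[str] = set()
        for fp, ip in items:
            if fp.item_id != ip.item_id:
                raise BankParameterError(
                    f"item id mismatch: {fp.item_id!r} vs {ip.item_id!r}"
                )
            if fp.item_id in seen:
                raise BankParameterError(f"duplicated item_id {fp.item_id!r}")
            seen.add(fp.item_id)
            expected_cats = len(fp.tau) + 1
            if ip.n_categories != expected_cats:
                raise BankParameterError(
                    f"{fp.item_id}: {expected_cats} categories implied by "
                    f"thresholds but IRT table says {ip.n_categories}"
                )
        n_ghq = sum(fp.instrument == "GHQ" for fp, _ in items)
        if n_ghq != self.EXPECTED_GHQ:
            raise BankParameterError(
                f"expected {self.EXPECTED_GHQ} GHQ items, got {n_ghq}"
            )
        self._items = items
        self._index = {fp.item_id: i for i, (fp, _) in enumerate(items)}

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    @property
    def items(self) -> list[tuple[ItemFactorParams, ItemIrtParams]]:
        return list(self._items)

    @property
    def factor_items(self) -> list[ItemFactorParams]:
        return [fp for fp, _ in self._items]

    @property
    def irt_items(self) -> list[ItemIrtParams]:
        return [ip for _, ip in self._items]

    @property
    def item_ids(self) -> list[str]:
        return [fp.item_id for fp, _ in self._items]

    def index_of(self, item_id: str) -> int:
        return self._index[item_id]

    def subset(self, instrument: str) -> list[ItemIrtParams]:
        """IRT parameters of one instrument ("GHQ" or "AFF")."""
        return [ip for fp, ip in self._items if fp.instrument == instrument]

    @property
    def ghq_fraction(self) -> float:
        n_ghq = sum(fp.instrument == "GHQ" for fp, _ in self._items)
        return n_ghq / len(self._items)

    def recomputed_irt(self) -> list[ItemIrtParams]:
        """IRT parameters recomputed from the factor table.

        These differ from the transcribed :attr:`irt_items` only through the
        rounding of the printed factor loadings.
        """
        return [convert_item(fp) for fp, _ in self._items]

    def as_administered(self) -> "ItemBank":
        """The bank in the slope-difficulty metric of the CAT simulation.

        The conversion formulas produce intercept-form thresholds
        (boundary probability ``expit(alpha * theta - t_k)``), whereas the
        R tooling this bank's adaptive administration was evaluated with
        (catIrt) parameterizes the graded response model in
        slope-difficulty form ``expit(alpha * (theta - b_k))`` and was
        supplied the ``t_k`` values in the difficulty slots.  The operative
        administered bank therefore has boundary locations ``b_k = t_k``,
        i.e. intercept-form thresholds ``alpha * t_k``.  The simulation
        study administers this metric to reproduce the published
        efficiency, mixing and accuracy tables; everything else in the
        package (conversion checks, information curves, probabilities)
        uses the nominal intercept metric.
        """
        items = [
            (
                fp,
                ItemIrtParams(
                    item_id=ip.item_id,
                    n_categories=ip.n_categories,
                    alpha=ip.alpha,
                    t=tuple(ip.alpha * tk for tk in ip.t),
                ),
            )
            for fp, ip in self._items
        ]
        return ItemBank(items)


def _read_table(path, what: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise BankParameterError(f"{what} table is empty: {path}") from exc
    if frame.empty:
        raise BankParameterError(f"{what} table has no rows: {path}")
    return frame


def _require_columns(frame: pd.DataFrame, cols: Iterable[str], what: str):
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise BankParameterError(f"{what} table is missing columns {missing}")


def load_item_bank(factor_table, irt_table) -> ItemBank:
    """Build an :class:`ItemBank` from two delimiter-separated tables.

    ``factor_table`` columns: item_id, instrument, wording, lambda_general,
    lambda_specific, tau1..tau4 (empty cells where a value does not exist).
    ``irt_table`` columns: item_id, n_categories, alpha, t1..t4.  Errors are
    raised with the offending row named.
    """
    ff = _read_table(factor_table, "factor")
    ff.columns = [c.strip() for c in ff.columns]
    _require_columns(
        ff,
        ["item_id", "instrument", "wording", "lambda_general",
         "lambda_specific", "tau1", "tau2", "tau3", "tau4"],
        "factor",
    )
    tf = _read_table(irt_table, "IRT")
    tf.columns = [c.strip() for c in tf.columns]
    _require_columns(
        tf, ["item_id", "n_categories", "alpha", "t1", "t2", "t3", "t4"],
        "IRT",
    )

    if tf["item_id"].duplicated().any():
        dup = tf.loc[tf["item_id"].duplicated(), "item_id"].iloc[0]
        raise BankParameterError(f"duplicated item_id {dup!r} in IRT table")
    irt_by_id: dict[str, ItemIrtParams] = {}
    for _, row in tf.iterrows():
        t = [row[f"t{k}"] for k in (1, 2, 3, 4)]
        t = [float(x) for x in t if pd.notna(x)]
        try:
            irt_by_id[row["item_id"]] = ItemIrtParams(
                item_id=row["item_id"],
                n_categories=int(row["n_categories"]),
                alpha=float(row["alpha"]),
                t=tuple(t),
            )
        except (TypeError, ValueError) as exc:
            raise BankParameterError(
                f"IRT table row {row['item_id']!r}: {exc}"
            ) from exc

    items: list[tuple[ItemFactorParams, ItemIrtParams]] = []
    seen: set[str] = set()
    for _, row in ff.iterrows():
        iid = row["item_id"]
        if iid in seen:
            raise BankParameterError(
                f"duplicated item_id {iid!r} in factor table"
            )
        seen.add(iid)
        tau = [row[f"tau{k}"] for k in (1, 2, 3, 4)]
        tau = [float(x) for x in tau if pd.notna(x)]
        lam_spec = row["lambda_specific"]
        try:
            fp = ItemFactorParams(
                item_id=iid,
                instrument=str(row["instrument"]).strip(),
                wording=str(row["wording"]).strip(),
                lambda_general=float(row["lambda_general"]),
                lambda_specific=(
                    None if pd.isna(lam_spec) else float(lam_spec)
                ),
                tau=tuple(tau),
                label=str(row.get("label", "") or ""),
            )
        except (TypeError, ValueError) as exc:
            raise BankParameterError(
                f"factor table row {iid!r}: {exc}"
            ) from exc
        if iid not in irt_by_id:
            raise BankParameterError(
                f"item {iid!r} present in factor table but missing from "
                "IRT table"
            )
        items.append((fp, irt_by_id.pop(iid)))
    if irt_by_id:
        extra = sorted(irt_by_id)
        raise BankParameterError(
            f"items {extra} present in IRT table but missing from factor "
            "table"
        )
    return ItemBank(items)


def load_default_bank() -> ItemBank:
    """Load the packaged GHQ-12 + Affectometer-2 bank."""
    data = resources.files("gpdcat") / "data"
    with resources.as_file(data / "factor_params.csv") as fpath, \
            resources.as_file(data / "irt_params.csv") as tpath:
        return load_item_bank(fpath, tpath)


def omega_hierarchical(bank: ItemBank) -> float:
    """Model-based reliability of the general factor (bifactor omega-H).

    Computed on the latent-response metric::

        omega_H = (sum lambda_gen)^2 /
                  [(sum lambda_gen)^2 + (sum_posGHQ lambda_spec)^2
                   + (sum_posAff lambda_spec)^2 + sum(1 - communality_i)]

    i.e. the variance attributable to the general factor divided by the
    total modeled variance of the unweighted item composite.
    """
    gen = 0.0
    spec_sums = {"GHQ": 0.0, "AFF": 0.0}
    unique = 0.0
    for fp in bank.factor_items:
        gen += fp.lambda_general
        if fp.lambda_specific is not None:
            spec_sums[fp.instrument] += fp.lambda_specific
        unique += 1.0 - fp.communality
    denom = gen**2 + spec_sums["GHQ"] ** 2 + spec_sums["AFF"] ** 2 + unique
    return gen**2 / denom
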