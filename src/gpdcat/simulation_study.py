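"""The 50-cell Monte Carlo evaluation of adaptive bank administration.

The design crosses trait estimators and item-selection rules —
MLE x {UW-FI, FP-KL} plus {BME, EAP} x {UW-FI, FP-KL} x {standard-normal,
uniform priors}, i.e. 10 estimator/selector/prior rows — with five SEM
termination thresholds (0.25, 0.32, 0.40, 0.45, 0.50), giving 50 cells.
The full design is run once per true-trait distribution (N(0,1) and
U(-3,3)).  Each cell reports the mean and SD of the administered-item
count, the mean percentage of GHQ-12 items among those administered, the
RMSE between estimated and true traits (on the logit scale), their Pearson
correlation, and per-item exposure counts.

Seeding is hierarchical: a master seed plus the cell index and the simulee
index determine every random stream, so any single cell (or simulee) can be
re-run independently.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cat_engine import CatConfig, CatSessionRecord, PriorSpec, SessionEngine
from .item_bank import ItemBank

__all__ = [
    "SEM_THRESHOLDS",
    "DESIGN_ROWS",
    "CellResult",
    "DesignResult",
    "ScatterData",
    "build_design_grid",
    "run_cell",
    "run_design",
    "correlation_scatter",
]

#: The five SEM termination thresholds of the design.
SEM_THRESHOLDS = (0.25, 0.32, 0.40, 0.45, 0.50)

#: The ten estimator/selector/prior rows, in presentation order.
DESIGN_ROWS: tuple[tuple[str, str, str], ...] = (
    ("MLE", "UW-FI", "none"),
    ("MLE", "FP-KL", "none"),
    ("BME", "UW-FI", "normal_standard"),
    ("BME", "UW-FI", "uniform"),
    ("BME", "FP-KL", "normal_standard"),
    ("BME", "FP-KL", "uniform"),
    ("EAP", "UW-FI", "normal_standard"),
    ("EAP", "UW-FI", "uniform"),
    ("EAP", "FP-KL", "normal_standard"),
    ("EAP", "FP-KL", "uniform"),
)

_PRIOR_LABEL = {"none": "-", "normal_standard": "Normal", "uniform": "Uniform"}


def build_design_grid(
    sem_thresholds: Sequence[float] = SEM_THRESHOLDS,
    rows: Sequence[tuple[str, str, str]] = DESIGN_ROWS,
) -> list[CatConfig]:
    """All estimator/selector/prior x threshold combinations (50 cells)."""
    grid = []
    for estimator, selector, prior_kind in rows:
        for thr in sem_thresholds:
            grid.append(
                CatConfig(
                    estimator=estimator,
                    selector=selector,
                    prior=PriorSpec(kind=prior_kind),
                    sem_threshold=float(thr),
                )
            )
    return grid


@dataclass
class CellResult:
    """Summary of one simulation cell."""

    config: CatConfig
    theta_dist: str
    n: int
    mean_items: float
    sd_items: float
    pct_ghq: float
    rmse: float
    correlation: float
    exposure: np.ndarray  # administration count per bank item
    item_ids: list[str]
    theta_true: np.ndarray
    theta_est: np.ndarray
    n_items_per_session: np.ndarray
    records: list[CatSessionRecord] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_ghq <= 100:
            raise ValueError("pct_ghq outside [0, 100]")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")
        if int(self.exposure.sum()) != int(self.n_items_per_session.sum()):
            raise ValueError("exposure counts inconsistent with sessions")

    def summary(self) -> dict:
        return {
            "estimator": self.config.estimator,
            "selector": self.config.selector,
            "prior": _PRIOR_LABEL[self.config.prior.kind],
            "sem_threshold": self.config.sem_threshold,
            "theta_dist": self.theta_dist,
            "n": self.n,
            "mean_items": self.mean_items,
            "sd_items": self.sd_items,
            "pct_ghq": self.pct_ghq,
            "rmse": self.rmse,
            "correlation": self.correlation,
        }


def run_cell(
    config: CatConfig,
    thetas: np.ndarray,
    bank: ItemBank,
    seed: int | Sequence[int] = 0,
    theta_dist: str = "",
    keep_records: bool = False,
    progress: bool = False,
    session_runner: Callable[[float, np.random.SeedSequence],
                             CatSessionRecord] | None = None,
) -> CellResult:
    """Run one cell: one adaptive session per true trait value.

    ``seed`` may be an int or a sequence of ints (e.g. master seed + cell
    index); simulee ``i`` uses the seed sequence ``[*seed, i]``.
    ``session_runner`` can replace the standard engine (used for oracle
    checks); it receives ``(theta_true, seed_sequence)``.
    """
    thetas = np.asarray(thetas, dtype=float)
    if session_runner is None:
        engine = SessionEngine(bank, config)
        session_runner = engine.run
    seed_head = [seed] if np.isscalar(seed) else list(seed)

    ghq_mask = np.array(
        [fp.instrument == "GHQ" for fp in bank.factor_items]
    )
    index_of = {iid: k for k, iid in enumerate(bank.item_ids)}

    n = thetas.size
    theta_est = np.empty(n)
    n_items = np.empty(n, dtype=np.int64)
    pct = np.empty(n)
    exposure = np.zeros(len(bank), dtype=np.int64)
    records: list[CatSessionRecord] | None = [] if keep_records else None

    iterator = range(n)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, file=sys.stderr, desc=config.label(),
                        leave=False)
    for i in iterator:
        ss = np.random.SeedSequence(seed_head + [i])
        rec = session_runner(thetas[i], ss)
        theta_est[i] = rec.final_estimate.theta
        n_items[i] = rec.n_administered
        rows = [index_of[iid] for iid in rec.administered]
        exposure[rows] += 1
        pct[i] = 100.0 * ghq_mask[rows].mean()
        if records is not None:
            records.append(rec)

    err = theta_est - thetas
    rmse = float(np.sqrt(np.mean(err * err)))
    if n >= 2 and np.std(thetas) > 0 and np.std(theta_est) > 0:
        corr = float(np.corrcoef(thetas, theta_est)[0, 1])
    else:
        corr = float("nan")
    return CellResult(
        config=config,
        theta_dist=theta_dist,
        n=int(n),
        mean_items=float(n_items.mean()),
        sd_items=float(n_items.std(ddof=1)) if n > 1 else 0.0,
        pct_ghq=float(pct.mean()),
        rmse=rmse,
        correlation=corr,
        exposure=exposure,
        item_ids=list(bank.item_ids),
        theta_true=thetas,
        theta_est=theta_est,
        n_items_per_session=n_items,
        records=records,
    )


@dataclass
class DesignResult:
    """All cell results of a design run, with table builders."""

    cells: list[CellResult]

    @property
    def frame(self) -> pd.DataFrame:
        """Tidy per-cell summary frame."""
        return pd.DataFrame([c.summary() for c in self.cells])

    def _wide(self, value: str, formatter=None) -> pd.DataFrame:
        df = self.frame
        df = df.assign(
            row=df["estimator"] + "/" + df["selector"] + "/" + df["prior"]
        )
        wide = df.pivot_table(
            index="row", columns=["theta_dist", "sem_threshold"],
            values=value, sort=False,
        )
        order = [
            f"{e}/{s}/{_PRIOR_LABEL[p]}" for e, s, p in DESIGN_ROWS
            if f"{e}/{s}/{_PRIOR_LABEL[p]}" in set(wide.index)
        ]
        wide = wide.loc[order]
        if formatter is not None:
            wide = wide.map(formatter)
        return wide

    def items_table(self) -> pd.DataFrame:
        """Mean administered items per cell (rows x thresholds)."""
        return self._wide("mean_items")

    def items_table_formatted(self) -> pd.DataFrame:
        """'mean (sd)' strings with the integer rounding used in print."""
        mean = self._wide("mean_items")
        sd = self._wide("sd_items")
        out = mean.copy().astype(object)
        for col in mean.columns:
            out[col] = [
                f"{round(m):.0f} ({round(s):.0f})"
                for m, s in zip(mean[col], sd[col])
            ]
        return out

    def pct_ghq_table(self) -> pd.DataFrame:
        """Mean % of GHQ-12 items among administered items."""
        return self._wide("pct_ghq")

    def rmse_table(self) -> pd.DataFrame:
        """RMSE between estimated and true traits (logits)."""
        return self._wide("rmse")

    def correlation_table(self) -> pd.DataFrame:
        return self._wide("correlation")

    def exposure_frame(self) -> pd.DataFrame:
        """Per-item administration counts, one column per cell."""
        cols = {}
        for c in self.cells:
            key = f"{c.config.label()}|{c.theta_dist}"
            cols[key] = c.exposure
        return pd.DataFrame(cols, index=self.cells[0].item_ids)


def run_design(
    grid: Sequence[CatConfig],
    bank: ItemBank,
    thetas_normal: np.ndarray | None,
    thetas_uniform: np.ndarray | None,
    seed: int = 0,
    keep_records: bool = False,
    progress: bool = False,
) -> DesignResult:
    """Run every grid cell under each supplied trait distribution.

    Cell ``c`` under distribution ``d`` uses seeds ``[seed, d, c, i]`` per
    simulee ``i``; two runs with the same master seed produce identical
    tables.
    """
    cells: list[CellResult] = []
    dists: list[tuple[int, str, np.ndarray]] = []
    if thetas_normal is not None:
        dists.append((0, "N(0,1)", np.asarray(thetas_normal)))
    if thetas_uniform is not None:
        dists.append((1, "U(-3,3)", np.asarray(thetas_uniform)))
    if not dists:
        raise ValueError("at least one theta distribution is required")
    for d_idx, d_label, thetas in dists:
        for c_idx, config in enumerate(grid):
            cells.append(
                run_cell(
                    config,
                    thetas,
                    bank,
                    seed=[seed, d_idx, c_idx],
                    theta_dist=d_label,
                    keep_records=keep_records,
                    progress=progress,
                )
            )
    return DesignResult(cells)


@dataclass(frozen=True)
class ScatterData:
    """Paired (theta_true, theta_est) values with their Pearson r."""

    theta_true: np.ndarray
    theta_est: np.ndarray
    r: float


def correlation_scatter(
    records: Sequence[CatSessionRecord],
) -> ScatterData:
    """Extract (true, estimated) trait pairs and their correlation.

    Raises ``ValueError`` when fewer than two sessions are given or either
    vector is constant (the correlation is undefined).
    """
    if len(records) < 2:
        raise ValueError("need at least two sessions")
    t = np.array([r.theta_true for r in records])
    e = np.array([r.final_estimate.theta for r in records])
    if np.std(t) == 0 or np.std(e) == 0:
        raise ValueError("correlation undefined for constant values")
    return ScatterData(t, e, float(np.corrcoef(t, e)[0, 1]))
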