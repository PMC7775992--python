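"""Participant- and node-level quality control plus nuisance regression.

Implements three gates applied before any coupling estimate is computed:

1. participant motion exclusion from framewise displacement (FD) and
   standardised DVARS traces;
2. cohort-wide node dropout masking from mean signal intensity z-scores;
3. per-node ordinary-least-squares removal of HRF-convolved task-event
   regressors.

FD and DVARS are read from confound tables (fMRIPrep column naming:
``framewise_displacement``, ``std_dvars``); they are never recomputed from
images, which lie outside this package's boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeriesRun",
    "MotionSummary",
    "MotionDecision",
    "MotionThresholds",
    "NodeMask",
    "motion_exclude",
    "flag_dropout_nodes",
    "regress_task_events",
]


@dataclass
class RoiTimeSeriesRun:
    """One run's BOLD table: volumes x nodes, in arbitrary units.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_volumes, n_nodes)``. No missing values.
    tr_seconds
        Repetition time between volumes.
    run_id
        Label for the acquisition run.
    node_ids
        Ordered, unique node labels matching the columns of ``data``.
    """

    data: np.ndarray
    tr_seconds: float
    run_id: str
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D volumes x nodes matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a run needs at least 2 volumes")
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values")
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for {self.data.shape[1]} columns"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.node_ids)

    def select_nodes(self, keep: list[str]) -> "RoiTimeSeriesRun":
        """Restrict the run to ``keep`` (in the given order)."""
        idx = [self.node_ids.index(n) for n in keep]
        return RoiTimeSeriesRun(
            data=self.data[:, idx],
            tr_seconds=self.tr_seconds,
            run_id=self.run_id,
            node_ids=list(keep),
        )


@dataclass(frozen=True)
class MotionThresholds:
    """Exclusion rule constants.

    A participant is excluded if more than ``frac_limit`` of volumes have
    FD > ``fd_volume`` mm or DVARS > ``dvars`` %, or if mean FD exceeds
    ``mean_fd`` mm.
    """

    fd_volume: float = 0.25
    dvars: float = 4.0
    frac_limit: float = 0.25
    mean_fd: float = 0.2


@dataclass
class MotionSummary:
    """Per-participant motion summary pooled over runs."""

    fd: np.ndarray
    dvars: np.ndarray
    mean_fd: float = field(init=False)
    frac_fd_gt_025: float = field(init=False)
    frac_dvars_gt_4: float = field(init=False)

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.shape != self.dvars.shape:
            raise ValueError("fd and dvars must be aligned to the same volumes")
        if (self.fd < 0).any() or (self.dvars < 0).any():
            raise ValueError("fd and dvars must be non-negative")
        self.mean_fd = float(self.fd.mean())
        # the "025"/"4" names record the conventional thresholds; the
        # decision itself re-derives fractions from MotionThresholds
        self.frac_fd_gt_025 = float((self.fd > 0.25).mean())
        self.frac_dvars_gt_4 = float((self.dvars > 4.0).mean())

    @classmethod
    def from_confounds(cls, confounds: list[pd.DataFrame]) -> "MotionSummary":
        """Pool fMRIPrep-style confound tables across runs.

        A NaN in the first row of each run (no predecessor volume) is
        treated as 0.
        """
        fd_parts, dv_parts = [], []
        for df in confounds:
            fd = pd.to_numeric(df["framewise_displacement"], errors="coerce").to_numpy()
            dv = pd.to_numeric(df["std_dvars"], errors="coerce").to_numpy()
            fd_parts.append(np.nan_to_num(fd, nan=0.0))
            dv_parts.append(np.nan_to_num(dv, nan=0.0))
        return cls(fd=np.concatenate(fd_parts), dvars=np.concatenate(dv_parts))


@dataclass(frozen=True)
class MotionDecision:
    keep: bool
    reasons: tuple[str, ...]


def motion_exclude(
    ms: MotionSummary, thresholds: MotionThresholds = MotionThresholds()
) -> MotionDecision:
    """Decide keep/exclude from motion summaries.

    Exclude iff the fraction of volumes with FD above the per-volume limit
    exceeds ``frac_limit``, OR the fraction with DVARS above the limit
    exceeds ``frac_limit``, OR mean FD exceeds ``mean_fd``. Every triggered
    rule is listed in the decision.
    """
    reasons = []
    frac_fd = float((ms.fd > thresholds.fd_volume).mean())
    frac_dv = float((ms.dvars > thresholds.dvars).mean())
    if frac_fd > thresholds.frac_limit:
        reasons.append(
            f"frac(FD>{thresholds.fd_volume})={frac_fd:.3f} > {thresholds.frac_limit}"
        )
    if frac_dv > thresholds.frac_limit:
        reasons.append(
            f"frac(DVARS>{thresholds.dvars})={frac_dv:.3f} > {thresholds.frac_limit}"
        )
    if ms.mean_fd > thresholds.mean_fd:
        reasons.append(f"mean FD={ms.mean_fd:.4f} > {thresholds.mean_fd}")
    return MotionDecision(keep=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class NodeMask:
    """Cohort-wide node keep/drop mask."""

    kept: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...]  # (node id, reason)

    @property
    def dropped_ids(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.dropped)


def flag_dropout_nodes(
    mean_signals: pd.DataFrame, z_threshold: float = -1.64
) -> NodeMask:
    """Flag signal-dropout nodes cohort-wide.

    Parameters
    ----------
    mean_signals
        Participants x nodes table of mean time-series signal intensity
        (one mean per node per participant, averaged across runs).
    z_threshold
        A node is dropped if its intensity z-score across nodes is
        ``<= z_threshold`` in ANY participant. Inclusive by contract.

    Notes
    -----
    Z-scores use the sample standard deviation (ddof=1).
    """
    values = mean_signals.to_numpy(dtype=float)
    nodes = [str(c) for c in mean_signals.columns]
    sd = values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = mean_signals.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(
            f"degenerate data: zero variance across nodes for participant {bad!r}"
        )
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    dropped = []
    for j, node in enumerate(nodes):
        hits = np.flatnonzero(z[:, j] <= z_threshold)
        if hits.size:
            worst = hits[np.argmin(z[hits, j])]
            dropped.append(
                (
                    node,
                    f"z={z[worst, j]:.3f} <= {z_threshold} "
                    f"in participant {mean_signals.index[worst]}",
                )
            )
    dropped_ids = {n for n, _ in dropped}
    kept = tuple(n for n in nodes if n not in dropped_ids)
    return NodeMask(kept=kept, dropped=tuple(dropped))


def regress_task_events(
    run: RoiTimeSeriesRun, regressors: np.ndarray
) -> RoiTimeSeriesRun:
    """Residualise each node's series against task-event regressors.

    Fits, per node, ordinary least squares on ``[intercept | regressors]``
    and returns the residuals (node order and shape preserved). A
    rank-deficient design triggers a warning; the minimum-norm solution is
    used, which leaves the residuals unchanged.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != run.n_volumes:
        if regressors.T.shape[0] == run.n_volumes:
            regressors = regressors.T
        else:
            raise ValueError(
                f"regressors have {regressors.shape[0]} rows for "
                f"{run.n_volumes} volumes"
            )
    X = np.column_stack([np.ones(run.n_volumes), regressors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient task design (rank {rank} < {X.shape[1]}); "
            "collinear columns contribute nothing to the fit",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    residuals = run.data - X @ beta
    return RoiTimeSeriesRun(
        data=residuals,
        tr_seconds=run.tr_seconds,
        run_id=run.run_id,
        node_ids=list(run.node_ids),
    )
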