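"""Multiplication of temporal derivatives (MTD) and window averaging.

The coupling estimate for a node pair at time t is the product of the two
nodes' SD-normalised first differences. Point-wise estimates are collapsed
into non-overlapping windows (default 15 TR) by element-wise averaging;
the trailing remainder is discarded.

Windows are defined on derivative time points (of which there are
``n_volumes - 1``), so a 179-volume run yields ``floor(178 / 15) = 11``
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dynfc.qc import RoiTimeSeriesRun

__all__ = [
    "DerivativeSeries",
    "WindowCouplingStack",
    "temporal_derivative",
    "mtd_pointwise",
    "window_average",
    "mtd_windows",
    "n_windows",
]


@dataclass
class DerivativeSeries:
    """SD-normalised first differences, ``(n_volumes - 1) x n_nodes``.

    Each column has unit sample standard deviation (ddof=1).
    """

    dt: np.ndarray
    node_ids: list[str]
    tr_seconds: float
    run_id: str


@dataclass
class WindowCouplingStack:
    """Ordered window-indexed symmetric node x node coupling matrices.

    ``windows`` has shape ``(n_windows, n_nodes, n_nodes)``; each slice is
    symmetric with a zero diagonal (self-coupling is ignored by
    convention).
    """

    windows: np.ndarray
    window_length_tr: int
    run_id: str
    node_ids: list[str]
    offset: int = 0

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.windows.shape[1]


def temporal_derivative(run: RoiTimeSeriesRun) -> DerivativeSeries:
    """First differences of each node's series, normalised by their SD.

    ``dt[t, i] = ts[t+1, i] - ts[t, i]``, then each column is divided by
    its sample standard deviation. Scale and shift of the input cancel, so
    the result is invariant to per-node affine rescaling (positive scale).

    Raises
    ------
    ValueError
        If any node's derivative has zero variance (constant series).
    """
    dt = np.diff(run.data, axis=0)
    sd = dt.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(run.node_ids[i] for i in zero[:5])
        raise ValueError(f"zero-variance derivative for node(s): {names}")
    return DerivativeSeries(
        dt=dt / sd,
        node_ids=list(run.node_ids),
        tr_seconds=run.tr_seconds,
        run_id=run.run_id,
    )


def mtd_pointwise(ds: DerivativeSeries) -> np.ndarray:
    """Point-wise coupling: ``M[t, i, j] = dt[t, i] * dt[t, j]``.

    Returns an array of shape ``(n_volumes - 1, n_nodes, n_nodes)``,
    symmetric in the last two axes by construction.
    """
    return np.einsum("ti,tj->tij", ds.dt, ds.dt)


def n_windows(n_points: int, window_length: int, offset: int = 0) -> int:
    """Number of complete non-overlapping windows: floor((points-offset)/w)."""
    return max(0, (n_points - offset) // window_length)


def window_average(
    pointwise: np.ndarray,
    window_length: int = 15,
    offset: int = 0,
    run_id: str = "run",
    node_ids: list[str] | None = None,
) -> WindowCouplingStack:
    """Average point-wise matrices over consecutive non-overlapping blocks.

    Blocks of ``window_length`` derivative points start at ``offset``; the
    trailing remainder is discarded. Diagonals are zeroed.
    """
    pointwise = np.asarray(pointwise, dtype=float)
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    n_pts = pointwise.shape[0]
    n_win = n_windows(n_pts, window_length, offset)
    if n_win == 0:
        raise ValueError(
            f"window_length {window_length} (offset {offset}) exceeds the "
            f"{n_pts} available derivative points"
        )
    usable = pointwise[offset : offset + n_win * window_length]
    n = usable.shape[1]
    windows = usable.reshape(n_win, window_length, n, n).mean(axis=1)
    idx = np.arange(n)
    windows[:, idx, idx] = 0.0
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    return WindowCouplingStack(
        windows=windows,
        window_length_tr=window_length,
        run_id=run_id,
        node_ids=list(node_ids),
        offset=offset,
    )


def mtd_windows(
    run: RoiTimeSeriesRun, window_length: int = 15, offset: int = 0
) -> WindowCouplingStack:
    """Full coupling path for one run: derivative -> point-wise -> windows."""
    ds = temporal_derivative(run)
    return window_average(
        mtd_pointwise(ds),
        window_length=window_length,
        offset=offset,
        run_id=run.run_id,
        node_ids=run.node_ids,
    )
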