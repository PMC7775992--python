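"""Cartographic profiles and metastate labelling.

For each time window, node-wise participation coefficients (PC) and
module degree z-scores (MDZ) — computed against that window's community
partition — are binned into a 2-D histogram (the cartographic profile,
default 10 x 10). K-means with k=2 over a participant's flattened
profiles splits windows into two states; the cluster whose centroid has
the higher expected PC (mass-weighted mean of PC bin centres) is labelled
"integrated", the other "segregated". Signed window coupling matrices
labelled integrated are averaged — pooled across runs, then across
detection repetitions — into one integrated network per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from dynfc.coupling import WindowCouplingStack

__all__ = [
    "CartographicProfile",
    "MetastateLabeling",
    "IntegratedNetwork",
    "participation_coefficient",
    "module_degree_zscore",
    "cartographic_profile",
    "kmeans_metastates",
    "integrated_network",
    "metastate_stats",
]

INTEGRATED, SEGREGATED = 1, 0


def participation_coefficient(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-node participation coefficient on a non-negative weighted graph.

    ``PC_i = 1 - sum_s (kappa_is / k_i)**2`` where ``kappa_is`` is the
    strength of node i into community s and ``k_i`` its total strength.
    Isolated nodes (``k_i = 0``) get PC 0.
    """
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("participation coefficient requires non-negative weights")
    labels = np.asarray(labels)
    n = w.shape[0]
    if labels.shape[0] != n:
        raise ValueError("every node must be labelled")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    k = w.sum(axis=1)
    _, dense = np.unique(labels, return_inverse=True)
    n_comm = dense.max() + 1
    onehot = np.zeros((n, n_comm))
    onehot[np.arange(n), dense] = 1.0
    kappa = w @ onehot  # strength of each node into each community
    pc = np.zeros(n)
    nz = k > 0
    pc[nz] = 1.0 - ((kappa[nz] / k[nz, None]) ** 2).sum(axis=1)
    return pc


def module_degree_zscore(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-node within-module strength z-score.

    Each node's strength to its own module is z-scored against the
    within-module strengths of its module peers (sample SD, ddof=1).
    Modules with fewer than 2 nodes or zero spread give z = 0.
    """
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("module degree z-score requires non-negative weights")
    labels = np.asarray(labels)
    n = w.shape[0]
    if labels.shape[0] != n:
        raise ValueError("every node must be labelled")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    z = np.zeros(n)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            continue
        kin = w[np.ix_(members, members)].sum(axis=1)
        sd = kin.std(ddof=1)
        if sd > 0:
            z[members] = (kin - kin.mean()) / sd
    return z


@dataclass
class CartographicProfile:
    """Normalised 2-D histogram of node-wise (PC, MDZ) for one window."""

    histogram: np.ndarray
    window_ref: tuple[str, int]  # (run id, window index)
    pc_edges: np.ndarray = field(repr=False, default=None)
    mdz_edges: np.ndarray = field(repr=False, default=None)

    def flatten(self) -> np.ndarray:
        return self.histogram.ravel()

    def expected_pc(self) -> float:
        """Mass-weighted mean of PC bin centres."""
        centers = 0.5 * (self.pc_edges[:-1] + self.pc_edges[1:])
        return float((self.histogram.sum(axis=1) * centers).sum())


def cartographic_profile(
    pc: np.ndarray,
    mdz: np.ndarray,
    bins: int = 10,
    mdz_range: tuple[float, float] = (-3.0, 3.0),
    window_ref: tuple[str, int] = ("run", 0),
) -> CartographicProfile:
    """Bin node-wise PC and MDZ into a normalised 2-D histogram.

    PC uses fixed edges on [0, 1]; MDZ values are clipped into
    ``mdz_range`` before binning so profiles are comparable across
    windows and participants.
    """
    pc = np.asarray(pc, dtype=float)
    mdz = np.clip(np.asarray(mdz, dtype=float), *mdz_range)
    hist, pc_edges, mdz_edges = np.histogram2d(
        pc, mdz, bins=bins, range=[(0.0, 1.0), mdz_range]
    )
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return CartographicProfile(
        histogram=hist, window_ref=window_ref, pc_edges=pc_edges, mdz_edges=mdz_edges
    )


@dataclass
class MetastateLabeling:
    """Binary integrated/segregated labels per (run, window).

    ``labels`` maps run id to an int array over that run's windows, with
    1 = integrated, 0 = segregated.
    """

    labels: dict[str, np.ndarray]
    repetition: int
    frac_integrated: float = field(init=False)
    n_switches_per_run: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        flat = np.concatenate([np.asarray(v) for v in self.labels.values()])
        self.frac_integrated = float(flat.mean()) if flat.size else 0.0
        self.n_switches_per_run = {
            run: int((np.diff(np.asarray(v)) != 0).sum())
            for run, v in self.labels.items()
        }


def kmeans_metastates(
    profiles_by_run: dict[str, list[CartographicProfile]],
    k: int = 2,
    seed: int = 0,
    repetition: int = 0,
    n_init: int = 10,
) -> MetastateLabeling:
    """Cluster one participant's window profiles into metastates.

    Profiles are pooled across runs, flattened, and clustered with
    k-means (Euclidean, ``n_init`` seeded restarts). The cluster whose
    centroid has the higher expected PC is labelled integrated; a cluster
    index swap therefore never changes state semantics.
    """
    runs = list(profiles_by_run)
    flat = np.vstack(
        [p.flatten() for run in runs for p in profiles_by_run[run]]
    )
    if flat.shape[0] < k:
        raise ValueError(f"need at least {k} windows to cluster")
    if np.allclose(flat, flat[0]):
        raise ValueError("all profiles identical; no clustering possible")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(flat)
    # expected PC of each centroid, via the PC-marginal of the first profile's grid
    any_profile = next(p for run in runs for p in profiles_by_run[run])
    centers = 0.5 * (any_profile.pc_edges[:-1] + any_profile.pc_edges[1:])
    bins = any_profile.histogram.shape
    centroid_pc = np.array(
        [
            (km.cluster_centers_[c].reshape(bins).sum(axis=1) * centers).sum()
            for c in range(k)
        ]
    )
    integrated_cluster = int(np.argmax(centroid_pc))
    labels: dict[str, np.ndarray] = {}
    pos = 0
    for run in runs:
        n_win = len(profiles_by_run[run])
        labels[run] = (
            assignments[pos : pos + n_win] == integrated_cluster
        ).astype(int)
        pos += n_win
    return MetastateLabeling(labels=labels, repetition=repetition)


@dataclass
class IntegratedNetwork:
    """Participant-level mean FC over integrated windows.

    Element-wise mean of the signed window coupling matrices labelled
    integrated, pooled across runs within a repetition and then averaged
    over repetitions.
    """

    mean_fc: np.ndarray
    n_windows_used: list[int]
    n_repetitions: int
    n_runs: int
    node_ids: list[str] | None = None


def integrated_network(
    stacks: list[WindowCouplingStack],
    labelings: list[MetastateLabeling],
    state: int = INTEGRATED,
) -> IntegratedNetwork:
    """Average the windows a repetition labels as ``state``.

    Per repetition, the mean of the selected signed window matrices
    (pooled across runs); the final network is the unweighted mean over
    repetitions. Repetitions with zero selected windows are skipped with
    a warning.
    """
    by_run = {s.run_id: s for s in stacks}
    rep_means = []
    n_used = []
    for lab in labelings:
        selected = []
        for run_id, state_vec in lab.labels.items():
            stack = by_run[run_id]
            if len(state_vec) != stack.n_windows:
                raise ValueError(
                    f"run {run_id}: {len(state_vec)} labels for "
                    f"{stack.n_windows} windows"
                )
            selected.extend(stack.windows[np.asarray(state_vec) == state])
        if not selected:
            warnings.warn(
                f"repetition {lab.repetition}: no windows in state {state}; skipped",
                stacklevel=2,
            )
            n_used.append(0)
            continue
        rep_means.append(np.mean(selected, axis=0))
        n_used.append(len(selected))
    if not rep_means:
        raise ValueError("no repetition produced any window in the requested state")
    node_ids = stacks[0].node_ids
    return IntegratedNetwork(
        mean_fc=np.mean(rep_means, axis=0),
        n_windows_used=n_used,
        n_repetitions=len(labelings),
        n_runs=len(stacks),
        node_ids=list(node_ids) if node_ids else None,
    )


def metastate_stats(labelings: list[MetastateLabeling]) -> dict[str, float]:
    """Participant summary over repetitions.

    ``pct_integrated``: percentage of all windows labelled integrated,
    averaged over repetitions. ``mean_switches``: consecutive-window
    label changes counted within each run (never across run boundaries),
    averaged across runs and repetitions.
    """
    pct = [lab.frac_integrated * 100.0 for lab in labelings]
    switches = [
        float(np.mean(list(lab.n_switches_per_run.values()))) for lab in labelings
    ]
    return {
        "pct_integrated": float(np.mean(pct)),
        "mean_switches": float(np.mean(switches)),
    }
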