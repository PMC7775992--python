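"""Multilayer (time-linked) community detection and partition dynamics.

Community structure across a run's window stack is found by greedy
Louvain-style maximisation of the multislice quality

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma * k_is k_js / (2 m_s)) d_sr
                               + d_ij * C_jsr ] * d(g_is, g_jr)

where layers are coupled ordinally (C_jsr = omega for adjacent layers
r = s +/- 1, else 0), the standard choice for temporal networks. Negative
window weights are set to zero before detection (strength-based null
models assume non-negative weights); signed values are retained upstream
for the averaged integrated network.

Partition-derived dynamics metrics: flexibility, allegiance, recruitment
and integration coefficients, community counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dynfc.coupling import WindowCouplingStack

__all__ = [
    "MultilayerPartition",
    "AllegianceMatrix",
    "multilayer_modularity",
    "partition_quality",
    "flexibility",
    "allegiance",
    "recruitment_integration",
    "community_count",
]


@dataclass
class MultilayerPartition:
    """Windows x nodes community labels from one detection repetition.

    Labels are dense positive integers (1..k, in order of first
    appearance across the flattened layer-major node sequence).
    """

    labels: np.ndarray
    gamma: float
    omega: float
    quality: float
    seed: int
    node_ids: list[str] | None = None

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: window, node_id, community."""
        layers, nodes = self.labels.shape
        node_ids = self.node_ids or [str(i) for i in range(nodes)]
        rows = [
            (w, node_ids[i], int(self.labels[w, i]))
            for w in range(layers)
            for i in range(nodes)
        ]
        return pd.DataFrame(rows, columns=["window", "node_id", "community"])


@dataclass
class AllegianceMatrix:
    """Node co-assignment frequencies across layers and repetitions."""

    p: np.ndarray
    node_ids: list[str] | None = None


def _layers_array(stack: WindowCouplingStack | np.ndarray) -> np.ndarray:
    if isinstance(stack, WindowCouplingStack):
        return np.asarray(stack.windows, dtype=float)
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a (layers, nodes, nodes) array")
    return arr


def _supra_modularity(
    layers: np.ndarray, gamma: float, omega: float
) -> tuple[np.ndarray, float]:
    """Dense supra-modularity matrix B and normalisation 2*mu.

    Supra index convention: x = layer * n_nodes + node.
    """
    n_layers, n_nodes, _ = layers.shape
    size = n_layers * n_nodes
    B = np.zeros((size, size))
    two_mu = 0.0
    for s in range(n_layers):
        A = np.clip(layers[s], 0.0, None)
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        m2 = k.sum()
        sl = slice(s * n_nodes, (s + 1) * n_nodes)
        if m2 > 0:
            B[sl, sl] = A - gamma * np.outer(k, k) / m2
        else:
            warnings.warn(
                f"layer {s} has no positive weights; kept without "
                "intra-layer cohesion",
                stacklevel=3,
            )
        two_mu += m2
    # ordinal (adjacent-layer) identity coupling
    for s in range(n_layers - 1):
        lo = s * n_nodes
        hi = (s + 1) * n_nodes
        idx = np.arange(n_nodes)
        B[lo + idx, hi + idx] += omega
        B[hi + idx, lo + idx] += omega
    two_mu += 2.0 * omega * n_nodes * max(0, n_layers - 1)
    return B, two_mu


def _move_phase(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One Louvain local-moving phase on a generic modularity matrix.

    Modifies ``labels`` in place; returns whether any node moved.
    """
    n = B.shape[0]
    tol = 1e-12
    counts = np.bincount(labels, minlength=n)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for x in rng.permutation(n):
            current = labels[x]
            w = B[x].copy()
            w[x] = 0.0  # self term is invariant under moves
            gains = np.bincount(labels, weights=w, minlength=counts.size)
            best = int(np.argmax(gains))
            if gains[best] > gains[current] + tol and best != current:
                counts[current] -= 1
                counts[best] += 1
                labels[x] = best
                improved = moved_any = True
            elif gains[current] < -tol and counts[current] > 1:
                # better off alone: move to a free label (one must exist)
                empty = int(np.flatnonzero(counts == 0)[0])
                counts[current] -= 1
                counts[empty] += 1
                labels[x] = empty
                improved = moved_any = True
    return moved_any


def _dense_relabel(labels: np.ndarray) -> np.ndarray:
    _, dense = np.unique(labels, return_inverse=True)
    # re-order by first appearance so output is deterministic
    order = {}
    out = np.empty_like(dense)
    for i, c in enumerate(dense):
        if c not in order:
            order[c] = len(order) + 1
        out[i] = order[c]
    return out


def _louvain(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Hierarchical Louvain on a symmetric (supra-)modularity matrix."""
    n = B.shape[0]
    node_map = np.arange(n)  # original supra-node -> current community
    level_B = B
    while True:
        labels = np.arange(level_B.shape[0])
        moved = _move_phase(level_B, labels, rng)
        if not moved:
            break
        _, dense = np.unique(labels, return_inverse=True)
        node_map = dense[node_map]
        k = dense.max() + 1
        onehot = np.zeros((level_B.shape[0], k))
        onehot[np.arange(level_B.shape[0]), dense] = 1.0
        level_B = onehot.T @ level_B @ onehot
        if k == 1:
            break
    return node_map


def multilayer_modularity(
    stack: WindowCouplingStack | np.ndarray,
    gamma: float = 1.0,
    omega: float = 1.0,
    seed: int = 0,
) -> MultilayerPartition:
    """Maximise multislice modularity over a window stack.

    Greedy Louvain with stochastic node-visit order controlled by
    ``seed``; identical seed and input give identical labels and Q. Label
    identity persists across layers through the inter-layer coupling
    ``omega`` — no post-hoc label matching is performed.
    """
    layers = _layers_array(stack)
    n_layers, n_nodes, _ = layers.shape
    B, two_mu = _supra_modularity(layers, gamma, omega)
    rng = np.random.default_rng(seed)
    flat = _louvain(B, rng)
    flat = _dense_relabel(flat)
    labels = flat.reshape(n_layers, n_nodes)
    quality = _quality_from_supra(B, two_mu, flat)
    node_ids = stack.node_ids if isinstance(stack, WindowCouplingStack) else None
    return MultilayerPartition(
        labels=labels,
        gamma=gamma,
        omega=omega,
        quality=quality,
        seed=seed,
        node_ids=list(node_ids) if node_ids else None,
    )


def _quality_from_supra(B: np.ndarray, two_mu: float, flat: np.ndarray) -> float:
    q = 0.0
    for c in np.unique(flat):
        members = np.flatnonzero(flat == c)
        q += B[np.ix_(members, members)].sum()
    return float(q / two_mu) if two_mu > 0 else 0.0


def partition_quality(
    stack: WindowCouplingStack | np.ndarray,
    labels: np.ndarray,
    gamma: float = 1.0,
    omega: float = 1.0,
) -> float:
    """Multislice Q of an arbitrary windows x nodes label matrix."""
    layers = _layers_array(stack)
    B, two_mu = _supra_modularity(layers, gamma, omega)
    return _quality_from_supra(B, two_mu, np.asarray(labels).ravel())


def flexibility(partition: MultilayerPartition) -> tuple[np.ndarray, float]:
    """Per-node fraction of consecutive-layer community switches.

    Returns the per-node values and their mean. Requires >= 2 layers.
    """
    labels = partition.labels
    if labels.shape[0] < 2:
        raise ValueError("flexibility needs at least 2 layers")
    switches = (np.diff(labels, axis=0) != 0).sum(axis=0)
    per_node = switches / (labels.shape[0] - 1)
    return per_node, float(per_node.mean())


def allegiance(partitions: list[MultilayerPartition]) -> AllegianceMatrix:
    """Co-assignment frequency over all (layer, repetition) pairs.

    ``p[i, j]`` is the fraction of layer-repetition slices in which nodes
    i and j share a community label. Diagonal is 1 by definition.
    """
    if not partitions:
        raise ValueError("at least one partition required")
    n_nodes = partitions[0].n_nodes
    for p in partitions:
        if p.n_nodes != n_nodes:
            raise ValueError("partitions must share the node set")
    count = np.zeros((n_nodes, n_nodes))
    total = 0
    for p in partitions:
        for layer in p.labels:
            count += layer[:, None] == layer[None, :]
            total += 1
    return AllegianceMatrix(p=count / total, node_ids=partitions[0].node_ids)


def recruitment_integration(
    am: AllegianceMatrix, systems: np.ndarray | list[str]
) -> pd.DataFrame:
    """Per-node recruitment and integration coefficients.

    Recruitment R_i is the mean allegiance of node i with the other nodes
    of its own a-priori system; integration I_i the mean allegiance with
    nodes of all other systems. A singleton system leaves R_i undefined
    (NaN).
    """
    systems = np.asarray(systems)
    p = am.p
    n = p.shape[0]
    if systems.shape[0] != n:
        raise ValueError("every node must be mapped to a system")
    same = systems[:, None] == systems[None, :]
    np.fill_diagonal(same, False)
    other = systems[:, None] != systems[None, :]
    r = np.full(n, np.nan)
    i_coef = np.full(n, np.nan)
    for i in range(n):
        if same[i].any():
            r[i] = p[i, same[i]].mean()
        if other[i].any():
            i_coef[i] = p[i, other[i]].mean()
    node_ids = am.node_ids or [str(i) for i in range(n)]
    return pd.DataFrame(
        {"node_id": node_ids, "system": systems, "recruitment": r, "integration": i_coef}
    )


def community_count(partition: MultilayerPartition) -> tuple[np.ndarray, float]:
    """Distinct communities per layer and their mean over layers."""
    counts = np.array([np.unique(layer).size for layer in partition.labels])
    return counts, float(counts.mean())
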