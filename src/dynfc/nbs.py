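"""Network Based Statistics.

Edge-wise general linear models over participant FC networks, connected
supra-threshold component extraction, and permutation family-wise-error
inference on the maximum component extent. Covariates are handled with
the Freedman-Lane scheme: residuals of the reduced (covariate-only)
model are permuted, the covariate fit is added back, and the full model
is refit — the covariate-safe default when the permutation scheme is
otherwise unspecified.

The per-edge model regresses edge FC on ``[intercept | contrast |
covariates]``; F is the partial F for the contrast (1 numerator df) and
t its signed square root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "EdgeStats",
    "NbsComponent",
    "NbsComponentResult",
    "build_design",
    "edgewise_glm",
    "supra_components",
    "permutation_fwe",
    "threshold_sweep",
    "cohens_f2",
    "subnetwork_report",
]


@dataclass(frozen=True)
class DesignSpec:
    """Which phenotype variable is tested against edge FC, and with what.

    ``contrast`` is the tested predictor (e.g. group status for an ANCOVA
    design, or a symptom change score for a regression design);
    ``covariates`` are adjusted for but not tested.
    """

    contrast: str
    covariates: tuple[str, ...] = ()
    kind: str = "regression"  # "ancova" | "regression"

    def __post_init__(self) -> None:
        if self.kind not in ("ancova", "regression"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        names = [self.contrast, *self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicated variables in design")


@dataclass
class EdgeStats:
    """Per-edge statistics on the upper triangle, stored as full matrices."""

    f: np.ndarray
    t: np.ndarray
    node_ids: list[str] | None = None


@dataclass
class NbsComponent:
    edges: list[tuple[str, str]]
    extent: int
    fwe_p: float


@dataclass
class NbsComponentResult:
    threshold: float
    components: list[NbsComponent]
    n_permutations: int
    stat_matrix: np.ndarray
    edge_t: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.025) -> list[NbsComponent]:
        return [c for c in self.components if c.fwe_p <= alpha]


def _encode_column(values: pd.Series) -> np.ndarray:
    """Numeric passthrough; two-level categoricals become 0/1."""
    arr = pd.to_numeric(values, errors="coerce")
    if not arr.isna().any():
        return arr.to_numpy(dtype=float)
    levels = sorted(values.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"variable {values.name!r} is non-numeric with {len(levels)} levels; "
            "only two-level factors are supported"
        )
    return (values.astype(str) == levels[1]).to_numpy(dtype=float)


def build_design(
    pheno: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices (full, reduced) from a phenotype table.

    Full: ``[1 | contrast | covariates]``; reduced drops the contrast.
    Raises on collinear designs, naming the offending columns.
    """
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["intercept"]
    for var in (design.contrast, *design.covariates):
        if var not in pheno.columns:
            raise ValueError(f"phenotype table lacks variable {var!r}")
        col = _encode_column(pheno[var])
        if var != design.contrast and np.ptp(col[~np.isnan(col)]) == 0:
            warnings.warn(
                f"covariate {var!r} is constant; dropped from the design",
                stacklevel=3,
            )
            continue
        cols.append(col)
        names.append(var)
    X = np.column_stack(cols)
    if np.isnan(X).any():
        bad = [names[j] for j in np.unique(np.nonzero(np.isnan(X))[1])]
        raise ValueError(f"missing phenotype values in columns: {bad}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design; columns: {names}")
    Z = np.delete(X, 1, axis=1)  # reduced model: covariates only
    return X, Z


def _edge_matrix(networks: list[np.ndarray] | np.ndarray) -> tuple[np.ndarray, int]:
    nets = np.asarray(networks, dtype=float)
    if nets.ndim != 3 or nets.shape[1] != nets.shape[2]:
        raise ValueError("networks must be participants x nodes x nodes")
    n_nodes = nets.shape[1]
    iu = np.triu_indices(n_nodes, k=1)
    return nets[:, iu[0], iu[1]], n_nodes


def _residual_maker(X: np.ndarray) -> np.ndarray:
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def _partial_f(
    Y: np.ndarray, rx: np.ndarray, rz: np.ndarray, dof_resid: int
) -> tuple[np.ndarray, np.ndarray]:
    """Partial F for the single contrast column, per response column."""
    rss_full = ((rx @ Y) ** 2).sum(axis=0)
    rss_red = ((rz @ Y) ** 2).sum(axis=0)
    # a residual indistinguishable from float noise (e.g. a constant edge)
    # must give F = 0, not a 0/0 blow-up
    tol = 1e-12 * np.maximum((Y**2).sum(axis=0), np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            rss_full > tol, (rss_red - rss_full) / (rss_full / dof_resid), 0.0
        )
    return np.clip(f, 0.0, None), rss_full


def _to_matrix(values: np.ndarray, n_nodes: int) -> np.ndarray:
    mat = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = values
    return mat + mat.T


def edgewise_glm(
    networks: list[np.ndarray] | np.ndarray,
    pheno: pd.DataFrame,
    design: DesignSpec,
    node_ids: list[str] | None = None,
) -> EdgeStats:
    """Per-edge partial F (and signed t) for the design's contrast."""
    Y, n_nodes = _edge_matrix(networks)
    if Y.shape[0] != len(pheno):
        raise ValueError("phenotype rows must match the number of networks")
    X, Z = build_design(pheno, design)
    dof = X.shape[0] - X.shape[1]
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    f, _ = _partial_f(Y, _residual_maker(X), _residual_maker(Z), dof)
    beta = np.linalg.pinv(X) @ Y
    t = np.sign(beta[1]) * np.sqrt(f)
    return EdgeStats(
        f=_to_matrix(f, n_nodes), t=_to_matrix(t, n_nodes), node_ids=node_ids
    )


def supra_components(
    stat_matrix: np.ndarray,
    threshold: float,
    node_ids: list[str] | None = None,
) -> list[dict]:
    """Connected components of the graph of edges with F >= threshold.

    Returns ``[{"edges": [...], "extent": int}, ...]`` sorted by
    descending extent. Empty list if nothing survives.
    """
    stat_matrix = np.asarray(stat_matrix, dtype=float)
    n = stat_matrix.shape[0]
    ids = node_ids or [str(i) for i in range(n)]
    g = nx.Graph()
    iu, ju = np.triu_indices(n, k=1)
    mask = stat_matrix[iu, ju] >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(ids[i], ids[j])
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        edges = sorted(tuple(sorted(e)) for e in sub.edges())
        comps.append({"edges": edges, "extent": sub.number_of_edges()})
    return sorted(comps, key=lambda c: -c["extent"])


def _null_max_extents(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    thresholds: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    n_nodes: int,
) -> np.ndarray:
    """Null distribution of max component extent, per threshold.

    Freedman-Lane: permute reduced-model residuals. Because fitted
    reduced values lie in the column space of both designs, the F
    statistic of the permuted data depends only on the permuted
    residuals.
    """
    rx, rz = _residual_maker(X), _residual_maker(Z)
    dof = X.shape[0] - X.shape[1]
    resid = rz @ Y
    iu = np.triu_indices(n_nodes, k=1)
    maxima = np.zeros((n_perm, thresholds.size))
    for p in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        f_perm, _ = _partial_f(resid[perm], rx, rz, dof)
        for k, thr in enumerate(thresholds):
            mask = f_perm >= thr
            if not mask.any():
                continue
            g = nx.Graph(zip(iu[0][mask], iu[1][mask]))
            maxima[p, k] = max(
                g.subgraph(c).number_of_edges()
                for c in nx.connected_components(g)
            )
    return maxima


def _run_nbs(
    networks,
    pheno: pd.DataFrame,
    design: DesignSpec,
    thresholds: np.ndarray,
    n_perm: int,
    seed: int,
    node_ids: list[str] | None,
) -> list[NbsComponentResult]:
    Y, n_nodes = _edge_matrix(networks)
    if Y.shape[0] != len(pheno):
        raise ValueError("phenotype rows must match the number of networks")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives unstable p-values", stacklevel=3)
    X, Z = build_design(pheno, design)
    dof = X.shape[0] - X.shape[1]
    f_obs, _ = _partial_f(Y, _residual_maker(X), _residual_maker(Z), dof)
    beta = np.linalg.pinv(X) @ Y
    t_obs = np.sign(beta[1]) * np.sqrt(f_obs)
    f_mat = _to_matrix(f_obs, n_nodes)
    t_mat = _to_matrix(t_obs, n_nodes)
    ids = node_ids or [str(i) for i in range(n_nodes)]

    rng = np.random.default_rng(seed)
    maxima = _null_max_extents(Y, X, Z, thresholds, n_perm, rng, n_nodes)

    results = []
    for k, thr in enumerate(thresholds):
        comps = supra_components(f_mat, thr, node_ids=ids)
        out = []
        for c in comps:
            exceed = int((maxima[:, k] >= c["extent"]).sum())
            fwe_p = (1 + exceed) / (1 + n_perm)
            out.append(
                NbsComponent(edges=c["edges"], extent=c["extent"], fwe_p=fwe_p)
            )
        results.append(
            NbsComponentResult(
                threshold=float(thr),
                components=out,
                n_permutations=n_perm,
                stat_matrix=f_mat,
                edge_t=t_mat,
                node_ids=list(ids),
            )
        )
    return results


def permutation_fwe(
    networks,
    pheno: pd.DataFrame,
    design: DesignSpec,
    threshold: float,
    n_perm: int = 5000,
    seed: int = 0,
    node_ids: list[str] | None = None,
) -> NbsComponentResult:
    """NBS at a single statistic threshold.

    FWE p of a component = ``(1 + #{perm max extent >= observed extent})
    / (1 + n_perm)`` — the +1 correction keeps p strictly positive.
    """
    return _run_nbs(
        networks, pheno, design, np.array([threshold], dtype=float),
        n_perm, seed, node_ids,
    )[0]


def threshold_sweep(
    networks,
    pheno: pd.DataFrame,
    design: DesignSpec,
    thresholds=None,
    n_perm: int = 5000,
    seed: int = 0,
    node_ids: list[str] | None = None,
) -> list[NbsComponentResult]:
    """NBS across an ascending range of F thresholds (default 6..28).

    Permutation draws are shared across thresholds, so the sweep costs
    barely more than a single run.
    """
    if thresholds is None:
        thresholds = np.arange(6.0, 29.0)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    return _run_nbs(networks, pheno, design, thresholds, n_perm, seed, node_ids)


def cohens_f2(
    networks,
    pheno: pd.DataFrame,
    design: DesignSpec,
    edge_subset: list[tuple[str, str]] | None = None,
    node_ids: list[str] | None = None,
) -> dict:
    """Local effect size of the contrast, per edge and summarised.

    ``f2 = (R2_full - R2_reduced) / (1 - R2_full)``, reduced model =
    covariates only. Summaries cover all upper-triangle edges and,
    optionally, a named edge subset. A saturated edge (R2_full = 1) is
    reported as infinite.
    """
    Y, n_nodes = _edge_matrix(networks)
    X, Z = build_design(pheno, design)
    rx, rz = _residual_maker(X), _residual_maker(Z)
    rss_full = ((rx @ Y) ** 2).sum(axis=0)
    rss_red = ((rz @ Y) ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_full = np.where(tss > 0, 1 - rss_full / tss, 0.0)
        r2_red = np.where(tss > 0, 1 - rss_red / tss, 0.0)
        f2 = np.where(r2_full < 1, (r2_full - r2_red) / (1 - r2_full), np.inf)
    f2_mat = _to_matrix(f2, n_nodes)
    ids = node_ids or [str(i) for i in range(n_nodes)]
    out = {
        "f2_matrix": f2_mat,
        "mean": float(np.mean(f2[np.isfinite(f2)])),
        "sd": float(np.std(f2[np.isfinite(f2)], ddof=1)) if f2.size > 1 else 0.0,
        "n_infinite": int(np.sum(~np.isfinite(f2))),
    }
    if edge_subset is not None:
        index = {nid: i for i, nid in enumerate(ids)}
        vals = np.array([f2_mat[index[a], index[b]] for a, b in edge_subset])
        finite = vals[np.isfinite(vals)]
        out["subset_mean"] = float(finite.mean()) if finite.size else float("nan")
        out["subset_sd"] = (
            float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        )
    return out


def subnetwork_report(
    result: NbsComponentResult,
    nodes: pd.DataFrame,
    networks=None,
    response: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate components with node metadata and degrees.

    ``nodes`` must index node ids and provide ``x, y, z, system``
    columns. Returns (node table, component table); if ``networks`` and
    ``response`` are given, each component row carries the Pearson
    correlation between its mean FC and the response.
    """
    meta = nodes.set_index(nodes["node_id"].astype(str)) if "node_id" in nodes else nodes
    node_rows, comp_rows = [], []
    for ci, comp in enumerate(result.components):
        degree: dict[str, int] = {}
        for a, b in comp.edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        for nid, deg in sorted(degree.items()):
            if nid not in meta.index:
                raise ValueError(f"unknown node id {nid!r} in component")
            row = meta.loc[nid]
            node_rows.append(
                {
                    "component": ci,
                    "node_id": nid,
                    "x": row.get("x"),
                    "y": row.get("y"),
                    "z": row.get("z"),
                    "system": row.get("system"),
                    "degree": deg,
                }
            )
        entry = {
            "component": ci,
            "extent": comp.extent,
            "fwe_p": comp.fwe_p,
            "threshold": result.threshold,
        }
        if networks is not None and response is not None:
            nets = np.asarray(networks, dtype=float)
            index = {nid: i for i, nid in enumerate(result.node_ids)}
            pairs = [(index[a], index[b]) for a, b in comp.edges]
            mean_fc = np.array(
                [np.mean([net[i, j] for i, j in pairs]) for net in nets]
            )
            entry["mean_fc_response_r"] = float(
                np.corrcoef(mean_fc, np.asarray(response, dtype=float))[0, 1]
            )
        comp_rows.append(entry)
    node_df = pd.DataFrame(
        node_rows, columns=["component", "node_id", "x", "y", "z", "system", "degree"]
    )
    comp_df = pd.DataFrame(comp_rows)
    return node_df, comp_df
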