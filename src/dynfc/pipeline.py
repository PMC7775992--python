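"""End-to-end orchestration: simulate/load -> QC -> coupling -> communities
-> cartography -> NBS, under one flat configuration.

All constants default to the analysis constants used throughout the
package (15-TR windows, gamma = omega = 1, 10 x 10 profiles, k = 2,
100 repetitions, F thresholds 6..28, 5000 permutations, FWE alpha .025,
motion limits FD 0.25 mm / DVARS 4% / 25% of volumes / mean FD 0.2,
dropout z -1.64). Unknown configuration keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from dynfc import io as dio
from dynfc._seeds import derive_seed
from dynfc.cartography import (
    INTEGRATED,
    cartographic_profile,
    integrated_network,
    kmeans_metastates,
    metastate_stats,
    module_degree_zscore,
    participation_coefficient,
)
from dynfc.communities import community_count, flexibility, multilayer_modularity
from dynfc.coupling import mtd_windows
from dynfc.nbs import DesignSpec, cohens_f2, subnetwork_report, threshold_sweep
from dynfc.qc import (
    MotionSummary,
    MotionThresholds,
    flag_dropout_nodes,
    motion_exclude,
    regress_task_events,
)
from dynfc.synthetic import (
    CohortSpec,
    SyntheticParticipant,
    cohort_phenotypes,
    make_hrf_regressor,
    node_metadata,
    simulate_cohort,
)

__all__ = [
    "PipelineConfig",
    "qc_cohort",
    "process_participant",
    "run_pipeline",
    "parameter_sweep",
    "cohort_stats",
]


@dataclass(frozen=True)
class PipelineConfig:
    window_length_tr: int = 15
    window_offset: int = 0
    cp_bins: int = 10
    gamma: float = 1.0
    omega: float = 1.0
    n_repetitions: int = 100
    k_states: int = 2
    nbs_threshold_min: float = 6.0
    nbs_threshold_max: float = 28.0
    n_permutations: int = 5000
    alpha: float = 0.025
    fd_volume: float = 0.25
    fd_frac: float = 0.25
    dvars: float = 4.0
    mean_fd: float = 0.2
    dropout_z: float = -1.64
    nbs_analyses: tuple = ("group", "panss_positive_change")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        for name in ("window_length_tr", "cp_bins", "n_repetitions", "k_states",
                     "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        mapping = dict(mapping)
        if "nbs_analyses" in mapping:
            mapping["nbs_analyses"] = tuple(mapping["nbs_analyses"])
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nbs_analyses"] = list(d["nbs_analyses"])
        return d

    @property
    def motion_thresholds(self) -> MotionThresholds:
        return MotionThresholds(
            fd_volume=self.fd_volume,
            dvars=self.dvars,
            frac_limit=self.fd_frac,
            mean_fd=self.mean_fd,
        )

    @property
    def nbs_thresholds(self) -> np.ndarray:
        return np.arange(self.nbs_threshold_min, self.nbs_threshold_max + 1)


def _seed_int(root: int, *keys) -> int:
    return int(derive_seed(root, *keys).generate_state(1)[0])


# ---------------------------------------------------------------------------
# QC stage


def qc_cohort(
    participants: list[SyntheticParticipant], config: PipelineConfig
) -> tuple[list[SyntheticParticipant], dict]:
    """Motion exclusion, cohort node masking, task-event residualisation.

    Returns the kept participants (with cleaned, node-masked runs) and a
    QC report: per-participant decision with reasons, summary stats, and
    the node mask.
    """
    report: dict = {"participants": {}, "node_mask": None}
    kept_participants = []
    decisions = {}
    for p in participants:
        ms = MotionSummary.from_confounds(p.confounds)
        decision = motion_exclude(ms, config.motion_thresholds)
        decisions[p.participant_id] = (p, decision)
        report["participants"][p.participant_id] = {
            "keep": decision.keep,
            "reasons": list(decision.reasons),
            "mean_fd": ms.mean_fd,
            "frac_fd_gt_limit": float((ms.fd > config.fd_volume).mean()),
            "frac_dvars_gt_limit": float((ms.dvars > config.dvars).mean()),
        }
    motion_kept = [p for p, d in decisions.values() if d.keep]
    if not motion_kept:
        raise ValueError("motion exclusion removed every participant")

    mean_signals = pd.DataFrame(
        {
            p.participant_id: np.mean([r.data.mean(axis=0) for r in p.runs], axis=0)
            for p in motion_kept
        },
        index=motion_kept[0].runs[0].node_ids,
    ).T
    mask = flag_dropout_nodes(mean_signals, z_threshold=config.dropout_z)
    report["node_mask"] = {
        "kept": list(mask.kept),
        "dropped": [{"node_id": n, "reason": r} for n, r in mask.dropped],
    }

    for p in motion_kept:
        cleaned_runs = []
        for run, events in zip(p.runs, p.events):
            regressors, _ = make_hrf_regressor(events, run.n_volumes, run.tr_seconds)
            resid = regress_task_events(run, regressors)
            cleaned_runs.append(resid.select_nodes(list(mask.kept)))
        kept_participants.append(
            SyntheticParticipant(
                participant_id=p.participant_id,
                runs=cleaned_runs,
                events=p.events,
                confounds=p.confounds,
                phenotype=p.phenotype,
                truth=p.truth,
            )
        )
    return kept_participants, report


# ---------------------------------------------------------------------------
# Per-participant metastate processing


@dataclass
class ParticipantResult:
    participant_id: str
    stacks: list
    labelings: list
    integrated: object
    summary: dict


def process_participant(
    participant: SyntheticParticipant,
    config: PipelineConfig,
) -> ParticipantResult:
    """Coupling, repeated community detection, metastate labelling, and
    the averaged integrated network for one participant."""
    stacks = [
        mtd_windows(
            run, window_length=config.window_length_tr, offset=config.window_offset
        )
        for run in participant.runs
    ]
    pid = participant.participant_id
    labelings = []
    flex_per_rep, comm_per_rep = [], []
    for rep in range(config.n_repetitions):
        profiles_by_run = {}
        rep_flex, rep_comm = [], []
        for stack in stacks:
            seed = _seed_int(config.seed, pid, stack.run_id, "louvain", rep)
            part = multilayer_modularity(
                stack, gamma=config.gamma, omega=config.omega, seed=seed
            )
            if part.n_layers >= 2:
                _, mean_flex = flexibility(part)
                rep_flex.append(mean_flex)
            _, mean_comm = community_count(part)
            rep_comm.append(mean_comm)
            profiles = []
            for w_idx in range(stack.n_windows):
                w_pos = np.clip(stack.windows[w_idx], 0.0, None)
                pc = participation_coefficient(w_pos, part.labels[w_idx])
                mdz = module_degree_zscore(w_pos, part.labels[w_idx])
                profiles.append(
                    cartographic_profile(
                        pc,
                        mdz,
                        bins=config.cp_bins,
                        window_ref=(stack.run_id, w_idx),
                    )
                )
            profiles_by_run[stack.run_id] = profiles
        km_seed = _seed_int(config.seed, pid, "kmeans", rep) % (2**32)
        labelings.append(
            kmeans_metastates(
                profiles_by_run, k=config.k_states, seed=km_seed, repetition=rep
            )
        )
        flex_per_rep.append(float(np.mean(rep_flex)) if rep_flex else np.nan)
        comm_per_rep.append(float(np.mean(rep_comm)))
    integrated = integrated_network(stacks, labelings, state=INTEGRATED)
    summary = metastate_stats(labelings)
    summary["flexibility"] = float(np.nanmean(flex_per_rep))
    summary["mean_communities"] = float(np.mean(comm_per_rep))
    summary["participant_id"] = pid
    return ParticipantResult(
        participant_id=pid,
        stacks=stacks,
        labelings=labelings,
        integrated=integrated,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Cohort reporting


def cohort_stats(
    summaries: pd.DataFrame,
    pheno: pd.DataFrame,
    spearman_pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Descriptive group comparisons and rank correlations.

    Welch t-tests and Mann-Whitney U on each metastate metric between
    the two phenotype groups, plus Spearman correlations for requested
    column pairs (columns may come from either table). All results are
    labelled descriptive; nothing here is FWE-controlled.
    """
    merged = summaries.merge(
        pheno.reset_index(), on="participant_id", how="inner"
    )
    groups = sorted(merged["group"].unique())
    report: dict = {"groups": groups, "comparisons": {}, "spearman": {}}
    metrics = ["pct_integrated", "mean_switches", "flexibility", "mean_communities"]
    for metric in metrics:
        if metric not in merged:
            continue
        entry: dict = {"n": int(merged[metric].notna().sum())}
        for g in groups:
            vals = merged.loc[merged["group"] == g, metric].dropna()
            entry[g] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                        "n": int(len(vals))}
        if len(groups) == 2:
            a = merged.loc[merged["group"] == groups[0], metric].dropna()
            b = merged.loc[merged["group"] == groups[1], metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                t = sps.ttest_ind(a, b, equal_var=False)
                u = sps.mannwhitneyu(a, b, alternative="two-sided")
                entry["welch_t"] = {"t": float(t.statistic), "p": float(t.pvalue)}
                entry["mannwhitney"] = {"u": float(u.statistic), "p": float(u.pvalue)}
            else:
                entry["note"] = "comparison skipped: a group has < 2 participants"
        report["comparisons"][metric] = entry
    for x, y in spearman_pairs or []:
        if x in merged and y in merged:
            xv = merged[x].to_numpy(dtype=float)
            yv = merged[y].to_numpy(dtype=float)
            ok = ~(np.isnan(xv) | np.isnan(yv))
            rho, p = sps.spearmanr(xv[ok], yv[ok])
            report["spearman"][f"{x}~{y}"] = {
                "rho": float(rho), "p": float(p), "n": int(ok.sum())
            }
    return report


GROUP_DESIGN = DesignSpec(
    contrast="group",
    covariates=("age", "mean_fd", "antipsychotic", "antidepressant"),
    kind="ancova",
)


def change_design(change_var: str) -> DesignSpec:
    return DesignSpec(
        contrast=change_var,
        covariates=(
            "sex",
            "age",
            "mean_fd",
            "antipsychotic",
            "antidepressant",
            "days_to_followup",
        ),
        kind="regression",
    )


def _nbs_analysis(
    name: str,
    results: dict,
    networks: np.ndarray,
    pheno: pd.DataFrame,
    node_ids: list[str],
    nodes_meta: pd.DataFrame | None,
    config: PipelineConfig,
) -> None:
    if name == "group":
        design = GROUP_DESIGN
        sub = pheno
        nets = networks
    else:
        design = change_design(name)
        chr_mask = (pheno["group"] == "CHR").to_numpy()
        sub = pheno[chr_mask]
        nets = networks[chr_mask]
    if len(sub) <= len(design.covariates) + 3:
        results[name] = {"skipped": f"only {len(sub)} participants for {name}"}
        return
    sweep = threshold_sweep(
        nets,
        sub,
        design,
        thresholds=config.nbs_thresholds,
        n_perm=config.n_permutations,
        seed=_seed_int(config.seed, "nbs", name),
        node_ids=node_ids,
    )
    entry: dict = {"design": {"contrast": design.contrast,
                              "covariates": list(design.covariates),
                              "kind": design.kind},
                   "n": int(len(sub)),
                   "thresholds": {}}
    significant_edges: list | None = None
    for res in sweep:
        sig = res.significant(config.alpha)
        entry["thresholds"][f"{res.threshold:g}"] = {
            "components": [
                {"extent": c.extent, "fwe_p": c.fwe_p, "edges": c.edges}
                for c in res.components
            ],
            "any_significant": bool(sig),
        }
        if sig and significant_edges is None:
            significant_edges = sig[0].edges
            if nodes_meta is not None:
                node_df, comp_df = subnetwork_report(
                    res,
                    nodes_meta,
                    networks=nets,
                    response=pd.to_numeric(sub[design.contrast], errors="coerce")
                    if design.kind == "regression"
                    else (sub[design.contrast] == sorted(sub[design.contrast].unique())[1]).astype(float),
                )
                entry["report_nodes"] = node_df.to_dict(orient="records")
                entry["report_components"] = comp_df.to_dict(orient="records")
    f2 = cohens_f2(nets, sub, design, edge_subset=significant_edges,
                   node_ids=node_ids)
    entry["cohens_f2"] = {
        "mean": f2["mean"], "sd": f2["sd"],
        "subset_mean": f2.get("subset_mean"), "subset_sd": f2.get("subset_sd"),
    }
    results[name] = entry


def run_pipeline(
    config: PipelineConfig,
    out_dir: Path,
    spec: CohortSpec | None = None,
    input_dir: Path | None = None,
) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Exactly one of ``spec`` (simulate) or ``input_dir`` (load) must be
    given. Deterministic for a fixed config (the config carries the root
    seed).
    """
    if (spec is None) == (input_dir is None):
        raise ValueError("provide exactly one of spec or input_dir")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if spec is not None:
        participants = simulate_cohort(spec)
        nodes_meta = node_metadata(spec)
        dio.write_cohort(participants, out_dir / "cohort", nodes=nodes_meta)
    else:
        participants = dio.load_cohort(input_dir)
        nodes_path = Path(input_dir) / "nodes.tsv"
        nodes_meta = (
            pd.read_csv(nodes_path, sep="\t") if nodes_path.exists() else None
        )

    kept, qc_report = qc_cohort(participants, config)
    dio.write_json(qc_report, out_dir / "qc_report.json")

    results = [process_participant(p, config) for p in kept]
    summaries = pd.DataFrame([r.summary for r in results])
    summaries.to_csv(out_dir / "metastate_summaries.csv", index=False,
                     float_format="%.10g")
    net_dir = out_dir / "integrated_networks"
    net_dir.mkdir(exist_ok=True)
    node_ids = results[0].integrated.node_ids
    for r in results:
        dio.write_adjacency(
            r.integrated.mean_fc, node_ids, net_dir / f"{r.participant_id}.tsv"
        )

    pheno = pd.DataFrame([p.phenotype for p in kept])
    for score in ("panss_positive", "panss_negative", "gaf"):
        b, f = f"{score}_baseline", f"{score}_followup"
        if b in pheno and f in pheno:
            pheno[f"{score}_change"] = pheno[f] - pheno[b]
    report = cohort_stats(
        summaries, pheno.set_index("participant_id"),
        spearman_pairs=[("mean_switches", "pct_integrated")],
    )
    dio.write_json(report, out_dir / "cohort_report.json")

    networks = np.stack([r.integrated.mean_fc for r in results])
    nbs_results: dict = {}
    for name in config.nbs_analyses:
        _nbs_analysis(name, nbs_results, networks, pheno, node_ids, nodes_meta, config)
    dio.write_json(nbs_results, out_dir / "nbs_results.json")

    manifest = {
        "config": config.to_dict(),
        "n_participants_in": len(participants),
        "n_participants_kept": len(kept),
        "n_nodes_kept": len(node_ids),
        "n_windows_per_run": [int(s.n_windows) for s in results[0].stacks],
        "n_windows_total": int(sum(s.n_windows for s in results[0].stacks)),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    dio.write_json(manifest, out_dir / "manifest.json")
    return {
        "manifest": manifest,
        "qc": qc_report,
        "summaries": summaries,
        "results": results,
        "cohort_report": report,
        "nbs": nbs_results,
        "phenotype": pheno,
    }


# ---------------------------------------------------------------------------
# Supplementary-style parameter sweep


def parameter_sweep(
    config: PipelineConfig,
    axes: dict[str, list],
    spec: CohortSpec,
) -> pd.DataFrame:
    """Grid execution over window length / offset / CP resolution.

    Each cell re-processes the same simulated cohort (shared seed) and
    reports the mean % time integrated and label stability (mean
    pairwise adjusted Rand index between repetitions' labelings).
    Infeasible cells (window longer than a run) are marked skipped.
    """
    if not axes:
        raise ValueError("axes must be non-empty")
    allowed = {"window_length_tr", "window_offset", "cp_bins"}
    if set(axes) - allowed:
        raise ValueError(f"sweep axes limited to {sorted(allowed)}")
    participants = simulate_cohort(spec)
    rows = []
    names = list(axes)
    for values in itertools.product(*(axes[n] for n in names)):
        cell = dict(zip(names, values))
        cfg = replace(config, **cell)
        try:
            cell_results = [process_participant(p, cfg) for p in participants]
        except ValueError as err:
            rows.append({**cell, "skipped": True, "reason": str(err)})
            continue
        pct = float(np.mean([r.summary["pct_integrated"] for r in cell_results]))
        aris = []
        for r in cell_results:
            flat = [
                np.concatenate([lab.labels[k] for k in sorted(lab.labels)])
                for lab in r.labelings
            ]
            for a, b in itertools.combinations(flat, 2):
                aris.append(adjusted_rand_score(a, b))
        rows.append(
            {
                **cell,
                "skipped": False,
                "pct_integrated": pct,
                "label_stability_ari": float(np.mean(aris)) if aris else np.nan,
            }
        )
    return pd.DataFrame(rows)
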