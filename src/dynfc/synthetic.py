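"""Synthetic multi-run BOLD cohorts with known dynamic community structure.

Cohorts alternate between two latent whole-brain regimes at window
granularity (blocks of ``window_length_tr`` volumes, aligned with the
coupling pipeline's windows so truth-vs-label accuracy is well defined):

- *segregated*: nodes share variance only with their own a-priori system
  (a per-system latent factor);
- *integrated*: an additional global factor couples all systems.

Each participant carries a planted edge set whose connectivity strength
is an individual trait (a variance-preserving noise mixing with a
per-participant mixing fraction), and the symptom-change phenotype is
tied to the realised mean planted-edge FC over integrated windows
(``change = planted_beta * mean_planted_fc + covariate terms + noise``),
so sub-network discovery methods can be validated against ground truth.

Covariates (age, sex, medication flags, motion, follow-up interval) are
drawn independently and enter the phenotype model with small fixed
coefficients, making covariate adjustment testable. FD/DVARS traces are
log-normal with configurable means so QC exclusion paths are
exercisable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from dynfc._seeds import derive_rng
from dynfc.qc import RoiTimeSeriesRun

__all__ = [
    "RegimeSchedule",
    "CohortSpec",
    "SyntheticParticipant",
    "simulate_cohort",
    "make_hrf_regressor",
    "default_planted_edges",
    "cohort_phenotypes",
    "node_metadata",
]

INTEGRATED, SEGREGATED = 1, 0

# fixed, deliberately small phenotype covariate coefficients
_COVARIATE_COEFS = {
    "age": 0.05,
    "sex": 0.2,
    "mean_fd": 2.0,
    "antipsychotic": 0.5,
    "antidepressant": 0.3,
    "days_to_followup": 0.001,
}


@dataclass(frozen=True)
class RegimeSchedule:
    """Two-state Markov dwell parameters over window-level regimes."""

    stay_integrated: float = 0.75
    stay_segregated: float = 0.75
    start_integrated: float = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one reproducible cohort."""

    n_participants: int
    n_nodes: int
    n_systems: int = 4
    n_runs: int = 3
    volumes_per_run: int = 179
    tr_seconds: float = 2.0
    window_length_tr: int = 15
    regime_schedule: RegimeSchedule = field(default_factory=RegimeSchedule)
    group_schedules: dict | None = None  # group label -> RegimeSchedule
    coupling_within: float = 1.0
    coupling_between: float = 1.0
    planted_edges: tuple = ()
    planted_beta: float = 0.0
    planted_strength: tuple[float, float] = (0.1, 0.45)
    noise_sd: float = 1.0
    pheno_noise_sd: float = 2.0
    frac_chr: float = 0.7
    n_task_nodes: int = 2
    task_amplitude: float = 0.5
    mean_fd_mu: float = 0.10
    mean_fd_sd: float = 0.03
    dvars_mu: float = 1.2
    baseline_intensity: float = 1000.0
    intensity_jitter: float = 5.0
    dropout_nodes: tuple = ()
    dropout_offset: float = -50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_nodes < 2 * self.n_systems:
            raise ValueError(
                f"n_nodes={self.n_nodes} must be >= 2 * n_systems={self.n_systems}"
            )
        if self.volumes_per_run - 1 < self.window_length_tr:
            raise ValueError(
                f"volumes_per_run={self.volumes_per_run} yields no complete "
                f"{self.window_length_tr}-TR window"
            )
        for name in ("stay_integrated", "stay_segregated", "start_integrated"):
            v = getattr(self.regime_schedule, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"regime_schedule.{name}={v} must be in (0, 1)")
        for i, j in self.planted_edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes and i != j):
                raise ValueError(f"planted edge ({i}, {j}) outside the node-pair set")
        if self.coupling_within < 0 or self.coupling_between < 0:
            raise ValueError("coupling levels must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for d in self.dropout_nodes:
            if not 0 <= d < self.n_nodes:
                raise ValueError(f"dropout node {d} outside the node set")
        if self.planted_edges:
            deg = np.zeros(self.n_nodes)
            for i, j in self.planted_edges:
                deg[i] += 1
                deg[j] += 1
            lo, hi = self.planted_strength
            if not 0 <= lo <= hi:
                raise ValueError("planted_strength bounds must satisfy 0 <= lo <= hi")
            if hi * deg.max() > 1.0:
                raise ValueError(
                    "planted_strength upper bound times max planted degree "
                    "exceeds 1; the noise-mixing construction would need "
                    "negative variance"
                )

    @property
    def n_windows_per_run(self) -> int:
        return (self.volumes_per_run - 1) // self.window_length_tr

    @property
    def systems(self) -> np.ndarray:
        """Contiguous, balanced node -> system assignment."""
        return (np.arange(self.n_nodes) * self.n_systems) // self.n_nodes


@dataclass
class SyntheticParticipant:
    """One simulated participant: data, metadata, and generation truth."""

    participant_id: str
    runs: list[RoiTimeSeriesRun]
    events: list[pd.DataFrame]
    confounds: list[pd.DataFrame]
    phenotype: dict
    truth: dict


def default_planted_edges(n_nodes: int, n_edges: int = 10) -> tuple:
    """A connected path of ``n_edges`` edges over evenly spaced nodes.

    Connectedness matters: component-extent inference can only recover a
    planted sub-network that is itself one component.
    """
    if n_edges + 1 > n_nodes:
        raise ValueError("not enough nodes for the requested path")
    nodes = np.linspace(0, n_nodes - 1, n_edges + 1).round().astype(int)
    if len(set(nodes)) != len(nodes):
        raise ValueError("node spacing collapsed; reduce n_edges")
    return tuple(
        (int(min(a, b)), int(max(a, b))) for a, b in zip(nodes[:-1], nodes[1:])
    )


def _double_gamma_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR.

    Peak ~6 s (shape 6, scale 1), undershoot ~16 s (shape 16, scale 1),
    peak:undershoot ratio 6:1.
    """
    t = np.arange(0.0, duration_s + tr / 2, tr)
    hrf = gamma_dist.pdf(t, a=6, scale=1) - gamma_dist.pdf(t, a=16, scale=1) / 6.0
    return hrf / hrf.max()


def make_hrf_regressor(
    events: pd.DataFrame, n_volumes: int, tr: float
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved task regressors, one column per trial_type.

    A stick/box function (one unit per volume covered by the event) is
    convolved with the canonical double-gamma HRF and truncated to the
    run. Events whose onset falls beyond the run end are dropped with a
    warning. An empty event table yields a single all-zero column.
    """
    import warnings

    if events is None or len(events) == 0:
        return np.zeros((n_volumes, 1)), []
    kernel = _double_gamma_hrf(tr)
    types = sorted(events["trial_type"].astype(str).unique())
    columns = []
    for tt in types:
        sticks = np.zeros(n_volumes)
        sub = events[events["trial_type"].astype(str) == tt]
        for onset, dur in zip(sub["onset"], sub["duration"]):
            start = int(round(float(onset) / tr))
            if start >= n_volumes or onset < 0:
                warnings.warn(
                    f"event at onset {onset}s outside the run; dropped",
                    stacklevel=2,
                )
                continue
            span = max(1, int(round(float(dur) / tr)))
            sticks[start : min(start + span, n_volumes)] += 1.0
        columns.append(np.convolve(sticks, kernel)[:n_volumes])
    return np.column_stack(columns), types


def _sample_regimes(
    schedule: RegimeSchedule, n_windows: int, rng: np.random.Generator
) -> np.ndarray:
    states = np.empty(n_windows, dtype=int)
    states[0] = INTEGRATED if rng.random() < schedule.start_integrated else SEGREGATED
    for w in range(1, n_windows):
        stay = (
            schedule.stay_integrated
            if states[w - 1] == INTEGRATED
            else schedule.stay_segregated
        )
        states[w] = states[w - 1] if rng.random() < stay else 1 - states[w - 1]
    return states


def _std_block(v: np.ndarray) -> np.ndarray:
    """Standardise a latent factor within its block (unit realised SD).

    Keeps the realised coupling of every window at its nominal level:
    without this, the sampled variance of a 15-point factor fluctuates by
    ~37% (chi-square), making some integrated windows genuinely look
    segregated and vice versa.
    """
    if v.shape[0] < 2:
        return v
    sd = v.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (v - v.mean(axis=0)) / sd


def _sample_block(
    spec: CohortSpec,
    regime: int,
    n_vol: int,
    rho_planted: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n_vol`` volumes from the regime's latent-factor model.

    The planted association is a variance-preserving noise mixing: each
    planted edge (i, j) shares a fraction ``rho_planted`` of the two
    nodes' observation-noise variance, raising that edge's correlation by
    ``rho_planted * noise_sd**2 / var`` without touching node variances
    or any other edge. Present in every regime — the planted sub-network
    is a stable trait of the participant.
    """
    e = rng.standard_normal((n_vol, spec.n_nodes))
    if rho_planted > 0 and spec.planted_edges:
        deg = np.zeros(spec.n_nodes)
        for i, j in spec.planted_edges:
            deg[i] += 1
            deg[j] += 1
        e *= np.sqrt(np.clip(1.0 - deg * rho_planted, 0.0, None))
        for i, j in spec.planted_edges:
            eta = _std_block(rng.standard_normal(n_vol))
            e[:, i] += math.sqrt(rho_planted) * eta
            e[:, j] += math.sqrt(rho_planted) * eta
    systems = spec.systems
    x = spec.noise_sd * e
    f = _std_block(rng.standard_normal((n_vol, spec.n_systems)))
    x += math.sqrt(spec.coupling_within) * f[:, systems]
    if regime == INTEGRATED:
        g = _std_block(rng.standard_normal(n_vol))
        x += math.sqrt(spec.coupling_between) * g[:, None]
    return x


def _default_events(
    spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    run_dur = spec.volumes_per_run * spec.tr_seconds
    rows = []
    for tt, n_ev in (("target", 8), ("novel", 8)):
        onsets = np.sort(rng.uniform(10.0, run_dur - 24.0, size=n_ev))
        rows.extend((float(o), 0.1, tt) for o in onsets)
    return (
        pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
        .sort_values("onset")
        .reset_index(drop=True)
    )


def _confounds(
    spec: CohortSpec, mean_fd: float, rng: np.random.Generator
) -> pd.DataFrame:
    sigma = 0.5
    fd = rng.lognormal(
        mean=math.log(mean_fd) - 0.5 * sigma**2, sigma=sigma, size=spec.volumes_per_run
    )
    dv = rng.lognormal(
        mean=math.log(spec.dvars_mu) - 0.5 * 0.2**2, sigma=0.2, size=spec.volumes_per_run
    )
    fd[0] = np.nan  # fMRIPrep convention: no predecessor volume
    dv[0] = np.nan
    return pd.DataFrame({"framewise_displacement": fd, "std_dvars": dv})


def _simulate_participant(spec: CohortSpec, idx: int) -> SyntheticParticipant:
    rng = derive_rng(spec.seed, "participant", idx)
    n_hc = spec.n_participants - int(round(spec.frac_chr * spec.n_participants))
    group = "HC" if idx < n_hc else "CHR"
    schedule = spec.regime_schedule
    if spec.group_schedules and group in spec.group_schedules:
        schedule = spec.group_schedules[group]

    lo, hi = spec.planted_strength
    rho_planted = float(rng.uniform(lo, hi)) if spec.planted_beta != 0 else 0.0

    pid = f"sub-{idx + 1:03d}"
    node_ids = [f"n{i:03d}" for i in range(spec.n_nodes)]

    # per-node baseline signal intensity: exponential jitter (mean == SD)
    # keeps the minimum z-score across nodes near -1, so only planted
    # dropout nodes can reach the z <= -1.64 exclusion zone
    intensity = spec.baseline_intensity + rng.exponential(
        spec.intensity_jitter, size=spec.n_nodes
    )
    for d in spec.dropout_nodes:
        intensity[d] = spec.baseline_intensity + spec.dropout_offset
    w = spec.window_length_tr
    n_win = spec.n_windows_per_run

    runs, events_list, confounds_list, regimes_by_run = [], [], [], {}
    integrated_segments: list[np.ndarray] = []  # per-run volume blocks, integrated only
    for r in range(spec.n_runs):
        run_id = f"run-{r + 1}"
        regimes = _sample_regimes(schedule, n_win, rng)
        regimes_by_run[run_id] = regimes
        blocks = [_sample_block(spec, int(regimes[0]), 1, rho_planted, rng)]  # lead-in
        for state in regimes:
            block = _sample_block(spec, int(state), w, rho_planted, rng)
            blocks.append(block)
            if state == INTEGRATED:
                integrated_segments.append(block)
        remainder = spec.volumes_per_run - 1 - n_win * w
        if remainder > 0:
            blocks.append(
                _sample_block(spec, int(regimes[-1]), remainder, rho_planted, rng)
            )
        data = np.vstack(blocks)

        events = _default_events(spec, rng)
        regressors, _ = make_hrf_regressor(events, spec.volumes_per_run, spec.tr_seconds)
        task = spec.task_amplitude * regressors.sum(axis=1)
        data = data.copy()
        data[:, : spec.n_task_nodes] += task[:, None]
        data += intensity[None, :]

        runs.append(
            RoiTimeSeriesRun(
                data=data,
                tr_seconds=spec.tr_seconds,
                run_id=run_id,
                node_ids=node_ids,
            )
        )
        events_list.append(events)

        mean_fd = max(0.02, rng.normal(spec.mean_fd_mu, spec.mean_fd_sd))
        confounds_list.append(_confounds(spec, mean_fd, rng))

    mean_planted_fc = _truth_planted_fc(spec, integrated_segments)
    phenotype = _phenotype(spec, pid, group, confounds_list, mean_planted_fc, rng)
    truth = {
        "regimes": {k: v.tolist() for k, v in regimes_by_run.items()},
        "systems": spec.systems.tolist(),
        "planted_edges": [list(e) for e in spec.planted_edges],
        "planted_strength": rho_planted,
        "mean_planted_fc": mean_planted_fc,
        "task_nodes": node_ids[: spec.n_task_nodes],
        "group": group,
    }
    return SyntheticParticipant(
        participant_id=pid,
        runs=runs,
        events=events_list,
        confounds=confounds_list,
        phenotype=phenotype,
        truth=truth,
    )


def _truth_planted_fc(
    spec: CohortSpec, integrated_segments: list[np.ndarray]
) -> float:
    """Mean planted-edge correlation over truth-integrated volumes.

    Computed on the task-free series (task signal is regressed out
    downstream and would only add shared variance to the task nodes).
    """
    if not spec.planted_edges or not integrated_segments:
        return 0.0
    data = np.vstack(integrated_segments)
    rs = []
    for i, j in spec.planted_edges:
        rs.append(np.corrcoef(data[:, i], data[:, j])[0, 1])
    return float(np.mean(rs))


def _phenotype(
    spec: CohortSpec,
    pid: str,
    group: str,
    confounds: list[pd.DataFrame],
    mean_planted_fc: float,
    rng: np.random.Generator,
) -> dict:
    age = float(rng.uniform(18, 35))
    sex = "M" if rng.random() < 0.5 else "F"
    p_med = 0.2 if group == "CHR" else 0.04
    antipsychotic = int(rng.random() < p_med)
    antidepressant = int(rng.random() < p_med)
    days = float(rng.lognormal(math.log(450.0), 0.4))
    fd_all = np.concatenate(
        [np.nan_to_num(c["framewise_displacement"].to_numpy()) for c in confounds]
    )
    mean_fd = float(fd_all.mean())

    covar = (
        _COVARIATE_COEFS["age"] * (age - 26.0)
        + _COVARIATE_COEFS["sex"] * (sex == "M")
        + _COVARIATE_COEFS["mean_fd"] * (mean_fd - spec.mean_fd_mu)
        + _COVARIATE_COEFS["antipsychotic"] * antipsychotic
        + _COVARIATE_COEFS["antidepressant"] * antidepressant
        + _COVARIATE_COEFS["days_to_followup"] * (days - 450.0)
    )
    noise = spec.pheno_noise_sd
    baseline = {
        "panss_positive": float(np.clip(rng.normal(14, 4), 7, 35)),
        "panss_negative": float(np.clip(rng.normal(11, 4), 7, 35)),
        "gaf": float(np.clip(rng.normal(60, 10), 20, 95)),
    }
    change_pos = spec.planted_beta * mean_planted_fc + covar + noise * rng.standard_normal()
    change_neg = covar + noise * rng.standard_normal()
    change_gaf = covar + noise * rng.standard_normal()
    return {
        "participant_id": pid,
        "group": group,
        "age": age,
        "sex": sex,
        "antipsychotic": antipsychotic,
        "antidepressant": antidepressant,
        "mean_fd": mean_fd,
        "days_to_followup": days,
        "panss_positive_baseline": baseline["panss_positive"],
        "panss_positive_followup": baseline["panss_positive"] + change_pos,
        "panss_negative_baseline": baseline["panss_negative"],
        "panss_negative_followup": baseline["panss_negative"] + change_neg,
        "gaf_baseline": baseline["gaf"],
        "gaf_followup": baseline["gaf"] + change_gaf,
    }


def simulate_cohort(spec: CohortSpec) -> list[SyntheticParticipant]:
    """Generate the full cohort. Bitwise reproducible for a fixed seed."""
    return [_simulate_participant(spec, i) for i in range(spec.n_participants)]


def truth_metastate_labeling(participant: SyntheticParticipant):
    """The generator's latent regime sequence as a metastate labeling.

    Lets downstream stages be exercised against ground-truth integrated/
    segregated windows, bypassing community detection and clustering.
    """
    from dynfc.cartography import MetastateLabeling

    return MetastateLabeling(
        labels={
            run: np.asarray(states, dtype=int)
            for run, states in participant.truth["regimes"].items()
        },
        repetition=0,
    )


def cohort_phenotypes(participants: list[SyntheticParticipant]) -> pd.DataFrame:
    """Stack participant phenotypes, with derived change scores."""
    df = pd.DataFrame([p.phenotype for p in participants]).set_index("participant_id")
    for score in ("panss_positive", "panss_negative", "gaf"):
        df[f"{score}_change"] = df[f"{score}_followup"] - df[f"{score}_baseline"]
    return df


def node_metadata(spec: CohortSpec, rng_seed: int = 0) -> pd.DataFrame:
    """Node table: id, pseudo-MNI coordinates, a-priori system label."""
    rng = derive_rng(rng_seed, "node-metadata")
    coords = rng.uniform(-70, 70, size=(spec.n_nodes, 3)).round(1)
    return pd.DataFrame(
        {
            "node_id": [f"n{i:03d}" for i in range(spec.n_nodes)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "system": [f"system-{s}" for s in spec.systems],
        }
    )
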