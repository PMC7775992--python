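"""Plain-text cohort serialisation.

Layout of a cohort directory::

    nodes.tsv                      node_id, x, y, z, system
    phenotype.csv                  one row per participant
    truth.json                     generator truth (simulated cohorts only)
    <participant>/
        <participant>_<run>_timeseries.tsv    volumes x nodes, header = node ids
        <participant>_<run>_events.tsv        BIDS-style onset/duration/trial_type
        <participant>_<run>_confounds.tsv     framewise_displacement, std_dvars

All tables are uncompressed TSV/CSV; truth and reports are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from dynfc.qc import RoiTimeSeriesRun
from dynfc.synthetic import SyntheticParticipant

__all__ = [
    "write_cohort",
    "load_cohort",
    "write_adjacency",
    "read_adjacency",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_adjacency(matrix: np.ndarray, node_ids: list[str], path: Path) -> None:
    """Symmetric matrix as TSV with node ids as header and row names."""
    df = pd.DataFrame(matrix, index=node_ids, columns=node_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="node_id")


def read_adjacency(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_cohort(
    participants: list[SyntheticParticipant],
    directory: Path,
    nodes: pd.DataFrame | None = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pheno_rows, truth = [], {}
    for p in participants:
        pdir = directory / p.participant_id
        pdir.mkdir(exist_ok=True)
        for run, events, conf in zip(p.runs, p.events, p.confounds):
            stem = f"{p.participant_id}_{run.run_id}"
            run.to_frame().to_csv(
                pdir / f"{stem}_timeseries.tsv",
                sep="\t",
                index=False,
                float_format=_FLOAT_FMT,
            )
            events.to_csv(
                pdir / f"{stem}_events.tsv",
                sep="\t",
                index=False,
                float_format=_FLOAT_FMT,
            )
            conf.to_csv(
                pdir / f"{stem}_confounds.tsv",
                sep="\t",
                index=False,
                float_format=_FLOAT_FMT,
            )
        pheno_rows.append(p.phenotype)
        if p.truth:
            truth[p.participant_id] = p.truth
    pd.DataFrame(pheno_rows).to_csv(
        directory / "phenotype.csv", index=False, float_format=_FLOAT_FMT
    )
    if truth:
        write_json(truth, directory / "truth.json")
    if nodes is not None:
        nodes.to_csv(
            directory / "nodes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )


def load_cohort(directory: Path) -> list[SyntheticParticipant]:
    """Load a cohort directory; truth is attached when present."""
    directory = Path(directory)
    pheno = pd.read_csv(directory / "phenotype.csv")
    truth_path = directory / "truth.json"
    truth_all = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    participants = []
    for _, row in pheno.iterrows():
        pid = str(row["participant_id"])
        pdir = directory / pid
        if not pdir.is_dir():
            raise FileNotFoundError(f"missing participant directory: {pdir}")
        runs, events, confounds = [], [], []
        ts_files = sorted(pdir.glob(f"{pid}_*_timeseries.tsv"))
        if not ts_files:
            raise FileNotFoundError(f"no time-series tables under {pdir}")
        for ts_path in ts_files:
            run_id = re.match(
                rf"{re.escape(pid)}_(.+)_timeseries\.tsv", ts_path.name
            ).group(1)
            df = pd.read_csv(ts_path, sep="\t")
            runs.append(
                RoiTimeSeriesRun(
                    data=df.to_numpy(dtype=float),
                    tr_seconds=2.0,
                    run_id=run_id,
                    node_ids=[str(c) for c in df.columns],
                )
            )
            events.append(pd.read_csv(pdir / f"{pid}_{run_id}_events.tsv", sep="\t"))
            confounds.append(
                pd.read_csv(pdir / f"{pid}_{run_id}_confounds.tsv", sep="\t")
            )
        participants.append(
            SyntheticParticipant(
                participant_id=pid,
                runs=runs,
                events=events,
                confounds=confounds,
                phenotype=row.to_dict(),
                truth=truth_all.get(pid, {}),
            )
        )
    return participants
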