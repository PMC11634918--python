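"""CSV/JSON round-tripping of the pipeline's data structures.

Formats (all UTF-8, plain text):

* long-format trials — ``subject,group,condition,trial,t,x,y,z`` (positions,
  mm) or ``subject,group,condition,trial,t,wv,wa,wj`` (precomputed scalars);
  ``t`` may be seconds or an integer sample index, rows must be in temporal
  order within a trial;
* tidy trial matrices — ``subject,group,condition,trial,timepoint,variable,value``;
* FPT trials — ``subject,group,condition,timepoint,variable,mean,sd`` plus
  target trial and stack size in a sidecar;
* distance matrices — square CSV with the subject ids as header row and
  first column, plus a sidecar JSON carrying group tags and condition.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import FPTTrial
from .distance import DistanceMatrix
from .kinematics import RawTrial, TrialMatrix, VARIABLE_NAMES

__all__ = [
    "trials_to_dataframe",
    "write_trials_csv",
    "load_trials_csv",
    "trial_matrices_to_dataframe",
    "write_trial_matrices_csv",
    "load_trial_matrices_csv",
    "fpts_to_dataframe",
    "write_fpts_csv",
    "write_distance_matrix",
    "load_distance_matrix",
]

_POSITION_COLS = ["x", "y", "z"]
_SCALAR_COLS = ["wv", "wa", "wj"]
_META_COLS = ["subject", "group", "condition", "trial", "t"]


def trials_to_dataframe(trials: Sequence[RawTrial]) -> pd.DataFrame:
    """Long-format dataframe of raw trials."""
    frames = []
    for tr in trials:
        data = tr.positions if tr.positions is not None else tr.scalars
        cols = _POSITION_COLS if tr.positions is not None else _SCALAR_COLS
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "t", np.arange(len(df)))
        df.insert(0, "trial", tr.trial_id)
        df.insert(0, "condition", tr.condition)
        df.insert(0, "group", tr.group)
        df.insert(0, "subject", tr.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_trials_csv(trials: Sequence[RawTrial], path) -> None:
    trials_to_dataframe(trials).to_csv(path, index=False, float_format="%.6f")


def load_trials_csv(path, sample_rate: float = 100.0) -> list[RawTrial]:
    """Read long-format trials; detects position vs scalar columns."""
    df = pd.read_csv(path)
    if all(c in df.columns for c in _POSITION_COLS):
        value_cols, kind = _POSITION_COLS, "positions"
    elif all(c in df.columns for c in _SCALAR_COLS):
        value_cols, kind = _SCALAR_COLS, "scalars"
    else:
        raise ValueError(
            f"{path}: expected columns {_POSITION_COLS} or {_SCALAR_COLS}, "
            f"got {list(df.columns)}"
        )
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[value_cols + ["t"]].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: missing value at line {row}")
    trials = []
    for (subject, group, condition, trial), sub in df.groupby(
        ["subject", "group", "condition", "trial"], sort=False
    ):
        sub = sub.sort_values("t", kind="stable")
        trials.append(
            RawTrial(
                subject_id=str(subject),
                group=str(group),
                condition=str(condition),
                trial_id=str(trial),
                sample_rate=sample_rate,
                **{kind: sub[value_cols].to_numpy(dtype=float)},
            )
        )
    return trials


def trial_matrices_to_dataframe(matrices: Sequence[TrialMatrix]) -> pd.DataFrame:
    rows = []
    for tm in matrices:
        for tp in range(tm.n_timepoints):
            for v_idx, v in enumerate(tm.variables):
                rows.append(
                    {
                        "subject": tm.subject_id,
                        "group": tm.group,
                        "condition": tm.condition,
                        "trial": tm.trial_id,
                        "timepoint": tp + 1,
                        "variable": v,
                        "value": tm.values[tp, v_idx],
                    }
                )
    return pd.DataFrame(rows)


def write_trial_matrices_csv(matrices: Sequence[TrialMatrix], path) -> None:
    trial_matrices_to_dataframe(matrices).to_csv(path, index=False)


def load_trial_matrices_csv(path) -> list[TrialMatrix]:
    df = pd.read_csv(path)
    matrices = []
    for (subject, group, condition, trial), sub in df.groupby(
        ["subject", "group", "condition", "trial"], sort=False
    ):
        pivot = sub.pivot(index="timepoint", columns="variable", values="value")
        variables = [v for v in VARIABLE_NAMES if v in pivot.columns]
        matrices.append(
            TrialMatrix(
                values=pivot.sort_index()[variables].to_numpy(dtype=float),
                subject_id=str(subject),
                group=str(group),
                condition=str(condition),
                trial_id=str(trial),
                variables=tuple(variables),
            )
        )
    return matrices


def fpts_to_dataframe(fpts: Sequence[FPTTrial]) -> pd.DataFrame:
    rows = []
    for f in fpts:
        for tp in range(f.mean.shape[0]):
            for v_idx, v in enumerate(VARIABLE_NAMES[: f.mean.shape[1]]):
                rows.append(
                    {
                        "subject": f.subject_id,
                        "group": f.group,
                        "condition": f.condition,
                        "timepoint": tp + 1,
                        "variable": v,
                        "mean": f.mean[tp, v_idx],
                        "sd": f.sd[tp, v_idx],
                        "t": f.t,
                        "target_trial": f.target_trial_id,
                    }
                )
    return pd.DataFrame(rows)


def write_fpts_csv(fpts: Sequence[FPTTrial], path) -> None:
    fpts_to_dataframe(fpts).to_csv(path, index=False)


def write_distance_matrix(D: DistanceMatrix, csv_path, json_path=None) -> None:
    """Square CSV with id header/index plus sidecar JSON of tags."""
    csv_path = Path(csv_path)
    pd.DataFrame(D.values, index=list(D.labels), columns=list(D.labels)).to_csv(
        csv_path
    )
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    Path(json_path).write_text(
        json.dumps(
            {
                "labels": list(D.labels),
                "groups": list(D.groups),
                "condition": D.condition,
            },
            indent=2,
        )
    )


def load_distance_matrix(csv_path, json_path=None) -> DistanceMatrix:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(json_path).read_text())
    if list(df.index) != meta["labels"] or list(df.columns) != meta["labels"]:
        raise ValueError(f"{csv_path}: matrix labels disagree with sidecar {json_path}")
    values = df.to_numpy(dtype=float)
    values = 0.5 * (values + values.T)  # CSV round-trip can break exact symmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        values=values,
        labels=tuple(meta["labels"]),
        groups=tuple(meta["groups"]),
        condition=meta["condition"],
    )
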