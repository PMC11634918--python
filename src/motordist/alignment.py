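"""Inter-trial alignment: collapse a subject's trials into one FPT trial.

One trial is chosen as the target; every other trial is Procrustes-fitted
onto it (scaling and reflection on). The target itself enters the stack
untransformed, so the stack holds exactly t matrices for t retained trials.
Averaging across the stack yields the subject's final Procrustes-transformed
(FPT) trial; the element-wise standard deviation captures inter-trial
variability at each time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinematics import TrialMatrix
from .procrustes import DegenerateShapeError, procrustes_fit

__all__ = ["FPTTrial", "align_trials", "align_all_subjects"]


@dataclass(frozen=True)
class FPTTrial:
    """A subject's single representative trial after inter-trial alignment."""

    mean: np.ndarray  # t_points x 3 FPT matrix
    sd: np.ndarray  # element-wise SD across the trial stack; >= 0
    t: int  # number of trials in the stack
    target_trial_id: str
    subject_id: str
    group: str
    condition: str

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("FPT trial needs at least one source trial")
        if (self.sd < 0).any():
            raise ValueError("sd must be non-negative")

    def as_trial_matrix(self) -> TrialMatrix:
        """The FPT mean as a TrialMatrix, validated non-degenerate."""
        tm = TrialMatrix(
            values=self.mean,
            subject_id=self.subject_id,
            group=self.group,
            condition=self.condition,
            trial_id=f"FPT({self.target_trial_id})",
        )
        if tm.is_degenerate():
            raise DegenerateShapeError(
                f"FPT trial of subject {self.subject_id!r} is degenerate"
            )
        return tm


def align_trials(
    trials: Sequence[TrialMatrix],
    target_index: int = 0,
    sd_ddof: int = 0,
) -> FPTTrial:
    """Align one subject's trials to a target trial and average the stack.

    Parameters
    ----------
    trials
        All retained trials of one subject-instance in one condition.
    target_index
        Which trial acts as the target matrix.
    sd_ddof
        Delta degrees of freedom for the stack SD. The default 0 is the
        population convention — the SD describes the variability of this
        fixed stack rather than estimating a wider population.
    """
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    if not 0 <= target_index < len(trials):
        raise IndexError(f"target_index {target_index} out of range for {len(trials)} trials")
    subjects = {(t.subject_id, t.condition) for t in trials}
    if len(subjects) > 1:
        raise ValueError(f"trials span multiple subject/condition pairs: {sorted(subjects)}")
    target = trials[target_index]
    for tm in trials:
        if tm.is_degenerate():
            raise DegenerateShapeError(
                f"trial {tm.trial_id!r} of subject {tm.subject_id!r} is degenerate"
            )
    stack = [target.values]
    for i, tm in enumerate(trials):
        if i == target_index:
            continue
        stack.append(procrustes_fit(target.values, tm.values).Z)
    arr = np.stack(stack, axis=2)  # t_points x 3 x t
    mean = arr.mean(axis=2)
    sd = arr.std(axis=2, ddof=sd_ddof) if arr.shape[2] > 1 else np.zeros_like(mean)
    return FPTTrial(
        mean=mean,
        sd=sd,
        t=len(trials),
        target_trial_id=target.trial_id,
        subject_id=target.subject_id,
        group=target.group,
        condition=target.condition,
    )


def _resolve_target_index(trials: Sequence[TrialMatrix], rule) -> int:
    if rule == "first_available":
        return 0
    if isinstance(rule, int):
        if not 0 <= rule < len(trials):
            raise IndexError(
                f"target rule index {rule} out of range for subject "
                f"{trials[0].subject_id!r} with {len(trials)} trials"
            )
        return rule
    # otherwise: a trial_id label
    for i, tm in enumerate(trials):
        if tm.trial_id == rule:
            return i
    raise ValueError(
        f"target trial {rule!r} not found for subject {trials[0].subject_id!r}"
    )


def align_all_subjects(
    trials: Sequence[TrialMatrix],
    target_rule="first_available",
    sd_ddof: int = 0,
) -> list[FPTTrial]:
    """One FPT trial per subject-instance, all trials from one condition.

    Confederate sessions must already be split into one instance per
    interaction partner (distinct ``subject_id`` values); each instance is
    treated as its own subject. ``target_rule`` is ``"first_available"``
    (default), an integer index into each subject's trial list, or a
    trial_id label.
    """
    if not trials:
        raise ValueError("empty trial list")
    conditions = {tm.condition for tm in trials}
    if len(conditions) > 1:
        raise ValueError(f"trials span multiple conditions: {sorted(conditions)}")
    by_subject: dict[str, list[TrialMatrix]] = {}
    for tm in trials:
        by_subject.setdefault(tm.subject_id, []).append(tm)
    fpts = []
    for subject_id in sorted(by_subject):
        sub_trials = by_subject[subject_id]
        idx = _resolve_target_index(sub_trials, target_rule)
        fpts.append(align_trials(sub_trials, target_index=idx, sd_ddof=sd_ddof))
    return fpts
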