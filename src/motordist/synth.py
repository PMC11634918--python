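"""Synthetic reach-to-grasp kinematics with controllable motor styles.

The generator emulates the study design the pipeline is built for: a single
confederate contributing 16 sessions (each treated as a separate
subject-instance and sharing one generative style), 16 distinct
participants, ~20 trials per instance, two grip conditions (PG, WHP),
sampled at 100 Hz.

A subject's style is a small parameter vector of a minimum-jerk reach:

* ``amplitude_mm`` — reach extent D along the primary axis;
* ``duration_s`` — movement time T;
* ``asymmetry`` — exponent gamma warping normalized time (u = tau^gamma),
  skewing the time-to-peak-velocity away from mid-movement;
* ``curvature_mm`` — out-of-axis bow of the path.

The position along the reach axis is the minimum-jerk polynomial
``D * (10 u^3 - 15 u^4 + 6 u^5)``; its peak speed for gamma = 1 is the
closed form 15 D / (8 T). Trial-to-trial variability has two independent
dials: multiplicative jitter of (D, T, gamma) with coefficient of variation
``param_cv``, and smooth additive positional noise (white noise low-passed
by a Gaussian kernel, tapered to zero at onset/offset) with standard
deviation ``additive_mm``.

Because the Procrustes comparison removes global translation, rotation and
scale, amplitude differences alone are invisible to it; styles are told
apart by duration (which changes the relative magnitudes of WV, WA and WJ),
asymmetry and curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .kinematics import RawTrial

__all__ = [
    "StyleRanges",
    "SyntheticStyle",
    "DatasetDesign",
    "SyntheticDataset",
    "draw_style",
    "generate_trial",
    "generate_dataset",
    "DEFAULT_RANGES",
]


@dataclass(frozen=True)
class StyleRanges:
    """Population-level (min, max) ranges the style sampler draws from."""

    amplitude_mm: tuple[float, float] = (200.0, 400.0)
    duration_s: tuple[float, float] = (0.6, 1.4)
    asymmetry: tuple[float, float] = (0.75, 1.3)
    curvature_mm: tuple[float, float] = (5.0, 40.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in asdict(self).items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


DEFAULT_RANGES = StyleRanges()


@dataclass(frozen=True)
class SyntheticStyle:
    """Subject-level generative parameters of the minimum-jerk simulator."""

    amplitude_mm: float
    duration_s: float
    asymmetry: float
    curvature_mm: float
    param_cv: float = 0.05  # per-trial CV of (D, T, gamma)
    additive_mm: float = 1.0  # SD of smooth positional noise

    def __post_init__(self) -> None:
        for name in ("amplitude_mm", "duration_s", "asymmetry", "curvature_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.param_cv < 0.3:
            raise ValueError("param_cv must lie in [0, 0.3) to keep trials non-degenerate")
        if self.additive_mm < 0:
            raise ValueError("additive_mm must be non-negative")

    def perturbed(self, rng: np.random.Generator, cv: float) -> "SyntheticStyle":
        """Multiplicative Gaussian jitter of (D, T, gamma), clipped to +/-50%."""
        factors = 1.0 + cv * rng.standard_normal(3)
        factors = np.clip(factors, 0.5, 1.5)
        return SyntheticStyle(
            amplitude_mm=self.amplitude_mm * factors[0],
            duration_s=self.duration_s * factors[1],
            asymmetry=self.asymmetry * factors[2],
            curvature_mm=self.curvature_mm,
            param_cv=self.param_cv,
            additive_mm=self.additive_mm,
        )


@dataclass(frozen=True)
class DatasetDesign:
    n_participants: int = 16
    n_confederate_instances: int = 16
    trials_per_instance: int = 20
    conditions: tuple[str, ...] = ("PG", "WHP")
    sample_rate: float = 100.0
    #: per-subject multiplicative style shift between conditions, so the two
    #: conditions' distance structures correlate without being identical
    condition_effect_cv: float = 0.05
    ranges: StyleRanges = field(default_factory=StyleRanges)
    param_cv: float = 0.05
    additive_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_confederate_instances, self.trials_per_instance) < 1:
            raise ValueError("design counts must be positive")
        if not self.conditions:
            raise ValueError("need at least one condition")


@dataclass(frozen=True)
class SyntheticDataset:
    raw_trials: list
    design: DatasetDesign
    seed: int
    true_styles: dict  # (subject_id, condition) -> SyntheticStyle


def draw_style(
    rng: np.random.Generator | int,
    ranges: StyleRanges = DEFAULT_RANGES,
    param_cv: float = 0.05,
    additive_mm: float = 1.0,
) -> SyntheticStyle:
    """Draw one subject style uniformly from the population ranges."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draw = lambda lo_hi: float(rng.uniform(*lo_hi))
    return SyntheticStyle(
        amplitude_mm=draw(ranges.amplitude_mm),
        duration_s=draw(ranges.duration_s),
        asymmetry=draw(ranges.asymmetry),
        curvature_mm=draw(ranges.curvature_mm),
        param_cv=param_cv,
        additive_mm=additive_mm,
    )


def _minimum_jerk_profile(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def generate_trial(
    style: SyntheticStyle,
    trial_seed: int | np.random.Generator,
    sample_rate: float = 100.0,
    subject_id: str = "synthetic",
    group: str = "participant",
    condition: str = "PG",
    trial_id: str = "T01",
) -> RawTrial:
    """Simulate one reach-to-grasp trial as a RawTrial with positions.

    Per-trial parameter jitter (CV ``style.param_cv`` on D, T, gamma) and
    smooth additive noise are both drawn from ``trial_seed``; zero noise and
    the same seed reproduce a trial exactly.
    """
    rng = (
        trial_seed
        if isinstance(trial_seed, np.random.Generator)
        else np.random.default_rng(trial_seed)
    )
    if not all(
        np.isfinite([style.amplitude_mm, style.duration_s, style.asymmetry, style.curvature_mm])
    ):
        raise ValueError("non-finite style parameters")
    cv = style.param_cv
    jitter = 1.0 + cv * rng.standard_normal(3) if cv > 0 else np.ones(3)
    jitter = np.clip(jitter, 0.5, 1.5)
    D = style.amplitude_mm * jitter[0]
    T = style.duration_s * jitter[1]
    gamma = style.asymmetry * jitter[2]

    n = int(round(T * sample_rate)) + 1
    n = max(n, 12)
    tau = np.linspace(0.0, 1.0, n)
    u = tau**gamma
    s = _minimum_jerk_profile(u)
    x = D * s
    y = style.curvature_mm * 4.0 * s * (1.0 - s)  # bow, zero at both ends
    z = np.zeros(n)
    positions = np.column_stack([x, y, z])

    if style.additive_mm > 0:
        noise = rng.standard_normal((n, 3))
        noise = gaussian_filter1d(noise, sigma=8.0, axis=0, mode="reflect")
        sd = noise.std(axis=0)
        sd[sd == 0] = 1.0
        noise = noise / sd * style.additive_mm
        taper = np.sin(np.pi * tau) ** 2
        positions = positions + noise * taper[:, None]

    return RawTrial(
        subject_id=subject_id,
        group=group,
        condition=condition,
        trial_id=trial_id,
        sample_rate=sample_rate,
        positions=positions,
    )


def generate_dataset(
    design: DatasetDesign = DatasetDesign(), seed: int = 0
) -> SyntheticDataset:
    """Generate the full multi-subject, multi-condition trial set.

    All confederate instances share one style (they are the same person on
    different sessions); each participant gets a fresh style. For conditions
    beyond the first, every subject's style is shifted by a per-subject
    multiplicative jitter (CV ``condition_effect_cv``), so cross-condition
    distance structure is correlated but not identical. Fully deterministic
    given (design, seed).
    """
    root = np.random.default_rng(seed)
    style_rng, cond_rng, trial_rng = root.spawn(3)

    confed_style = draw_style(
        style_rng, design.ranges, design.param_cv, design.additive_mm
    )
    participant_styles = [
        draw_style(style_rng, design.ranges, design.param_cv, design.additive_mm)
        for _ in range(design.n_participants)
    ]

    trials = []
    true_styles = {}
    for c_idx, condition in enumerate(design.conditions):
        # the condition shift applies per underlying person, so all sessions
        # of the confederate still share one style within each condition
        if c_idx == 0:
            confed_c = confed_style
            part_c = participant_styles
        else:
            confed_c = confed_style.perturbed(cond_rng, design.condition_effect_cv)
            part_c = [
                s.perturbed(cond_rng, design.condition_effect_cv)
                for s in participant_styles
            ]
        subjects = [
            (f"conf{i + 1:02d}", "confederate_instance", confed_c)
            for i in range(design.n_confederate_instances)
        ] + [
            (f"part{i + 1:02d}", "participant", part_c[i])
            for i in range(design.n_participants)
        ]
        for subject_id, group, style in subjects:
            true_styles[(subject_id, condition)] = style
            for k in range(design.trials_per_instance):
                trials.append(
                    generate_trial(
                        style,
                        trial_rng,
                        sample_rate=design.sample_rate,
                        subject_id=subject_id,
                        group=group,
                        condition=condition,
                        trial_id=f"T{k + 1:02d}",
                    )
                )
    return SyntheticDataset(
        raw_trials=trials, design=design, seed=seed, true_styles=true_styles
    )
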