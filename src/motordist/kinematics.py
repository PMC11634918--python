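"""Per-trial kinematic preprocessing.

Turns raw wrist-marker trajectories (or precomputed scalar kinematics) into
the time-normalized trial matrix consumed by the Procrustes machinery:

1. zero-phase low-pass filtering of each position axis (Butterworth, 8 Hz
   default cutoff at 100 Hz sampling);
2. derivation of the three scalar kinematic variables

   * WV — wrist velocity, the module (Euclidean norm) of the first position
     derivative, mm/s;
   * WA — wrist acceleration, the rate of change of WV, mm/s^2 (an
     alternative reading, the signed rate of change computed from the module
     of the acceleration vector, is exposed via ``wa_definition``);
   * WJ — wrist jerk, the rate of change of the module of the acceleration
     vector, mm/s^3;

3. decile time-normalization: the movement window is split into ``n_bins``
   non-overlapping bins of (near-)equal sample count and each variable is
   averaged within bins, making trials of different durations comparable.

Trials are assumed to be pre-windowed from reach onset to offset; no onset
detection or gap interpolation happens here — gaps are a load-time error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "RawTrial",
    "KinematicSeries",
    "TrialMatrix",
    "lowpass_filter",
    "compute_kinematics",
    "decile_average",
    "build_trial_matrix",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_N_TIMEPOINTS",
    "VARIABLE_NAMES",
]

DEFAULT_CUTOFF_HZ = 8.0
DEFAULT_N_TIMEPOINTS = 10
#: column order of the trial matrix
VARIABLE_NAMES = ("wv", "wa", "wj")

#: Butterworth design order; applied forward and backward (zero phase), so the
#: effective magnitude response is the squared order-2 response.
FILTER_ORDER = 2


@dataclass(frozen=True)
class RawTrial:
    """One pre-windowed reach-to-grasp trial.

    Exactly one of ``positions`` (n x 3 wrist marker coordinates, mm) or
    ``scalars`` (n x 3 precomputed (wv, wa, wj) samples) must be provided.
    """

    subject_id: str
    group: str  # "participant" or "confederate_instance"
    condition: str  # "PG" or "WHP"
    trial_id: str
    sample_rate: float  # Hz
    positions: np.ndarray | None = None
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if (self.positions is None) == (self.scalars is None):
            raise ValueError("provide exactly one of positions or scalars")
        data = self.positions if self.positions is not None else self.scalars
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"trial data must be n x 3, got shape {arr.shape}")
        if arr.shape[0] < 10:
            raise ValueError(
                f"trial {self.trial_id!r}: need at least 10 samples, got {arr.shape[0]}"
            )
        if not np.isfinite(arr).all():
            raise ValueError(
                f"trial {self.trial_id!r}: missing or non-finite samples are a "
                "load-time error (gaps are not interpolated)"
            )
        object.__setattr__(
            self, "positions" if self.positions is not None else "scalars", arr
        )

    @property
    def n_samples(self) -> int:
        data = self.positions if self.positions is not None else self.scalars
        return data.shape[0]


@dataclass(frozen=True)
class KinematicSeries:
    """The three scalar kinematic time series of one trial."""

    wv: np.ndarray  # wrist speed, mm/s; >= 0
    wa: np.ndarray  # rate of change of wv, mm/s^2 (may be negative)
    wj: np.ndarray  # rate of change of |acceleration|, mm/s^3
    sample_rate: float

    def __post_init__(self) -> None:
        if not (len(self.wv) == len(self.wa) == len(self.wj)):
            raise ValueError("wv, wa, wj must have equal length")
        if (self.wv < -1e-12).any():
            raise ValueError("wv (a vector module) cannot be negative")


@dataclass(frozen=True)
class TrialMatrix:
    """Time-point x variable representation of one movement.

    ``values`` has ``n_timepoints`` rows (default 10) and one column per
    variable, ordered (WV, WA, WJ). In shape terms: the time points are
    landmarks living in the (WV, WA, WJ) space.
    """

    values: np.ndarray
    subject_id: str
    group: str
    condition: str
    trial_id: str
    variables: tuple[str, ...] = VARIABLE_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.variables):
            raise ValueError(
                f"trial matrix must be t x {len(self.variables)}, got {arr.shape}"
            )
        if not np.isfinite(arr).all():
            raise ValueError(f"trial {self.trial_id!r}: non-finite matrix entries")
        object.__setattr__(self, "values", arr)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def is_degenerate(self, tol: float = 1e-12) -> bool:
        """True if all landmarks coincide (zero centered sum of squares)."""
        centered = self.values - self.values.mean(axis=0)
        return float(np.sum(centered**2)) <= tol


def lowpass_filter(
    series: np.ndarray, cutoff: float, sample_rate: float
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    An order-``FILTER_ORDER`` design is applied forward and backward
    (``filtfilt``), so the output has no group delay and the effective
    magnitude response is the design response squared. DC is preserved.

    Parameters
    ----------
    series
        1-D scalar series or 2-D (n x k) array filtered column-wise.
    cutoff
        Cutoff frequency in Hz; must be below the Nyquist frequency.
    sample_rate
        Sampling rate in Hz.
    """
    arr = np.asarray(series, dtype=float)
    nyquist = sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={nyquist} Hz), got {cutoff} Hz"
        )
    b, a = signal.butter(FILTER_ORDER, cutoff / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))  # filtfilt default
    n = arr.shape[0]
    if n <= padlen:
        raise ValueError(
            f"series of length {n} too short to filter: need more than "
            f"{padlen} samples for edge padding"
        )
    return signal.filtfilt(b, a, arr, axis=0)


def _derivative(arr: np.ndarray, dt: float) -> np.ndarray:
    """Central differences on interior samples, one-sided at the endpoints."""
    return np.gradient(arr, dt, axis=0)


def compute_kinematics(
    trial: RawTrial,
    wa_definition: Literal["speed_derivative", "acceleration_module"]
    = "speed_derivative",
) -> KinematicSeries:
    """Derive (WV, WA, WJ) from a position-based trial.

    WV is the module of the first position derivative. WA is, by default, the
    signed rate of change of WV ("speed_derivative"); the alternative reading
    ("acceleration_module") takes WA as the module of the acceleration vector
    itself — always non-negative, and different from |d(wv)/dt| on curved
    paths. WJ is the rate of change of the module of the acceleration vector.
    """
    if trial.positions is None:
        raise ValueError(
            "trial carries precomputed scalars; bypass compute_kinematics and "
            "feed them to decile_average / build_trial_matrix directly"
        )
    if trial.n_samples < 5:
        raise ValueError("need at least 5 samples to differentiate twice")
    dt = 1.0 / trial.sample_rate
    vel = _derivative(trial.positions, dt)
    wv = np.linalg.norm(vel, axis=1)
    acc = _derivative(vel, dt)
    acc_module = np.linalg.norm(acc, axis=1)
    if wa_definition == "speed_derivative":
        wa = _derivative(wv, dt)
    elif wa_definition == "acceleration_module":
        wa = acc_module
    else:
        raise ValueError(f"unknown wa_definition {wa_definition!r}")
    wj = _derivative(acc_module, dt)
    return KinematicSeries(wv=wv, wa=wa, wj=wj, sample_rate=trial.sample_rate)


def decile_average(series: Sequence[float], n_bins: int = DEFAULT_N_TIMEPOINTS) -> np.ndarray:
    """Non-overlapping moving average over ``n_bins`` equal time deciles.

    Bin ``b`` (1-based) averages the samples with 0-based index in
    ``[floor((b-1) N / n_bins), floor(b N / n_bins))``; the bins are
    non-overlapping and cover every sample exactly once.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("decile_average expects a 1-D series")
    n = arr.shape[0]
    if n < n_bins:
        raise ValueError(f"series of length {n} has fewer samples than {n_bins} bins")
    edges = (np.arange(n_bins + 1) * n) // n_bins
    return np.array([arr[edges[b] : edges[b + 1]].mean() for b in range(n_bins)])


def build_trial_matrix(
    trial: RawTrial,
    filter_cutoff: float | None = DEFAULT_CUTOFF_HZ,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    variables: Sequence[str] = VARIABLE_NAMES,
    wa_definition: str = "speed_derivative",
) -> TrialMatrix:
    """Full per-trial pipeline: filter -> kinematics -> decile averages.

    Position-based trials are low-pass filtered per axis before
    differentiation (derivatives amplify residual noise, so the trajectory is
    filtered once, not each derived variable). Scalar-based trials bypass
    filtering and differentiation. ``filter_cutoff=None`` disables filtering.
    """
    unknown = set(variables) - set(VARIABLE_NAMES)
    if unknown:
        raise ValueError(f"unknown variables {sorted(unknown)}; choose from {VARIABLE_NAMES}")
    if trial.positions is not None:
        if filter_cutoff is not None:
            filtered = lowpass_filter(trial.positions, filter_cutoff, trial.sample_rate)
            trial = RawTrial(
                subject_id=trial.subject_id,
                group=trial.group,
                condition=trial.condition,
                trial_id=trial.trial_id,
                sample_rate=trial.sample_rate,
                positions=filtered,
            )
        series = compute_kinematics(trial, wa_definition=wa_definition)
        columns = {"wv": series.wv, "wa": series.wa, "wj": series.wj}
    else:
        columns = dict(zip(VARIABLE_NAMES, trial.scalars.T))
    values = np.column_stack(
        [decile_average(columns[v], n_bins=n_timepoints) for v in variables]
    )
    return TrialMatrix(
        values=values,
        subject_id=trial.subject_id,
        group=trial.group,
        condition=trial.condition,
        trial_id=trial.trial_id,
        variables=tuple(variables),
    )
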