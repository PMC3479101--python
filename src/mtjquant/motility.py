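"""Touch-evoked escape-response scoring.

An embryo starts at the center of two concentric circles (inner diameter
5 mm, outer diameter 10 mm) and is touched; the readout is the time to
leave the field of view, operationalized as the first crossing of the outer
circle (5 mm from the start). Embryos that never exit are imputed the
slowest observed exit time after biological replicates of the experiment
are pooled, so non-responders penalize rather than drop out of the group
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stats import GroupComparison, paired_t_test, welch_t_test

__all__ = [
    "ARENA_EXIT_RADIUS_MM",
    "EscapeTrial",
    "exit_time_from_trajectory",
    "select_best_response",
    "impute_nonresponders",
    "compare_escape_times",
]

#: Radius of the outer circle (mm); crossing it counts as exiting the field
#: of view. The inner 5 mm diameter circle is an alignment guide only.
ARENA_EXIT_RADIUS_MM = 5.0


@dataclass
class EscapeTrial:
    """One touch-evoked trial: a trajectory or a pre-scored exit time.

    Trajectories are sequences of (t in ms, x in mm, y in mm) with the
    arena center at the origin; exactly one of ``trajectory`` and the
    recorded (``exit_time_ms``, ``exited``) pair must be present.
    """

    embryo_id: str = ""
    group: str = ""
    replicate: int = 0
    t_ms: Optional[np.ndarray] = None
    x_mm: Optional[np.ndarray] = None
    y_mm: Optional[np.ndarray] = None
    exit_time_ms: Optional[float] = None
    exited: Optional[bool] = None

    def __post_init__(self) -> None:
        has_traj = self.t_ms is not None
        has_rec = self.exited is not None
        if has_traj == has_rec:
            raise ValueError(
                "exactly one of trajectory and recorded score must be present")
        if has_traj:
            self.t_ms = np.asarray(self.t_ms, dtype=float)
            self.x_mm = np.asarray(self.x_mm, dtype=float)
            self.y_mm = np.asarray(self.y_mm, dtype=float)
            if not (len(self.t_ms) == len(self.x_mm) == len(self.y_mm)):
                raise ValueError("trajectory arrays must have equal length")
            if np.any(np.diff(self.t_ms) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        elif self.exited and not (self.exit_time_ms or 0) > 0:
            raise ValueError("exited trials need exit_time_ms > 0")

    @property
    def has_trajectory(self) -> bool:
        return self.t_ms is not None


def exit_time_from_trajectory(trial: EscapeTrial) -> Optional[float]:
    """First time (ms) the embryo crosses the outer circle, or None.

    The crossing time is linearly interpolated on the radial distance
    between the two samples bracketing the crossing. Returns None when the
    trajectory never leaves the arena (a non-responder).
    """
    if not trial.has_trajectory:
        raise ValueError("trial has no trajectory; use its recorded score")
    r = np.hypot(trial.x_mm, trial.y_mm)
    if r[0] > ARENA_EXIT_RADIUS_MM:
        raise ValueError("trajectory starts outside the arena")
    outside = r > ARENA_EXIT_RADIUS_MM
    if not outside.any():
        return None
    i = int(np.argmax(outside))  # first sample beyond the circle
    if i == 0:  # pragma: no cover - excluded by the start check
        return float(trial.t_ms[0])
    r0, r1 = r[i - 1], r[i]
    t0, t1 = trial.t_ms[i - 1], trial.t_ms[i]
    frac = (ARENA_EXIT_RADIUS_MM - r0) / (r1 - r0)
    return float(t0 + frac * (t1 - t0))


def score_trial(trial: EscapeTrial) -> tuple[Optional[float], bool]:
    """(exit_time_ms or None, exited) for either trial representation."""
    if trial.has_trajectory:
        t = exit_time_from_trajectory(trial)
        return t, t is not None
    return (trial.exit_time_ms if trial.exited else None), bool(trial.exited)


def select_best_response(trials: Sequence[EscapeTrial]) -> EscapeTrial:
    """The most robust response among repeated pokes: the fastest exit.

    If no trial exited, a (the first) non-exiting trial is returned.
    """
    if len(trials) == 0:
        raise ValueError("no trials given")
    best, best_t = None, np.inf
    for trial in trials:
        t, exited = score_trial(trial)
        if exited and t < best_t:
            best, best_t = trial, t
    return best if best is not None else trials[0]


def impute_nonresponders(times, exited):
    """Assign non-responders the slowest exit time of the pooled experiment.

    ``times``/``exited`` are per-embryo final scores pooled across the
    biological replicates of one experiment; embryos with ``exited`` False
    receive max(times[exited]); exiting embryos are unchanged. Idempotent.
    """
    times = np.asarray(times, dtype=float)
    exited = np.asarray(exited, dtype=bool)
    if times.shape != exited.shape:
        raise ValueError("times and exited must have the same shape")
    if not exited.any():
        raise ValueError("no embryo exited: imputation undefined")
    out = times.copy()
    out[~exited] = np.max(times[exited])
    return out


def compare_escape_times(times_a, times_b) -> GroupComparison:
    """Group comparison of imputed escape times, paired by replicate index.

    Equal-size groups get the two-tailed paired t test; unequal sizes fall
    back to an unpaired Welch test with a warning. Single-pair groups are
    flagged non-computable (no degrees of freedom).
    """
    import warnings

    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.size == 1 and b.size == 1:
        return GroupComparison(float(a[0]), float(b[0]), np.nan, np.nan,
                               np.nan, 0, np.nan, "none", "non-computable",
                               note="single-pair groups: df = 0")
    if a.size != b.size:
        warnings.warn(
            "unequal group sizes: falling back to unpaired Welch t test",
            stacklevel=2)
        return welch_t_test(a, b)
    return paired_t_test(a, b)
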