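"""Wave measurement, event detection and outcome classification.

The "WT wave" is every non-carrier and the "drive wave" every carrier;
heights are class-specific (each wave's density is computed from its own
members only, so the two waves stay separable where they overlap).  A
wave's peak is the member attaining the maximum class density, ties broken
toward the leading edge (largest position).  Velocities are the mean
per-generation displacement of the leading (rightmost) individual over the
window ending at the first boundary contact or the first penetration.
Heights and widths are measured one generation after drive introduction.

Events: *penetration* is a wild-type at least sigma units behind the drive
wave's trailing edge (its leftmost carrier); *chasing* is the drive
subsequently re-entering the region recolonized by those wild-types; a run
ends in *success* (WT eradicated by generation 1000) or *failure* via
drift loss, WT escape, or indefinite coexistence.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .model_core import kernel_density

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import SimulationRecord

__all__ = [
    "WaveMetrics",
    "Outcome",
    "FailureMode",
    "OutcomeLabel",
    "wave_peak_and_height",
    "leading_edge_peak",
    "wave_velocity",
    "measure_widths",
    "measure_wave_snapshot",
    "attach_velocities",
    "detect_penetration",
    "detect_chasing",
    "classify_outcome",
]


@dataclasses.dataclass
class WaveMetrics:
    """Measured velocity, height and width components of one run's waves."""

    wt_velocity: Optional[float] = None
    drive_velocity: Optional[float] = None
    wt_height: Optional[float] = None
    drive_height: Optional[float] = None
    wt_width: Optional[float] = None
    drive_leading_half_width: Optional[float] = None
    drive_trailing_half_width: Optional[float] = None
    drive_width: Optional[float] = None
    measured_through_generation: Optional[int] = None

    @property
    def relative_velocity(self) -> Optional[float]:
        if self.wt_velocity is None or self.drive_velocity is None:
            return None
        return self.drive_velocity - self.wt_velocity


class Outcome(str, enum.Enum):
    SUCCESS = "SUCCESS"
    FAILURE = "FAILURE"


class FailureMode(str, enum.Enum):
    NONE = "NONE"
    DRIFT_LOSS = "DRIFT_LOSS"
    WT_ESCAPE = "WT_ESCAPE"
    COEXISTENCE = "COEXISTENCE"


@dataclasses.dataclass(frozen=True)
class OutcomeLabel:
    outcome: Outcome
    failure_mode: FailureMode
    penetration: bool
    chasing: bool
    drive_loss: bool


def wave_peak_and_height(
    x: np.ndarray, carrier: np.ndarray, wave: str
) -> tuple[float, float]:
    """Peak position and height (max class-specific local density) of a wave.

    ``wave`` is ``"WT"`` (non-carriers) or ``"DRIVE"`` (carriers).  Raises
    ``ValueError`` when the class is empty (the height is then undefined).
    Ties in density are resolved toward the largest position.
    """
    x = np.asarray(x, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    member = carrier if wave.upper() == "DRIVE" else ~carrier
    cls_x = x[member]
    if cls_x.size == 0:
        raise ValueError(f"no individuals in the {wave} wave; height undefined")
    dens = kernel_density(cls_x, cls_x)
    height = float(dens.max())
    peak = float(cls_x[dens == height].max())
    return peak, height


def wave_velocity(leading_edge_series: Sequence[float]) -> float:
    """Mean per-generation displacement of the leading individual.

    The mean of successive differences telescopes to
    ``(last - first) / (n - 1)``.
    """
    s = np.asarray(leading_edge_series, dtype=float)
    if s.size < 2:
        raise ValueError("velocity needs at least two generations")
    return float((s[-1] - s[0]) / (s.size - 1))


def leading_edge_peak(cls_x: np.ndarray) -> float:
    """Position where the leading-edge wave crests: the rightmost member
    whose class density reaches the class's median (bulk) density.

    The wild-type profile is a travelling front backed by a broad plateau
    at carrying capacity, so the *global* density maximum is just a noise
    fluctuation somewhere in the bulk; the front's crest — where the wave
    first attains bulk density coming from the leading tip — is the
    measurement point that makes the width a property of the wave rather
    than of the plateau.
    """
    cls_x = np.asarray(cls_x, dtype=float)
    if cls_x.size == 0:
        raise ValueError("empty wave; leading-edge peak undefined")
    dens = kernel_density(cls_x, cls_x)
    at_bulk = dens >= np.median(dens)
    return float(cls_x[at_bulk].max())


def measure_widths(x: np.ndarray, carrier: np.ndarray) -> dict[str, float]:
    """Width components of both waves from one population snapshot.

    WT width is twice the distance from the leading (rightmost) wild-type
    to the WT wave's leading-edge peak (see :func:`leading_edge_peak`);
    the drive wave's leading/trailing half widths are the distances from
    its peak (its maximum-density member — the drive wave is a single
    hump, so the maximizer is the crest) to its extreme members.  All
    clipped at 0.
    """
    x = np.asarray(x, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    _, wt_height = wave_peak_and_height(x, carrier, "WT")
    dr_peak, dr_height = wave_peak_and_height(x, carrier, "DRIVE")
    wt_x = x[~carrier]
    dr_x = x[carrier]
    wt_peak = leading_edge_peak(wt_x)
    wt_width = max(0.0, 2.0 * (float(wt_x.max()) - wt_peak))
    leading = max(0.0, float(dr_x.max()) - dr_peak)
    trailing = max(0.0, dr_peak - float(dr_x.min()))
    return {
        "wt_width": wt_width,
        "wt_height": wt_height,
        "wt_peak": wt_peak,
        "drive_height": dr_height,
        "drive_peak": dr_peak,
        "drive_leading_half_width": leading,
        "drive_trailing_half_width": trailing,
        "drive_width": leading + trailing,
    }


def measure_wave_snapshot(
    x: np.ndarray, carrier: np.ndarray, generation: int
) -> WaveMetrics:
    """Heights and widths from the one-generation-post-introduction snapshot."""
    w = measure_widths(x, carrier)
    return WaveMetrics(
        wt_height=w["wt_height"],
        drive_height=w["drive_height"],
        wt_width=w["wt_width"],
        drive_leading_half_width=w["drive_leading_half_width"],
        drive_trailing_half_width=w["drive_trailing_half_width"],
        drive_width=w["drive_width"],
        measured_through_generation=generation,
    )


def attach_velocities(
    metrics: Optional[WaveMetrics],
    edges: pd.DataFrame,
    sigma: float,
    landscape_length: float,
    first_penetration: Optional[int],
) -> Optional[WaveMetrics]:
    """Fill in wave velocities from the per-generation leading-edge series.

    The measurement window starts at drive introduction (generation 0) and
    ends just before the first generation in which either wave's leading
    individual is within sigma of the right landscape edge, or at the
    first penetration, whichever comes first.
    """
    if edges.empty:
        return metrics
    end = len(edges)
    contact = np.flatnonzero(
        (edges["wt_max"].to_numpy() >= landscape_length - sigma)
        | (edges["dr_max"].to_numpy() >= landscape_length - sigma)
    )
    if contact.size:
        end = min(end, int(contact[0]))
    if first_penetration is not None:
        end = min(end, int(first_penetration))
    wt = edges["wt_max"].to_numpy()[:end]
    dr = edges["dr_max"].to_numpy()[:end]
    wt = wt[np.isfinite(wt)]
    dr = dr[np.isfinite(dr)]
    if wt.size < 2 and dr.size < 2:
        return metrics
    if metrics is None:
        metrics = WaveMetrics()
    if wt.size >= 2:
        metrics.wt_velocity = wave_velocity(wt)
    if dr.size >= 2:
        metrics.drive_velocity = wave_velocity(dr)
    if metrics.measured_through_generation is None:
        metrics.measured_through_generation = max(end - 1, 0)
    return metrics


def detect_penetration(
    wt_x: np.ndarray, drive_x: np.ndarray, sigma: float
) -> bool:
    """Has a wild-type moved >= sigma beyond the drive's trailing edge?

    The trailing edge is the carrier with the lowest position.  Raises
    ``ValueError`` when no carriers remain (the drive is already lost, so
    the event is undefined).
    """
    drive_x = np.asarray(drive_x, dtype=float)
    if drive_x.size == 0:
        raise ValueError("penetration undefined without drive carriers")
    wt_x = np.asarray(wt_x, dtype=float)
    if wt_x.size == 0:
        return False
    return bool(wt_x.min() <= drive_x.min() - sigma)


def detect_chasing(
    dr_min: Sequence[float],
    wt_max_behind_prev_trail: Sequence[float],
    first_penetration: Optional[int],
) -> bool:
    """Did the drive re-enter the region recolonized by penetrating WTs?

    Scans generations after the first penetration; chasing is flagged when
    the drive's trailing edge falls at or below the rightmost wild-type
    that sat behind the previous generation's trailing edge (the
    recolonizing subpopulation's leading edge).  False when no penetration
    occurred.
    """
    if first_penetration is None:
        return False
    dr_min = np.asarray(dr_min, dtype=float)
    back = np.asarray(wt_max_behind_prev_trail, dtype=float)
    for t in range(first_penetration + 1, dr_min.size):
        if np.isfinite(dr_min[t]) and np.isfinite(back[t]) and dr_min[t] <= back[t]:
            return True
    return False


def classify_outcome(record: "SimulationRecord") -> OutcomeLabel:
    """Assign the run's outcome per the event taxonomy.

    SUCCESS iff the wild-type population was eradicated on or before the
    final generation; otherwise FAILURE through drift loss (drive lost,
    never penetrated), WT escape (drive lost after penetration) or
    coexistence (both allele classes extant at the stopping generation).
    """
    penetration = record.first_penetration_generation is not None
    drive_loss = record.drive_loss_generation is not None
    if record.wt_extinction_generation is not None:
        return OutcomeLabel(
            Outcome.SUCCESS, FailureMode.NONE, penetration, record.chasing_observed, drive_loss
        )
    if drive_loss:
        mode = FailureMode.WT_ESCAPE if penetration else FailureMode.DRIFT_LOSS
    elif record.config.drive_system.value != "NONE":
        mode = FailureMode.COEXISTENCE
    else:
        mode = FailureMode.NONE
    return OutcomeLabel(
        Outcome.FAILURE, mode, penetration, record.chasing_observed, drive_loss
    )
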