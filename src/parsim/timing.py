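"""Acquisition-readout synchronization algebra for parallel-readout SIM.

A parallel acquisition-readout SIM frame tiles six (or nine) patterned
sub-ROIs onto the rolling-shutter sensor so that the staggered row readout
of the first half of the patterns overlaps the exposure of the second half.
The quantities below are the timing signals that make this work:

``T_i``
    galvo dwell per sub-ROI position (us),
``T_ii``
    SLM pattern switching duration (us) -- the hard lower bound on the
    per-pattern time, set by the modulator's polarity-reset cycle,
``T_iii``
    SLM high-voltage (positive illumination) window (us),
``T_D1 .. T_D3``
    trigger delays: frame-to-frame exposure delay, exposure-to-scan delay,
    and the per-step SLM-to-galvo settling buffer.

The synchronization identity ``T_ii + T_D3 = T_i`` ties the galvo dwell to
the modulator duration, and the rolling-shutter slope constraint
``(N/2) * t_row >= (n_subframes/2) * T_ii`` bounds how few sensor rows can
be opened while still hiding the readout behind the exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, Field, NonNegativeFloat

__all__ = [
    "TimingPlan",
    "FluxReport",
    "Violation",
    "min_opened_rows",
    "max_raw_framerate",
    "sim_framerate",
    "validate_plan",
    "info_flux",
    "rolling_cadence",
    "acquisition_counts",
    "scan_order",
    "ADVISED_PLANS",
    "MINIMAL_PLANS",
]

#: sensor line readout time of the reference sCMOS camera (us per row)
DEFAULT_LINE_TIME_US = 9.74


class TimingPlan(BaseModel):
    """The full set of synchronization times for one acquisition mode."""

    name: str = ""
    T_i: NonNegativeFloat
    T_ii: NonNegativeFloat
    T_iii: NonNegativeFloat
    T_D1: NonNegativeFloat = 0.0
    T_D2: NonNegativeFloat = 0.0
    T_D3: NonNegativeFloat = 0.0
    t_row: float = Field(DEFAULT_LINE_TIME_US, gt=0)
    n_subframes_per_frame: int = Field(6, ge=1)
    n_patterns_per_recon: int = Field(6, ge=1)
    opened_rows: int = Field(..., ge=2)
    subroi_rows: int = Field(..., ge=1)

    @property
    def frame_time_us(self) -> float:
        """Whole-frame period: T_D1 + T_D2 + n_subframes * T_i."""
        return self.T_D1 + self.T_D2 + self.n_subframes_per_frame * self.T_i

    @property
    def framerate_hz(self) -> int:
        return sim_framerate(self.T_D1, self.T_D2, self.T_i,
                             self.n_subframes_per_frame)


@dataclass(frozen=True)
class FluxReport:
    """Spatio-temporal information flux of a reconstruction mode."""

    sim_framerate: float
    effective_width: int
    effective_height: int
    flux: float  # MPixels / s, 1 decimal


@dataclass(frozen=True)
class Violation:
    rule: str
    message: str


def min_opened_rows(T_ii: float, t_row: float = DEFAULT_LINE_TIME_US,
                    n_subframes: int = 6, row_granularity: int = 4) -> int:
    """Minimum number of sensor rows that must be opened.

    The opened frame must span ``n_subframes * T_ii / t_row`` rows so the
    rolling readout of one half-frame of patterns fits under the exposure
    of the other half; the result is rounded up to the sensor's row
    granularity.
    """
    if T_ii <= 0 or t_row <= 0 or n_subframes <= 0 or row_granularity <= 0:
        raise ValueError("all timing inputs must be positive")
    raw = n_subframes * T_ii / t_row
    return int(math.ceil(raw / row_granularity)) * row_granularity


def max_raw_framerate(T_ii: float) -> int:
    """Theoretical maximum raw (per-pattern) framerate, floor(1e6 / T_ii) Hz."""
    if T_ii <= 0:
        raise ValueError("T_ii must be positive")
    return int(math.floor(1e6 / T_ii))


def sim_framerate(T_D1: float, T_D2: float, T_i: float,
                  n_patterns: int) -> int:
    """SIM framerate in Hz for a frame of ``n_patterns`` sub-ROIs.

    The whole frame time is ``T_D1 + T_D2 + n_patterns * T_i``; the
    framerate is floored to an integer as quoted by instrument software.
    """
    if T_i <= 0:
        raise ValueError("T_i must be positive")
    if T_D1 < 0 or T_D2 < 0:
        raise ValueError("delays must be non-negative")
    return int(math.floor(1e6 / (T_D1 + T_D2 + n_patterns * T_i)))


def validate_plan(plan: TimingPlan, tol_us: float = 1.0) -> list[Violation]:
    """Check a timing plan against the synchronization constraints.

    Returns a list of :class:`Violation` (empty when the plan is valid):

    a. ``T_ii + T_D3 == T_i`` within ``tol_us``;
    b. ``T_ii <= T_i`` (otherwise pattern crosstalk between sub-ROIs);
    c. ``T_iii <= T_ii``;
    d. ``subroi_rows * t_row >= (n_subframes / 2) * T_ii`` (the readout
       slope of half the patterns must fit in one sub-ROI's row budget);
    e. ``opened_rows >= 2 * subroi_rows``.
    """
    v: list[Violation] = []
    mismatch = plan.T_ii + plan.T_D3 - plan.T_i
    if abs(mismatch) > tol_us:
        v.append(Violation(
            "a", f"T_ii + T_D3 = {plan.T_ii + plan.T_D3:g} us does not equal "
                 f"T_i = {plan.T_i:g} us (mismatch {mismatch:g} us)"))
    if plan.T_ii > plan.T_i:
        v.append(Violation(
            "b", f"T_ii = {plan.T_ii:g} us exceeds T_i = {plan.T_i:g} us: "
                 f"crosstalk among sub-ROIs or frames"))
    if plan.T_iii > plan.T_ii:
        v.append(Violation(
            "c", f"T_iii = {plan.T_iii:g} us exceeds T_ii = {plan.T_ii:g} us"))
    half = plan.n_subframes_per_frame / 2.0
    budget = plan.subroi_rows * plan.t_row
    need = half * plan.T_ii
    if budget < need:
        v.append(Violation(
            "d", f"sub-ROI row budget {budget:g} us "
                 f"({plan.subroi_rows} rows x {plan.t_row:g} us) is below "
                 f"{half:g} x T_ii = {need:g} us"))
    if plan.opened_rows < 2 * plan.subroi_rows:
        v.append(Violation(
            "e", f"opened rows {plan.opened_rows} < 2 x sub-ROI rows "
                 f"{plan.subroi_rows}"))
    return v


def info_flux(framerate: float, width: int, height: int) -> FluxReport:
    """Spatio-temporal information flux, MPixels/s rounded to 1 decimal."""
    if framerate <= 0 or width <= 0 or height <= 0:
        raise ValueError("framerate, width and height must be positive")
    flux = round(framerate * width * height / 1e6, 1)
    return FluxReport(framerate, width, height, flux)


def rolling_cadence(frame_time_ms: float, n_subframes: int,
                    step: int) -> tuple[float, float]:
    """Output interval and framerate of a rolling (sliding-window) cadence.

    Advancing the reconstruction window by ``step`` sub-images instead of a
    whole pattern set multiplies the output rate by ``n_subframes / step``.
    Returns ``(interval_ms, framerate_hz)``, the rate rounded to 2 decimals.
    """
    if frame_time_ms <= 0:
        raise ValueError("frame_time must be positive")
    if n_subframes % step != 0:
        raise ValueError(
            f"rolling step {step} does not divide the pattern-set size "
            f"{n_subframes}")
    interval = frame_time_ms * step / n_subframes
    return interval, round(1000.0 / interval, 2)


def acquisition_counts(duration_s: float, frame_time_ms: float,
                       n_subframes: int) -> tuple[int, int]:
    """Whole frames and raw sub-ROIs captured in ``duration_s`` seconds."""
    if frame_time_ms <= 0 or n_subframes <= 0 or duration_s < 0:
        raise ValueError("invalid acquisition parameters")
    frames = int(math.floor(duration_s * 1000.0 / frame_time_ms))
    return frames, frames * n_subframes


def scan_order(sensor_half: str = "top") -> list[tuple[int, int]]:
    """Galvo scan order over the 2x3 sub-ROI grid for one sensor half.

    The rolling shutter opens from the sensor center outward, so the galvo
    must visit the grid row nearer the sensor center first (left to right),
    then the outer row.  For a sub-frame placed on the top half of the
    sensor the center is below it (inner row = bottom grid row); on the
    bottom half the order is the vertical mirror image.

    Returns the (grid_row, grid_col) positions visited for patterns P1..P6.
    """
    if sensor_half not in ("top", "bottom"):
        raise ValueError("sensor_half must be 'top' or 'bottom'")
    inner_first = [(1, 0), (1, 1), (1, 2), (0, 0), (0, 1), (0, 2)]
    if sensor_half == "top":
        return inner_first
    return [(1 - r, c) for r, c in inner_first]


def _advised(name, T_i, T_ii, T_iii, T_D3, rows, subroi_rows):
    return TimingPlan(name=name, T_i=T_i, T_ii=T_ii, T_iii=T_iii,
                      T_D1=0, T_D2=0, T_D3=T_D3,
                      opened_rows=rows, subroi_rows=subroi_rows)


#: advised synchronization plans for the two SLM series at the two
#: pattern-exposure settings (key: (slm, actual exposure us))
ADVISED_PLANS: dict[tuple[str, int], TimingPlan] = {
    ("sxga", 200): _advised("SXGA 0.2 ms", 795, 745, 370, 50, 484, 242),
    ("sxga", 400): _advised("SXGA 0.4 ms", 995, 945, 540, 50, 608, 304),
    ("qxga", 200): _advised("QXGA 0.2 ms", 649, 589, 210, 60, 400, 192),
    ("qxga", 400): _advised("QXGA 0.4 ms", 819, 789, 290, 30, 496, 248),
}


def _minimal(name, T_ii):
    rows = min_opened_rows(T_ii)
    return TimingPlan(name=name, T_i=T_ii, T_ii=T_ii, T_iii=T_ii / 2,
                      T_D1=0, T_D2=0, T_D3=0,
                      opened_rows=rows, subroi_rows=rows // 2)


#: theoretical minimum-row plans (T_i = T_ii, no margins)
MINIMAL_PLANS: dict[tuple[str, int], TimingPlan] = {
    ("sxga", 200): _minimal("SXGA 0.2 ms minimal", 745),
    ("sxga", 400): _minimal("SXGA 0.4 ms minimal", 945),
    ("qxga", 200): _minimal("QXGA 0.2 ms minimal", 589),
    ("qxga", 400): _minimal("QXGA 0.4 ms minimal", 789),
}
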