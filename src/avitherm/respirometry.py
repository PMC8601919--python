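"""Reduction of open flow-through respirometry traces to steady-state rates.

A multiplexed flow-through system pushes dry air through a metabolic
chamber at a known mass-flow rate and subsamples the excurrent stream
through a water-vapor analyzer and (after a drying column) an oxygen
analyzer.  The analyzed channel alternates between animal chambers and an
empty baseline chamber on a fixed schedule.  This module takes one such
trace — 1 Hz fractional O2 and water-vapor pressure with segment markers —
and produces a single steady-state oxygen-consumption rate (VO2, ml O2
min^-1) and evaporative water loss (EWL, mg H2O h^-1):

1. analyzer drift is removed with a Catmull-Rom spline anchored on the
   baseline segments;
2. instantaneous rates are computed from the dry-air gas-exchange
   equations (CO2 unscrubbed, respiratory quotient fixed at 0.70);
3. after discarding a chamber-washout equilibration window, the lowest
   stable 2-min window of the VO2 series is located and both rates are
   averaged over it.

The "lowest stable" rule targets resting metabolism: the bird's quietest
stretch at each test temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicHermiteSpline

logger = logging.getLogger(__name__)

__all__ = [
    "RespirometryTrace",
    "SteadyStateMeasure",
    "ThermalProfile",
    "WindowResult",
    "drift_correct",
    "lowest_stable_window",
    "vo2_from_fractions",
    "ewl_from_wvp",
    "reduce_trace",
]

#: Density of water vapor at STP, mg per ml — converts a volumetric water
#: flux (ml min^-1 STP) to a mass rate.
WATER_VAPOR_DENSITY_STP = 0.803

#: Respiratory quotient of a postabsorptive bird catabolizing lipids.
DEFAULT_RQ = 0.70


@dataclass
class RespirometryTrace:
    """One channel's time series with baseline/animal segment markers.

    Arrays are aligned and uniformly sampled.  ``o2`` is the fractional
    O2 concentration seen by the analyzer (water scrubbed upstream, CO2
    not scrubbed); ``wvp`` is water-vapor pressure in kPa.  ``fio2`` and
    ``incurrent_wvp`` are the nominal incurrent values the baseline
    segments should read in the absence of drift.
    """

    time: np.ndarray  # s
    o2: np.ndarray  # fractional O2
    wvp: np.ndarray  # kPa
    segment_id: np.ndarray  # int
    is_baseline: np.ndarray  # bool
    flow_rate: float  # ml min^-1 STP
    barometric_pressure: float  # kPa
    ta: float  # deg C
    fio2: float = 0.2095
    incurrent_wvp: float = 0.0  # kPa
    chamber_volume_l: float = 3.9
    individual_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.wvp = np.asarray(self.wvp, dtype=float)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        self.is_baseline = np.asarray(self.is_baseline, dtype=bool)
        n = self.time.size
        if not all(a.size == n for a in (self.o2, self.wvp, self.segment_id,
                                         self.is_baseline)):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.time))) if self.time.size > 1 else 1.0

    @property
    def washout_tau(self) -> float:
        """Chamber washout time constant, s (volume / flow)."""
        return self.chamber_volume_l * 1000.0 / self.flow_rate * 60.0


@dataclass
class SteadyStateMeasure:
    """Steady-state VO2 and EWL for one individual at one temperature."""

    individual_id: str
    ta: float  # deg C
    vo2: float  # ml O2 min^-1
    ewl: float  # mg h^-1
    window_start: float  # s
    window_end: float  # s
    window_sd: float  # SD of the VO2 series inside the window
    flags: list[str] = field(default_factory=list)


@dataclass
class ThermalProfile:
    """Per-individual steady-state VO2 and EWL across test temperatures."""

    individual_id: str
    temps: np.ndarray  # deg C
    vo2: np.ndarray  # ml O2 min^-1
    ewl: np.ndarray  # mg h^-1

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.ewl = np.asarray(self.ewl, dtype=float)
        if self.temps.size == 0:
            raise ValueError("profile needs at least one temperature")
        if self.temps.size != self.vo2.size or self.temps.size != self.ewl.size:
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.temps) <= 0):
            raise ValueError("test temperatures must be strictly increasing")


class WindowResult(NamedTuple):
    start_index: int
    mean: float
    sd: float
    stable: bool


def vo2_from_fractions(fio2, feo2, flow_rate: float, rq: float = DEFAULT_RQ):
    """Oxygen consumption from incurrent/excurrent O2 fractions.

    Dry-air, CO2-unscrubbed form of the standard flow-through equation:

        VO2 = FR * (FiO2 - FeO2) / (1 - FiO2 * (1 - RQ))

    with FR the incurrent mass-flow rate in ml min^-1 STP.  The
    denominator corrects for the volume deficit between O2 removed and
    CO2 added (RQ = VCO2/VO2).  Returns ml O2 min^-1; 0 when the
    fractions are equal.  Accepts scalars or arrays.
    """
    fio2 = np.asarray(fio2, dtype=float)
    feo2 = np.asarray(feo2, dtype=float)
    if np.any(fio2 <= 0) or np.any(fio2 >= 1) or np.any(feo2 <= 0):
        raise ValueError("O2 fractions must lie in (0, 1)")
    if np.any(feo2 > fio2 + 1e-12):
        raise ValueError("FeO2 > FiO2 would imply negative O2 consumption")
    if flow_rate <= 0:
        raise ValueError("flow_rate must be positive")
    out = flow_rate * (fio2 - feo2) / (1.0 - fio2 * (1.0 - rq))
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def ewl_from_wvp(wvp_in, wvp_ex, barometric_pressure: float, flow_rate: float):
    """Evaporative water loss from water-vapor pressures, mg h^-1.

    Water-vapor fractions are ``F(i/e)H2O = wvp / BP``.  The volumetric
    flux of water added by the animal is

        FR * (FeH2O - FiH2O) / (1 - FeH2O)    [ml min^-1 STP]

    (the denominator accounts for the flow enrichment by added vapor),
    converted to mass with the STP vapor density 0.803 mg ml^-1 and to
    an hourly rate.  Accepts scalars or arrays.
    """
    wvp_in = np.asarray(wvp_in, dtype=float)
    wvp_ex = np.asarray(wvp_ex, dtype=float)
    if np.any(wvp_in < 0) or np.any(wvp_ex < 0):
        raise ValueError("water-vapor pressures must be non-negative")
    if np.any(wvp_ex >= barometric_pressure):
        raise ValueError("excurrent WVP must be below barometric pressure")
    if np.any(wvp_ex < wvp_in - 1e-12):
        raise ValueError("excurrent WVP below incurrent would imply water uptake")
    fe = wvp_ex / barometric_pressure
    fi = wvp_in / barometric_pressure
    flux = flow_rate * (fe - fi) / (1.0 - fe)  # ml min^-1
    out = np.maximum(flux, 0.0) * WATER_VAPOR_DENSITY_STP * 60.0
    return float(out) if out.ndim == 0 else out


def _catmull_rom(tk: np.ndarray, pk: np.ndarray):
    """Catmull-Rom interpolant through anchor points, linear outside.

    Tangents are centered differences at interior anchors and one-sided
    differences at the ends; with two anchors the curve degenerates to
    the straight line through them.
    """
    tk = np.asarray(tk, dtype=float)
    pk = np.asarray(pk, dtype=float)
    if tk.size == 1:
        c = float(pk[0])
        return lambda t: np.full(np.shape(t), c, dtype=float)
    m = np.empty_like(pk)
    m[0] = (pk[1] - pk[0]) / (tk[1] - tk[0])
    m[-1] = (pk[-1] - pk[-2]) / (tk[-1] - tk[-2])
    if tk.size > 2:
        m[1:-1] = (pk[2:] - pk[:-2]) / (tk[2:] - tk[:-2])
    spline = CubicHermiteSpline(tk, pk, m)

    def evaluate(t):
        t = np.asarray(t, dtype=float)
        out = spline(np.clip(t, tk[0], tk[-1]))
        below = t < tk[0]
        above = t > tk[-1]
        if np.any(below):
            out = np.where(below, pk[0] + m[0] * (t - tk[0]), out)
        if np.any(above):
            out = np.where(above, pk[-1] + m[-1] * (t - tk[-1]), out)
        return out

    return evaluate


def baseline_anchors(trace: RespirometryTrace, signal: np.ndarray,
                     trim: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Anchor points (midpoint time, trimmed mean) of each baseline segment.

    The central ``1 - 2*trim`` fraction of each segment (in time) is
    averaged, discarding the edges where multiplexer switching artifacts
    live.
    """
    times, values = [], []
    for seg in np.unique(trace.segment_id[trace.is_baseline]):
        mask = (trace.segment_id == seg) & trace.is_baseline
        t = trace.time[mask]
        v = signal[mask]
        n = t.size
        lo = int(np.floor(n * trim))
        hi = n - lo
        times.append(0.5 * (t[0] + t[-1]))
        values.append(float(np.mean(v[lo:hi])))
    return np.asarray(times), np.asarray(values)


def drift_correct(trace: RespirometryTrace, trim: float = 0.1) -> RespirometryTrace:
    """Remove analyzer drift using a spline through the baseline segments.

    For each analyte a Catmull-Rom spline is passed through the baseline
    anchor points and subtracted from the whole signal; the nominal
    incurrent value (``fio2`` for O2, ``incurrent_wvp`` for water) is
    added back so corrected baseline segments read the nominal values.
    With a single baseline segment a constant offset correction is used
    (and logged).
    """
    n_baselines = np.unique(trace.segment_id[trace.is_baseline]).size
    if n_baselines == 0:
        raise ValueError("trace has no baseline segments")
    if n_baselines == 1:
        logger.warning("single baseline segment: falling back to constant "
                       "offset drift correction")
    tk_o2, pk_o2 = baseline_anchors(trace, trace.o2, trim=trim)
    tk_w, pk_w = baseline_anchors(trace, trace.wvp, trim=trim)
    o2 = trace.o2 - _catmull_rom(tk_o2, pk_o2)(trace.time) + trace.fio2
    wvp = trace.wvp - _catmull_rom(tk_w, pk_w)(trace.time) + trace.incurrent_wvp
    flags = list(trace.flags)
    if n_baselines == 1:
        flags.append("single_baseline_offset_correction")
    return replace(trace, o2=o2, wvp=np.maximum(wvp, 0.0), flags=flags)


def lowest_stable_window(series: np.ndarray, duration: float = 120.0,
                         sample_interval: float = 1.0,
                         stability_frac: float = 0.05) -> WindowResult:
    """Locate the lowest stable window of a rate time series.

    Among all contiguous windows of ``duration`` seconds whose internal
    SD is at most ``stability_frac`` times the window mean, the one with
    the minimal mean is returned (earliest start on ties).  If no window
    qualifies as stable, the minimal-SD window is returned with
    ``stable=False``.
    """
    series = np.asarray(series, dtype=float)
    w = int(round(duration / sample_interval))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if series.size < w:
        raise ValueError(
            f"series of {series.size} samples shorter than the "
            f"{w}-sample window"
        )
    means, sds = _rolling_mean_sd(series, w)
    stable = sds <= stability_frac * np.abs(means)
    if np.any(stable):
        candidates = np.where(stable)[0]
        best = candidates[np.argmin(means[candidates])]
        return WindowResult(int(best), float(means[best]), float(sds[best]), True)
    best = int(np.argmin(sds))
    return WindowResult(best, float(means[best]), float(sds[best]), False)


def _rolling_mean_sd(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    means = s1 / w
    var = np.maximum(s2 / w - means * means, 0.0)
    return means, np.sqrt(var)


def reduce_trace(trace: RespirometryTrace, duration: float = 120.0,
                 equilibration_taus: float = 5.0,
                 stability_frac: float = 0.05,
                 rq: float = DEFAULT_RQ,
                 drift_corrected: bool = False) -> SteadyStateMeasure:
    """Reduce a trace to one steady-state VO2/EWL measurement.

    Applies :func:`drift_correct` (unless told the trace already is),
    discards all animal samples earlier than ``equilibration_taus``
    chamber time constants after the start of exposure (the chamber is
    flushed continuously from the moment the bird is sealed in, so the
    washout clock runs from the trace start regardless of which channel
    the multiplexer is reading), computes instantaneous VO2 and EWL for
    the remaining animal samples, and averages both over the lowest
    stable window of the VO2 series.
    """
    corrected = trace if drift_corrected else drift_correct(trace)
    tau = corrected.washout_tau
    t0 = corrected.time[0] + equilibration_taus * tau
    mask = ~corrected.is_baseline & (corrected.time >= t0)
    flags = list(corrected.flags)
    dt = corrected.sample_interval
    needed = int(round(duration / dt))
    if mask.sum() < needed:
        raise ValueError(
            "fewer than one stable-window's worth of equilibrated animal "
            f"samples ({int(mask.sum())} < {needed}); lengthen the animal "
            "segments or lower equilibration_taus"
        )
    t = corrected.time[mask]
    depletion = np.maximum(corrected.fio2 - corrected.o2[mask], 0.0)
    vo2_series = corrected.flow_rate * depletion / (
        1.0 - corrected.fio2 * (1.0 - rq))
    fe = np.clip(corrected.wvp[mask], 0.0, None) / corrected.barometric_pressure
    fi = corrected.incurrent_wvp / corrected.barometric_pressure
    flux = corrected.flow_rate * np.maximum(fe - fi, 0.0) / (1.0 - fe)
    ewl_series = flux * WATER_VAPOR_DENSITY_STP * 60.0

    window = lowest_stable_window(vo2_series, duration=duration,
                                  sample_interval=dt,
                                  stability_frac=stability_frac)
    if not window.stable:
        flags.append("no_stable_window")
    i0 = window.start_index
    i1 = i0 + needed
    return SteadyStateMeasure(
        individual_id=corrected.individual_id,
        ta=corrected.ta,
        vo2=float(np.mean(vo2_series[i0:i1])),
        ewl=float(np.mean(ewl_series[i0:i1])),
        window_start=float(t[i0]),
        window_end=float(t[i1 - 1]),
        window_sd=window.sd,
        flags=flags,
    )
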