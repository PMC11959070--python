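"""Blood-pressure landmarks and foot-to-foot pulse transit time.

The carotid-femoral pulse wave velocity (cfPWV) is the field's standard
arterial-stiffness marker: the wave-travel distance between the carotid
and femoral sites divided by the pulse transit time. The transit time is
measured with the intersecting-tangent method: the foot of each pulse is
the intersection of the tangent at the steepest point of the systolic
upstroke with the horizontal line through the preceding diastolic
minimum. Both constructions are affine-covariant in pressure and
equivariant under time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d


class WaveformError(ValueError):
    """Raised for waveforms that violate an extraction precondition."""


@dataclass
class PressureWaveform:
    """Uniformly sampled pressure trace spanning whole cardiac cycles."""

    time: np.ndarray
    pressure: np.ndarray
    period: float
    n_cycles: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.shape != self.pressure.shape or self.time.ndim != 1:
            raise WaveformError("time and pressure must be equal-length 1-D")
        if len(self.time) < 4:
            raise WaveformError("waveform too short")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise WaveformError("sampling must be uniform")
        if not (np.isfinite(self.pressure).all() and np.isfinite(self.time).all()):
            raise WaveformError("waveform contains non-finite values")
        if self.period <= 0 or self.n_cycles < 1:
            raise WaveformError("period must be positive, n_cycles >= 1")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    def cycle_slice(self, index: int) -> slice:
        spc = self.samples_per_cycle
        if not 0 <= index < self.n_cycles:
            raise WaveformError(
                f"cycle index {index} outside 0..{self.n_cycles - 1}"
            )
        start = index * spc
        stop = min(start + spc, len(self.time))
        if stop - start < 4:
            raise WaveformError(f"cycle {index} has too few samples")
        return slice(start, stop)


@dataclass(frozen=True)
class BPFeatures:
    """Systolic/diastolic/pulse/mean pressure of one cycle (mmHg)."""

    sbp: float
    dbp: float
    pp: float
    map: float


@dataclass
class TransitResult:
    """Per-cycle foot times at two sites and their mean difference (s)."""

    proximal_feet: np.ndarray
    distal_feet: np.ndarray
    delta_t: np.ndarray
    valid: np.ndarray
    mean_delta_t: float
    n_cycles_used: int


def extract_bp_features(wave: PressureWaveform) -> BPFeatures:
    """SBP = max, DBP = min, PP = SBP-DBP, MAP = time-average, all over
    the final complete cycle."""
    sl = wave.cycle_slice(wave.n_cycles - 1)
    p = wave.pressure[sl]
    sbp = float(p.max())
    dbp = float(p.min())
    return BPFeatures(sbp=sbp, dbp=dbp, pp=sbp - dbp, map=float(p.mean()))


def detect_foot_intersecting_tangent(
    wave: PressureWaveform,
    cycle_index: int = 0,
    slope_window: int = 5,
) -> float:
    """Pulse-foot time (s) by the intersecting-tangent construction.

    The steepest-upstroke point is located between the cycle's diastolic
    minimum and its systolic peak (excluding the dicrotic limb); its
    tangent is intersected with the horizontal through the minimum. The
    slope is a centred finite difference smoothed over ``slope_window``
    samples.
    """
    sl = wave.cycle_slice(cycle_index)
    t = wave.time[sl]
    p = wave.pressure[sl]
    dpdt = np.gradient(p, wave.dt)
    if slope_window > 1:
        dpdt = uniform_filter1d(dpdt, size=slope_window, mode="nearest")
    # the systolic upstroke is the steepest rise of the cycle; taking its
    # global maximum (rather than bracketing between cycle min and max)
    # is robust to post-pulse undershoots and dicrotic-limb slopes
    k = int(np.argmax(dpdt))
    slope = dpdt[k]
    if slope <= 0:
        raise WaveformError("non-positive maximum upstroke slope")
    if k < 1:
        raise WaveformError("upstroke starts at the cycle boundary")
    # diastolic minimum preceding the upstroke
    i_min = int(np.argmin(p[: k + 1]))
    p_min = p[i_min]
    return float(t[k] - (p[k] - p_min) / slope)


def transit_time(
    proximal: PressureWaveform,
    distal: PressureWaveform,
    min_cycles: int = 10,
    slope_window: int = 5,
) -> TransitResult:
    """Foot-to-foot pulse transit time averaged over cardiac cycles.

    Per cycle, delta_t = foot(distal) - foot(proximal), wrapped into
    (0, period) so the distal foot is paired with the proximal upstroke
    that produced it. Cycles whose wrapped delay collapses to ~0 are
    flagged invalid; at least one valid cycle is required, and fewer than
    ``min_cycles`` complete cycles in either trace is an error.
    """
    if abs(proximal.period - distal.period) > 1e-9:
        raise WaveformError("waveforms have different cycle lengths")
    if abs(proximal.dt - distal.dt) > 1e-12:
        raise WaveformError("waveforms have different sampling grids")
    n = min(proximal.n_cycles, distal.n_cycles)
    if n < min_cycles:
        raise WaveformError(
            f"need at least {min_cycles} complete cycles, have {n}"
        )
    period = proximal.period
    feet_p = np.empty(n)
    feet_d = np.empty(n)
    delta = np.empty(n)
    valid = np.ones(n, dtype=bool)
    eps = proximal.dt  # delays within one sample of zero are degenerate
    for k in range(n):
        feet_p[k] = detect_foot_intersecting_tangent(proximal, k, slope_window)
        feet_d[k] = detect_foot_intersecting_tangent(distal, k, slope_window)
        raw = feet_d[k] - feet_p[k]
        if abs(raw) < eps or abs(abs(raw) - period) < eps:
            valid[k] = False
            delta[k] = np.nan
            continue
        delta[k] = raw % period
    if not valid.any():
        raise WaveformError("no cycle yielded a usable transit time")
    mean_dt = float(np.nanmean(delta[valid]))
    return TransitResult(
        proximal_feet=feet_p,
        distal_feet=feet_d,
        delta_t=delta,
        valid=valid,
        mean_delta_t=mean_dt,
        n_cycles_used=int(valid.sum()),
    )


def segment_cycles(
    time: np.ndarray,
    pressure: np.ndarray,
    min_period: float = 0.3,
) -> PressureWaveform:
    """Build a cycle-segmented waveform from an imported trace.

    The cycle length is taken as the median spacing of the diastolic
    minima (prominent troughs at least ``min_period`` apart), and the
    trace is cropped to whole cycles starting at the first minimum. Use
    this for device exports whose period is not known a priori; simulated
    waveforms already carry their period.
    """
    from scipy.signal import find_peaks

    time = np.asarray(time, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if len(time) < 8:
        raise WaveformError("trace too short to segment")
    dt = time[1] - time[0]
    prominence = 0.25 * (pressure.max() - pressure.min())
    troughs, _ = find_peaks(
        -pressure, distance=max(2, int(min_period / dt)),
        prominence=prominence,
    )
    if len(troughs) < 2:
        raise WaveformError("fewer than two diastolic minima found")
    period = float(np.median(np.diff(troughs))) * dt
    start = troughs[0]
    n_cycles = int((len(time) - start) * dt / period)
    if n_cycles < 1:
        raise WaveformError("no complete cycle after the first minimum")
    stop = start + int(round(n_cycles * period / dt))
    return PressureWaveform(
        time[start:stop] - time[start], pressure[start:stop],
        period, n_cycles,
    )


def write_waveform_csv(wave: PressureWaveform, path) -> None:
    """Write a waveform as CSV (time_s, pressure_mmHg) with the sampling
    rate and period recorded in header comments."""
    header = (
        f"# sampling_rate_hz: {1.0 / wave.dt:.6f}\n"
        f"# period_s: {wave.period:.9f}\n"
        f"# n_cycles: {wave.n_cycles}\n"
        "time_s,pressure_mmHg\n"
    )
    body = "\n".join(
        f"{t:.6f},{p:.6f}" for t, p in zip(wave.time, wave.pressure)
    )
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def read_waveform_csv(path) -> PressureWaveform:
    """Read a waveform written by :func:`write_waveform_csv`; traces
    without the period comment are segmented from their minima."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = np.genfromtxt(fh, delimiter=",", names=True)
    time = np.asarray(data["time_s"], dtype=float)
    pressure = np.asarray(data["pressure_mmHg"], dtype=float)
    if "period_s" in meta:
        n_cycles = int(meta.get("n_cycles", 1))
        return PressureWaveform(time, pressure, meta["period_s"], n_cycles)
    return segment_cycles(time, pressure)


def cfpwv(path_length: float, delta_t: float) -> float:
    """Pulse wave velocity (m/s) = travel distance (m) / transit time (s)."""
    if path_length <= 0 or delta_t <= 0:
        raise ValueError("path_length and delta_t must be positive")
    return path_length / delta_t


def clinical_path_length(surface_distance: float, correction: float = 0.8) -> float:
    """Wave-travel distance (m) from a body-surface carotid-femoral
    distance, using the standard 0.8 shortening correction for the
    over-estimation of the true arterial path by surface tape measure."""
    if surface_distance <= 0:
        raise ValueError("surface_distance must be positive")
    return surface_distance * correction
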