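"""Aortic inflow boundary waveforms.

The proximal boundary condition of the network is a prescribed aortic
flow wave: zero diastolic flow and a systolic ejection lobe of duration
ET whose time integral over one period equals the stroke volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SHAPES = ("half_sine", "constant")


@dataclass
class InflowWave:
    """One period of aortic inflow.

    ``samples`` holds flow in mL/s on a uniform grid spanning one period
    (t = 0 inclusive to period exclusive); the solver resamples it onto
    its own time grid by linear interpolation with periodic wrap.
    """

    stroke_volume: float
    heart_rate: float
    ejection_time: float
    shape: str = "half_sine"
    samples: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def flow_at(self, t: np.ndarray | float) -> np.ndarray:
        """Flow (mL/s) at times t (s), periodic."""
        tt = np.atleast_1d(np.asarray(t, dtype=float)) % self.period
        n = len(self.samples)
        grid = np.arange(n) * (self.period / n)
        # wrap-around point for periodic interpolation
        out = np.interp(tt, np.append(grid, self.period),
                        np.append(self.samples, self.samples[0]))
        return out if np.ndim(t) else float(out[0])

    def volume(self) -> float:
        """Integral of flow over one period (mL), trapezoid with wrap."""
        n = len(self.samples)
        dt = self.period / n
        closed = np.append(self.samples, self.samples[0])
        return float(np.trapezoid(closed, dx=dt))


def synthesize_inflow(
    stroke_volume: float,
    heart_rate: float,
    ejection_time: float,
    shape: str = "half_sine",
    n_samples: int = 2000,
) -> InflowWave:
    """Build an inflow wave with a systolic lobe of duration ET whose
    period integral equals the stroke volume.

    For the default half-sine shape the peak flow is SV*pi/(2*ET) mL/s.
    The "constant" shape ignores ET and spreads the stroke volume over
    the whole period (steady flow), which is useful for steady-state
    checks rather than physiology.
    """
    if stroke_volume <= 0:
        raise ValueError("stroke_volume must be positive")
    if not 20.0 <= heart_rate <= 220.0:
        raise ValueError("heart_rate outside the supported 20-220 bpm range")
    period = 60.0 / heart_rate
    if shape not in _SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {_SHAPES}")
    if shape != "constant" and not 0.0 < ejection_time < period:
        raise ValueError(
            f"ejection_time {ejection_time} must lie in (0, period={period:.3f})"
        )
    t = np.arange(n_samples) * (period / n_samples)
    if shape == "half_sine":
        peak = stroke_volume * np.pi / (2.0 * ejection_time)
        q = np.where(t < ejection_time,
                     peak * np.sin(np.pi * t / ejection_time), 0.0)
    else:  # constant
        q = np.full(n_samples, stroke_volume / period)
    return InflowWave(
        stroke_volume=stroke_volume,
        heart_rate=heart_rate,
        ejection_time=ejection_time,
        shape=shape,
        samples=q,
    )
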