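"""Python-facing wrapper around the compiled 1-D network solver.

Flattens an :class:`ArterialTree` into the array layout the kernel
expects, chooses a CFL-limited time step, runs cardiac cycles until the
root pressure is periodic, and returns clinically-scaled waveforms at
the tree's named sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import units
from . import _kernels
from .inflow import InflowWave
from .tree import ArterialTree, BloodProperties


class SolverError(RuntimeError):
    """Numerical failure (blow-up or boundary Newton divergence)."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the 1-D solver.

    cfl: Courant number relative to the fastest estimated wave speed.
    dx_target: grid spacing target (cm) for segments without an explicit
        grid-point count.
    max_cycles / periodicity_tolerance: the run stops once the
    cycle-to-cycle maximum change of root pressure, relative to its
    magnitude, drops below the tolerance.
    friction_coefficient: k_f in the Poiseuille-type momentum sink
        -k_f pi nu Q/A (k_f = 8 is a parabolic profile; flatter
        physiological profiles warrant larger values).
    """

    cfl: float = 0.8
    dx_target: float = 2.0
    max_cycles: int = 30
    periodicity_tolerance: float = 1e-3
    friction_coefficient: float = 22.0
    junction_rule: str = "pressure_continuity"

    def __post_init__(self) -> None:
        if not 0.0 < self.cfl <= 0.95:
            raise ValueError("cfl must be in (0, 0.95]")
        if self.periodicity_tolerance <= 0:
            raise ValueError("periodicity_tolerance must be positive")
        if self.junction_rule != "pressure_continuity":
            raise ValueError(
                "only the 'pressure_continuity' junction rule is implemented"
            )


@dataclass
class SimulationResult:
    """Waveforms over the final simulated cycle at every named site.

    time is in seconds (one cycle, starting at the cycle phase of the
    inflow wave), pressures in mmHg, flows in mL/s.
    """

    time: np.ndarray
    pressure: dict[str, np.ndarray]
    flow: dict[str, np.ndarray]
    converged: bool
    cycles_used: int
    period: float
    # volume balance over the final cycle (mL)
    inflow_volume: float = 0.0
    outflow_volume: float = 0.0
    storage_change: float = 0.0
    sites: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, site, pressure_mmHg, flow_ml_s."""
        rows = []
        for site in self.sites:
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "site": site,
                        "pressure_mmHg": self.pressure[site],
                        "flow_ml_s": self.flow[site],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _grid_points(length_cm: float, explicit: int | None, dx_target: float) -> int:
    if explicit is not None:
        return explicit
    return max(3, int(round(length_cm / dx_target)) + 1)


def solve(
    tree: ArterialTree,
    inflow: InflowWave,
    blood: BloodProperties | None = None,
    config: SolverConfig | None = None,
    extra_sites: dict[str, tuple[str, float]] | None = None,
) -> SimulationResult:
    """Run the 1-D pulse-wave simulation on a validated tree.

    Raises :class:`SolverError` on numerical blow-up; a run that merely
    fails to reach periodicity within ``max_cycles`` is returned with
    ``converged=False``.
    """
    blood = blood or tree.blood
    config = config or SolverConfig()
    tree.validate()

    # breadth-first ordering with the root segment first
    order = [tree.root]
    for name in order:
        order.extend(tree.topology.get(name, []))
    seg_idx = {name: i for i, name in enumerate(order)}

    nseg = len(order)
    seg_n = np.empty(nseg, dtype=np.int64)
    seg_dx = np.empty(nseg)
    seg_first = np.empty(nseg, dtype=np.int64)
    pos = 0
    for i, name in enumerate(order):
        g = tree.segment(name).geometry
        n = _grid_points(g.length, g.n_grid_points, config.dx_target)
        seg_first[i] = pos
        seg_n[i] = n
        seg_dx[i] = g.length * units.CM_TO_M / (n - 1)
        pos += n
    nnode = pos

    Aref = np.empty(nnode)
    dAref_dx = np.empty(nnode)
    Dsi = np.empty(nnode)
    bcoef = np.empty(nnode)
    for i, name in enumerate(order):
        seg = tree.segment(name)
        g, w = seg.geometry, seg.wall
        n = seg_n[i]
        sl = slice(seg_first[i], seg_first[i] + n)
        xi = np.linspace(0.0, 1.0, n)
        d = (g.inlet_diameter + (g.outlet_diameter - g.inlet_diameter) * xi)
        Aref[sl] = np.pi * (d * units.CM_TO_M) ** 2 / 4
        dAref_dx[sl] = np.gradient(Aref[sl], seg_dx[i])
        Dsi[sl] = units.distensibility_to_si(w.distensibility_ref)
        bcoef[sl] = w.nonlinearity_coefficient

    pref_pa = units.mmhg_to_pa(tree.reference_pressure)

    # junction tables
    parents = [name for name in order if tree.topology.get(name)]
    njun = len(parents)
    jparent_end = np.empty(njun, dtype=np.int64)
    jnchild = np.empty(njun, dtype=np.int64)
    jchild_start = np.zeros((max(njun, 1), 3), dtype=np.int64)
    jchild_seg = np.zeros((max(njun, 1), 3), dtype=np.int64)
    for j, name in enumerate(parents):
        children = tree.topology[name]
        if len(children) > 3:
            raise SolverError(
                f"junction at {name!r} has {len(children)} children; max 3"
            )
        i = seg_idx[name]
        jparent_end[j] = seg_first[i] + seg_n[i] - 1
        jnchild[j] = len(children)
        for cidx, c in enumerate(children):
            ci = seg_idx[c]
            jchild_start[j, cidx] = seg_first[ci]
            jchild_seg[j, cidx] = ci

    # terminal tables
    leaves = [name for name in order if name in tree.terminals]
    nterm = len(leaves)
    term_node = np.empty(nterm, dtype=np.int64)
    term_r1 = np.empty(nterm)
    term_r2 = np.empty(nterm)
    term_c = np.empty(nterm)
    term_pout = np.empty(nterm)
    for t, name in enumerate(leaves):
        i = seg_idx[name]
        wk = tree.terminals[name]
        term_node[t] = seg_first[i] + seg_n[i] - 1
        term_r1[t] = units.resistance_to_si(wk.proximal_resistance)
        term_r2[t] = units.resistance_to_si(wk.distal_resistance)
        term_c[t] = units.compliance_to_si(wk.compliance)
        term_pout[t] = units.mmhg_to_pa(wk.outflow_pressure)

    # recording sites
    sites = dict(tree.named_sites)
    if extra_sites:
        sites.update(extra_sites)
    site_names = sorted(sites)
    rec_nodes = np.empty(len(site_names), dtype=np.int64)
    for k, s in enumerate(site_names):
        seg_name, frac = sites[s]
        i = seg_idx[seg_name]
        rec_nodes[k] = seg_first[i] + int(round(frac * (seg_n[i] - 1)))

    # time step from a conservative wave-speed bound (area at 280 mmHg)
    rho = blood.density
    p_hi = units.mmhg_to_pa(280.0)
    c_max = 0.0
    for i in range(nnode):
        if bcoef[i] == 0.0:
            a_hi = Aref[i] * (1.0 + Dsi[i] * (p_hi - pref_pa))
        else:
            a_hi = Aref[i] * (
                1.0
                + np.log1p(bcoef[i] * Dsi[i] * (p_hi - pref_pa)) / bcoef[i]
            )
        c_hi = float(
            _kernels._wave_speed(a_hi, Aref[i], Dsi[i], bcoef[i], rho)
        )
        c_max = max(c_max, c_hi)
    u_margin = 2.5  # m/s advective allowance
    dt_max = config.cfl * seg_dx.min() / (c_max + u_margin)

    period = inflow.period
    nsteps = int(np.ceil(period / dt_max))
    dt = period / nsteps

    t_grid = np.arange(nsteps) * dt
    qin = inflow.flow_at(t_grid) * units.ML_TO_M3  # m^3/s

    (P_rec, Q_rec, _root_P, cycles_used, converged, err_code,
     vol_in, vol_out, d_storage, _pc) = _kernels.run_simulation(
        seg_first, seg_n, seg_dx,
        Aref, dAref_dx, Dsi, bcoef,
        pref_pa, rho, blood.viscosity / rho, config.friction_coefficient,
        dt, nsteps, qin,
        jparent_end, jnchild, jchild_start, jchild_seg,
        term_node, term_r1, term_r2, term_c, term_pout,
        rec_nodes,
        config.max_cycles, config.periodicity_tolerance,
    )

    if err_code == _kernels.ERR_NAN:
        raise SolverError(
            f"solution blew up during cycle {cycles_used + 1} "
            f"(dt={dt:.2e} s); check CFL/geometry"
        )
    if err_code == _kernels.ERR_NEWTON:
        raise SolverError(
            f"boundary Newton iteration diverged during cycle "
            f"{cycles_used + 1} (dt={dt:.2e} s)"
        )

    pressure = {
        s: P_rec[k] * units.PA_TO_MMHG for k, s in enumerate(site_names)
    }
    flow = {s: Q_rec[k] * units.M3_TO_ML for k, s in enumerate(site_names)}
    return SimulationResult(
        time=t_grid + dt,  # states are recorded at the end of each step
        pressure=pressure,
        flow=flow,
        converged=bool(converged),
        cycles_used=int(cycles_used),
        period=period,
        inflow_volume=vol_in * units.M3_TO_ML,
        outflow_volume=vol_out * units.M3_TO_ML,
        storage_change=d_storage * units.M3_TO_ML,
        sites=site_names,
    )
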