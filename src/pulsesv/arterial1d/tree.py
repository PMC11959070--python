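"""Arterial-network description: segment geometry, wall laws, Windkessel
terminals and the rooted-tree topology that the 1-D solver integrates.

External units are clinical: lengths and diameters in cm, pressures in
mmHg, distensibility in 10^-3/mmHg, resistances in mmHg*s/mL, compliances
in mL/mmHg. Path lengths between named sites are reported in metres, the
unit in which pulse-wave velocities are expressed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from ..units import CM_TO_M


class TreeValidationError(ValueError):
    """Raised when a tree configuration violates a structural invariant."""


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties: density (kg/m^3) and dynamic viscosity (Pa*s)."""

    density: float = 1050.0
    viscosity: float = 0.004

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood density and viscosity must be positive")


@dataclass(frozen=True)
class SegmentGeometry:
    """Tapered cylindrical segment: length (cm), inlet/outlet diameter (cm).

    The lumen tapers linearly from ``inlet_diameter`` to ``outlet_diameter``.
    ``n_grid_points`` may be None, in which case the solver chooses a grid
    from its target spacing.
    """

    length: float
    inlet_diameter: float
    outlet_diameter: float
    n_grid_points: int | None = None


@dataclass(frozen=True)
class WallLaw:
    """Pressure-area relation of the vessel wall.

    ``distensibility_ref`` is the fractional area change per unit pressure
    (10^-3/mmHg) at ``reference_pressure`` (mmHg). With
    ``nonlinearity_coefficient`` b = 0 the law is linear,
    A(P) = A_ref (1 + D (P - P_ref)); b > 0 gives exponential stiffening
    with the same slope at the reference point.
    """

    distensibility_ref: float
    reference_pressure: float = 90.0
    nonlinearity_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.distensibility_ref <= 0:
            raise ValueError("distensibility_ref must be positive")


@dataclass(frozen=True)
class WindkesselTerminal:
    """Three-element Windkessel closing a truncated artery.

    proximal_resistance/distal_resistance in mmHg*s/mL, compliance in
    mL/mmHg, outflow (venous) pressure in mmHg.
    """

    proximal_resistance: float
    distal_resistance: float
    compliance: float
    outflow_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.proximal_resistance < 0 or self.distal_resistance < 0:
            raise ValueError("Windkessel resistances must be non-negative")
        if self.compliance <= 0:
            raise ValueError("Windkessel compliance must be positive")
        if self.outflow_pressure < 0:
            raise ValueError("Windkessel outflow pressure must be non-negative")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance


@dataclass(frozen=True)
class Segment:
    name: str
    geometry: SegmentGeometry
    wall: WallLaw


@dataclass
class ArterialTree:
    """A validated rooted arterial network.

    ``topology`` maps a parent segment name to its children; every leaf is
    closed by a Windkessel terminal; ``named_sites`` maps measurement names
    (e.g. aortic_root, left_brachial, carotid, femoral) to a
    (segment, fractional position) pair.
    """

    segments: list[Segment]
    topology: dict[str, list[str]]
    root: str
    terminals: dict[str, WindkesselTerminal]
    named_sites: dict[str, tuple[str, float]]
    blood: BloodProperties = field(default_factory=BloodProperties)
    reference_height: float = 180.0
    reference_aortic_distensibility: float = 5.0
    reference_pressure: float = 90.0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------

    def segment(self, name: str) -> Segment:
        try:
            return self._by_name[name]
        except AttributeError:
            self._index()
            return self._by_name[name]

    def _index(self) -> None:
        self._by_name = {s.name: s for s in self.segments}
        parents: dict[str, str] = {}
        for p, children in self.topology.items():
            for c in children:
                parents[c] = p
        self._parent = parents

    def parent_of(self, name: str) -> str | None:
        if not hasattr(self, "_parent"):
            self._index()
        return self._parent.get(name)

    @property
    def leaves(self) -> list[str]:
        return [s.name for s in self.segments if not self.topology.get(s.name)]

    def validate(self) -> None:
        self._index()
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise TreeValidationError("duplicate segment names")
        name_set = set(names)
        for s in self.segments:
            g = s.geometry
            if g.length <= 0:
                raise TreeValidationError(
                    f"segment {s.name!r}: non-positive length {g.length}"
                )
            if g.inlet_diameter <= 0 or g.outlet_diameter <= 0:
                raise TreeValidationError(
                    f"segment {s.name!r}: non-positive diameter"
                )
            if g.n_grid_points is not None and g.n_grid_points < 3:
                raise TreeValidationError(
                    f"segment {s.name!r}: n_grid_points must be >= 3"
                )
        for p, children in self.topology.items():
            if p not in name_set:
                raise TreeValidationError(f"topology parent {p!r} is not a segment")
            for c in children:
                if c not in name_set:
                    raise TreeValidationError(
                        f"topology child {c!r} of {p!r} is not a segment"
                    )
        if self.root not in name_set:
            raise TreeValidationError(f"root {self.root!r} is not a segment")
        if self.parent_of(self.root) is not None:
            raise TreeValidationError("root segment has a parent")
        # reachability + acyclicity from the root
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise TreeValidationError(f"cycle in topology at segment {n!r}")
            seen.add(n)
            stack.extend(self.topology.get(n, []))
        if seen != name_set:
            orphans = sorted(name_set - seen)
            raise TreeValidationError(
                f"segments not reachable from root: {orphans}"
            )
        for leaf in self.leaves:
            if leaf not in self.terminals:
                raise TreeValidationError(
                    f"leaf segment {leaf!r} has no Windkessel terminal"
                )
        for t in self.terminals:
            if t not in name_set:
                raise TreeValidationError(f"terminal on unknown segment {t!r}")
            if self.topology.get(t):
                raise TreeValidationError(
                    f"terminal on non-leaf segment {t!r}"
                )
        for site, (seg, pos) in self.named_sites.items():
            if seg not in name_set:
                raise TreeValidationError(
                    f"site {site!r} references unknown segment {seg!r}"
                )
            if not 0.0 <= pos <= 1.0:
                raise TreeValidationError(
                    f"site {site!r}: position {pos} outside [0, 1]"
                )

    # -- geometry ------------------------------------------------------

    def _root_distance(self, seg: str, pos: float) -> float:
        """Distance (cm) from the tree root to a point on a segment."""
        d = pos * self.segment(seg).geometry.length
        p = self.parent_of(seg)
        while p is not None:
            d += self.segment(p).geometry.length
            seg, p = p, self.parent_of(p)
        return d

    def _ancestors(self, seg: str) -> list[str]:
        chain = [seg]
        p = self.parent_of(seg)
        while p is not None:
            chain.append(p)
            p = self.parent_of(p)
        return chain

    def path_length(self, site_a: str, site_b: str) -> float:
        """Anatomical distance (m) between two named sites along the tree.

        The path runs from each site up to the deepest common ancestor
        segment; this mirrors how carotid-to-femoral wave travel distance
        is accumulated along the arterial axis.
        """
        for s in (site_a, site_b):
            if s not in self.named_sites:
                raise KeyError(f"unknown site {s!r}")
        seg_a, pos_a = self.named_sites[site_a]
        seg_b, pos_b = self.named_sites[site_b]
        anc_a, anc_b = self._ancestors(seg_a), self._ancestors(seg_b)
        common = next(s for s in anc_a if s in set(anc_b))
        da = self._root_distance(seg_a, pos_a)
        db = self._root_distance(seg_b, pos_b)
        dc_in = self._root_distance(common, 0.0)
        dc_out = dc_in + self.segment(common).geometry.length
        if seg_a == common or seg_b == common:
            # one site lies on the common segment: plain difference
            dist = abs(da - db)
        else:
            # both descend from the common segment's outlet junction
            dist = (da - dc_out) + (db - dc_out)
        return dist * CM_TO_M

    # -- transformed copies --------------------------------------------

    def with_scaled(
        self,
        length_factor: float = 1.0,
        diameter_factor: float = 1.0,
        distensibility_factor: float = 1.0,
        resistance_factor: float = 1.0,
    ) -> "ArterialTree":
        """Return a new tree with uniform multiplicative scalings applied.

        Lengths, diameters and segment distensibilities scale per segment;
        terminal compliances follow the distensibility factor and terminal
        resistances (both elements) the resistance factor, so the parallel
        total scales by the same factor.
        """
        if min(length_factor, diameter_factor, distensibility_factor,
               resistance_factor) <= 0:
            raise ValueError("scaling factors must be positive")
        segments = [
            Segment(
                name=s.name,
                geometry=replace(
                    s.geometry,
                    length=s.geometry.length * length_factor,
                    inlet_diameter=s.geometry.inlet_diameter * diameter_factor,
                    outlet_diameter=s.geometry.outlet_diameter * diameter_factor,
                ),
                wall=replace(
                    s.wall,
                    distensibility_ref=s.wall.distensibility_ref
                    * distensibility_factor,
                ),
            )
            for s in self.segments
        ]
        terminals = {
            name: replace(
                t,
                proximal_resistance=t.proximal_resistance * resistance_factor,
                distal_resistance=t.distal_resistance * resistance_factor,
                compliance=t.compliance * distensibility_factor,
            )
            for name, t in self.terminals.items()
        }
        return ArterialTree(
            segments=segments,
            topology=copy.deepcopy(self.topology),
            root=self.root,
            terminals=terminals,
            named_sites=dict(self.named_sites),
            blood=self.blood,
            reference_height=self.reference_height,
            reference_aortic_distensibility=self.reference_aortic_distensibility,
            reference_pressure=self.reference_pressure,
        )

    def total_peripheral_resistance(self) -> float:
        """Parallel combination of all terminal total resistances (mmHg*s/mL)."""
        g = sum(1.0 / t.total_resistance for t in self.terminals.values())
        return 1.0 / g


def default_tree_path() -> Path:
    return Path(__file__).resolve().parent.parent / "data" / "default_tree.yaml"


def build_tree(geometry_config: dict | str | Path | None = None) -> ArterialTree:
    """Construct and validate an :class:`ArterialTree` from a config.

    ``geometry_config`` may be a parsed mapping, a path to a YAML document,
    or None for the packaged reduced systemic tree (aortic root to femoral,
    with carotid and brachial branches).
    """
    if geometry_config is None:
        geometry_config = default_tree_path()
    if isinstance(geometry_config, (str, Path)):
        with open(geometry_config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = geometry_config

    ref = cfg.get("reference", {})
    blood_cfg = cfg.get("blood", {})
    ref_pressure = float(ref.get("pressure_mmhg", 90.0))

    segments = []
    for s in cfg["segments"]:
        segments.append(
            Segment(
                name=s["name"],
                geometry=SegmentGeometry(
                    length=float(s["length"]),
                    inlet_diameter=float(s["din"]),
                    outlet_diameter=float(s["dout"]),
                    n_grid_points=s.get("n_grid_points"),
                ),
                wall=WallLaw(
                    distensibility_ref=float(s["distensibility"]),
                    reference_pressure=float(
                        s.get("reference_pressure", ref_pressure)
                    ),
                    nonlinearity_coefficient=float(s.get("nonlinearity", 0.0)),
                ),
            )
        )
    terminals = {
        name: WindkesselTerminal(
            proximal_resistance=float(t["r1"]),
            distal_resistance=float(t["r2"]),
            compliance=float(t["compliance"]),
            outflow_pressure=float(t.get("pout", 0.0)),
        )
        for name, t in cfg.get("terminals", {}).items()
    }
    sites = {
        name: (s["segment"], float(s["position"]))
        for name, s in cfg.get("sites", {}).items()
    }
    return ArterialTree(
        segments=segments,
        topology={k: list(v) for k, v in cfg.get("topology", {}).items()},
        root=cfg["root"],
        terminals=terminals,
        named_sites=sites,
        blood=BloodProperties(
            density=float(blood_cfg.get("density", 1050.0)),
            viscosity=float(blood_cfg.get("viscosity", 0.004)),
        ),
        reference_height=float(ref.get("height_cm", 180.0)),
        reference_aortic_distensibility=float(
            ref.get("aortic_distensibility", 5.0)
        ),
        reference_pressure=ref_pressure,
    )
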