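"""Arterial-tree data model, file I/O and parameter scaling.

The systemic arterial tree is represented as a rooted binary tree of
elastic segments (cylindrical vessels).  Each segment carries the
geometry and wall elasticity needed by the transmission-line equations
(length, inner radius, wall thickness, Young's modulus); every terminal
segment is closed by a three-element Windkessel load standing in for the
downstream vascular bed.

Units follow the conventions of the arterial-modelling literature:
geometry in cm, Young's modulus in Pa, vascular resistances in
Pa·s·m^-5 (SI volumetric impedance) and compliances in m^5·Pa^-1.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

__all__ = [
    "HemodynamicConstants",
    "WindkesselLoad",
    "ArterialSegment",
    "ArterialTree",
    "ScaleFactors",
    "TreeValidationError",
    "load_tree",
    "write_tree",
    "scale_tree",
    "path_length",
    "reference_tree",
]

#: names every full-tree fixture is expected to resolve
STANDARD_SITES = (
    "ascending_aorta",
    "carotid",
    "brachial",
    "radial",
    "femoral",
    "tibial",
)

# Default site placement on the vendored reference tree: the distal end
# of the named artery (ascending aorta is measured at its inlet, where
# the flow source is applied).
_REFERENCE_SITES: dict[str, tuple[str, float]] = {
    "ascending_aorta": ("ascending aorta", 0.0),
    "carotid": ("R. common carotid", 1.0),
    "brachial": ("R. subclavian B (brachial)", 1.0),
    "radial": ("R. radial", 1.0),
    "femoral": ("R. femoral", 1.0),
    "tibial": ("R. anterior tibial", 1.0),
}


class TreeValidationError(ValueError):
    """Raised when a segment table violates the tree invariants."""


@dataclass(frozen=True)
class HemodynamicConstants:
    """Blood and wall constants entering the transmission-line equations.

    Parameters
    ----------
    rho
        Blood density in g/cm^3.
    nu
        Kinematic viscosity of blood in cm^2/s (0.04 P dynamic
        viscosity at rho = 1.05 gives 0.0381).
    sigma
        Poisson's ratio of the arterial wall (0.5 = incompressible).
    phi
        Wall viscoelastic phase angle in radians.  0 models a purely
        elastic wall; a callable ``phi(omega)`` may be supplied for a
        frequency-dependent loss angle.
    """

    rho: float = 1.05
    nu: float = 0.0381
    sigma: float = 0.5
    phi: float | Callable[[float], float] = 0.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.nu <= 0:
            raise ValueError("rho and nu must be positive")
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError("sigma must lie in [0, 1)")
        if not callable(self.phi) and self.phi < 0:
            raise ValueError("phi must be non-negative")

    def phi_at(self, omega: float) -> float:
        return self.phi(omega) if callable(self.phi) else self.phi

    @property
    def rho_si(self) -> float:
        """Blood density in kg/m^3."""
        return self.rho * 1000.0

    @property
    def nu_si(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return self.nu * 1e-4


@dataclass(frozen=True)
class WindkesselLoad:
    """Three-element Windkessel terminal load.

    ``R1`` is the proximal (high-frequency) resistor, ``R0`` the distal
    resistor, ``Cp`` the load compliance; Z(w) = R1 + R0/(1 + jw R0 Cp).
    Resistances in Pa·s·m^-5, compliance in m^5·Pa^-1.
    """

    R1: float
    R0: float
    Cp: float

    def __post_init__(self) -> None:
        if min(self.R1, self.R0, self.Cp) <= 0:
            raise ValueError("Windkessel parameters must be strictly positive")


@dataclass(frozen=True)
class ArterialSegment:
    """One cylindrical vessel of the tree.

    Geometry in cm, Young's modulus in Pa.  ``children`` holds the ids
    of 0, 1 or 2 daughter segments; a terminal load is present exactly
    when the segment has no daughters.
    """

    id: int
    name: str
    length: float
    radius: float
    thickness: float
    young_modulus: float
    children: tuple[int, ...] = ()
    terminal_load: WindkesselLoad | None = None
    elastic_class: str = ""

    def __post_init__(self) -> None:
        for attr in ("length", "radius", "thickness", "young_modulus"):
            if not getattr(self, attr) > 0:
                raise TreeValidationError(
                    f"segment {self.id} ({self.name!r}): {attr} must be positive"
                )
        if len(self.children) > 2:
            raise TreeValidationError(
                f"segment {self.id}: more than two daughters"
            )
        if bool(self.children) == (self.terminal_load is not None):
            raise TreeValidationError(
                f"segment {self.id} ({self.name!r}): a terminal load is "
                "required exactly when the segment has no daughters"
            )

    @property
    def diameter(self) -> float:
        """Inner diameter D = 2r in cm."""
        return 2.0 * self.radius


@dataclass(frozen=True)
class ScaleFactors:
    """Global multipliers for the sweep studies.

    ``e_scale`` multiplies every Young's modulus, ``rp_scale`` both
    Windkessel resistors of every terminal load, ``cp_scale`` every load
    compliance.  ``r0_scale`` additionally scales R0 alone (used for the
    null experiment in which R1 is held fixed).
    """

    e_scale: float = 1.0
    rp_scale: float = 1.0
    cp_scale: float = 1.0
    r0_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.e_scale, self.rp_scale, self.cp_scale, self.r0_scale) <= 0:
            raise ValueError("scale factors must be strictly positive")

    def inverse(self) -> "ScaleFactors":
        return ScaleFactors(
            1.0 / self.e_scale, 1.0 / self.rp_scale,
            1.0 / self.cp_scale, 1.0 / self.r0_scale,
        )


class ArterialTree:
    """A validated, rooted arterial network.

    Parameters
    ----------
    segments
        Iterable of :class:`ArterialSegment`; ids must be unique and the
        `children` references must form a single connected tree.
    sites
        Mapping from measurement-site name to ``(segment id, position)``
        where position is the fractional distance along the segment
        (0 = proximal end, 1 = distal end).
    """

    def __init__(
        self,
        segments: Iterable[ArterialSegment],
        sites: Mapping[str, tuple[int, float]] | None = None,
    ):
        self.segments: dict[int, ArterialSegment] = {}
        for seg in segments:
            if seg.id in self.segments:
                raise TreeValidationError(f"duplicate segment id {seg.id}")
            self.segments[seg.id] = seg
        if not self.segments:
            raise TreeValidationError("empty segment table")
        self._parent: dict[int, int] = {}
        for seg in self.segments.values():
            for child in seg.children:
                if child not in self.segments:
                    raise TreeValidationError(
                        f"segment {seg.id} references unknown child {child}"
                    )
                if child in self._parent:
                    raise TreeValidationError(
                        f"segment {child} has more than one parent"
                    )
                self._parent[child] = seg.id
        roots = [i for i in self.segments if i not in self._parent]
        if len(roots) != 1:
            raise TreeValidationError(
                f"tree must have exactly one root, found {sorted(roots)}"
            )
        self.root: int = roots[0]
        # connectivity / acyclicity: walk from the root
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            i = stack.pop()
            if i in seen:
                raise TreeValidationError(f"cycle detected at segment {i}")
            seen.add(i)
            stack.extend(self.segments[i].children)
        if seen != set(self.segments):
            orphans = sorted(set(self.segments) - seen)
            raise TreeValidationError(f"orphan segments not reachable: {orphans}")
        self.sites: dict[str, tuple[int, float]] = {}
        for name, (seg_id, pos) in (sites or {}).items():
            if seg_id not in self.segments:
                raise TreeValidationError(
                    f"site {name!r} references unknown segment {seg_id}"
                )
            if not 0.0 <= pos <= 1.0:
                raise TreeValidationError(f"site {name!r}: position outside [0, 1]")
            self.sites[name] = (seg_id, float(pos))

    # -- topology helpers -------------------------------------------------

    def parent(self, seg_id: int) -> int | None:
        return self._parent.get(seg_id)

    @property
    def leaves(self) -> list[int]:
        return [i for i, s in self.segments.items() if not s.children]

    def path_from_root(self, seg_id: int) -> list[int]:
        """Segment ids from the root down to (and including) ``seg_id``."""
        if seg_id not in self.segments:
            raise KeyError(f"unknown segment {seg_id}")
        path = [seg_id]
        while (p := self._parent.get(path[-1])) is not None:
            path.append(p)
        return path[::-1]

    def resolve_site(self, site: str) -> tuple[int, float]:
        try:
            return self.sites[site]
        except KeyError:
            raise KeyError(
                f"unknown site {site!r}; available: {sorted(self.sites)}"
            ) from None

    def postorder(self) -> list[int]:
        """Leaf-to-root evaluation order (every child before its parent)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.segments[i].children)
        return order[::-1]

    def with_sites(self, sites: Mapping[str, tuple[int, float]]) -> "ArterialTree":
        return ArterialTree(self.segments.values(), {**self.sites, **sites})

    def copy(self) -> "ArterialTree":
        return ArterialTree(self.segments.values(), dict(self.sites))

    def __len__(self) -> int:
        return len(self.segments)

    def __repr__(self) -> str:
        return (
            f"ArterialTree({len(self)} segments, {len(self.leaves)} terminal, "
            f"root={self.root}, sites={sorted(self.sites)})"
        )


# -- file I/O -------------------------------------------------------------

_COLUMNS = [
    "id", "name", "parent", "length_cm", "radius_cm", "thickness_cm",
    "elastic_class", "E_Pa", "R1", "R0", "Cp",
]

_UNIT_HEADER = (
    "# units: length_cm,radius_cm,thickness_cm in cm; E_Pa in Pa; "
    "R1,R0 in Pa.s.m^-5; Cp in m^5.Pa^-1; parent=0 marks the root"
)


def _tree_from_frame(
    df: pd.DataFrame, sites: Mapping[str, tuple[str, float]] | None
) -> ArterialTree:
    if df.empty:
        raise TreeValidationError("empty segment table")
    required = {"id", "name", "parent", "length_cm", "radius_cm",
                "thickness_cm", "E_Pa"}
    missing = required - set(df.columns)
    if missing:
        raise TreeValidationError(f"missing columns: {sorted(missing)}")
    children: dict[int, list[int]] = {}
    rows = {}
    for _, row in df.iterrows():
        seg_id = int(row["id"])
        if seg_id in rows:
            raise TreeValidationError(f"duplicate segment id {seg_id}")
        rows[seg_id] = row
        parent = int(row["parent"]) if not pd.isna(row["parent"]) else 0
        if parent:
            children.setdefault(parent, []).append(seg_id)
    for parent in children:
        if parent not in rows:
            raise TreeValidationError(
                f"rows {children[parent]} reference unknown parent {parent}"
            )
    segments = []
    for seg_id, row in rows.items():
        kids = tuple(children.get(seg_id, ()))
        load = None
        if not kids:
            vals = [row.get(k) for k in ("R1", "R0", "Cp")]
            if any(v is None or pd.isna(v) for v in vals):
                raise TreeValidationError(
                    f"terminal segment {seg_id} ({row['name']!r}) has no "
                    "Windkessel load"
                )
            load = WindkesselLoad(*(float(v) for v in vals))
        segments.append(
            ArterialSegment(
                id=seg_id,
                name=str(row["name"]),
                length=float(row["length_cm"]),
                radius=float(row["radius_cm"]),
                thickness=float(row["thickness_cm"]),
                young_modulus=float(row["E_Pa"]),
                children=kids,
                terminal_load=load,
                elastic_class=str(row.get("elastic_class", "") or ""),
            )
        )
    tree = ArterialTree(segments)
    if sites:
        by_name = {s.name: s.id for s in segments}
        resolved = {}
        for site, (seg_name, pos) in sites.items():
            if seg_name in by_name:
                resolved[site] = (by_name[seg_name], pos)
        tree = tree.with_sites(resolved)
    return tree


def load_tree(
    source: str | Path | io.IOBase | pd.DataFrame,
    sites: Mapping[str, tuple[str, float]] | None = None,
) -> ArterialTree:
    """Read a segment-parameter table (CSV or JSON) into a validated tree.

    The CSV header is ``id,name,parent,length_cm,radius_cm,thickness_cm,
    elastic_class,E_Pa,R1,R0,Cp`` (``#`` lines are unit metadata); the
    JSON mirror is a list of row objects with the same keys.  ``sites``
    maps site names to ``(segment name, position)`` pairs; by default the
    standard six sites are attached when the reference segment names are
    present.
    """
    if sites is None:
        sites = _REFERENCE_SITES
    if isinstance(source, pd.DataFrame):
        return _tree_from_frame(source, sites)
    if isinstance(source, (str, Path)) and str(source).endswith(".json"):
        with open(source) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(source, comment="#", float_precision="round_trip")
    return _tree_from_frame(df, sites)


def write_tree(tree: ArterialTree, path: str | Path) -> None:
    """Write a tree back to CSV (or JSON) at full precision."""
    records = []
    for seg_id in sorted(tree.segments):
        seg = tree.segments[seg_id]
        load = seg.terminal_load
        records.append({
            "id": seg.id,
            "name": seg.name,
            "parent": tree.parent(seg.id) or 0,
            "length_cm": seg.length,
            "radius_cm": seg.radius,
            "thickness_cm": seg.thickness,
            "elastic_class": seg.elastic_class,
            "E_Pa": seg.young_modulus,
            "R1": load.R1 if load else None,
            "R0": load.R0 if load else None,
            "Cp": load.Cp if load else None,
        })
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1))
        return
    df = pd.DataFrame.from_records(records, columns=_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_UNIT_HEADER + "\n")
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def reference_tree() -> ArterialTree:
    """The vendored 55-segment human arterial tree.

    Geometry (lengths, radii, wall thicknesses) follows the classical
    55-segment systemic tree of the 1-D modelling literature; Young's
    moduli are grouped into three elasticity classes (4e5 Pa aorta and
    large central arteries, 8e5 Pa medium muscular arteries, 16e5 Pa
    peripheral arteries); Windkessel loads distribute the total
    peripheral resistance over the 28 terminal branches.  See the
    package data file for per-column provenance notes.
    """
    ref = resources.files("pwpsim").joinpath("data/arterial_tree_55.csv")
    with resources.as_file(ref) as path:
        return load_tree(path)


def scale_tree(tree: ArterialTree, factors: ScaleFactors) -> ArterialTree:
    """Return a copy with Young's moduli and terminal loads rescaled.

    ``e_scale`` multiplies every E, ``rp_scale`` every R1 and R0,
    ``cp_scale`` every Cp, ``r0_scale`` every R0 alone.  Geometry and
    topology are untouched; the input tree is not modified.
    """
    segments = []
    for seg in tree.segments.values():
        load = seg.terminal_load
        if load is not None:
            load = WindkesselLoad(
                R1=load.R1 * factors.rp_scale,
                R0=load.R0 * factors.rp_scale * factors.r0_scale,
                Cp=load.Cp * factors.cp_scale,
            )
        segments.append(replace(
            seg, young_modulus=seg.young_modulus * factors.e_scale,
            terminal_load=load,
        ))
    return ArterialTree(segments, dict(tree.sites))


def _root_distance(tree: ArterialTree, site: str) -> float:
    seg_id, pos = tree.resolve_site(site)
    path = tree.path_from_root(seg_id)
    dist = sum(tree.segments[i].length for i in path[:-1])
    return dist + pos * tree.segments[seg_id].length


def path_length(tree: ArterialTree, site_a: str, site_b: str) -> float:
    """Pulse path length between two sites by the heart-path subtraction
    convention: L(root→b) − L(root→a), each a sum of segment lengths
    down the tree plus the within-segment site offset (cm).

    This is the convention used clinically for carotid–femoral and
    brachial–ankle distances; the two sites need not lie on one
    root-to-leaf path.
    """
    return _root_distance(tree, site_b) - _root_distance(tree, site_a)
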