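"""Compartmental cell morphologies: SWC I/O, standardization, morphometry.

A cell is a rooted tree of cylindrical compartments.  The root is always the
soma (a single equivalent cylinder); dendrites branch off the soma, and a
standardized four-region axon (initial segment, narrow segment, sodium-channel
band overlay, distal axon) can be attached so that every cell shares the same
axonal geometry.  Surface areas are lateral cylinder areas (end faces
omitted).  Geometry is purely topological downstream: 3D coordinates are used
only to derive cylinder lengths when reading SWC reconstructions.

Units: lengths and diameters in um, areas in um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable


class Region(str, Enum):
    SOMA = "soma"
    DENDRITE = "dendrite"
    INITIAL_SEGMENT = "initial_segment"
    NARROW_SEGMENT = "narrow_segment"
    DISTAL_AXON = "distal_axon"

    @property
    def is_axonal(self) -> bool:
        return self in (Region.INITIAL_SEGMENT, Region.NARROW_SEGMENT,
                        Region.DISTAL_AXON)


AXONAL_REGIONS = (Region.INITIAL_SEGMENT, Region.NARROW_SEGMENT,
                  Region.DISTAL_AXON)


class MorphologyError(ValueError):
    """Base class for morphology construction problems."""


class SWCParseError(MorphologyError):
    """Malformed SWC content (reports the offending line number)."""


class StructureError(MorphologyError):
    """Broken tree topology (missing parent, multiple roots, cycles)."""


@dataclass
class Compartment:
    """One cylindrical element of membrane.

    ``arc_from_soma`` is the path distance (um) from the soma surface to the
    compartment midpoint, defined only on axonal compartments (``nan``
    elsewhere).  ``in_socb`` marks membership of the sodium-channel band,
    decided by the midpoint arc distance falling in [30, 70) um.
    """
    id: int
    parent_id: int | None
    region: Region
    length: float
    diameter: float
    arc_from_soma: float = math.nan
    in_socb: bool = False

    @property
    def area(self) -> float:
        """Lateral surface area pi*d*L in um^2 (end faces omitted)."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class AxonSpec:
    """Geometry of the standardized four-region axon.

    The sodium-channel band (SOCB) is an overlay spanning the distal part of
    the initial segment and the proximal part of the narrow segment: it starts
    30 um from the soma and extends 40 um.
    """
    initial_segment_length: float = 40.0
    initial_segment_diameter: float | None = None  # defaults to distal diameter
    narrow_length: float = 90.0
    narrow_diameter: float = 0.4
    socb_start: float = 30.0
    socb_length: float = 40.0
    distal_length: float = 5340.0
    distal_diameter: float = 1.0

    def __post_init__(self):
        if self.socb_start + self.socb_length > (
                self.initial_segment_length + self.narrow_length):
            raise ValueError("SOCB must lie within the proximal axon")
        for name in ("initial_segment_length", "narrow_length",
                     "narrow_diameter", "socb_start", "socb_length",
                     "distal_length", "distal_diameter"):
            if getattr(self, name) <= 0 and name != "socb_start":
                raise ValueError(f"{name} must be positive")

    @property
    def resolved_initial_diameter(self) -> float:
        return (self.initial_segment_diameter
                if self.initial_segment_diameter is not None
                else self.distal_diameter)

    @property
    def total_length(self) -> float:
        return (self.initial_segment_length + self.narrow_length
                + self.distal_length)


@dataclass(frozen=True)
class MorphometryReport:
    """Summary statistics of a cell.

    ``S_total`` excludes the axon (soma + dendrites only), so that cells
    sharing the standardized axon are distinguished by their unique geometry.
    """
    S_total: float
    S_soma: float
    S_axon: float
    S_dendrite: float
    D_axon: float
    D_dendrite_mean: float
    R_dend_total: float
    R_soma_total: float
    n_tips: int
    n_bifurcations: int
    mean_dendritic_compartment_length: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class Morphology:
    """Rooted tree of compartments; root is the soma."""

    def __init__(self, compartments: Iterable[Compartment]):
        self.compartments: list[Compartment] = list(compartments)
        self._index = {c.id: c for c in self.compartments}
        if len(self._index) != len(self.compartments):
            raise StructureError("duplicate compartment ids")
        self.validate()

    # -- structure ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.compartments)

    def __getitem__(self, cid: int) -> Compartment:
        return self._index[cid]

    @property
    def root(self) -> Compartment:
        return self._root

    def children(self, cid: int) -> list[Compartment]:
        return self._children.get(cid, [])

    def validate(self) -> None:
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, got {len(roots)}")
        self._root = roots[0]
        if self._root.region is not Region.SOMA:
            raise StructureError("root compartment must be the soma")
        self._children: dict[int, list[Compartment]] = {}
        for c in self.compartments:
            if c.length <= 0 or c.diameter <= 0:
                raise MorphologyError(
                    f"compartment {c.id}: non-positive length or diameter")
            if c.parent_id is not None:
                if c.parent_id not in self._index:
                    raise StructureError(
                        f"compartment {c.id}: parent {c.parent_id} does not exist")
                self._children.setdefault(c.parent_id, []).append(c)
        # connectivity + acyclicity via traversal from the root
        seen = set()
        stack = [self._root.id]
        while stack:
            cid = stack.pop()
            if cid in seen:
                raise StructureError("cycle detected in compartment tree")
            seen.add(cid)
            stack.extend(ch.id for ch in self.children(cid))
        if len(seen) != len(self.compartments):
            raise StructureError("compartment tree is not connected")

    # -- regions -----------------------------------------------------------
    def by_region(self, *regions: Region) -> list[Compartment]:
        return [c for c in self.compartments if c.region in regions]

    @property
    def has_axon(self) -> bool:
        return any(c.region.is_axonal for c in self.compartments)

    def total_area(self) -> float:
        return sum(c.area for c in self.compartments)

    def topological(self) -> list[Compartment]:
        """Compartments in root-first order (every parent before its children)."""
        out = []
        stack = [self._root]
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(reversed(self.children(c.id)))
        return out

    def copy(self) -> "Morphology":
        return Morphology([replace(c) for c in self.compartments])


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_SOMA = 1
_SWC_AXON = 2
_SWC_DEND = (3, 4)  # basal and apical dendrites are not distinguished


def read_swc(path: str | Path) -> Morphology:
    """Read an SWC reconstruction into a compartment tree.

    Each non-soma SWC point becomes a cylinder whose length is the Euclidean
    distance to its parent point and whose diameter is twice the point's own
    radius.  Soma points are collapsed to a single equivalent-lateral-area
    cylinder with aspect ratio L = d (a lone soma point is treated as a sphere
    of that radius, 4*pi*r^2 = pi*d*L with L = d = 2r).  Axonal points are
    assigned to initial/narrow/distal regions by arc distance from the soma
    using the standard axon boundaries.
    """
    path = Path(path)
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                pid = int(cols[0])
                ptype = int(cols[1])
                x, y, z, r = (float(v) for v in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise SWCParseError(f"{path.name}:{lineno}: {exc}") from None
            if r <= 0:
                raise MorphologyError(
                    f"{path.name}:{lineno}: zero or negative radius")
            if pid in points:
                raise SWCParseError(f"{path.name}:{lineno}: duplicate id {pid}")
            points[pid] = (ptype, x, y, z, r, parent)
            order.append(pid)

    if not points:
        raise SWCParseError(f"{path.name}: no data lines")
    roots = [pid for pid in order if points[pid][5] == -1]
    if len(roots) != 1:
        raise StructureError(
            f"{path.name}: expected one root point, got {len(roots)}")
    for pid in order:
        parent = points[pid][5]
        if parent != -1 and parent not in points:
            raise StructureError(
                f"{path.name}: point {pid} references missing parent {parent}")

    soma_ids = [pid for pid in order if points[pid][0] == _SWC_SOMA]
    if not soma_ids:
        raise StructureError(f"{path.name}: no soma point")

    # Collapse soma points to a single L = d cylinder of equal lateral area.
    if len(soma_ids) == 1:
        r = points[soma_ids[0]][4]
        soma_area = 4.0 * math.pi * r * r
    else:
        soma_area = 0.0
        for pid in soma_ids:
            ptype, x, y, z, r, parent = points[pid]
            if parent in points and points[parent][0] == _SWC_SOMA:
                px, py, pz = points[parent][1:4]
                dist = math.dist((x, y, z), (px, py, pz))
                soma_area += math.pi * (2.0 * r) * dist
        if soma_area <= 0:  # contour without usable segments: fall back
            r = max(points[pid][4] for pid in soma_ids)
            soma_area = 4.0 * math.pi * r * r
    soma_d = math.sqrt(soma_area / math.pi)  # pi*d*L = area with L = d

    soma_set = set(soma_ids)
    comps: list[Compartment] = [
        Compartment(id=1, parent_id=None, region=Region.SOMA,
                    length=soma_d, diameter=soma_d)
    ]
    id_map: dict[int, int] = {pid: 1 for pid in soma_set}
    next_id = 2
    # Arc distances for axonal region assignment.
    arcs: dict[int, float] = {pid: 0.0 for pid in soma_set}
    spec = AxonSpec()
    # Traverse parent-first regardless of file ordering.
    kids: dict[int, list[int]] = {}
    for pid in order:
        parent = points[pid][5]
        if parent != -1:
            kids.setdefault(parent, []).append(pid)
    topo: list[int] = []
    stack = [roots[0]]
    while stack:
        pid = stack.pop()
        topo.append(pid)
        stack.extend(reversed(kids.get(pid, [])))
    if len(topo) != len(order):
        raise StructureError(f"{path.name}: point tree is not connected")
    for pid in topo:
        if pid in soma_set:
            continue
        ptype, x, y, z, r, parent = points[pid]
        px, py, pz = points[parent][1:4]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0:
            raise MorphologyError(
                f"{path.name}: point {pid} coincides with its parent")
        parent_arc = arcs.get(parent, 0.0)
        arc_mid = parent_arc + length / 2.0
        arcs[pid] = parent_arc + length
        if ptype == _SWC_AXON:
            if arc_mid < spec.initial_segment_length:
                region = Region.INITIAL_SEGMENT
            elif arc_mid < spec.initial_segment_length + spec.narrow_length:
                region = Region.NARROW_SEGMENT
            else:
                region = Region.DISTAL_AXON
            socb = spec.socb_start <= arc_mid < spec.socb_start + spec.socb_length
            comp = Compartment(id=next_id, parent_id=id_map[parent],
                               region=region, length=length, diameter=2.0 * r,
                               arc_from_soma=arc_mid, in_socb=socb)
        else:
            comp = Compartment(id=next_id, parent_id=id_map[parent],
                               region=Region.DENDRITE, length=length,
                               diameter=2.0 * r)
        comps.append(comp)
        id_map[pid] = next_id
        next_id += 1
    return Morphology(comps)


_GOLDEN_ANGLE = 2.39996322972865332


def _direction(seq: int) -> tuple[float, float, float]:
    # Deterministic, roughly isotropic unit vectors for dendrite layout.
    phi = _GOLDEN_ANGLE * seq
    ct = math.cos(0.9 * seq) * 0.8
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    return (st * math.cos(phi), st * math.sin(phi), ct)


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as SWC, synthesizing 3D coordinates.

    The electrical model is purely topological, so coordinates are laid out
    deterministically: the axon extends along -x, dendrites along a fixed
    quasi-isotropic direction sequence.  Unit direction vectors guarantee that
    ``read_swc`` recovers the cylinder lengths exactly (up to the printed
    precision).
    """
    path = Path(path)
    pos: dict[int, tuple[float, float, float]] = {}
    lines = ["# SWC written by rgcsim (synthetic coordinates)"]
    seq = 0
    for c in morph.topological():
        if c.parent_id is None:
            pos[c.id] = (0.0, 0.0, 0.0)
            lines.append(f"{c.id} 1 0 0 0 {c.diameter / 2.0:.9g} -1")
            continue
        px, py, pz = pos[c.parent_id]
        if c.region.is_axonal:
            d = (-1.0, 0.0, 0.0)
            stype = 2
        else:
            seq += 1
            d = _direction(seq)
            stype = 3
        p = (px + c.length * d[0], py + c.length * d[1], pz + c.length * d[2])
        pos[c.id] = p
        lines.append(
            f"{c.id} {stype} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} "
            f"{c.diameter / 2.0:.9g} {c.parent_id}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Standardized axon
# ---------------------------------------------------------------------------

def attach_standard_axon(morph: Morphology,
                         spec: AxonSpec | None = None) -> Morphology:
    """Replace any pre-existing axon with the standardized four-region axon.

    The chain initial segment -> narrow segment -> distal axon is attached at
    the soma with compartment boundaries pinned at 30, 40, 70 and 130 um so
    the SOCB interval [30, 70) um is exactly representable under any further
    discretization.
    """
    spec = spec or AxonSpec()
    if not any(c.parent_id is None and c.region is Region.SOMA
               for c in morph.compartments):
        raise StructureError("morphology has no soma root")
    # Drop existing axonal compartments (and anything hanging off them).
    drop: set[int] = set()
    ordered = morph.topological()
    for c in ordered:
        if c.region.is_axonal or (c.parent_id in drop):
            drop.add(c.id)
    kept = [replace(c) for c in ordered if c.id not in drop]
    next_id = max(c.id for c in kept) + 1
    soma_id = next(c.id for c in kept if c.parent_id is None)

    d_init = spec.resolved_initial_diameter
    # Boundaries along the axon where compartments must break.
    socb_end = spec.socb_start + spec.socb_length
    is_end = spec.initial_segment_length
    narrow_end = is_end + spec.narrow_length
    cuts = sorted({0.0, spec.socb_start, is_end, socb_end, narrow_end,
                   narrow_end + spec.distal_length})
    parent = soma_id
    new = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = (a + b) / 2.0
        if mid < is_end:
            region, diam = Region.INITIAL_SEGMENT, d_init
        elif mid < narrow_end:
            region, diam = Region.NARROW_SEGMENT, spec.narrow_diameter
        else:
            region, diam = Region.DISTAL_AXON, spec.distal_diameter
        comp = Compartment(
            id=next_id, parent_id=parent, region=region, length=b - a,
            diameter=diam, arc_from_soma=mid,
            in_socb=spec.socb_start <= mid < socb_end)
        new.append(comp)
        parent = next_id
        next_id += 1
    return Morphology(kept + new)


def discretize(morph: Morphology, max_segment_length: float) -> Morphology:
    """Split compartments longer than ``max_segment_length`` into equal parts.

    Diameters (hence total lateral area, exactly) are preserved; axonal region
    and SOCB flags are recomputed from the midpoint arc distance of each
    sub-cylinder.
    """
    if max_segment_length <= 0:
        raise ValueError("max_segment_length must be positive")
    spec = AxonSpec()
    socb_end = spec.socb_start + spec.socb_length
    out: list[Compartment] = []
    next_id = 1
    id_map: dict[int, int] = {}
    for c in morph.topological():
        parent_new = id_map[c.parent_id] if c.parent_id is not None else None
        n = max(1, math.ceil(c.length / max_segment_length - 1e-12))
        sub_len = c.length / n
        arc_start = (c.arc_from_soma - c.length / 2.0
                     if c.region.is_axonal else math.nan)
        prev = parent_new
        for k in range(n):
            mid = (arc_start + (k + 0.5) * sub_len
                   if c.region.is_axonal else math.nan)
            socb = (c.region.is_axonal
                    and spec.socb_start <= mid < socb_end)
            out.append(Compartment(
                id=next_id, parent_id=prev, region=c.region, length=sub_len,
                diameter=c.diameter, arc_from_soma=mid, in_socb=socb))
            prev = next_id
            next_id += 1
        id_map[c.id] = prev  # children of c attach to its last sub-cylinder
    return Morphology(out)


# ---------------------------------------------------------------------------
# Morphometry and perturbations
# ---------------------------------------------------------------------------

def morphometry(morph: Morphology) -> MorphometryReport:
    """Compute the standard summary statistics of a cell.

    Tips are dendritic compartments with no dendritic children; bifurcations
    are dendritic compartments with two or more dendritic children.  The soma
    is never counted as a bifurcation, however many primary dendrites it
    bears.  ``D_dendrite_mean`` is the unweighted mean of dendritic
    compartment diameters; ``D_axon`` is the length-weighted mean axonal
    diameter.
    """
    s_soma = sum(c.area for c in morph.by_region(Region.SOMA))
    dend = morph.by_region(Region.DENDRITE)
    axon = morph.by_region(*AXONAL_REGIONS)
    s_dend = sum(c.area for c in dend)
    s_axon = sum(c.area for c in axon)
    s_total = s_soma + s_dend
    n_tips = 0
    n_bif = 0
    for c in dend:
        nd = sum(1 for ch in morph.children(c.id)
                 if ch.region is Region.DENDRITE)
        if nd == 0:
            n_tips += 1
        elif nd >= 2:
            n_bif += 1
    axon_len = sum(c.length for c in axon)
    return MorphometryReport(
        S_total=s_total,
        S_soma=s_soma,
        S_axon=s_axon,
        S_dendrite=s_dend,
        D_axon=(sum(c.diameter * c.length for c in axon) / axon_len
                if axon else math.nan),
        D_dendrite_mean=(sum(c.diameter for c in dend) / len(dend)
                         if dend else math.nan),
        R_dend_total=s_dend / s_total if s_total else math.nan,
        R_soma_total=s_soma / s_total if s_total else math.nan,
        n_tips=n_tips,
        n_bifurcations=n_bif,
        mean_dendritic_compartment_length=(
            sum(c.length for c in dend) / len(dend) if dend else math.nan),
    )


def scale_morphology(morph: Morphology, target: str,
                     factor: float) -> Morphology:
    """Shrink part of a cell while leaving channel densities untouched.

    ``target`` is one of ``dendrite_diameter`` (every dendritic diameter
    multiplied by ``factor``), ``dendrite_length`` (lengths), or ``soma``
    (both soma diameter and length, so soma area scales by ``factor**2``).
    The axon is never touched.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must be in (0, 1]")
    if target not in ("dendrite_diameter", "dendrite_length", "soma"):
        raise ValueError(f"unknown scaling target {target!r}")
    comps = []
    for c in morph.compartments:
        c = replace(c)
        if target == "dendrite_diameter" and c.region is Region.DENDRITE:
            c.diameter *= factor
        elif target == "dendrite_length" and c.region is Region.DENDRITE:
            c.length *= factor
        elif target == "soma" and c.region is Region.SOMA:
            c.diameter *= factor
            c.length *= factor
        comps.append(c)
    return Morphology(comps)
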