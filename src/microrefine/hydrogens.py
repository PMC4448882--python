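"""Geometric hydrogen placement and the riding model.

Hydrogens on carbon are placed from the heavy-atom geometry (sp¹ linear
continuation, sp² external bisector, sp³ tetrahedral completion with
staggered CH₂/CH₃), then constrained to ride: an H inherits its parent's
positional shifts exactly and its u_iso is re-derived every cycle as a
multiplier × the parent's equivalent isotropic U.  An optional separate
soft-restrained least-squares pass refines only the H positions against
the data before the riding model takes over.

Default target lengths are the conventional small-molecule X-ray values:
0.95 Å for sp¹/sp², 0.98 Å for sp³; u_iso multipliers 1.2 (1.5 for methyl).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .crystal_model import (
    CrystalModel,
    AtomSite,
    Fix,
    Ride,
    build_parameter_map,
    metric_tensors,
    orthogonalization_matrix,
)
from .restraints import Restraint, RestraintSet

__all__ = [
    "HydrogenPlanEntry",
    "place_hydrogens",
    "riding_constraints",
    "restrained_h_cycle",
    "DEFAULT_XH",
]

DEFAULT_XH = {"sp1": 0.95, "sp2": 0.95, "sp3": 0.98}


@dataclass
class HydrogenPlanEntry:
    """Hydrogen recipe for one parent atom."""

    parent: str
    geometry: str  # sp1 | sp2 | sp3
    n_h: int = 1
    bond_length: float | None = None  # Å; None → class default
    uiso_multiplier: float | None = None  # None → 1.2 (1.5 for CH3)
    reference: str | None = None  # substituent fixing CH3 torsion

    def __post_init__(self):
        if self.geometry not in ("sp1", "sp2", "sp3"):
            raise ValueError(f"unknown geometry class {self.geometry!r}")
        if self.bond_length is None:
            self.bond_length = DEFAULT_XH[self.geometry]
        if self.uiso_multiplier is None:
            self.uiso_multiplier = 1.5 if (self.geometry == "sp3" and self.n_h == 3) else 1.2
        if self.uiso_multiplier <= 0:
            raise ValueError("u_iso multiplier must be > 0")


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise ValueError("zero-length direction in hydrogen placement")
    return v / n


def _h_directions(entry: HydrogenPlanEntry, parent_xyz, neighbour_xyz, ref_xyz=None):
    """Unit C→H directions in Cartesian space."""
    vs = [_unit(x - parent_xyz) for x in neighbour_xyz]
    geom, n_h = entry.geometry, entry.n_h
    if geom == "sp1":
        if len(vs) != 1 or n_h != 1:
            raise ValueError("sp1 placement needs exactly one neighbour and one H")
        return [-vs[0]]
    if geom == "sp2":
        if len(vs) == 2 and n_h == 1:
            return [-_unit(vs[0] + vs[1])]  # external bisector, in plane
        if len(vs) == 1 and n_h == 2 and ref_xyz is not None:
            # terminal sp2 CH2: both H in the reference plane at 120°
            axis = vs[0]
            inplane = _unit(ref_xyz - parent_xyz - (np.dot(ref_xyz - parent_xyz, axis)) * axis)
            # rotate -axis by ±60° within the plane spanned by (axis, inplane)
            out = []
            for sign in (+1.0, -1.0):
                theta = math.radians(60.0)
                out.append(_unit(-axis * math.cos(theta) + sign * inplane * math.sin(theta)))
            return out
        raise ValueError("unsupported sp2 hydrogen pattern")
    # sp3
    if len(vs) == 3 and n_h == 1:
        return [-_unit(vs[0] + vs[1] + vs[2])]
    if len(vs) == 2 and n_h == 2:
        b = _unit(vs[0] + vs[1])       # internal bisector
        p = _unit(np.cross(vs[0], vs[1]))  # normal of the X-C-Y plane
        half = math.radians(109.47 / 2.0)
        return [_unit(-b * math.cos(half) + s * p * math.sin(half)) for s in (+1.0, -1.0)]
    if len(vs) == 1 and n_h == 3:
        axis = -vs[0]
        if ref_xyz is not None:
            seed = ref_xyz - parent_xyz
        else:
            warnings.warn(
                f"CH3 on {entry.parent}: no reference substituent, using default torsion",
                stacklevel=3,
            )
            seed = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(_unit(seed), axis)) > 0.9:
                seed = np.array([0.0, 1.0, 0.0])
        perp = _unit(seed - np.dot(seed, axis) * axis)
        perp2 = np.cross(axis, perp)
        tet = math.radians(180.0 - 109.47)
        out = []
        for k in range(3):
            # staggered: 60° away from the reference, then every 120°
            phi = math.radians(60.0 + 120.0 * k)
            radial = perp * math.cos(phi) + perp2 * math.sin(phi)
            out.append(_unit(axis * math.cos(tet) + radial * math.sin(tet)))
        return out
    raise ValueError(
        f"cannot place {n_h} H on {entry.parent} ({geom}) with {len(vs)} neighbours"
    )


def place_hydrogens(model: CrystalModel, connectivity, plan) -> tuple:
    """Add geometrically placed H sites; returns (new model, Ride list).

    ``connectivity`` is an iterable of bonded label pairs among heavy
    atoms; ``plan`` a list of HydrogenPlanEntry.  Placed C-H distances
    equal the plan values by construction.
    """
    out = model.copy()
    m = orthogonalization_matrix(model.cell)
    minv = np.linalg.inv(m)
    neighbours: dict[str, list] = {}
    for a, b in connectivity:
        neighbours.setdefault(a, []).append(b)
        neighbours.setdefault(b, []).append(a)
    rides = []
    for entry in plan:
        parent = out.get_site(entry.parent)
        parent_xyz = m @ parent.frac
        nb_labels = neighbours.get(entry.parent, [])
        nb_xyz = [m @ out.get_site(lab).frac for lab in nb_labels]
        ref_xyz = m @ out.get_site(entry.reference).frac if entry.reference else None
        if ref_xyz is None and entry.geometry == "sp3" and entry.n_h == 3 and len(nb_labels) == 1:
            # try a substituent on the single neighbour as torsion reference
            nb2 = [lab for lab in neighbours.get(nb_labels[0], []) if lab != entry.parent]
            if nb2:
                ref_xyz = m @ out.get_site(nb2[0]).frac
        dirs = _h_directions(entry, parent_xyz, nb_xyz, ref_xyz)
        for k, dvec in enumerate(dirs, start=1):
            label = f"H{k}{entry.parent}" if len(dirs) > 1 else f"H{entry.parent}"
            h_xyz = parent_xyz + entry.bond_length * dvec
            out.atoms.append(
                AtomSite(
                    label=label,
                    element="H",
                    frac=minv @ h_xyz,
                    occupancy=parent.occupancy,
                    u_iso=entry.uiso_multiplier * model.u_eq(entry.parent),
                    riding_on=entry.parent,
                    uiso_multiplier=entry.uiso_multiplier,
                )
            )
            rides.append(Ride(follower=label, leader=entry.parent, uiso_multiplier=entry.uiso_multiplier))
    return out, rides


def riding_constraints(model: CrystalModel, rides=None, extra_constraints=()):
    """Parameter map with every H riding on its parent.

    H positional derivatives chain onto the parent's indices, so n_free
    gains no positional parameters from the hydrogens; u_iso(H) is
    refreshed as multiplier × U_eq(parent) each cycle.
    """
    if rides is None:
        rides = [
            Ride(a.label, a.riding_on, a.uiso_multiplier or 1.2)
            for a in model.atoms
            if a.riding_on is not None
        ]
    return build_parameter_map(model, list(extra_constraints) + list(rides))


def restrained_h_cycle(model: CrystalModel, reflections, plan, connectivity, config=None,
                       distance_sigma: float = 0.02, angle_sigma: float = 0.04) -> CrystalModel:
    """Refine only H positions with soft geometry restraints; heavy atoms fixed.

    DISTANCE (X-H) restraints come from the plan targets; H...Y 1-3
    distances to the parent's neighbours are restrained at the current
    (placed) geometry, keeping angles sensible.  Returns the updated model.
    """
    from .refine_engine import RefineConfig, refine

    h_atoms = [a for a in model.atoms if a.element == "H"]
    if not h_atoms:
        return model.copy()
    config = config or RefineConfig(max_cycles=5, tol=0.01)
    plan_by_parent = {e.parent: e for e in plan}
    neighbours: dict[str, list] = {}
    for a, b in connectivity:
        neighbours.setdefault(a, []).append(b)
        neighbours.setdefault(b, []).append(a)

    constraints = [Fix(a.label, ("*",)) for a in model.atoms if a.element != "H"]
    constraints += [Fix(s.label, ("*",)) for s in model.shapes]
    constraints += [Fix(a.label, ("uiso", "occ")) for a in h_atoms]
    work = model.copy()
    work.scale_fixed = True
    pmap = build_parameter_map(work, constraints)

    restr = RestraintSet()
    g, _, _ = metric_tensors(model.cell)
    for h in h_atoms:
        parent = h.riding_on
        if parent is None:
            continue
        entry = plan_by_parent.get(parent)
        target = entry.bond_length if entry else DEFAULT_XH["sp3"]
        restr.add(Restraint("DISTANCE", atoms=(parent, h.label), target=target, sigma=distance_sigma))
        for nb in neighbours.get(parent, []):
            delta = work.get_site(nb).frac - h.frac
            d13 = math.sqrt(float(delta @ g @ delta))
            restr.add(Restraint("DISTANCE", atoms=(nb, h.label), target=d13, sigma=angle_sigma))
    result = refine(work, reflections, pmap, restraints=restr, config=config)
    return result.model
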