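"""Crystal model: unit cell metrics, symmetry, sites and the parameter map.

The model side of the refinement: a triclinic-capable unit cell with its
direct/reciprocal metric tensors, explicit symmetry operator lists, atomic
sites carrying isotropic or anisotropic displacement parameters (CIF U
convention, Å²), non-atomic "special shape" scatterers (spherical shell,
line, torus) for severely disordered groups, and the ``ParameterMap`` that
connects refinable model quantities to the least-squares vector while
honouring constraints (fixed parameters, riding hydrogens, shared ADPs,
occupancy sums).

Orthogonal-frame convention used throughout: x along **a**, y in the
**a**-**b** plane, z completing the right-handed set.  Shape orientations
(declination = angle from z, azimuth = in-plane angle from x) refer to this
frame and the convention is recorded in CIF output.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .exceptions import (
    ConstraintConflictError,
    InvalidCellError,
    NothingToRefineError,
    UndefinedReflectionError,
)

__all__ = [
    "UnitCell",
    "SymmetryOp",
    "AtomSite",
    "SpecialShapeSite",
    "CrystalModel",
    "ParameterMap",
    "Fix",
    "Ride",
    "ShareADP",
    "OccupancySum",
    "metric_tensors",
    "d_spacing",
    "orthogonalization_matrix",
    "apply_symmetry",
    "build_parameter_map",
    "SYMMETRY_FIXTURES",
    "ANISO_COMPONENTS",
]

# CIF order of the six unique components of U
ANISO_COMPONENTS = ("u11", "u22", "u33", "u12", "u13", "u23")


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"non-positive cell length in {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {ang} outside (0, 180)")
        if self.metric_det() <= 0:
            raise InvalidCellError(f"degenerate cell (volume^2 <= 0): {self}")

    def metric_det(self) -> float:
        g = _metric(self)
        return float(np.linalg.det(g))

    @property
    def volume(self) -> float:
        return math.sqrt(self.metric_det())

    def as_tuple(self):
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def _metric(cell: UnitCell) -> np.ndarray:
    a, b, c = cell.a, cell.b, cell.c
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


def metric_tensors(cell: UnitCell):
    """Direct metric G, reciprocal metric G* = G⁻¹ and cell volume (Å³)."""
    g = _metric(cell)
    det = float(np.linalg.det(g))
    if det <= 0:
        raise InvalidCellError(f"degenerate cell: {cell}")
    gstar = np.linalg.inv(g)
    return g, gstar, math.sqrt(det)


def d_spacing(cell: UnitCell, hkl) -> float:
    """Resolution d = 1/sqrt(hᵗ G* h) in Å."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise UndefinedReflectionError("d-spacing undefined for (0,0,0)")
    _, gstar, _ = metric_tensors(cell)
    return float(1.0 / math.sqrt(h @ gstar @ h))


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Matrix M with x_cart = M x_frac; x along a, y in the a-b plane.

    Columns are the cell vectors in the Cartesian frame; MᵗM = G.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    # third cell vector components in this frame
    cx = c * cb
    cy = c * (ca - cb * cg) / sg
    cz2 = c * c - cx * cx - cy * cy
    if cz2 <= 0:
        raise InvalidCellError(f"degenerate cell: {cell}")
    return np.array([[a, b * cg, cx], [0.0, b * sg, cy], [0.0, 0.0, math.sqrt(cz2)]])


# ---------------------------------------------------------------------------
# Symmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymmetryOp:
    """Symmetry operator on fractional coordinates: x' = R x + t."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # length 3, fractional, reduced to [0,1)

    def __post_init__(self):
        r = np.asarray(self.rotation)
        det = round(float(np.linalg.det(r)))
        if det not in (1, -1):
            raise ValueError(f"rotation determinant {det} not ±1")
        object.__setattr__(self, "rotation", tuple(map(tuple, np.asarray(self.rotation, dtype=int))))
        object.__setattr__(self, "translation", tuple(float(t) % 1.0 for t in self.translation))

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def tran(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOp":
        op = gemmi.Op(triplet)
        den = gemmi.Op.DEN
        rot = np.asarray(op.rot, dtype=float) / den
        if not np.allclose(rot, np.round(rot)):
            raise ValueError(f"non-integer rotation in triplet {triplet!r}")
        return cls(tuple(map(tuple, np.round(rot).astype(int))), tuple(np.asarray(op.tran, dtype=float) / den))

    def triplet(self) -> str:
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(v) * den for v in row] for row in self.rotation]
        op.tran = [int(round(t * den)) for t in self.translation]
        return op.triplet()

    def __mul__(self, other: "SymmetryOp") -> "SymmetryOp":
        r = np.asarray(self.rotation) @ np.asarray(other.rotation)
        t = np.asarray(self.rotation) @ np.asarray(other.translation, dtype=float) + self.tran
        return SymmetryOp(tuple(map(tuple, r)), tuple(t % 1.0))


def apply_symmetry(op: SymmetryOp, frac_xyz, wrap: bool = False) -> np.ndarray:
    """x' = R x + t, optionally wrapped into [0,1)."""
    x = op.rot @ np.asarray(frac_xyz, dtype=float) + op.tran
    return x % 1.0 if wrap else x


#: Explicit operator lists for the shipped groups.
SYMMETRY_FIXTURES: dict[str, list[str]] = {
    "P1": ["x,y,z"],
    "P-1": ["x,y,z", "-x,-y,-z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "P21/c": ["x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2"],
}


def symmetry_ops(name_or_triplets) -> list[SymmetryOp]:
    """Operator list from a fixture name or an iterable of triplet strings."""
    if isinstance(name_or_triplets, str):
        name_or_triplets = SYMMETRY_FIXTURES[name_or_triplets]
    return [SymmetryOp.from_triplet(t) for t in name_or_triplets]


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

@dataclass
class AtomSite:
    """An atomic site with fractional coordinates and iso/aniso ADP.

    ``u_aniso`` holds the six unique Uij in CIF order (U11,U22,U33,U12,U13,U23).
    ``fix`` lists parameter names held fixed beyond the defaults;
    occupancy refines only when ``refine_occupancy`` is set.
    """

    label: str
    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    u_iso: float | None = 0.02
    u_aniso: np.ndarray | None = None
    fix: frozenset = frozenset()
    refine_occupancy: bool = False
    riding_on: str | None = None  # set for riding hydrogens
    uiso_multiplier: float | None = None  # riding u_iso rule

    def __post_init__(self):
        self.frac = np.asarray(self.frac, dtype=float)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)
            self.u_iso = None
        self.fix = frozenset(self.fix)
        if not 0.0 < self.occupancy <= 1.0 + 1e-9:
            raise ValueError(f"{self.label}: occupancy {self.occupancy} outside (0,1]")
        if self.u_iso is not None and self.u_iso < 0:
            raise ValueError(f"{self.label}: negative u_iso")

    @property
    def is_aniso(self) -> bool:
        return self.u_aniso is not None

    def adp_names(self) -> tuple:
        return ANISO_COMPONENTS if self.is_aniso else ("uiso",)

    def param_names(self) -> tuple:
        names = ("x", "y", "z") + self.adp_names()
        if self.refine_occupancy:
            names = names + ("occ",)
        return tuple(n for n in names if n not in self.fix)

    def get_param(self, name: str) -> float:
        if name in ("x", "y", "z"):
            return float(self.frac["xyz".index(name)])
        if name == "occ":
            return float(self.occupancy)
        if name == "uiso":
            return float(self.u_iso)
        return float(self.u_aniso[ANISO_COMPONENTS.index(name)])

    def set_param(self, name: str, value: float) -> None:
        if name in ("x", "y", "z"):
            self.frac["xyz".index(name)] = value
        elif name == "occ":
            self.occupancy = value
        elif name == "uiso":
            self.u_iso = value
        else:
            self.u_aniso[ANISO_COMPONENTS.index(name)] = value


@dataclass
class SpecialShapeSite:
    """A non-atomic scatterer: spherical shell, line segment or ideal torus.

    ``magnitude`` is the radius (shell, torus) or the full length (line).
    Orientation (line axis / torus normal) is given by declination from the
    Cartesian z axis and azimuth from x in the x-y plane, in degrees; the
    shell ignores both.  ``multiplicity`` is the number of atoms smeared
    onto the shape.
    """

    label: str
    kind: str  # shell | line | torus
    element: str
    frac: np.ndarray
    u_iso: float = 0.05
    magnitude: float = 1.0
    declination: float = 0.0
    azimuth: float = 0.0
    multiplicity: int = 1
    occupancy: float = 1.0
    fix: frozenset = frozenset()
    refine_occupancy: bool = False

    def __post_init__(self):
        if self.kind not in ("shell", "line", "torus"):
            raise ValueError(f"unknown special shape kind {self.kind!r}")
        self.frac = np.asarray(self.frac, dtype=float)
        self.fix = frozenset(self.fix)
        if self.magnitude <= 0:
            raise ValueError(f"{self.label}: shape magnitude must be > 0")
        if not 0.0 <= self.declination <= 180.0:
            raise ValueError(f"{self.label}: declination outside [0,180]")
        self.azimuth = float(self.azimuth) % 360.0
        if self.multiplicity < 1:
            raise ValueError(f"{self.label}: multiplicity must be >= 1")

    @property
    def is_aniso(self) -> bool:
        return False

    def axis(self) -> np.ndarray:
        """Unit orientation vector in the Cartesian frame."""
        d = math.radians(self.declination)
        a = math.radians(self.azimuth)
        return np.array([math.sin(d) * math.cos(a), math.sin(d) * math.sin(a), math.cos(d)])

    def param_names(self) -> tuple:
        names = ["x", "y", "z", "uiso", "mag"]
        if self.kind in ("line", "torus"):
            names += ["decl", "azim"]
        if self.refine_occupancy:
            names.append("occ")
        return tuple(n for n in names if n not in self.fix)

    def get_param(self, name: str) -> float:
        if name in ("x", "y", "z"):
            return float(self.frac["xyz".index(name)])
        return float(
            {
                "occ": self.occupancy,
                "uiso": self.u_iso,
                "mag": self.magnitude,
                "decl": self.declination,
                "azim": self.azimuth,
            }[name]
        )

    def set_param(self, name: str, value: float) -> None:
        if name in ("x", "y", "z"):
            self.frac["xyz".index(name)] = value
        elif name == "occ":
            self.occupancy = value
        elif name == "uiso":
            self.u_iso = value
        elif name == "mag":
            self.magnitude = value
        elif name == "decl":
            self.declination = value
        elif name == "azim":
            self.azimuth = value
        else:
            raise KeyError(name)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class CrystalModel:
    """Unit cell + symmetry + atomic and special-shape sites + overall scale."""

    cell: UnitCell
    symmetry: list = field(default_factory=lambda: [SymmetryOp.identity()])
    atoms: list = field(default_factory=list)
    shapes: list = field(default_factory=list)
    scale: float = 1.0
    scale_fixed: bool = False
    name: str = "model"

    def sites(self):
        """All scatterers, atoms first."""
        return list(self.atoms) + list(self.shapes)

    def get_site(self, label: str):
        for s in self.sites():
            if s.label == label:
                return s
        raise KeyError(f"no site labelled {label!r}")

    def has_site(self, label: str) -> bool:
        return any(s.label == label for s in self.sites())

    def copy(self) -> "CrystalModel":
        return _copy.deepcopy(self)

    def u_eq(self, label: str) -> float:
        """Equivalent isotropic U (trace of Cartesian U / 3) for a site."""
        site = self.get_site(label)
        if not getattr(site, "is_aniso", False):
            return float(site.u_iso)
        return float(np.trace(u_cif_to_cartesian(self.cell, site.u_aniso)) / 3.0)


def u_cif_to_cartesian(cell: UnitCell, u6) -> np.ndarray:
    """Convert six CIF Uij (Å²) to the Cartesian 3×3 tensor."""
    u11, u22, u33, u12, u13, u23 = np.asarray(u6, dtype=float)
    u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
    md = _md_matrix(cell)
    return md @ u @ md.T


def u_iso_to_cif(cell: UnitCell, u_iso: float) -> np.ndarray:
    """Equivalent anisotropic CIF Uij for an isotropic ADP."""
    md = _md_matrix(cell)
    inv = np.linalg.inv(md)
    u = u_iso * inv @ inv.T
    return np.array([u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2]])


def _md_matrix(cell: UnitCell) -> np.ndarray:
    """M · diag(a*, b*, c*): maps CIF U to Cartesian via (MD) U (MD)ᵗ."""
    m = orthogonalization_matrix(cell)
    _, gstar, _ = metric_tensors(cell)
    astar = np.sqrt(np.diag(gstar))
    return m @ np.diag(astar)


# ---------------------------------------------------------------------------
# Constraints and the parameter map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fix:
    """Hold the named parameters of a site fixed ('*' = everything)."""

    label: str
    params: tuple = ("*",)


@dataclass(frozen=True)
class Ride:
    """Positional riding: follower shifts exactly with its leader."""

    follower: str
    leader: str
    uiso_multiplier: float = 1.2


@dataclass(frozen=True)
class ShareADP:
    """All members share one set of ADP parameters (first member leads)."""

    labels: tuple


@dataclass(frozen=True)
class OccupancySum:
    """Member occupancies sum to ``total``; the last member is eliminated."""

    labels: tuple
    total: float = 1.0


@dataclass
class ParameterMap:
    """Bijection between refinable quantities and the refinement vector.

    ``slots`` maps (site label, parameter name) to a linear gather
    ``[(index, coeff), ...]`` over the free vector; a free parameter owns a
    single (index, 1.0) entry, a fixed one an empty list, and constrained
    parameters chain onto other indices (riding follower → leader indices,
    shared ADP → leader indices, eliminated occupancy → minus the partners).
    The overall scale uses the pseudo-label ``""``.
    """

    slots: dict
    names: list
    index_owner: list  # (label, pname) owning each free index
    n_free: int
    riding: list = field(default_factory=list)  # Ride constraints, for refresh

    def entries(self, label: str, pname: str):
        return self.slots.get((label, pname), [])

    def gather(self, model: CrystalModel) -> np.ndarray:
        """Current values of the free parameters."""
        v = np.empty(self.n_free)
        for i, (label, pname) in enumerate(self.index_owner):
            if label == "":
                v[i] = model.scale
            else:
                v[i] = model.get_site(label).get_param(pname)
        return v

    def apply_shifts(self, model: CrystalModel, shifts: np.ndarray) -> None:
        """Apply a shift vector through all constraint chains."""
        for (label, pname), chain in self.slots.items():
            if not chain:
                continue
            delta = sum(c * shifts[i] for i, c in chain)
            if delta == 0.0:
                continue
            if label == "":
                model.scale += delta
            else:
                site = model.get_site(label)
                site.set_param(pname, site.get_param(pname) + delta)
        self.refresh_dependents(model)

    def refresh_dependents(self, model: CrystalModel) -> None:
        """Re-derive riding u_iso and eliminated occupancies from leaders."""
        for ride in self.riding:
            follower = model.get_site(ride.follower)
            if ride.uiso_multiplier is not None and follower.u_iso is not None:
                follower.u_iso = ride.uiso_multiplier * model.u_eq(ride.leader)

    def scatter_row(self, contribs: dict, n: int | None = None) -> np.ndarray:
        """Dense derivative row from per-slot derivative values."""
        row = np.zeros(self.n_free if n is None else n)
        for key, dval in contribs.items():
            for i, c in self.entries(*key):
                row[i] += c * dval
        return row


def build_parameter_map(model: CrystalModel, constraints=()) -> ParameterMap:
    """Assemble the refinement-vector map honouring all constraints.

    Raises ``ConstraintConflictError`` when a parameter is simultaneously
    fixed and a member of a free shared group, and ``NothingToRefineError``
    when no free parameter remains.
    """
    fixed: dict[str, set] = {}
    ride_by_follower: dict[str, Ride] = {}
    share_leader: dict[str, str] = {}
    occ_elim: dict[str, OccupancySum] = {}
    occ_free: set[str] = set()

    for con in constraints:
        if isinstance(con, Fix):
            model.get_site(con.label)
            fixed.setdefault(con.label, set()).update(con.params)
        elif isinstance(con, Ride):
            leader = model.get_site(con.leader)  # noqa: F841 - existence check
            model.get_site(con.follower)
            if con.leader in ride_by_follower:
                raise ConstraintConflictError(
                    f"riding chain: {con.leader} already rides on {ride_by_follower[con.leader].leader}"
                )
            ride_by_follower[con.follower] = con
        elif isinstance(con, ShareADP):
            lead = con.labels[0]
            for lab in con.labels[1:]:
                model.get_site(lab)
                share_leader[lab] = lead
        elif isinstance(con, OccupancySum):
            for lab in con.labels:
                model.get_site(lab)
                occ_free.add(lab)
            occ_elim[con.labels[-1]] = con
        else:
            raise TypeError(f"unknown constraint {con!r}")
    # a follower must not lead another rider (no chains)
    for ride in ride_by_follower.values():
        if ride.leader in ride_by_follower:
            raise ConstraintConflictError(
                f"{ride.follower} rides on {ride.leader}, which itself rides"
            )

    def is_fixed(label: str, pname: str) -> bool:
        pats = fixed.get(label, set())
        return "*" in pats or pname in pats

    slots: dict = {}
    names: list = []
    owners: list = []

    def new_index(label: str, pname: str) -> int:
        idx = len(names)
        names.append(f"{label}.{pname}" if label else pname)
        owners.append((label, pname))
        return idx

    # overall scale first
    slots[("", "scale")] = [] if model.scale_fixed else [(new_index("", "scale"), 1.0)]

    sites = model.sites()
    adp_lead_indices: dict[str, list] = {}

    for site in sites:
        label = site.label
        pnames = list(site.param_names())
        if site.refine_occupancy or label in occ_free:
            if "occ" not in pnames and not is_fixed(label, "occ"):
                pnames.append("occ")
        ride = ride_by_follower.get(label)
        for pname in pnames:
            if is_fixed(label, pname):
                slots[(label, pname)] = []
                continue
            if ride is not None and pname in ("x", "y", "z"):
                slots[(label, pname)] = None  # fill after leader allocated
                continue
            if ride is not None and pname == "uiso":
                slots[(label, pname)] = []  # derived, not refined
                continue
            if label in share_leader and pname in ANISO_COMPONENTS + ("uiso",):
                slots[(label, pname)] = None  # chained to leader below
                continue
            if pname == "occ" and label in occ_elim:
                slots[(label, pname)] = None
                continue
            slots[(label, pname)] = [(new_index(label, pname), 1.0)]
        # also create empty slots for parameters fixed by default flags
        for pname in ("x", "y", "z", "occ", "uiso") + ANISO_COMPONENTS:
            slots.setdefault((label, pname), [])

    # second pass: resolve chained slots
    for site in sites:
        label = site.label
        ride = ride_by_follower.get(label)
        if ride is not None:
            for pname in ("x", "y", "z"):
                if slots.get((label, pname)) is None:
                    slots[(label, pname)] = list(slots.get((ride.leader, pname), []))
        if label in share_leader:
            lead = share_leader[label]
            lead_site = model.get_site(lead)
            for pname in ANISO_COMPONENTS + ("uiso",):
                if slots.get((label, pname)) is None:
                    chain = slots.get((lead, pname), [])
                    if not chain and lead_site.get_param_safe(pname) is None:
                        raise ConstraintConflictError(
                            f"shared-ADP leader {lead} has no {pname}"
                        )
                    slots[(label, pname)] = list(chain)
        if label in occ_elim and slots.get((label, "occ")) is None:
            con = occ_elim[label]
            chain = []
            for other in con.labels[:-1]:
                for i, c in slots.get((other, "occ"), []):
                    chain.append((i, -c))
            slots[(label, "occ")] = chain

    # conflict check: fixed parameter chained into a free share group
    for con in constraints:
        if isinstance(con, ShareADP):
            lead = con.labels[0]
            for lab in con.labels:
                for pname in ANISO_COMPONENTS + ("uiso",):
                    if is_fixed(lab, pname) and slots.get((lead, pname)):
                        raise ConstraintConflictError(
                            f"{lab}.{pname} is fixed but shares a free ADP group led by {lead}"
                        )

    n_free = len(names)
    if n_free == 0:
        raise NothingToRefineError("no free parameters")
    riding = list(ride_by_follower.values())
    return ParameterMap(slots=slots, names=names, index_owner=owners, n_free=n_free, riding=riding)


def _get_param_safe(self, name):
    try:
        return self.get_param(name)
    except (TypeError, KeyError, IndexError):
        return None


AtomSite.get_param_safe = _get_param_safe
SpecialShapeSite.get_param_safe = _get_param_safe
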