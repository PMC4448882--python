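"""Ground-truth models and simulated diffraction data for every test stage.

Each fixture is a small crystal whose geometry isolates one feature of
the refinement machinery:

* ``pyridine_pair`` — two idealised pyridine rings (C-C 1.39 Å, C-N
  1.34 Å) in P1, with the four-line SAME scheme tying the second ring and
  the mirrored copies of both rings back onto the first.
* ``benzene_torus``  — a librating benzene: six carbons (and six
  hydrogens) on two concentric rings, provided both as discrete atoms and
  as the equivalent pair of concentric torus scatterers.
* ``cf3_disorder``   — a disordered CF₃ group: two components rotated 60°
  with occupancies 0.7/0.3 and asymmetric ADP similarity restraints from
  the major onto the minor component.
* ``collinear_occupancy`` — two same-element scatterers at nearly the
  same site with both occupancies free: a deliberately ill-conditioned
  normal matrix.
* ``random_structure`` — a seeded random mix of iso/aniso atoms (optional
  space group, optional shape) for derivative and recovery tests.

Simulated observations cover the full hkl sphere to d_min with
Yo = |Fc|²(1 + noise·ε), ε ~ N(0,1), σ = noise·|Fc|² floored at a small
positive constant; noise 0 gives exact data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .crystal_model import (
    AtomSite,
    CrystalModel,
    SpecialShapeSite,
    UnitCell,
    orthogonalization_matrix,
    symmetry_ops,
)
from .io_formats import ReflectionSet
from .scattering import FormFactorTable, calc_structure_factors

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "simulate_observations", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "pyridine_pair",
    "benzene_torus",
    "cf3_disorder",
    "collinear_occupancy",
    "random_structure",
)

SIGMA_FLOOR = 1e-6


@dataclass
class FixtureSpec:
    name: str
    d_min: float = 0.9
    noise: float = 0.0
    seed: int = 0
    cell: UnitCell | None = None

    def __post_init__(self):
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}")
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class Fixture:
    """Ground truth model + connectivity + restraint text + metadata."""

    model: CrystalModel
    connectivity: list = field(default_factory=list)
    restraint_text: str = ""
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------

def _pyridine_ring_xy(cc: float = 1.39, cn: float = 1.34) -> np.ndarray:
    """Idealised pyridine: five carbons of a regular hexagon of side ``cc``
    plus the nitrogen placed on the mirror axis at distance ``cn`` from
    both ortho carbons.  Rows: N, C2, C3, C4, C5, C6 (mirror axis = y)."""
    r = cc
    angles = {"C2": 30, "C3": -30, "C4": -90, "C5": 210, "C6": 150}
    pos = {k: r * np.array([math.cos(math.radians(v)), math.sin(math.radians(v))])
           for k, v in angles.items()}
    x2, y2 = pos["C2"]
    y_n = y2 + math.sqrt(cn**2 - x2**2)
    coords = [np.array([0.0, y_n]), pos["C2"], pos["C3"], pos["C4"], pos["C5"], pos["C6"]]
    return np.array(coords)


PYRIDINE_SAME_TEXT = """\
BOND N1 TO C2, C2 TO C3, C3 TO C4, C4 TO C5, C5 TO C6, C6 TO N1
BOND N11 TO C12, C12 TO C13, C13 TO C14, C14 TO C15, C15 TO C16, C16 TO N11
# four-line SAME scheme for two pyridine rings:
# ring2 -> ring1, mirror(ring1) -> ring1, mirror(ring2) -> ring1,
# mirror(ring2) -> ring2 (mirror swaps the ortho/meta positions)
SAME 0.01, 0.02 = N1 C2 C3 C4 C5 C6 AND N11 C12 C13 C14 C15 C16
SAME 0.01, 0.02 = N1 C2 C3 C4 C5 C6 AND N1 C6 C5 C4 C3 C2
SAME 0.01, 0.02 = N1 C2 C3 C4 C5 C6 AND N11 C16 C15 C14 C13 C12
SAME 0.01, 0.02 = N11 C12 C13 C14 C15 C16 AND N11 C16 C15 C14 C13 C12
"""


def _ring_connectivity(labels):
    return [(labels[i], labels[(i + 1) % len(labels)]) for i in range(len(labels))]


def _make_pyridine_pair(spec: FixtureSpec) -> Fixture:
    cell = spec.cell or UnitCell(8.0, 9.0, 10.0, 90.0, 90.0, 90.0)
    m = orthogonalization_matrix(cell)
    minv = np.linalg.inv(m)
    ring = _pyridine_ring_xy()
    atoms = []
    centres = [np.array([2.5, 2.5, 2.5]), np.array([5.5, 6.0, 6.5])]
    label_sets = [["N1", "C2", "C3", "C4", "C5", "C6"],
                  ["N11", "C12", "C13", "C14", "C15", "C16"]]
    # second ring tilted so the two rings are not trivially related
    tilt = _rotation_matrix(np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0), math.radians(40.0))
    for iring, (centre, labels) in enumerate(zip(centres, label_sets)):
        for lab, xy in zip(labels, ring):
            xyz = np.array([xy[0], xy[1], 0.0])
            if iring == 1:
                xyz = tilt @ xyz
            cart = centre + xyz
            atoms.append(
                AtomSite(label=lab, element="N" if lab.startswith("N") else "C",
                         frac=minv @ cart, u_iso=0.025 + 0.005 * iring)
            )
    conn = _ring_connectivity(label_sets[0]) + _ring_connectivity(label_sets[1])
    model = CrystalModel(cell=cell, symmetry=symmetry_ops("P1"), atoms=atoms,
                         scale=1.0, name="pyridine_pair")
    return Fixture(model=model, connectivity=conn, restraint_text=PYRIDINE_SAME_TEXT,
                   info={"rings": label_sets})


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _make_benzene_torus(spec: FixtureSpec) -> Fixture:
    """Benzene as 6 C + 6 H discrete atoms and as two concentric tori."""
    cell = spec.cell or UnitCell(9.0, 9.0, 9.0, 90.0, 90.0, 90.0)
    m = orthogonalization_matrix(cell)
    minv = np.linalg.inv(m)
    centre = np.array([4.5, 4.5, 4.5])
    r_c, r_h = 1.39, 1.39 + 1.08
    atoms = []
    for i in range(6):
        phi = math.radians(60.0 * i)
        for el, radius, stem in (("C", r_c, "C"), ("H", r_h, "H")):
            cart = centre + radius * np.array([math.cos(phi), math.sin(phi), 0.0])
            atoms.append(AtomSite(label=f"{stem}{i + 1}", element=el,
                                  frac=minv @ cart, u_iso=0.04))
    shapes = [
        SpecialShapeSite(label="TORC", kind="torus", element="C", frac=minv @ centre,
                         u_iso=0.04, magnitude=r_c, declination=0.0, azimuth=0.0,
                         multiplicity=6),
        SpecialShapeSite(label="TORH", kind="torus", element="H", frac=minv @ centre,
                         u_iso=0.04, magnitude=r_h, declination=0.0, azimuth=0.0,
                         multiplicity=6),
    ]
    discrete = CrystalModel(cell=cell, symmetry=symmetry_ops("P1"), atoms=atoms,
                            name="benzene_discrete")
    smeared = CrystalModel(cell=cell, symmetry=symmetry_ops("P1"), shapes=shapes,
                           name="benzene_torus")
    conn = _ring_connectivity([f"C{i+1}" for i in range(6)]) + [
        (f"C{i+1}", f"H{i+1}") for i in range(6)
    ]
    fx = Fixture(model=smeared, connectivity=conn,
                 info={"ring_radius": r_c, "h_radius": r_h})
    fx.info["discrete_model"] = discrete
    return fx


def _make_cf3_disorder(spec: FixtureSpec) -> Fixture:
    """Two CF₃ components rotated 60° about the C-C bond, occ 0.7/0.3.

    Asymmetric similarity restraints tie each minor-component fluorine's
    ADP to its major-component partner (the reference, whose parameters
    are not perturbed).
    """
    cell = spec.cell or UnitCell(8.0, 8.0, 8.0, 90.0, 90.0, 90.0)
    m = orthogonalization_matrix(cell)
    minv = np.linalg.inv(m)
    c1 = np.array([4.0, 4.0, 3.0])     # anchor carbon
    c2 = np.array([4.0, 4.0, 4.54])    # CF3 carbon, C-C along z
    atoms = [
        AtomSite(label="C1", element="C", frac=minv @ c1, u_iso=0.03),
        AtomSite(label="C2", element="C", frac=minv @ c2, u_iso=0.035),
    ]
    cf, tet = 1.33, math.radians(180.0 - 109.5)
    for comp, (occ, phi0, tag) in enumerate((
        (0.7, 0.0, ""), (0.3, 60.0, "3"),
    )):
        for k in range(3):
            phi = math.radians(phi0 + 120.0 * k)
            d = np.array([math.sin(tet) * math.cos(phi),
                          math.sin(tet) * math.sin(phi), math.cos(tet)])
            atoms.append(
                AtomSite(label=f"F{tag}{k + 1}", element="F", frac=minv @ (c2 + cf * d),
                         occupancy=occ,
                         u_aniso=np.array([0.05, 0.05, 0.04, 0.01, 0.0, 0.0])
                         + (0.005 * comp) * np.array([1, 1, 1, 0, 0, 0]))
            )
    restr = "SIMU 0.04 = F1 F2 F3 TO F31 F32 F33 ASYM\n"
    conn = [("C1", "C2")] + [(f"C2", f"F{k+1}") for k in range(3)] + [
        ("C2", f"F3{k+1}") for k in range(3)
    ]
    model = CrystalModel(cell=cell, symmetry=symmetry_ops("P1"), atoms=atoms,
                         name="cf3_disorder")
    return Fixture(model=model, connectivity=conn, restraint_text=restr,
                   info={"major": ["F1", "F2", "F3"], "minor": ["F31", "F32", "F33"]})


def _make_collinear_occupancy(spec: FixtureSpec) -> Fixture:
    """Two same-element scatterers at nearly the same site, occupancies free."""
    cell = spec.cell or UnitCell(7.0, 7.0, 7.0, 90.0, 90.0, 90.0)
    atoms = [
        AtomSite(label="NI1", element="Ni", frac=np.array([0.25, 0.25, 0.25]),
                 occupancy=0.5, u_iso=0.02, fix=frozenset({"x", "y", "z", "uiso"}),
                 refine_occupancy=True),
        AtomSite(label="NI2", element="Ni", frac=np.array([0.252, 0.25, 0.248]),
                 occupancy=0.5, u_iso=0.02, fix=frozenset({"x", "y", "z", "uiso"}),
                 refine_occupancy=True),
        AtomSite(label="C1", element="C", frac=np.array([0.60, 0.10, 0.35]), u_iso=0.03),
        AtomSite(label="C2", element="C", frac=np.array([0.10, 0.65, 0.70]), u_iso=0.03),
        AtomSite(label="O1", element="O", frac=np.array([0.40, 0.80, 0.15]), u_iso=0.025),
    ]
    model = CrystalModel(cell=cell, symmetry=symmetry_ops("P1"), atoms=atoms,
                         scale=1.0, scale_fixed=True, name="collinear_occupancy")
    return Fixture(model=model, info={"occupancy_sites": ["NI1", "NI2"]})


def _make_random_structure(spec: FixtureSpec, n_atoms: int = 6, spacegroup: str = "P1",
                           aniso_fraction: float = 0.35, with_shape: bool = False) -> Fixture:
    rng = np.random.default_rng(spec.seed)
    cell = spec.cell or UnitCell(7.5, 8.5, 9.5, 90.0, 95.0, 90.0)
    elements = ["C", "N", "O", "C", "S", "C"]
    atoms = []
    for i in range(n_atoms):
        el = elements[i % len(elements)]
        if rng.random() < aniso_fraction:
            diag = 0.02 + 0.02 * rng.random(3)
            off = 0.004 * rng.standard_normal(3)
            u = np.array([diag[0], diag[1], diag[2], off[0], off[1], off[2]])
            atoms.append(AtomSite(label=f"{el}{i + 1}", element=el,
                                  frac=rng.random(3), u_aniso=u))
        else:
            atoms.append(AtomSite(label=f"{el}{i + 1}", element=el,
                                  frac=rng.random(3), u_iso=0.015 + 0.03 * rng.random()))
    shapes = []
    if with_shape:
        shapes.append(
            SpecialShapeSite(label="TOR1", kind="torus", element="C",
                             frac=rng.random(3), u_iso=0.05, magnitude=1.4,
                             declination=35.0, azimuth=120.0, multiplicity=3)
        )
    model = CrystalModel(cell=cell, symmetry=symmetry_ops(spacegroup),
                         atoms=atoms, shapes=shapes, name="random_structure")
    return Fixture(model=model, info={"seed": spec.seed, "spacegroup": spacegroup})


def make_fixture(spec: FixtureSpec | str, **kwargs) -> Fixture:
    """Build a named fixture; extra kwargs reach the specific builder."""
    if isinstance(spec, str):
        spec = FixtureSpec(name=spec, **{k: v for k, v in kwargs.items()
                                         if k in ("d_min", "noise", "seed", "cell")})
        kwargs = {k: v for k, v in kwargs.items()
                  if k not in ("d_min", "noise", "seed", "cell")}
    builder = {
        "pyridine_pair": _make_pyridine_pair,
        "benzene_torus": _make_benzene_torus,
        "cf3_disorder": _make_cf3_disorder,
        "collinear_occupancy": _make_collinear_occupancy,
        "random_structure": _make_random_structure,
    }[spec.name]
    fx = builder(spec, **kwargs) if kwargs else builder(spec)
    fx.info.setdefault("seed", spec.seed)
    fx.info["fixture"] = spec.name
    return fx


# ---------------------------------------------------------------------------
# Simulated observations
# ---------------------------------------------------------------------------

def full_sphere_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller indices (both Friedel halves) with d ≥ d_min, minus (000)."""
    from .crystal_model import metric_tensors

    _, gstar, _ = metric_tensors(cell)
    hmax = [int(math.floor(length / d_min)) + 1 for length in (cell.a, cell.b, cell.c)]
    grid = np.array(list(itertools.product(*[range(-n, n + 1) for n in hmax])), dtype=int)
    grid = grid[np.any(grid != 0, axis=1)]
    inv_d2 = np.einsum("ni,ij,nj->n", grid.astype(float), gstar, grid.astype(float))
    return grid[inv_d2 <= 1.0 / d_min**2 + 1e-12]


def simulate_observations(
    model: CrystalModel,
    d_min: float,
    noise_frac: float = 0.0,
    seed: int = 0,
    table: FormFactorTable | None = None,
) -> ReflectionSet:
    """Simulate Fo² data on the full sphere to d_min.

    Yo = |Fc|²(1 + noise·ε) with ε ~ N(0,1) at a fixed seed;
    σ = noise·|Fc|² floored at a small positive constant.  noise 0 gives
    exact intensities (σ = floor, i.e. effectively uniform weights).
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    hkl = full_sphere_hkl(model.cell, d_min)
    sf = calc_structure_factors(model, hkl, table=table)
    y_true = sf.amplitude**2
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        y = y_true * (1.0 + noise_frac * rng.standard_normal(y_true.size))
        sigma = np.maximum(noise_frac * y_true, SIGMA_FLOOR)
    else:
        y = y_true.copy()
        sigma = np.full_like(y, SIGMA_FLOOR)
    return ReflectionSet(hkl=hkl, y=y, sigma=sigma)
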