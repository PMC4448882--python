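"""Geometric and ADP restraints: observational equations appended to the data.

Supported kinds:

* ``DISTANCE`` / ``ANGLE`` — absolute geometry targets;
* ``EQUIV_DISTANCE`` / ``EQUIV_ANGLE`` — equivalence restraints generated by
  decomposing a ``SAME`` directive over the connectivity of its target
  group (angle equivalences are realised as 1-3 distance equivalences,
  which are uniquely determined once the 1-2 restraints are present);
* ``SIMU`` — ADP similarity (component-wise Uij differences);
* ``DELU`` — rigid-bond (Hirshfeld) restraints: the difference of the two
  atoms' mean-square displacements along their bond, target 0;
* ``LIMIT`` — shift-limiting equations, equivalent to Levenberg-style
  damping of the normal-matrix diagonal.

A restraint may be *asymmetric*: the first (reference) group's Jacobian
entries are masked to zero, so refinement pulls only the dependent group
toward the reference while the reference is re-read each cycle but never
perturbed.

Every equation is returned pre-divided by its σ, so restraints enter the
normal matrix with weight 1/σ² on the same footing as the data.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .crystal_model import (
    ANISO_COMPONENTS,
    CrystalModel,
    metric_tensors,
    orthogonalization_matrix,
    u_iso_to_cif,
)
from .exceptions import MicrorefineError, RestraintParseError

__all__ = [
    "Restraint",
    "RestraintSet",
    "parse_restraints",
    "expand_same",
    "expand_simu",
    "expand_delu",
    "hirshfeld_delta",
    "restraint_equation",
    "shift_limit_equations",
    "DEFAULT_SIGMAS",
]

DEFAULT_SIGMAS = {
    "DISTANCE": 0.01,   # Å
    "ANGLE": 1.0,       # degrees
    "EQUIV_DISTANCE": 0.01,
    "EQUIV_ANGLE": 0.02,  # Å (1-3 distance equivalence)
    "SIMU": 0.04,       # Å²
    "DELU": 0.01,       # Å²
}

_KINDS = {"DISTANCE", "ANGLE", "SIMU", "DELU", "LIMIT", "EQUIV_DISTANCE", "EQUIV_ANGLE"}


@dataclass(frozen=True)
class Restraint:
    """One observational equation (or equivalence) with target and σ."""

    kind: str
    atoms: tuple
    target: float | None = None
    sigma: float = 0.01
    atoms2: tuple | None = None      # second tuple for EQUIV_* / paired SIMU
    asymmetric: bool = False         # atoms (or atoms2's partner set) is the reference
    origin: str = "explicit"         # 'explicit' or the generating SAME line

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError(f"restraint sigma must be > 0, got {self.sigma}")
        if self.kind.startswith("EQUIV"):
            if self.atoms2 is None or len(self.atoms2) != len(self.atoms):
                raise ValueError("EQUIV restraints need two tuples of equal arity")


@dataclass
class RestraintSet:
    """An ordered collection of restraints with provenance bookkeeping."""

    restraints: list = field(default_factory=list)

    def __len__(self):
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    def add(self, r: Restraint):
        self.restraints.append(r)

    def extend(self, rs):
        self.restraints.extend(rs)

    def by_kind(self, *kinds):
        return [r for r in self.restraints if r.kind in kinds]

    def report(self) -> str:
        """Tabular audit dump of all (expanded) restraints."""
        lines = ["kind            target   sigma  atoms                       origin"]
        for r in self.restraints:
            tgt = "match" if r.target is None else f"{r.target:8.4f}"
            at = " ".join(r.atoms) + (" | " + " ".join(r.atoms2) if r.atoms2 else "")
            lines.append(f"{r.kind:<15} {tgt:>8} {r.sigma:7.4f}  {at:<27} {r.origin}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_restraints(text: str, connectivity=None, known_labels=None) -> RestraintSet:
    """Parse the plain-text restraint grammar.

        BOND A1 TO A2 [, A3 TO A4 ...]      (connectivity declaration)
        DISTANCE <target>, <sigma> = A1 TO A2
        ANGLE <target>, <sigma> = A1 TO A2 TO A3
        SAME [<sigma_d>, <sigma_13>] = A1 A2 ... AND B1 B2 ... [AND ...]
        SIMU [<sigma>] = A1 A2 A3 ...                  (all pairs in group)
        SIMU [<sigma>] = A1 A2 TO B1 B2 [ASYM]         (paired groups)
        DELU [<sigma>] = A1 TO A2 [, A3 TO A4 ...]
        LIMIT <sigma>

    ``#``/``!`` start comments.  SAME directives need connectivity
    covering the target group, either passed in as bonded label pairs or
    declared with BOND lines earlier in the file.  When ``known_labels``
    is given, unresolvable atom labels raise a parse error naming the
    line.
    """
    out = RestraintSet()
    conn = list(connectivity) if connectivity is not None else []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = re.split(r"[#!]", raw)[0].strip()
        if not line:
            continue
        m = re.match(r"([A-Za-z_]+)\s*(.*)$", line)
        keyword = m.group(1).upper()
        rest = m.group(2).strip()

        def err(msg):
            raise RestraintParseError(msg, line=lineno)

        def check_labels(labels):
            if known_labels is not None:
                for lab in labels:
                    if lab not in known_labels:
                        err(f"unknown atom label {lab!r}")

        if keyword == "LIMIT":
            try:
                sigma = float(rest)
            except ValueError:
                err(f"LIMIT needs a numeric sigma, got {rest!r}")
            if sigma <= 0:
                err("sigma must be > 0")
            out.add(Restraint("LIMIT", atoms=(), target=0.0, sigma=sigma))
            continue

        if keyword == "BOND":
            for chunk in rest.split(","):
                labels = [t.strip() for t in re.split(r"\s+TO\s+", chunk.strip(), flags=re.I)]
                if len(labels) != 2 or not all(labels):
                    err("BOND needs comma-separated 'A TO B' pairs")
                check_labels(labels)
                conn.append(tuple(labels))
            continue

        if keyword not in ("DISTANCE", "ANGLE", "SAME", "SIMU", "DELU"):
            err(f"unknown keyword {keyword!r}")

        if "=" in rest:
            head, _, body = rest.partition("=")
            head = head.strip()
            body = body.strip()
        else:
            head, body = "", rest
        numbers = []
        if head:
            try:
                numbers = [float(tok) for tok in re.split(r"[,\s]+", head) if tok]
            except ValueError:
                err(f"bad numeric field in {head!r}")

        if keyword == "DISTANCE" or keyword == "ANGLE":
            arity = 2 if keyword == "DISTANCE" else 3
            if len(numbers) != 2:
                err(f"{keyword} needs '<target>, <sigma> ='")
            target, sigma = numbers
            if sigma <= 0:
                err("sigma must be > 0")
            labels = [t for t in re.split(r"\s+TO\s+", body, flags=re.I)]
            labels = [lab.strip() for lab in labels]
            if len(labels) != arity or not all(labels):
                err(f"{keyword} needs {arity} atom labels joined by TO")
            check_labels(labels)
            out.add(Restraint(keyword, atoms=tuple(labels), target=target, sigma=sigma))

        elif keyword == "SAME":
            sigma_d = numbers[0] if len(numbers) > 0 else DEFAULT_SIGMAS["EQUIV_DISTANCE"]
            sigma_a = numbers[1] if len(numbers) > 1 else DEFAULT_SIGMAS["EQUIV_ANGLE"]
            if sigma_d <= 0 or sigma_a <= 0:
                err("sigma must be > 0")
            groups = [g.split() for g in re.split(r"\s+AND\s+", body, flags=re.I)]
            if len(groups) < 2:
                err("SAME needs a target group AND at least one mapped group")
            check_labels([lab for g in groups for lab in g])
            if not conn:
                err("SAME directive requires connectivity (BOND lines or argument)")
            try:
                out.extend(
                    expand_same(
                        groups[0], groups[1:], conn,
                        sigma_distance=sigma_d, sigma_angle=sigma_a,
                        origin=f"SAME line {lineno}",
                    )
                )
            except MicrorefineError as exc:
                err(str(exc))

        elif keyword == "SIMU":
            sigma = numbers[0] if numbers else DEFAULT_SIGMAS["SIMU"]
            if sigma <= 0:
                err("sigma must be > 0")
            asym = False
            if re.search(r"\bASYM\b", body, flags=re.I):
                body = re.sub(r"\bASYM\b", "", body, flags=re.I).strip()
                asym = True
            parts = re.split(r"\s+TO\s+", body, flags=re.I)
            if len(parts) == 2:
                g1, g2 = parts[0].split(), parts[1].split()
                if len(g1) != len(g2):
                    err("paired SIMU groups must have equal length")
                check_labels(g1 + g2)
                out.extend(expand_simu([g1, g2], sigma=sigma, asymmetric=asym))
            else:
                labels = body.split()
                check_labels(labels)
                if asym:
                    err("ASYM requires two groups joined by TO")
                out.extend(expand_simu([labels], sigma=sigma))

        elif keyword == "DELU":
            sigma = numbers[0] if numbers else DEFAULT_SIGMAS["DELU"]
            if sigma <= 0:
                err("sigma must be > 0")
            pairs = []
            for chunk in body.split(","):
                labels = [t.strip() for t in re.split(r"\s+TO\s+", chunk.strip(), flags=re.I)]
                if len(labels) != 2 or not all(labels):
                    err("DELU needs comma-separated 'A TO B' pairs")
                check_labels(labels)
                pairs.append(tuple(labels))
            out.extend(expand_delu(pairs, sigma=sigma))
    return out


# ---------------------------------------------------------------------------
# SAME decomposition
# ---------------------------------------------------------------------------

def _pairs_from_connectivity(group, connectivity):
    """Index pairs (into group) of 1-2 bonds and of 1-3 (angle) contacts."""
    idx = {lab: i for i, lab in enumerate(group)}
    bonds = set()
    for a, b in connectivity:
        if a in idx and b in idx:
            i, j = idx[a], idx[b]
            bonds.add((min(i, j), max(i, j)))
    neighbours: dict[int, set] = {i: set() for i in range(len(group))}
    for i, j in bonds:
        neighbours[i].add(j)
        neighbours[j].add(i)
    angles = set()
    for j, nbrs in neighbours.items():
        nbrs = sorted(nbrs)
        for ii in range(len(nbrs)):
            for kk in range(ii + 1, len(nbrs)):
                i, k = nbrs[ii], nbrs[kk]
                if (min(i, k), max(i, k)) not in bonds:
                    angles.add((min(i, k), max(i, k)))
    return sorted(bonds), sorted(angles)


def expand_same(
    target_group,
    mapped_groups,
    connectivity,
    sigma_distance: float = DEFAULT_SIGMAS["EQUIV_DISTANCE"],
    sigma_angle: float = DEFAULT_SIGMAS["EQUIV_ANGLE"],
    asymmetric: bool = False,
    origin: str = "SAME",
) -> RestraintSet:
    """Decompose a SAME directive into equivalence restraints.

    The connectivity of the *target* group decides which 1-2 distances and
    1-3 (angle-defining) distances are equivalenced; every mapped group
    contributes one EQUIV restraint per pair, tying its value to the
    target's.  Mirrored mappings are expressed by supplying the
    mirror-permuted atom order as a mapped group; duplicates arising from
    mirror self-maps are retained (one equation each).
    """
    target_group = list(target_group)
    out = RestraintSet()
    bonds, angles = _pairs_from_connectivity(target_group, connectivity)
    if not bonds:
        raise MicrorefineError(
            "connectivity does not cover the SAME target group (no bonds found)"
        )
    for group in mapped_groups:
        group = list(group)
        if len(group) != len(target_group):
            raise MicrorefineError(
                f"SAME group length mismatch: {len(group)} vs {len(target_group)}"
            )
        for kind, pairs, sigma in (
            ("EQUIV_DISTANCE", bonds, sigma_distance),
            ("EQUIV_ANGLE", angles, sigma_angle),
        ):
            for i, j in pairs:
                out.add(
                    Restraint(
                        kind,
                        atoms=(target_group[i], target_group[j]),
                        atoms2=(group[i], group[j]),
                        target=None,
                        sigma=sigma,
                        asymmetric=asymmetric,
                        origin=origin,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# ADP restraints
# ---------------------------------------------------------------------------

def expand_simu(groups, sigma: float = DEFAULT_SIGMAS["SIMU"], asymmetric: bool = False) -> RestraintSet:
    """SIMU → per-pair ADP similarity restraints.

    One group: every unordered pair within it.  Two groups: corresponding
    members are paired; with ``asymmetric`` the first group is the
    reference whose parameters are not perturbed.
    """
    out = RestraintSet()
    if len(groups) == 1:
        labels = list(groups[0])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                out.add(Restraint("SIMU", atoms=(labels[i], labels[j]), target=0.0, sigma=sigma))
    elif len(groups) == 2:
        g1, g2 = list(groups[0]), list(groups[1])
        if len(g1) != len(g2):
            raise MicrorefineError("paired SIMU groups must have equal length")
        for a, b in zip(g1, g2):
            out.add(
                Restraint("SIMU", atoms=(a, b), target=0.0, sigma=sigma, asymmetric=asymmetric)
            )
    else:
        raise MicrorefineError("SIMU takes one group or two paired groups")
    return out


def expand_delu(bonded_pairs, sigma: float = DEFAULT_SIGMAS["DELU"]) -> RestraintSet:
    """DELU → one rigid-bond (Hirshfeld) equation per bond, target 0."""
    out = RestraintSet()
    for a, b in bonded_pairs:
        out.add(Restraint("DELU", atoms=(a, b), target=0.0, sigma=sigma))
    return out


def _u_cif_and_chain(model: CrystalModel, label: str):
    """Site's CIF U tensor plus the chain rule to its own parameters.

    Returns (u6, {pname: du6/dpname}) — isotropic sites are promoted to
    the equivalent tensor, whose derivative chains back to u_iso.
    """
    site = model.get_site(label)
    if getattr(site, "u_aniso", None) is not None:
        u6 = np.asarray(site.u_aniso, dtype=float)
        chain = {c: np.eye(6)[i] for i, c in enumerate(ANISO_COMPONENTS)}
        return u6, chain
    unit = u_iso_to_cif(model.cell, 1.0)
    return site.u_iso * unit, {"uiso": unit}


def hirshfeld_delta(model_or_cell, label_a=None, label_b=None, *, atom_a=None, atom_b=None) -> float:
    """Rigid-bond difference Δ_AB = z̄ᵗU_A^cart z̄ − z̄ᵗU_B^cart z̄ (Å²).

    z̄ is the unit Cartesian vector along the A-B bond.  Call either with a
    CrystalModel and two labels, or a UnitCell plus ``atom_a``/``atom_b``
    sites.  Isotropic ADPs are promoted to their equivalent tensors.
    """
    if label_a is not None:
        model = model_or_cell
        cell = model.cell
        a, b = model.get_site(label_a), model.get_site(label_b)
    else:
        cell = model_or_cell
        model = CrystalModel(cell=cell, atoms=[atom_a, atom_b])
        a, b = atom_a, atom_b
    delta, _, _ = _hirshfeld_core(model, a.label, b.label)
    return delta


def _hirshfeld_core(model: CrystalModel, label_a: str, label_b: str):
    cell = model.cell
    a, b = model.get_site(label_a), model.get_site(label_b)
    m = orthogonalization_matrix(cell)
    dvec = m @ (np.asarray(a.frac) - np.asarray(b.frac))
    norm = np.linalg.norm(dvec)
    if norm < 1e-8:
        raise MicrorefineError(f"coincident atoms {label_a}/{label_b}: bond direction undefined")
    z = dvec / norm
    _, gstar, _ = metric_tensors(cell)
    astar = np.sqrt(np.diag(gstar))
    v = (m @ np.diag(astar)).T @ z  # Δ = Σ coeff_k U_k with these projections
    coeff6 = np.array([v[0] ** 2, v[1] ** 2, v[2] ** 2,
                       2 * v[0] * v[1], 2 * v[0] * v[2], 2 * v[1] * v[2]])
    ua, chain_a = _u_cif_and_chain(model, label_a)
    ub, chain_b = _u_cif_and_chain(model, label_b)
    delta = float(coeff6 @ (ua - ub))
    da = {p: float(coeff6 @ d) for p, d in chain_a.items()}
    db = {p: -float(coeff6 @ d) for p, d in chain_b.items()}
    # positional dependence through the bond direction z̄:
    # dΔ/dδ_frac = Mᵗ (I − z̄z̄ᵗ) (2 W z̄) / |M δ| with W = U_A^cart − U_B^cart
    from .crystal_model import u_cif_to_cartesian

    w = u_cif_to_cartesian(cell, ua - ub)
    gpos = m.T @ ((np.eye(3) - np.outer(z, z)) @ (2.0 * w @ z)) / norm
    for k, p in enumerate(("x", "y", "z")):
        da[p] = da.get(p, 0.0) + float(gpos[k])
        db[p] = db.get(p, 0.0) - float(gpos[k])
    return delta, da, db


# ---------------------------------------------------------------------------
# Observational equations
# ---------------------------------------------------------------------------

def _distance_and_grads(model: CrystalModel, la: str, lb: str):
    """d(A,B) in Å and ∂d/∂frac for both atoms (3-vectors each)."""
    g, _, _ = metric_tensors(model.cell)
    a, b = model.get_site(la), model.get_site(lb)
    delta = np.asarray(a.frac) - np.asarray(b.frac)
    d = math.sqrt(float(delta @ g @ delta))
    if d < 1e-8:
        raise MicrorefineError(f"coincident atoms {la}/{lb} in distance restraint")
    grad = (g @ delta) / d
    return d, grad, -grad


def _angle_and_grads(model: CrystalModel, la: str, lb: str, lc: str):
    """Angle A-B-C in degrees and fractional gradients for the three atoms."""
    m = orthogonalization_matrix(model.cell)
    xa = m @ model.get_site(la).frac
    xb = m @ model.get_site(lb).frac
    xc = m @ model.get_site(lc).frac
    u, v = xa - xb, xc - xb
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-8 or nv < 1e-8:
        raise MicrorefineError(f"degenerate angle {la}-{lb}-{lc}")
    cosang = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    sinang = math.sqrt(max(1.0 - cosang**2, 1e-16))
    # dθ/du and dθ/dv in Cartesian (radians)
    du = (cosang * u / nu**2 - v / (nu * nv)) / sinang
    dv = (cosang * v / nv**2 - u / (nu * nv)) / sinang
    deg = 180.0 / math.pi
    ga = deg * (m.T @ du)
    gc = deg * (m.T @ dv)
    gb = -(ga + gc)
    return ang, ga, gb, gc


def restraint_equation(restraint: Restraint, model: CrystalModel, param_map):
    """Weighted residual and sparse Jacobian row for one restraint.

    Returns ``(residual, jacobian)`` with residual = (current − target)/σ
    and jacobian a {free-index: value/σ} dict.  For asymmetric restraints
    the reference group's entries are zeroed before mapping, so the
    reference only guides and is never pulled.
    """
    kind = restraint.kind
    sigma = restraint.sigma
    contribs: dict = {}  # (label, pname) -> d(residual·σ)/d(param)
    ref_labels: set = set()

    if kind == "DISTANCE":
        d, ga, gb = _distance_and_grads(model, *restraint.atoms)
        value = d - restraint.target
        for lab, grad in zip(restraint.atoms, (ga, gb)):
            for k, p in enumerate(("x", "y", "z")):
                contribs[(lab, p)] = contribs.get((lab, p), 0.0) + grad[k]
    elif kind == "ANGLE":
        ang, ga, gb, gc = _angle_and_grads(model, *restraint.atoms)
        value = ang - restraint.target
        for lab, grad in zip(restraint.atoms, (ga, gb, gc)):
            for k, p in enumerate(("x", "y", "z")):
                contribs[(lab, p)] = contribs.get((lab, p), 0.0) + grad[k]
    elif kind in ("EQUIV_DISTANCE", "EQUIV_ANGLE"):
        d1, g1a, g1b = _distance_and_grads(model, *restraint.atoms)
        d2, g2a, g2b = _distance_and_grads(model, *restraint.atoms2)
        value = d2 - d1
        for lab, grad in zip(restraint.atoms2, (g2a, g2b)):
            for k, p in enumerate(("x", "y", "z")):
                contribs[(lab, p)] = contribs.get((lab, p), 0.0) + grad[k]
        for lab, grad in zip(restraint.atoms, (g1a, g1b)):
            for k, p in enumerate(("x", "y", "z")):
                contribs[(lab, p)] = contribs.get((lab, p), 0.0) - grad[k]
        if restraint.asymmetric:
            ref_labels.update(restraint.atoms)
    elif kind == "SIMU":
        la, lb = restraint.atoms
        ua, chain_a = _u_cif_and_chain(model, la)
        ub, chain_b = _u_cif_and_chain(model, lb)
        # component-wise equations are emitted one per call via sub-index;
        # here we fold them into a single combined residual per component
        # list — instead, SIMU restraints are expanded per component below.
        rows = []
        for comp in range(6):
            value = float(ua[comp] - ub[comp])
            contribs = {}
            for p, dvec in chain_a.items():
                contribs[(la, p)] = contribs.get((la, p), 0.0) + float(dvec[comp])
            for p, dvec in chain_b.items():
                contribs[(lb, p)] = contribs.get((lb, p), 0.0) - float(dvec[comp])
            if restraint.asymmetric:
                contribs = {k: v for k, v in contribs.items() if k[0] != la}
            rows.append(_finalize(value, contribs, sigma, param_map))
        return rows
    elif kind == "DELU":
        la, lb = restraint.atoms
        delta, da, db = _hirshfeld_core(model, la, lb)
        value = delta - (restraint.target or 0.0)
        for p, dv in da.items():
            contribs[(la, p)] = dv
        for p, dv in db.items():
            contribs[(lb, p)] = dv
        if restraint.asymmetric:
            ref_labels.add(la)
    elif kind == "LIMIT":
        return shift_limit_equations(param_map, sigma)
    else:
        raise ValueError(f"unknown restraint kind {kind!r}")

    if ref_labels:
        contribs = {k: v for k, v in contribs.items() if k[0] not in ref_labels}
    return _finalize(value, contribs, sigma, param_map)


def _finalize(value, contribs, sigma, param_map):
    residual = value / sigma
    jac: dict[int, float] = {}
    for key, dval in contribs.items():
        for i, c in param_map.entries(*key):
            jac[i] = jac.get(i, 0.0) + c * dval / sigma
    jac = {i: v for i, v in jac.items() if v != 0.0}
    return residual, jac


def equations_for(restraints, model: CrystalModel, param_map):
    """Flat list of (residual, jacobian) rows for a whole restraint set."""
    rows = []
    for r in restraints:
        eq = restraint_equation(r, model, param_map)
        if isinstance(eq, list):
            rows.extend(eq)
        else:
            rows.append(eq)
    return rows


def shift_limit_equations(param_map, sigma: float):
    """One damping equation per free parameter: residual 0, weight 1/σ².

    Accumulating these adds 1/σ² to every diagonal element of the normal
    matrix — additive Levenberg-style damping; σ→∞ leaves shifts unchanged.
    """
    if sigma <= 0:
        raise ValueError("shift-limit sigma must be > 0")
    return [(0.0, {i: 1.0 / sigma}) for i in range(param_map.n_free)]
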