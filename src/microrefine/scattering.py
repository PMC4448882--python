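"""Structure factors, form factors, shape transforms and fit statistics.

The calculated structure factor of the model is

    Fc(h) = K · Σ_sym Σ_sites occ · f(s) · T(h) · S(q) · exp(2πi h·(Rx+t))

with K the overall scale, f(s) the element form factor at s = sinθ/λ,
T the Debye-Waller attenuation (isotropic or anisotropic, CIF U
convention) and S(q) the real smearing factor of a special shape (1 for
ordinary atoms).  A per-reflection complex solvent term, e.g. from a
void-density analysis, is added to the molecular sum before taking the
modulus:  |Fc| = |Fc_molecule + Fc_solvent|.

Shape smearing factors (uniform densities, in the Cartesian frame):

* spherical shell, radius R:          S = sin(qR)/(qR)            (j₀)
* line, length L, axis n:             S = sinc(q·n · L/2)
* ideal ring torus, radius R, normal n: S = J₀(R |q − (q·n)n|)

each multiplied by multiplicity, occupancy, the element form factor and
the isotropic Debye-Waller factor of the shape's u_iso.

Analytic derivatives are provided for coordinates, ADPs, occupancies and
the overall scale; shape magnitude/declination/azimuth derivatives use a
five-point central difference (Bessel-term derivatives are deliberately
not hand-coded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.special import j0 as _bessel_j0

from .crystal_model import (
    ANISO_COMPONENTS,
    CrystalModel,
    SpecialShapeSite,
    metric_tensors,
    orthogonalization_matrix,
)
from .exceptions import MissingScattererError

__all__ = [
    "FormFactorTable",
    "StructureFactorSet",
    "atomic_form_factor",
    "debye_waller",
    "shape_form_factor",
    "calc_structure_factors",
    "design_row",
    "design_matrix",
    "agreement_statistics",
]

TWO_PI = 2.0 * math.pi

# central-difference steps for shape parameters (Å for magnitude, degrees
# for declination/azimuth)
SHAPE_FD_STEP = 1e-5


# ---------------------------------------------------------------------------
# Form factors
# ---------------------------------------------------------------------------

class FormFactorTable:
    """Sum-of-Gaussians X-ray form factors f(s) = Σ aᵢ exp(−bᵢ s²) + c.

    Coefficients default to the International Tables 4-Gaussian fits as
    shipped by gemmi; ``custom`` entries {element: (a[4], b[4], c)}
    override or extend the built-ins.
    """

    def __init__(self, custom: dict | None = None):
        self._cache: dict[str, tuple] = {}
        if custom:
            for el, (a, b, c) in custom.items():
                self._cache[el] = (np.asarray(a, float), np.asarray(b, float), float(c))

    def coefficients(self, element: str) -> tuple:
        if element not in self._cache:
            el = gemmi.Element(element)
            if el.atomic_number == 0:
                raise MissingScattererError(f"no form factor for element {element!r}")
            it92 = el.it92
            self._cache[element] = (
                np.asarray(it92.a, float),
                np.asarray(it92.b, float),
                float(it92.c),
            )
        return self._cache[element]

    def value(self, element: str, s) -> np.ndarray | float:
        """f at s = sinθ/λ (Å⁻¹); accepts scalars or arrays."""
        a, b, c = self.coefficients(element)
        s2 = np.square(np.asarray(s, dtype=float))
        out = c + np.sum(a * np.exp(-b * s2[..., None]), axis=-1)
        return float(out) if out.ndim == 0 else out


def atomic_form_factor(element: str, s: float, table: FormFactorTable | None = None) -> float:
    """Element form factor at s = sinθ/λ in Å⁻¹, in electrons."""
    if s < 0:
        raise ValueError("s must be >= 0")
    table = table or FormFactorTable()
    return float(table.value(element, s))


# ---------------------------------------------------------------------------
# Debye-Waller factors
# ---------------------------------------------------------------------------

def debye_waller(adp, hkl, cell) -> float:
    """Attenuation factor for one reflection.

    ``adp`` is either a scalar u_iso or the six CIF Uij (Å²):
    isotropic  exp(−8π² u s²) ;
    anisotropic exp(−2π² Σᵢⱼ Uᵢⱼ hᵢ hⱼ aᵢ* aⱼ*).

    A non-positive-semidefinite tensor yields a warning diagnostic but the
    factor is still returned.
    """
    h = np.asarray(hkl, dtype=float)
    _, gstar, _ = metric_tensors(cell)
    adp_arr = np.atleast_1d(np.asarray(adp, dtype=float))
    if adp_arr.size == 1:
        s2 = float(h @ gstar @ h) / 4.0
        return math.exp(-8.0 * math.pi**2 * float(adp_arr[0]) * s2)
    if adp_arr.size != 6:
        raise ValueError("adp must be a scalar u_iso or six CIF Uij")
    bmat = _aniso_exponent_matrix(cell, adp_arr)
    from .crystal_model import u_cif_to_cartesian

    if np.min(np.linalg.eigvalsh(u_cif_to_cartesian(cell, adp_arr))) < -1e-12:
        import warnings

        warnings.warn("anisotropic ADP is not positive semi-definite", stacklevel=2)
    return math.exp(-(h @ bmat @ h))


def _aniso_exponent_matrix(cell, u6) -> np.ndarray:
    """Matrix B with DW = exp(−hᵗ B h):  B = 2π² diag(a*) U diag(a*)."""
    _, gstar, _ = metric_tensors(cell)
    astar = np.sqrt(np.diag(gstar))
    u11, u22, u33, u12, u13, u23 = u6
    u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
    return 2.0 * math.pi**2 * np.outer(astar, astar) * u


# ---------------------------------------------------------------------------
# Special-shape smearing factors
# ---------------------------------------------------------------------------

def _shape_factor_arrays(kind: str, magnitude: float, axis: np.ndarray | None, q: np.ndarray) -> np.ndarray:
    """Smearing factor for an (n,3) array of Cartesian q vectors (Å⁻¹)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if kind == "shell":
        x = np.linalg.norm(q, axis=1) * magnitude
        return np.sinc(x / math.pi)  # sin(x)/x
    if kind == "line":
        x = (q @ axis) * (magnitude / 2.0)
        return np.sinc(x / math.pi)
    if kind == "torus":
        qpar = np.outer(q @ axis, axis)
        qperp = np.linalg.norm(q - qpar, axis=1)
        return _bessel_j0(magnitude * qperp)
    raise ValueError(f"unknown special shape kind {kind!r}")


def shape_form_factor(shape: SpecialShapeSite, q_cartesian) -> float | np.ndarray:
    """Real smearing factor of a shape for Cartesian scattering vector(s) q.

    q has |q| = 2π/d for a reflection of resolution d.  The value is 1 at
    q → 0 for every shape.
    """
    axis = shape.axis() if shape.kind in ("line", "torus") else None
    out = _shape_factor_arrays(shape.kind, shape.magnitude, axis, q_cartesian)
    return float(out[0]) if np.asarray(q_cartesian).ndim == 1 else out


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

@dataclass
class StructureFactorSet:
    """Per-reflection complex molecular and solvent structure factors."""

    hkl: np.ndarray
    f_molecule: np.ndarray
    f_solvent: np.ndarray = field(default=None)

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.f_molecule = np.asarray(self.f_molecule, dtype=complex)
        if self.f_solvent is None:
            self.f_solvent = np.zeros_like(self.f_molecule)
        self.f_solvent = np.asarray(self.f_solvent, dtype=complex)

    @property
    def f_total(self) -> np.ndarray:
        return self.f_molecule + self.f_solvent

    @property
    def amplitude(self) -> np.ndarray:
        """|Fc| = |Fc_molecule + Fc_solvent|."""
        return np.abs(self.f_total)

    @property
    def phase(self) -> np.ndarray:
        """Phase in degrees."""
        return np.degrees(np.angle(self.f_total))


class _SFContext:
    """Precomputed geometry shared by Fc and derivative evaluation."""

    def __init__(self, model: CrystalModel, hkl: np.ndarray, table: FormFactorTable):
        self.model = model
        self.table = table
        self.H = np.atleast_2d(np.asarray(hkl, dtype=float))
        g, gstar, _ = metric_tensors(model.cell)
        self.gstar = gstar
        self.s2 = 0.25 * np.einsum("ni,ij,nj->n", self.H, gstar, self.H)
        self.s = np.sqrt(self.s2)
        m = orthogonalization_matrix(model.cell)
        self.minv = np.linalg.inv(m)
        self.m = m
        self.astar = np.sqrt(np.diag(gstar))
        self.ops = model.symmetry
        # rotated indices and translation phases per op
        self.heff = [self.H @ op.rot for op in self.ops]
        self.phase_t = [self.H @ op.tran for op in self.ops]
        # Cartesian rotation of each op (for shape axes)
        self.cart_rot = [m @ op.rot @ self.minv for op in self.ops]
        self.f_el: dict[str, np.ndarray] = {}

    def form_factor(self, element: str) -> np.ndarray:
        if element not in self.f_el:
            self.f_el[element] = self.table.value(element, self.s)
        return self.f_el[element]

    def atom_op_contrib(self, site, iop: int):
        """Per-reflection complex contribution of one site under one op,
        split as (occ-free base, occ·base); shapes included."""
        heff = self.heff[iop]
        phase = TWO_PI * (heff @ site.frac + self.phase_t[iop])
        f = self.form_factor(site.element)
        if isinstance(site, SpecialShapeSite):
            dw = np.exp(-8.0 * math.pi**2 * site.u_iso * self.s2)
            q = TWO_PI * (heff @ self.minv)
            axis = self.cart_rot[iop] @ site.axis() if site.kind in ("line", "torus") else None
            sf = _shape_factor_arrays(site.kind, site.magnitude, axis, q)
            base = site.multiplicity * f * dw * sf * np.exp(1j * phase)
        else:
            if site.u_aniso is not None:
                b = _aniso_exponent_matrix(self.model.cell, site.u_aniso)
                dw = np.exp(-np.einsum("ni,ij,nj->n", heff, b, heff))
            else:
                dw = np.exp(-8.0 * math.pi**2 * (site.u_iso or 0.0) * self.s2)
            base = f * dw * np.exp(1j * phase)
        return base


def calc_structure_factors(
    model: CrystalModel,
    reflections,
    solvent=None,
    table: FormFactorTable | None = None,
) -> StructureFactorSet:
    """Complex structure factors for an (n,3) array of Miller indices.

    ``solvent`` is an optional aligned complex array added to the molecular
    term before the modulus is taken.  Friedel symmetry Fc(−h) = conj(Fc(h))
    holds by construction (no anomalous scattering).
    """
    hkl = np.atleast_2d(np.asarray(reflections, dtype=int))
    if solvent is not None:
        solvent = np.asarray(solvent, dtype=complex)
        if solvent.shape[0] != hkl.shape[0]:
            raise ValueError(
                f"solvent array length {solvent.shape[0]} does not match "
                f"{hkl.shape[0]} reflections"
            )
    ctx = _SFContext(model, hkl, table or FormFactorTable())
    fmol = np.zeros(hkl.shape[0], dtype=complex)
    for site in model.sites():
        for iop in range(len(ctx.ops)):
            fmol += site.occupancy * ctx.atom_op_contrib(site, iop)
    fmol *= model.scale
    return StructureFactorSet(hkl=hkl, f_molecule=fmol, f_solvent=solvent)


# ---------------------------------------------------------------------------
# Derivatives (design matrix)
# ---------------------------------------------------------------------------

def _complex_derivatives(ctx: _SFContext, param_map) -> dict:
    """dFc_molecule/d(slot) as complex per-reflection arrays, unscaled by K
    except where noted; keyed by (label, pname)."""
    model = ctx.model
    derivs: dict = {}

    def want(label, pname):
        return bool(param_map.entries(label, pname))

    for site in model.sites():
        label = site.label
        is_shape = isinstance(site, SpecialShapeSite)
        pos_wanted = any(want(label, p) for p in ("x", "y", "z"))
        occ_wanted = want(label, "occ")
        uiso_wanted = want(label, "uiso")
        aniso_wanted = [c for c in ANISO_COMPONENTS if want(label, c)] if not is_shape else []
        shape_wanted = [p for p in ("mag", "decl", "azim") if want(label, p)] if is_shape else []
        if not (pos_wanted or occ_wanted or uiso_wanted or aniso_wanted or shape_wanted):
            continue
        acc: dict = {}
        for iop in range(len(ctx.ops)):
            base = ctx.atom_op_contrib(site, iop)
            contrib = site.occupancy * base
            heff = ctx.heff[iop]
            if pos_wanted:
                for k, p in enumerate(("x", "y", "z")):
                    acc[p] = acc.get(p, 0) + contrib * (TWO_PI * 1j * heff[:, k])
            if occ_wanted:
                acc["occ"] = acc.get("occ", 0) + base
            if uiso_wanted and getattr(site, "u_aniso", None) is None:
                acc["uiso"] = acc.get("uiso", 0) + contrib * (-8.0 * math.pi**2 * ctx.s2)
            for comp in aniso_wanted:
                i, j = {"u11": (0, 0), "u22": (1, 1), "u33": (2, 2),
                        "u12": (0, 1), "u13": (0, 2), "u23": (1, 2)}[comp]
                mult = 1.0 if i == j else 2.0
                coef = -2.0 * math.pi**2 * mult * ctx.astar[i] * ctx.astar[j]
                acc[comp] = acc.get(comp, 0) + contrib * (coef * heff[:, i] * heff[:, j])
            if shape_wanted:
                # five-point central difference on the shape factor only
                q = TWO_PI * (heff @ ctx.minv)
                f = ctx.form_factor(site.element)
                dw = np.exp(-8.0 * math.pi**2 * site.u_iso * ctx.s2)
                phase = np.exp(1j * TWO_PI * (heff @ site.frac + ctx.phase_t[iop]))
                pref = site.occupancy * site.multiplicity * f * dw * phase

                def sfac(mag, decl, azim):
                    if site.kind in ("line", "torus"):
                        d, a = math.radians(decl), math.radians(azim)
                        ax = ctx.cart_rot[iop] @ np.array(
                            [math.sin(d) * math.cos(a), math.sin(d) * math.sin(a), math.cos(d)]
                        )
                    else:
                        ax = None
                    return _shape_factor_arrays(site.kind, mag, ax, q)

                p0 = {"mag": site.magnitude, "decl": site.declination, "azim": site.azimuth}
                for p in shape_wanted:
                    h = SHAPE_FD_STEP

                    def at(delta, p=p):
                        args = dict(p0)
                        args[p] += delta
                        return sfac(args["mag"], args["decl"], args["azim"])

                    dsf = (-at(2 * h) + 8 * at(h) - 8 * at(-h) + at(-2 * h)) / (12 * h)
                    acc[p] = acc.get(p, 0) + pref * dsf
        for pname, val in acc.items():
            derivs[(label, pname)] = model.scale * val
    return derivs


def design_matrix(
    model: CrystalModel,
    hkl,
    param_map,
    mode: str = "F2",
    solvent=None,
    table: FormFactorTable | None = None,
):
    """Design matrix ∂Yc/∂p (n_refl × n_free) and the StructureFactorSet.

    ``mode`` selects the refinement target Y: "F" (|Fc|) or "F2" (|Fc|²).
    Riding-hydrogen and other constraint chains fold follower derivatives
    onto their leaders' columns through the parameter map.
    """
    if mode not in ("F", "F2"):
        raise ValueError(f"mode must be 'F' or 'F2', got {mode!r}")
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    table = table or FormFactorTable()
    sf = calc_structure_factors(model, hkl, solvent=solvent, table=table)
    ctx = _SFContext(model, hkl, table)
    cderivs = _complex_derivatives(ctx, param_map)
    # scale derivative: dFc_mol/dK = Fc_mol / K
    if param_map.entries("", "scale"):
        cderivs[("", "scale")] = sf.f_molecule / model.scale

    ftot = sf.f_total
    amp = np.abs(ftot)
    B = np.zeros((hkl.shape[0], param_map.n_free))
    for key, dfc in cderivs.items():
        if mode == "F2":
            dy = 2.0 * np.real(np.conj(ftot) * dfc)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                dy = np.where(amp > 0, np.real(np.conj(ftot) * dfc) / np.where(amp > 0, amp, 1.0), 0.0)
        for i, c in param_map.entries(*key):
            B[:, i] += c * dy
    return B, sf


def design_row(model, hkl, param_map, mode: str = "F2", solvent=None, table=None) -> np.ndarray:
    """Single derivative row ∂Yc/∂p for one reflection."""
    B, _ = design_matrix(model, np.asarray(hkl, dtype=int).reshape(1, 3), param_map,
                         mode=mode, solvent=solvent, table=table)
    return B[0]


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def agreement_statistics(yo, sigma, yc, weights=None, n_params: int = 0, mode: str = "F2") -> dict:
    """Least-squares objective and standard agreement indices.

    M   = Σ w (Yo − Yc)²           (the minimised function)
    R1  = Σ | |Fo| − |Fc| | / Σ |Fo|
    GoF = sqrt(M / (n_obs − n_params)), None when n_obs ≤ n_params.
    """
    yo = np.asarray(yo, dtype=float)
    yc = np.asarray(yc, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if weights is None:
        with np.errstate(divide="ignore"):
            weights = np.where(sigma > 0, 1.0 / sigma**2, 0.0)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    m = float(np.sum(weights * (yo - yc) ** 2))
    if mode == "F2":
        fo = np.sqrt(np.clip(yo, 0.0, None))
        fc = np.sqrt(np.clip(yc, 0.0, None))
    else:
        fo, fc = np.abs(yo), np.abs(yc)
    denom = float(np.sum(fo))
    r1 = float(np.sum(np.abs(fo - fc)) / denom) if denom > 0 else float("nan")
    n_obs = yo.size
    gof = math.sqrt(m / (n_obs - n_params)) if n_obs > n_params else None
    return {"M": m, "R1": r1, "GoF": gof, "n_obs": n_obs, "n_params": n_params}
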