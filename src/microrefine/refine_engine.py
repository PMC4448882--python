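"""Normal-equations assembly, conditioning, solving and the refinement loop.

The least-squares cycle minimises M = Σ w (Yo − Yc)² over data and
restraints jointly.  Reflections are processed in batches: each batch's
design-matrix block B is formed, then N += Bᵗ W B and g += Bᵗ W r are
accumulated in double precision (the result is batch-size invariant).
Restraint rows are so sparse — a distance restraint touches at most six
parameters — that they are accumulated one by one as rank-1 updates of
the affected sub-block only.

Before solving, the normal matrix is preconditioned by the diagonal
matrix C with Cᵢᵢ = 1/√Nᵢᵢ, so N' = C N C has unit diagonal; the inverse
is recovered as N⁻¹ = C N'⁻¹ C.  The solve itself is an LDLᵗ
(Bunch-Kaufman) factorisation that fails loudly, naming the offending
parameters, when a pivot underflows; eigenvalue filtering is the
opt-in fallback that discards near-null eigenvalue contributions and
always returns finite shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .crystal_model import CrystalModel, ParameterMap
from .exceptions import NothingToRefineError, SingularMatrixError
from .restraints import equations_for, shift_limit_equations
from .scattering import FormFactorTable, agreement_statistics, design_matrix

__all__ = [
    "NormalEquations",
    "RefineConfig",
    "RefinementResult",
    "accumulate_normal_matrix",
    "accumulate_restraints",
    "precondition",
    "solve_normal_equations",
    "condition_diagnostics",
    "refine",
]


@dataclass
class NormalEquations:
    """N = AᵗWA, gradient g = AᵗW r, and bookkeeping counts."""

    N: np.ndarray
    g: np.ndarray
    n_obs: int = 0
    n_restraints: int = 0
    C: np.ndarray | None = None
    undetermined: tuple = ()

    @property
    def n_free(self) -> int:
        return self.g.shape[0]


@dataclass
class RefineConfig:
    """Engine options.

    target: 'F2' refines against intensities, 'F' against amplitudes.
    weights: 'sigma' → w = 1/σ²(Yo); 'unit' → w = 1.
    shift_limit: σ of optional shift-limiting (damping) restraints; None off.
    solver: 'ldlt' (fails on singular N) or 'eigen_filter' (pseudo-inverse).
    tol: convergence when max |shift|/esd < tol.
    """

    target: str = "F2"
    weights: str = "sigma"
    batch_size: int = 256
    max_cycles: int = 20
    tol: float = 0.01
    solver: str = "ldlt"
    filter_tol: float = 1e-8
    shift_limit: float | None = None
    compute_esds: bool = True
    table: FormFactorTable | None = None


@dataclass
class RefinementResult:
    """Refined model plus per-cycle history and esds."""

    model: CrystalModel
    history: list = field(default_factory=list)
    esds: dict = field(default_factory=dict)
    param_names: list = field(default_factory=list)
    converged: bool = False
    diverged: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def final(self) -> dict:
        return self.history[-1] if self.history else {}


# ---------------------------------------------------------------------------
# Accumulation
# ---------------------------------------------------------------------------

def _observation_arrays(reflections, mode: str):
    """(Yo, σ) on the refinement-target scale from a ReflectionSet."""
    if mode == "F2":
        return np.asarray(reflections.y, float), np.asarray(reflections.sigma, float)
    return reflections.amplitude_data()


def accumulate_normal_matrix(
    model: CrystalModel,
    reflections,
    param_map: ParameterMap,
    batch_size: int = 256,
    mode: str = "F2",
    weights: str = "sigma",
    table: FormFactorTable | None = None,
) -> NormalEquations:
    """Assemble N and g from the diffraction data in reflection batches."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = param_map.n_free
    if n == 0:
        raise NothingToRefineError("no free parameters")
    N = np.zeros((n, n))
    g = np.zeros(n)
    hkl = np.asarray(reflections.hkl, dtype=int)
    yo, sig = _observation_arrays(reflections, mode)
    w = np.ones_like(yo) if weights == "unit" else np.where(sig > 0, 1.0 / sig**2, 0.0)
    solvent = getattr(reflections, "solvent", None)
    yc_all = np.empty_like(yo)
    for start in range(0, hkl.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        solv = solvent[sl] if solvent is not None else None
        B, sf = design_matrix(model, hkl[sl], param_map, mode=mode, solvent=solv, table=table)
        amp = sf.amplitude
        yc = amp**2 if mode == "F2" else amp
        yc_all[sl] = yc
        wb = w[sl]
        N += (B * wb[:, None]).T @ B
        g += B.T @ (wb * (yo[sl] - yc))
    ne = NormalEquations(N=N, g=g, n_obs=hkl.shape[0])
    ne.yc = yc_all  # cached for statistics
    ne.w = w
    return ne


def accumulate_restraints(ne: NormalEquations, restraint_rows) -> NormalEquations:
    """Sparse one-by-one accumulation of restraint equations into N and g."""
    n = ne.n_free
    for residual, jac in restraint_rows:
        if not jac:
            ne.n_restraints += 1
            continue
        idx = np.fromiter(jac.keys(), dtype=int)
        if idx.min() < 0 or idx.max() >= n:
            raise IndexError(f"restraint row index out of range (n_free={n})")
        vals = np.fromiter(jac.values(), dtype=float)
        ne.N[np.ix_(idx, idx)] += np.outer(vals, vals)
        ne.g[idx] += vals * (-residual)
        ne.n_restraints += 1
    return ne


# ---------------------------------------------------------------------------
# Conditioning and solving
# ---------------------------------------------------------------------------

def precondition(ne: NormalEquations):
    """Unit-diagonal scaling: N' = C N C with Cᵢᵢ = 1/√Nᵢᵢ.

    Zero-diagonal parameters are flagged undetermined and excluded (their
    row/column replaced by the identity so the solve stays well-posed and
    their shift is exactly zero).
    """
    diag = np.diag(ne.N).copy()
    if np.all(diag <= 0):
        raise NothingToRefineError("normal matrix has an all-zero diagonal")
    mask = diag > 0
    C = np.where(mask, 1.0 / np.sqrt(np.where(mask, diag, 1.0)), 0.0)
    Np = (C[:, None] * ne.N) * C[None, :]
    dead = np.where(~mask)[0]
    for i in dead:
        Np[i, :] = 0.0
        Np[:, i] = 0.0
        Np[i, i] = 1.0
    ne.C = C
    ne.undetermined = tuple(int(i) for i in dead)
    return Np, C


def _ldlt_solve(Np: np.ndarray, gp: np.ndarray, names=None, pivot_tol: float = 1e-10):
    """Solve N' x = g' via Bunch-Kaufman LDLᵗ; also return N'⁻¹.

    Raises SingularMatrixError naming the parameter(s) behind an
    underflowing pivot block.
    """
    lu, d, perm = scipy.linalg.ldl(Np, lower=True)
    # detect singular pivots in the block-diagonal D
    n = Np.shape[0]
    ref = max(np.abs(d).max(), 1.0)
    bad: list[int] = []
    i = 0
    while i < n:
        if i + 1 < n and d[i + 1, i] != 0.0:
            det = d[i, i] * d[i + 1, i + 1] - d[i, i + 1] * d[i + 1, i]
            if abs(det) < (pivot_tol * ref) ** 2:
                bad.extend([perm[i], perm[i + 1]])
            i += 2
        else:
            if abs(d[i, i]) < pivot_tol * ref:
                bad.append(perm[i])
            i += 1
    if bad:
        labels = [names[j] for j in bad] if names else [str(j) for j in bad]
        raise SingularMatrixError(
            "singular normal matrix: zero pivot for parameter(s) " + ", ".join(labels),
            parameter_indices=bad,
            parameter_names=labels,
        )
    L = lu[perm, :]  # lower triangular
    rhs = np.column_stack([gp, np.eye(n)])
    z = scipy.linalg.solve_triangular(L, rhs[perm, :], lower=True)
    wv = _block_diag_solve(d, z)
    y = scipy.linalg.solve_triangular(L.T, wv, lower=False)
    out = np.empty_like(rhs)
    out[perm, :] = y
    x = out[:, 0]
    ninv = out[:, 1:]
    return x, ninv


def _block_diag_solve(d: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve D z = b for the 1×1/2×2 block-diagonal D from scipy's ldl."""
    n = d.shape[0]
    z = np.empty_like(b)
    i = 0
    while i < n:
        if i + 1 < n and d[i + 1, i] != 0.0:
            blk = d[i : i + 2, i : i + 2]
            z[i : i + 2] = np.linalg.solve(blk, b[i : i + 2])
            i += 2
        else:
            z[i] = b[i] / d[i, i]
            i += 1
    return z


def solve_normal_equations(
    Np: np.ndarray,
    gp: np.ndarray,
    method: str = "ldlt",
    filter_tol: float = 1e-8,
    names=None,
):
    """Solve the preconditioned system; returns (shifts', N'⁻¹).

    'ldlt' raises SingularMatrixError on a numerically singular matrix;
    'eigen_filter' discards eigenvalue contributions below
    filter_tol × λ_max (pseudo-inverse) and always returns finite shifts.
    """
    Np = np.asarray(Np, dtype=float)
    if not np.allclose(Np, Np.T, atol=1e-10 * max(1.0, np.abs(Np).max())):
        raise ValueError("normal matrix must be symmetric")
    if method == "ldlt":
        return _ldlt_solve(Np, np.asarray(gp, float), names=names)
    if method == "eigen_filter":
        evals, evecs = np.linalg.eigh(Np)
        lam_max = float(evals.max())
        keep = evals > filter_tol * max(lam_max, 0.0)
        inv_evals = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
        ninv = (evecs * inv_evals) @ evecs.T
        return ninv @ np.asarray(gp, float), ninv
    raise ValueError(f"unknown solver {method!r}")


def condition_diagnostics(Np: np.ndarray, names=None, k: int = 3, top: int = 4) -> dict:
    """λ_max/λ_min plus the dominant parameters of the k smallest eigenvectors.

    The largest-|component| labels of each small eigenvector name the
    near-collinear parameter combination behind an ill-conditioned system.
    """
    evals, evecs = np.linalg.eigh(np.asarray(Np, float))
    lam_min, lam_max = float(evals[0]), float(evals[-1])
    cond = math.inf if lam_min <= 0 else lam_max / lam_min
    modes = []
    for i in range(min(k, evals.size)):
        vec = evecs[:, i]
        order = np.argsort(-np.abs(vec))[:top]
        modes.append(
            {
                "eigenvalue": float(evals[i]),
                "indices": [int(j) for j in order],
                "labels": [names[j] if names else str(j) for j in order],
                "components": [float(vec[j]) for j in order],
            }
        )
    return {"condition_number": cond, "lambda_min": lam_min, "lambda_max": lam_max, "modes": modes}


# ---------------------------------------------------------------------------
# The refinement loop
# ---------------------------------------------------------------------------

def _cycle_statistics(reflections, yc, w, n_params, mode):
    yo, sig = _observation_arrays(reflections, mode)
    return agreement_statistics(yo, sig, yc, weights=w, n_params=n_params, mode=mode)


def refine(
    model: CrystalModel,
    reflections,
    param_map: ParameterMap,
    restraints=None,
    config: RefineConfig | None = None,
) -> RefinementResult:
    """Full-matrix least-squares refinement.

    Per cycle: structure factors and design rows → batched normal-equation
    accumulation → one-by-one restraint accumulation (+ optional
    shift-limiting damping) → preconditioning → solve → shifts applied
    through all constraint chains → statistics.  Stops at ``max_cycles``
    or when max |shift|/esd < tol; flags divergence when M rises on three
    consecutive cycles.  esd(pᵢ) = GoF · √(N⁻¹)ᵢᵢ, mapped back through C.
    """
    config = config or RefineConfig()
    work = model.copy()
    param_map.refresh_dependents(work)
    restraint_list = list(restraints) if restraints is not None else []
    n_free = param_map.n_free
    if reflections.hkl.shape[0] < n_free and not restraint_list:
        import warnings

        warnings.warn(
            f"fewer observations ({reflections.hkl.shape[0]}) than parameters "
            f"({n_free}) and no restraints",
            stacklevel=2,
        )

    result = RefinementResult(model=work, param_names=list(param_map.names))
    rises = 0
    prev_m = None

    for cycle in range(max(config.max_cycles, 0) + 1):
        ne = accumulate_normal_matrix(
            work, reflections, param_map,
            batch_size=config.batch_size, mode=config.target,
            weights=config.weights, table=config.table,
        )
        rows = equations_for(restraint_list, work, param_map)
        if config.shift_limit is not None:
            rows = rows + shift_limit_equations(param_map, config.shift_limit)
        accumulate_restraints(ne, rows)
        m_restr = sum(r * r for r, _ in rows)
        stats = _cycle_statistics(reflections, ne.yc, ne.w, n_free, config.target)
        m_total = stats["M"] + m_restr
        n_total = ne.n_obs + ne.n_restraints
        gof_aug = (
            math.sqrt(m_total / (n_total - n_free)) if n_total > n_free else None
        )

        entry = {
            "cycle": cycle,
            "M": m_total,
            "M_data": stats["M"],
            "R1": stats["R1"],
            "GoF": gof_aug,
            "max_shift_over_esd": None,
        }

        if cycle == config.max_cycles or config.max_cycles == 0:
            result.history.append(entry)
            break

        Np, C = precondition(ne)
        gp = C * ne.g
        shifts_p, ninv_p = solve_normal_equations(
            Np, gp, method=config.solver, filter_tol=config.filter_tol,
            names=param_map.names,
        )
        shifts = C * shifts_p
        var = C**2 * np.clip(np.diag(ninv_p), 0.0, None)
        gof_for_esd = gof_aug if gof_aug else 1.0
        esds = gof_for_esd * np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(esds > 0, np.abs(shifts) / esds, 0.0)
        entry["max_shift_over_esd"] = float(ratio.max()) if ratio.size else 0.0
        result.history.append(entry)
        result.esds = dict(zip(param_map.names, esds))

        param_map.apply_shifts(work, shifts)

        # negligible absolute shifts (noiseless data at the numerical floor)
        # also count as convergence: the shift/esd ratio is ill-posed there
        at_floor = float(np.abs(shifts).max()) < 1e-8 if shifts.size else True

        if prev_m is not None and entry["M"] > prev_m * (1.0 + 1e-9) and not at_floor:
            rises += 1
            if rises >= 3:
                result.diverged = True
                break
        else:
            rises = 0
        prev_m = entry["M"]

        if entry["max_shift_over_esd"] < config.tol or at_floor:
            result.converged = True
            # final statistics at the converged model
            ne_f = accumulate_normal_matrix(
                work, reflections, param_map,
                batch_size=config.batch_size, mode=config.target,
                weights=config.weights, table=config.table,
            )
            stats_f = _cycle_statistics(reflections, ne_f.yc, ne_f.w, n_free, config.target)
            rows_f = equations_for(restraint_list, work, param_map)
            m_restr_f = sum(r * r for r, _ in rows_f)
            result.history.append(
                {
                    "cycle": cycle + 1,
                    "M": stats_f["M"] + m_restr_f,
                    "M_data": stats_f["M"],
                    "R1": stats_f["R1"],
                    "GoF": entry["GoF"],
                    "max_shift_over_esd": None,
                }
            )
            break

    # condition diagnostics at the final model
    try:
        ne_d = accumulate_normal_matrix(
            work, reflections, param_map,
            batch_size=config.batch_size, mode=config.target,
            weights=config.weights, table=config.table,
        )
        accumulate_restraints(ne_d, equations_for(restraint_list, work, param_map))
        Np_d, _ = precondition(ne_d)
        result.diagnostics = condition_diagnostics(Np_d, names=param_map.names)
    except NothingToRefineError:
        pass
    return result
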