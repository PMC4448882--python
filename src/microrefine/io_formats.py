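"""Readers and writers: SHELX-style .hkl, .fab solvent files, minimal CIF, fcf.

All readers reject malformed records with an error naming the line
number rather than silently coercing; all round trips are lossless at
printed precision.

Reflection data use the HKLF-4 convention: fixed-width ``3I4, 2F8.2``
records of (h k l Fo² σ(Fo²)), terminated by an all-zero hkl line or
EOF.  Refinement on F converts with |Fo| = sqrt(max(Fo², 0)) and
σ(F) = σ(F²)/(2|Fo|), guarded at weak intensities.

The CIF dialect covers ``_cell_length_*``/``_cell_angle_*``,
``_symmetry_equiv_pos_as_xyz``, the ``_atom_site_*`` and
``_atom_site_aniso_*`` loops, and a documented custom loop
(``_microrefine_shape_*``) that serialises special-shape sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crystal_model import (
    AtomSite,
    CrystalModel,
    SpecialShapeSite,
    SymmetryOp,
    UnitCell,
    metric_tensors,
)
from .exceptions import FileFormatError

__all__ = [
    "ReflectionSet",
    "read_hkl",
    "write_hkl",
    "read_fab",
    "write_fab",
    "attach_solvent",
    "read_cif",
    "write_cif",
    "write_fcf",
]

#: floor used when propagating σ(F) from σ(F²) at weak intensities
WEAK_F_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# Reflection container
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    """Observed reflections: Miller indices, Yo (Fo² by default), σ(Yo),
    and an optional per-reflection complex solvent contribution."""

    hkl: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    solvent: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.y = np.asarray(self.y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.hkl.shape[0] != self.y.size or self.y.size != self.sigma.size:
            raise ValueError("hkl, y and sigma must be aligned")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be > 0")
        if self.solvent is not None:
            self.solvent = np.asarray(self.solvent, dtype=complex)
            if self.solvent.size != self.y.size:
                raise ValueError("solvent array must align with reflections")

    def __len__(self):
        return self.y.size

    def d_spacings(self, cell: UnitCell) -> np.ndarray:
        _, gstar, _ = metric_tensors(cell)
        h = self.hkl.astype(float)
        return 1.0 / np.sqrt(np.einsum("ni,ij,nj->n", h, gstar, h))

    def amplitude_data(self):
        """(|Fo|, σ(|Fo|)) from (Fo², σ(Fo²)) with weak-intensity guard."""
        f = np.sqrt(np.clip(self.y, 0.0, None))
        sf = self.sigma / (2.0 * np.maximum(f, WEAK_F_FLOOR))
        return f, sf

    def merge_duplicates(self) -> "ReflectionSet":
        """Weighted-mean merge of duplicate hkl entries (w = 1/σ²)."""
        key = {}
        order = []
        for i, hkl in enumerate(map(tuple, self.hkl)):
            key.setdefault(hkl, []).append(i)
            if len(key[hkl]) == 1:
                order.append(hkl)
        hkl_out, y_out, s_out = [], [], []
        solv_out = [] if self.solvent is not None else None
        for hkl in order:
            idx = key[hkl]
            w = 1.0 / self.sigma[idx] ** 2
            y_out.append(float(np.sum(w * self.y[idx]) / np.sum(w)))
            s_out.append(float(1.0 / math.sqrt(np.sum(w))))
            hkl_out.append(hkl)
            if solv_out is not None:
                solv_out.append(self.solvent[idx[0]])
        return ReflectionSet(
            hkl=np.array(hkl_out, dtype=int),
            y=np.array(y_out),
            sigma=np.array(s_out),
            solvent=np.array(solv_out) if solv_out is not None else None,
        )


# ---------------------------------------------------------------------------
# SHELX .hkl (HKLF 4)
# ---------------------------------------------------------------------------

def read_hkl(path) -> ReflectionSet:
    """Read fixed-width HKLF-4 intensities (3I4, 2F8.2) until terminator/EOF."""
    hkl, y, sig = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if len(line) < 28:
                raise FileFormatError(
                    f"HKLF-4 record too short ({len(line)} chars)", line=lineno
                )
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])  # noqa: E741
                yo = float(line[12:20])
                so = float(line[20:28])
            except ValueError as exc:
                raise FileFormatError(f"non-numeric field: {exc}", line=lineno) from None
            if h == k == l == 0:
                break
            hkl.append((h, k, l))
            y.append(yo)
            sig.append(so)
    return ReflectionSet(hkl=np.array(hkl, int), y=np.array(y), sigma=np.array(sig))


def write_hkl(reflections: ReflectionSet, path) -> None:
    """Write HKLF-4 records plus the all-zero terminator line.

    σ is clamped below at 0.01 (the smallest value the F8.2 field can
    print) so a written file always reads back as valid data.
    """
    with open(path, "w") as fh:
        for (h, k, l), yo, so in zip(reflections.hkl, reflections.y, reflections.sigma):  # noqa: E741
            so = max(so, 0.01)
            if abs(yo) >= 1e6 or so >= 1e6:
                raise ValueError(
                    f"value too large for fixed-width HKLF-4 field: {yo} / {so}"
                )
            fh.write(f"{h:4d}{k:4d}{l:4d}{yo:8.2f}{so:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


# ---------------------------------------------------------------------------
# .fab solvent contributions
# ---------------------------------------------------------------------------

def read_fab(path) -> dict:
    """Read whitespace-delimited ``h k l A B`` lines into {hkl: A+iB}.

    Comment lines starting with ``!`` or ``#`` are skipped; a duplicate
    hkl raises an error naming the line.
    """
    out: dict[tuple, complex] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FileFormatError(
                    f"expected 'h k l A B', got {len(parts)} fields", line=lineno
                )
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])  # noqa: E741
                a, b = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise FileFormatError(f"non-numeric field: {exc}", line=lineno) from None
            if h == k == l == 0:
                break
            if (h, k, l) in out:
                raise FileFormatError(f"duplicate hkl ({h} {k} {l})", line=lineno)
            out[(h, k, l)] = complex(a, b)
    return out


def write_fab(contributions: dict, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"! {comment}\n")
        for (h, k, l), z in contributions.items():  # noqa: E741
            fh.write(f"{h:4d} {k:3d} {l:3d} {z.real:12.4f} {z.imag:12.4f}\n")


def attach_solvent(reflections: ReflectionSet, contributions: dict):
    """Align .fab contributions with a ReflectionSet by hkl.

    Reflections absent from the file get a zero contribution; the number
    of misses is returned alongside the updated set.
    """
    solvent = np.zeros(len(reflections), dtype=complex)
    missing = 0
    for i, hkl in enumerate(map(tuple, reflections.hkl)):
        if hkl in contributions:
            solvent[i] = contributions[hkl]
        else:
            missing += 1
    return (
        ReflectionSet(hkl=reflections.hkl, y=reflections.y, sigma=reflections.sigma, solvent=solvent),
        missing,
    )


# ---------------------------------------------------------------------------
# Minimal CIF
# ---------------------------------------------------------------------------

@dataclass
class _Tok:
    value: str
    line: int


def _tokenize_cif(text: str):
    toks: list[_Tok] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        i = 0
        while i < len(line):
            if line[i].isspace():
                i += 1
                continue
            if line[i] in "'\"":
                quote = line[i]
                j = line.find(quote, i + 1)
                if j < 0:
                    raise FileFormatError("unterminated quoted string", line=lineno)
                toks.append(_Tok(line[i + 1 : j], lineno))
                i = j + 1
            else:
                j = i
                while j < len(line) and not line[j].isspace():
                    j += 1
                tok = line[i:j]
                if tok.startswith("#"):
                    break
                toks.append(_Tok(tok, lineno))
                i = j
    return toks


def _parse_cif_blocks(text: str):
    """Tags {name: (value, line)} and loops [(headers, rows, line)]."""
    toks = _tokenize_cif(text)
    tags: dict[str, tuple] = {}
    loops: list[tuple] = []
    i = 0
    n = len(toks)
    while i < n:
        t = toks[i]
        low = t.value.lower()
        if low.startswith("data_"):
            i += 1
            continue
        if low == "loop_":
            start_line = t.line
            i += 1
            headers = []
            while i < n and toks[i].value.startswith("_"):
                headers.append(toks[i].value)
                i += 1
            if not headers:
                raise FileFormatError("loop_ without column tags", line=start_line)
            values = []
            while i < n and not toks[i].value.startswith("_") and toks[i].value.lower() not in ("loop_",) and not toks[i].value.lower().startswith("data_"):
                values.append(toks[i])
                i += 1
            if len(values) % len(headers) != 0:
                raise FileFormatError(
                    f"loop with {len(headers)} columns has {len(values)} values",
                    line=start_line,
                )
            rows = [values[j : j + len(headers)] for j in range(0, len(values), len(headers))]
            loops.append((headers, rows, start_line))
        elif t.value.startswith("_"):
            if i + 1 >= n:
                raise FileFormatError(f"tag {t.value} has no value", line=t.line)
            tags[t.value] = (toks[i + 1].value, t.line)
            i += 2
        else:
            raise FileFormatError(f"unexpected token {t.value!r}", line=t.line)
    return tags, loops


def _num(tok: _Tok | tuple) -> float:
    """Numeric CIF value; strips a parenthesised su, e.g. 1.234(5)."""
    value, line = (tok.value, tok.line) if isinstance(tok, _Tok) else tok
    v = value.split("(")[0]
    try:
        return float(v)
    except ValueError:
        raise FileFormatError(f"expected a number, got {value!r}", line=line) from None


def read_cif(path) -> CrystalModel:
    """Read the minimal model dialect into a CrystalModel."""
    with open(path) as fh:
        text = fh.read()
    tags, loops = _parse_cif_blocks(text)

    def need(tag):
        if tag not in tags:
            raise FileFormatError(f"missing required tag {tag}", line=1)
        return _num(tags[tag])

    cell = UnitCell(
        need("_cell_length_a"), need("_cell_length_b"), need("_cell_length_c"),
        need("_cell_angle_alpha"), need("_cell_angle_beta"), need("_cell_angle_gamma"),
    )
    scale = _num(tags["_microrefine_scale"]) if "_microrefine_scale" in tags else 1.0

    symmetry = []
    atoms: list[AtomSite] = []
    shapes: list[SpecialShapeSite] = []
    aniso_rows = []

    for headers, rows, start_line in loops:
        hset = [h.lower() for h in headers]
        if "_symmetry_equiv_pos_as_xyz" in hset:
            col = hset.index("_symmetry_equiv_pos_as_xyz")
            for row in rows:
                try:
                    symmetry.append(SymmetryOp.from_triplet(row[col].value))
                except (ValueError, RuntimeError) as exc:
                    raise FileFormatError(
                        f"bad symmetry string {row[col].value!r}: {exc}", line=row[col].line
                    ) from None
        elif any(h.startswith("_atom_site_aniso") for h in hset):
            cols = {h: j for j, h in enumerate(hset)}
            for row in rows:
                label = row[cols["_atom_site_aniso_label"]].value
                u6 = [
                    _num(row[cols[f"_atom_site_aniso_u_{c}"]])
                    for c in ("11", "22", "33", "12", "13", "23")
                ]
                aniso_rows.append((label, u6, row[0].line))
        elif any(h.startswith("_microrefine_shape") for h in hset):
            cols = {h: j for j, h in enumerate(hset)}

            def sv(row, name, default=None):
                j = cols.get(f"_microrefine_shape_{name}")
                if j is None:
                    if default is None:
                        raise FileFormatError(f"shape loop missing _{name}", line=start_line)
                    return default
                return row[j]

            for row in rows:
                shapes.append(
                    SpecialShapeSite(
                        label=sv(row, "label").value,
                        kind=sv(row, "kind").value,
                        element=sv(row, "element").value,
                        frac=np.array([_num(sv(row, "fract_x")), _num(sv(row, "fract_y")), _num(sv(row, "fract_z"))]),
                        u_iso=_num(sv(row, "u_iso")),
                        magnitude=_num(sv(row, "magnitude")),
                        declination=_num(sv(row, "declination")),
                        azimuth=_num(sv(row, "azimuth")),
                        multiplicity=int(_num(sv(row, "multiplicity"))),
                        occupancy=_num(sv(row, "occupancy")),
                    )
                )
        elif any(h.startswith("_atom_site_") for h in hset):
            cols = {h: j for j, h in enumerate(hset)}
            for row in rows:
                try:
                    flags = (
                        row[cols["_microrefine_refinement_flags"]].value
                        if "_microrefine_refinement_flags" in cols
                        else "."
                    )
                    fix = frozenset(p[4:] for p in flags.split(",") if p.startswith("fix_"))
                    atoms.append(
                        AtomSite(
                            label=row[cols["_atom_site_label"]].value,
                            element=row[cols["_atom_site_type_symbol"]].value,
                            frac=np.array([
                                _num(row[cols["_atom_site_fract_x"]]),
                                _num(row[cols["_atom_site_fract_y"]]),
                                _num(row[cols["_atom_site_fract_z"]]),
                            ]),
                            occupancy=_num(row[cols["_atom_site_occupancy"]]) if "_atom_site_occupancy" in cols else 1.0,
                            u_iso=_num(row[cols["_atom_site_u_iso_or_equiv"]]) if "_atom_site_u_iso_or_equiv" in cols else 0.02,
                            fix=fix or frozenset(),
                            refine_occupancy="occ" in flags.split(","),
                        )
                    )
                except KeyError as exc:
                    raise FileFormatError(f"atom_site loop missing column {exc}", line=start_line) from None

    for label, u6, line in aniso_rows:
        for atom in atoms:
            if atom.label == label:
                atom.u_aniso = np.asarray(u6, dtype=float)
                atom.u_iso = None
                break
        else:
            raise FileFormatError(f"aniso label {label!r} has no matching atom site", line=line)

    if not symmetry:
        symmetry = [SymmetryOp.identity()]
    return CrystalModel(cell=cell, symmetry=symmetry, atoms=atoms, shapes=shapes, scale=scale)


def write_cif(model: CrystalModel, path, name: str = "microrefine") -> None:
    """Serialise a model, including the custom special-shape loop.

    Shape orientation angles refer to the package's orthogonal frame
    (x along a, y in the a-b plane); the convention is recorded in the
    output metadata tag.
    """
    cell = model.cell
    lines = [f"data_{name}"]
    lines += [
        f"_cell_length_a     {cell.a:.6f}",
        f"_cell_length_b     {cell.b:.6f}",
        f"_cell_length_c     {cell.c:.6f}",
        f"_cell_angle_alpha  {cell.alpha:.6f}",
        f"_cell_angle_beta   {cell.beta:.6f}",
        f"_cell_angle_gamma  {cell.gamma:.6f}",
        f"_microrefine_scale {model.scale:.8f}",
        "_microrefine_orthogonal_frame 'x along a, y in a-b plane, z right-handed'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    for op in model.symmetry:
        lines.append(f"  '{op.triplet()}'")
    if model.atoms:
        lines += [
            "loop_",
            "_atom_site_label",
            "_atom_site_type_symbol",
            "_atom_site_fract_x",
            "_atom_site_fract_y",
            "_atom_site_fract_z",
            "_atom_site_occupancy",
            "_atom_site_U_iso_or_equiv",
            "_microrefine_refinement_flags",
        ]
        for a in model.atoms:
            ueq = model.u_eq(a.label)
            flags = [f"fix_{p}" for p in sorted(a.fix)]
            if a.refine_occupancy:
                flags.append("occ")
            lines.append(
                f"  {a.label} {a.element} {a.frac[0]:.6f} {a.frac[1]:.6f} {a.frac[2]:.6f} "
                f"{a.occupancy:.4f} {ueq:.6f} {','.join(flags) if flags else '.'}"
            )
        aniso = [a for a in model.atoms if a.is_aniso]
        if aniso:
            lines += ["loop_", "_atom_site_aniso_label"]
            lines += [f"_atom_site_aniso_U_{c}" for c in ("11", "22", "33", "12", "13", "23")]
            for a in aniso:
                vals = " ".join(f"{v:.6f}" for v in a.u_aniso)
                lines.append(f"  {a.label} {vals}")
    if model.shapes:
        lines += ["loop_"]
        lines += [
            "_microrefine_shape_label",
            "_microrefine_shape_kind",
            "_microrefine_shape_element",
            "_microrefine_shape_fract_x",
            "_microrefine_shape_fract_y",
            "_microrefine_shape_fract_z",
            "_microrefine_shape_u_iso",
            "_microrefine_shape_magnitude",
            "_microrefine_shape_declination",
            "_microrefine_shape_azimuth",
            "_microrefine_shape_multiplicity",
            "_microrefine_shape_occupancy",
        ]
        for s in model.shapes:
            lines.append(
                f"  {s.label} {s.kind} {s.element} {s.frac[0]:.6f} {s.frac[1]:.6f} {s.frac[2]:.6f} "
                f"{s.u_iso:.6f} {s.magnitude:.6f} {s.declination:.6f} {s.azimuth:.6f} "
                f"{s.multiplicity:d} {s.occupancy:.4f}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fcf-like output
# ---------------------------------------------------------------------------

def write_fcf(path, reflections: ReflectionSet, sf_set) -> None:
    """Write an fcf-like text table: h k l Fo² σ(Fo²) |Fc| phase(deg)."""
    amp = sf_set.amplitude
    phase = sf_set.phase
    with open(path, "w") as fh:
        fh.write("#   h   k   l       Fo2     sigma       |Fc|   phase\n")
        for (h, k, l), yo, so, fc, ph in zip(  # noqa: E741
            reflections.hkl, reflections.y, reflections.sigma, amp, phase
        ):
            fh.write(f"{h:5d}{k:4d}{l:4d}{yo:10.2f}{so:10.2f}{fc:11.4f}{ph:8.2f}\n")
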