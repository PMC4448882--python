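"""Form factors, Debye-Waller factors, shape transforms, Fc and derivatives."""

import math

import gemmi
import numpy as np
import pytest

import microrefine as mr
from microrefine.crystal_model import u_iso_to_cif
from microrefine.scattering import FormFactorTable

# electron counts for the f(0) ≈ Z sanity check
ELEMENTS = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
            "Cl": 17, "K": 19, "Ni": 28, "Br": 35, "I": 53}


class TestFormFactors:
    @pytest.mark.parametrize("element,z", sorted(ELEMENTS.items()))
    def test_f_at_zero_is_electron_count(self, element, z):
        assert mr.atomic_form_factor(element, 0.0) == pytest.approx(z, rel=0.02)

    @pytest.mark.parametrize("element", sorted(ELEMENTS))
    def test_decreasing_with_s(self, element):
        table = FormFactorTable()
        s = np.linspace(0.0, 1.5, 40)
        f = table.value(element, s)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element_rejected(self):
        with pytest.raises(mr.MissingScattererError):
            mr.atomic_form_factor("Xx", 0.1)

    def test_custom_coefficients_override(self):
        table = FormFactorTable(custom={"C": ([0, 0, 0, 0], [1, 1, 1, 1], 1.0)})
        assert table.value("C", 0.7) == pytest.approx(1.0)


class TestDebyeWaller:
    def test_zero_u_gives_unity(self, cubic_cell):
        assert mr.debye_waller(0.0, (3, 1, 2), cubic_cell) == pytest.approx(1.0)

    def test_isotropic_closed_form(self, cubic_cell):
        # s = 1/(2d) = 0.05 for (100) in a 10 Å cubic cell
        expected = math.exp(-8 * math.pi**2 * 0.05 * 0.05**2)
        assert mr.debye_waller(0.05, (1, 0, 0), cubic_cell) == pytest.approx(expected, rel=1e-12)

    def test_iso_aniso_representation_equivalence(self, triclinic_cell):
        u6 = u_iso_to_cif(triclinic_cell, 0.04)
        for hkl in [(1, 0, 0), (2, -1, 3), (0, 1, 4)]:
            assert mr.debye_waller(u6, hkl, triclinic_cell) == pytest.approx(
                mr.debye_waller(0.04, hkl, triclinic_cell), abs=1e-10
            )

    def test_non_psd_tensor_warns_but_computes(self, cubic_cell):
        bad = np.array([-0.01, 0.02, 0.02, 0.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            value = mr.debye_waller(bad, (1, 0, 0), cubic_cell)
        assert value > 1.0  # negative U along x amplifies


def _shape(kind, **kw):
    args = dict(label="S", element="C", frac=np.zeros(3), u_iso=0.0,
                magnitude=1.4, declination=0.0, azimuth=0.0, multiplicity=1)
    args.update(kw)
    return mr.SpecialShapeSite(kind=kind, **args)


def _brute_force_average(kind, magnitude, axis, q, n=10_000):
    """Independent oracle: average of exp(i q·r) over points on the shape."""
    if kind == "torus":
        phi = 2 * math.pi * (np.arange(n) + 0.5) / n
        e1, e2 = _perp_basis(axis)
        pts = magnitude * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
    elif kind == "line":
        t = magnitude * ((np.arange(n) + 0.5) / n - 0.5)
        pts = np.outer(t, axis)
    elif kind == "shell":
        # Gauss-Legendre in cos(theta) × uniform phi: spectrally accurate
        ng = 100
        x, w = np.polynomial.legendre.leggauss(ng)
        phi = 2 * math.pi * (np.arange(ng) + 0.5) / ng
        ct, ph = np.meshgrid(x, phi)
        st_ = np.sqrt(1 - ct**2)
        pts = magnitude * np.stack(
            [st_ * np.cos(ph), st_ * np.sin(ph), ct], axis=-1
        ).reshape(-1, 3)
        wts = np.tile(w, ng)
        vals = np.exp(1j * pts @ q)
        return float(np.real(np.sum(wts * vals) / np.sum(wts)))
    vals = np.exp(1j * pts @ q)
    return float(np.real(vals.mean()))


def _perp_basis(axis):
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


class TestShapeFormFactors:
    @pytest.mark.parametrize("kind", ["shell", "line", "torus"])
    def test_unity_at_q_zero(self, kind):
        assert mr.shape_form_factor(_shape(kind), np.zeros(3)) == pytest.approx(1.0)

    def test_shell_zero_at_qr_pi(self):
        shape = _shape("shell", magnitude=2.0)
        q = np.array([math.pi / 2.0, 0.0, 0.0])  # |q|R = π
        assert mr.shape_form_factor(shape, q) == pytest.approx(0.0, abs=1e-12)

    def test_torus_unity_for_axial_q(self):
        shape = _shape("torus", declination=0.0)
        q = np.array([0.0, 0.0, 3.7])  # parallel to the normal
        assert mr.shape_form_factor(shape, q) == pytest.approx(1.0)

    def test_torus_in_plane_matches_ring_average(self):
        shape = _shape("torus", magnitude=1.4)
        q = np.array([1.0, 0.0, 0.0])
        oracle = _brute_force_average("torus", 1.4, np.array([0.0, 0.0, 1.0]), q)
        assert mr.shape_form_factor(shape, q) == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("kind", ["shell", "line", "torus"])
    def test_closed_forms_match_point_scatterer_oracle(self, kind):
        """100 random q vectors per shape against the brute-force average."""
        rng = np.random.default_rng(42)
        shape = _shape(kind, magnitude=1.7, declination=55.0, azimuth=210.0)
        axis = shape.axis()
        for _ in range(100):
            q = rng.uniform(-6.0, 6.0, 3)
            mine = mr.shape_form_factor(shape, q)
            oracle = _brute_force_average(kind, shape.magnitude, axis, q)
            assert mine == pytest.approx(oracle, abs=1e-4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            _shape("cube")


def _flat_table():
    """f ≡ 1 for every tabulated element (phase-only structure factors)."""
    return FormFactorTable(custom={el: ([0, 0, 0, 0], [1, 1, 1, 1], 1.0) for el in ELEMENTS})


class TestStructureFactors:
    def test_single_atom_at_origin_gives_unity(self, cubic_cell):
        model = mr.CrystalModel(
            cell=cubic_cell,
            atoms=[mr.AtomSite(label="C1", element="C", frac=np.zeros(3), u_iso=0.0)],
        )
        sf = mr.calc_structure_factors(model, [(1, 0, 0), (2, 3, 1)], table=_flat_table())
        assert np.allclose(sf.f_molecule, 1.0 + 0.0j, atol=1e-12)

    def test_destructive_interference(self, cubic_cell):
        atoms = [
            mr.AtomSite(label="C1", element="C", frac=np.zeros(3), u_iso=0.0),
            mr.AtomSite(label="C2", element="C", frac=np.array([0.5, 0, 0]), u_iso=0.0),
        ]
        model = mr.CrystalModel(cell=cubic_cell, atoms=atoms)
        sf = mr.calc_structure_factors(model, [(1, 0, 0)], table=_flat_table())
        assert abs(sf.f_molecule[0]) == pytest.approx(0.0, abs=1e-12)

    def test_friedel_symmetry(self, random_model):
        hkl = np.array([[1, 2, 3], [-1, -2, -3], [2, 0, -1], [-2, 0, 1]])
        sf = mr.calc_structure_factors(random_model, hkl)
        assert sf.f_molecule[1] == pytest.approx(np.conj(sf.f_molecule[0]), rel=1e-10)
        assert sf.f_molecule[3] == pytest.approx(np.conj(sf.f_molecule[2]), rel=1e-10)

    def test_lattice_translation_invariance(self, random_model):
        hkl = mr.full_sphere_hkl(random_model.cell, 2.0)
        base = mr.calc_structure_factors(random_model, hkl)
        moved = random_model.copy()
        t = np.array([0.13, -0.27, 0.41])
        for site in moved.sites():
            site.frac = site.frac + t
        shifted = mr.calc_structure_factors(moved, hkl)
        assert np.allclose(np.abs(shifted.f_molecule), np.abs(base.f_molecule), rtol=1e-10)
        expected_phase = np.exp(2j * math.pi * (hkl @ t))
        assert np.allclose(shifted.f_molecule, base.f_molecule * expected_phase, rtol=1e-8)

    def test_occupancy_linearity(self, cubic_cell):
        atoms = [
            mr.AtomSite(label="C1", element="C", frac=np.array([0.1, 0.2, 0.3]),
                        occupancy=0.5, u_iso=0.02),
            mr.AtomSite(label="N2", element="N", frac=np.array([0.6, 0.1, 0.8]),
                        occupancy=0.25, u_iso=0.03),
        ]
        model = mr.CrystalModel(cell=cubic_cell, atoms=atoms)
        hkl = [(1, 2, 0), (3, -1, 2)]
        base = mr.calc_structure_factors(model, hkl).f_molecule
        doubled = model.copy()
        for atom in doubled.atoms:
            atom.occupancy *= 2
        assert np.allclose(
            mr.calc_structure_factors(doubled, hkl).f_molecule, 2 * base, rtol=1e-12
        )

    def test_against_gemmi_small_structure_oracle(self, random_model):
        """Independent cross-check of Fc on a mixed iso/aniso structure."""
        model = random_model.copy()
        model.shapes = []  # gemmi knows nothing of shape scatterers
        hkl = mr.full_sphere_hkl(model.cell, 1.5)[:80]
        mine = mr.calc_structure_factors(model, hkl).f_molecule
        ss = gemmi.SmallStructure()
        ss.cell = gemmi.UnitCell(*model.cell.as_tuple())
        ss.spacegroup_hm = "P 1"
        for a in model.atoms:
            site = gemmi.SmallStructure.Site()
            site.label = a.label
            site.element = gemmi.Element(a.element)
            site.fract = gemmi.Fractional(*a.frac)
            site.occ = a.occupancy
            if a.u_aniso is not None:
                site.aniso = gemmi.SMat33d(*a.u_aniso)
            else:
                site.u_iso = a.u_iso
            ss.add_site(site)
        calc = gemmi.StructureFactorCalculatorX(ss.cell)
        ref = np.array(
            [calc.calculate_sf_from_small_structure(ss, [int(v) for v in h]) for h in hkl]
        )
        assert np.allclose(mine, ref, rtol=2e-5, atol=2e-5)

    def test_torus_equivalent_to_discrete_ring_at_low_resolution(self):
        """Six carbons on a ring vs one multiplicity-6 torus: R-factor < 1%."""
        fx = mr.make_fixture("benzene_torus")
        carbons = [a for a in fx.info["discrete_model"].atoms if a.element == "C"]
        disc = mr.CrystalModel(cell=fx.model.cell, atoms=carbons)
        tor = mr.CrystalModel(cell=fx.model.cell,
                              shapes=[s for s in fx.model.shapes if s.label == "TORC"])
        hkl = mr.full_sphere_hkl(disc.cell, 2.5)
        a1 = mr.calc_structure_factors(disc, hkl).amplitude
        a2 = mr.calc_structure_factors(tor, hkl).amplitude
        assert np.sum(np.abs(a1 - a2)) / np.sum(a1) < 0.01

    def test_solvent_contribution(self, cubic_cell):
        model = mr.CrystalModel(
            cell=cubic_cell,
            atoms=[mr.AtomSite(label="C1", element="C", frac=np.zeros(3), u_iso=0.02)],
        )
        hkl = [(1, 0, 0), (0, 2, 0)]
        plain = mr.calc_structure_factors(model, hkl)
        with_zero = mr.calc_structure_factors(model, hkl, solvent=np.zeros(2, complex))
        assert np.allclose(plain.amplitude, with_zero.amplitude, atol=1e-12)
        empty = mr.CrystalModel(cell=cubic_cell)
        sf = mr.calc_structure_factors(empty, [(1, 0, 0)], solvent=np.array([3 + 4j]))
        assert sf.amplitude[0] == pytest.approx(5.0)

    def test_misaligned_solvent_rejected(self, cubic_cell):
        model = mr.CrystalModel(cell=cubic_cell)
        with pytest.raises(ValueError):
            mr.calc_structure_factors(model, [(1, 0, 0)], solvent=np.zeros(3, complex))


class TestDesignRows:
    @pytest.mark.parametrize("mode", ["F", "F2"])
    def test_derivatives_match_finite_differences(self, random_model, mode):
        """Every design-row entry vs central differences on a seeded structure."""
        model = random_model
        pmap = mr.build_parameter_map(model)
        hkl = mr.full_sphere_hkl(model.cell, 1.6)[:30]
        B, _ = mr.design_matrix(model, hkl, pmap, mode=mode)
        steps = {"mag": 1e-5, "decl": 1e-4, "azim": 1e-4}
        for i, (label, pname) in enumerate(pmap.index_owner):
            h = steps.get(pname, 1e-6)
            plus, minus = model.copy(), model.copy()
            if label == "":
                plus.scale += h
                minus.scale -= h
            else:
                sp, sm = plus.get_site(label), minus.get_site(label)
                sp.set_param(pname, sp.get_param(pname) + h)
                sm.set_param(pname, sm.get_param(pname) - h)
            def y(m):
                amp = mr.calc_structure_factors(m, hkl).amplitude
                return amp**2 if mode == "F2" else amp
            fd = (y(plus) - y(minus)) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-6)
            assert np.abs(B[:, i] - fd).max() / scale < 1e-5, (label, pname)

    def test_fixed_parameter_has_no_entry(self, random_model):
        model = random_model
        label = model.atoms[0].label
        pmap = mr.build_parameter_map(model, [mr.Fix(label, ("x", "y", "z"))])
        assert not any(name.startswith(f"{label}.x") for name in pmap.names)

    def test_scale_derivative_is_amplitude_in_f_mode(self, random_model):
        model = random_model.copy()
        model.scale = 1.0
        pmap = mr.build_parameter_map(model)
        hkl = np.array([[1, 2, 0], [0, 1, 3]])
        B, sf = mr.design_matrix(model, hkl, pmap, mode="F")
        i = pmap.names.index("scale")
        assert np.allclose(B[:, i], sf.amplitude, rtol=1e-10)


class TestAgreementStatistics:
    def test_perfect_fit(self):
        stats = mr.agreement_statistics([4.0, 9.0], [0.1, 0.1], [4.0, 9.0], n_params=1)
        assert stats["M"] == 0.0 and stats["R1"] == 0.0

    def test_simple_objective(self):
        stats = mr.agreement_statistics([2.0, 2.0], [1.0, 1.0], [1.0, 1.0],
                                        weights=np.ones(2), n_params=0)
        assert stats["M"] == pytest.approx(2.0)

    def test_gof_undefined_when_underdetermined(self):
        stats = mr.agreement_statistics([1.0], [0.1], [1.0], n_params=5)
        assert stats["GoF"] is None

    def test_gof_calibration_chi_square(self):
        """Gaussian noise of width σ and w = 1/σ² give GoF ≈ 1."""
        rng = np.random.default_rng(3)
        n, p = 2000, 50
        yt = rng.uniform(10, 100, n)
        sigma = 0.05 * yt
        yo = yt + sigma * rng.standard_normal(n)
        stats = mr.agreement_statistics(yo, sigma, yt, n_params=p)
        assert stats["GoF"] == pytest.approx(1.0, abs=3 / math.sqrt(2 * (n - p)))
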