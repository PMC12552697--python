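"""Voxel FE solver: elasticity oracles, interfaces, and fracture."""

import numpy as np
import pytest

from sgbr.image import ImageVolume
from sgbr.materials import MaterialModel
from sgbr.voxfem import (LoadCase, DirichletBC, Load, assemble_and_solve,
                         crack_initiation, failure_ratios, propagate_crack,
                         stiffness_from_curve, frictional, BONDED, EXCLUDED,
                         FloatingIslandError, StressField, SolverError)
from conftest import face_mask, uniaxial_bar_case


def bar(shape, label=1, h=0.5):
    return ImageVolume(np.full(shape, label, dtype=np.int16), (h, h, h))


def loaded_bar_case(shape, force):
    case = uniaxial_bar_case(shape)
    case.loads.append(Load(face_mask(shape, 0, -1), (force, 0.0, 0.0),
                           face="+x"))
    return case


class TestElasticity:
    def test_uniaxial_bar_closed_form(self, pek):
        """Tip displacement of a roller-supported bar equals FL/(EA)."""
        shape = (20, 4, 4)  # L=10, A=4 at h=0.5
        sf = assemble_and_solve(bar(shape), {1: pek},
                                loaded_bar_case(shape, 96.0))
        tip = sf.displacement[-1, :, :, 0].mean()
        assert tip == pytest.approx(96.0 * 10 / (2400.0 * 4.0), rel=0.01)
        assert sf.stress[:, 0].mean() == pytest.approx(24.0, rel=1e-6)

    def test_zero_load_zero_state(self, pek):
        shape = (8, 3, 3)
        sf = assemble_and_solve(bar(shape), {1: pek},
                                loaded_bar_case(shape, 0.0))
        assert np.abs(sf.displacement).max() < 1e-12
        assert np.abs(sf.stress).max() < 1e-9

    def test_cantilever_beam_theory(self, pek):
        """Tip deflection within 5% of Euler-Bernoulli FL^3/(3EI)."""
        L, b, t, h, F = 16.0, 2.0, 2.0, 0.25, 5.0
        shape = (int(L / h), int(b / h), int(t / h))
        labels = bar(shape, h=h)
        case = LoadCase(
            dirichlet=[DirichletBC(face_mask(shape, 0, 0), (0, 1, 2),
                                   face="-x")],
            loads=[Load(face_mask(shape, 0, -1), (0, 0, -F), face="+x")])
        sf = assemble_and_solve(labels, {1: pek}, case)
        tip = sf.displacement[-1, :, :, 2].mean()
        I = b * t ** 3 / 12
        assert tip == pytest.approx(-F * L ** 3 / (3 * 2400.0 * I), rel=0.05)

    def test_patch_test_uniform_strain(self, pek):
        """Affine boundary displacement reproduces uniform stress to
        machine precision (hexahedral patch test)."""
        shape = (4, 4, 4)
        eps = np.array([[1e-3, 2e-4, 0.0],
                        [2e-4, -3e-4, 1e-4],
                        [0.0, 1e-4, 5e-4]])
        bnd = np.zeros(shape, bool)
        bnd[[0, -1], :, :] = bnd[:, [0, -1], :] = bnd[:, :, [0, -1]] = True
        case = LoadCase(dirichlet=[DirichletBC(bnd, (0, 1, 2),
                                               lambda x: x @ eps.T)])
        sf = assemble_and_solve(bar(shape, h=0.7), {1: pek}, case)
        assert np.abs(sf.stress - sf.stress[0]).max() < 1e-9

    def test_mirror_symmetry(self, pek):
        """Mirrored geometry and loads give the mirrored displacement."""
        shape = (10, 6, 3)
        lab = np.ones(shape, np.int16)
        lab[3:5, 0:2, :] = 0  # asymmetric cut-out
        labels = ImageVolume(lab, (0.5,) * 3)
        case = LoadCase(
            dirichlet=[DirichletBC(face_mask(shape, 0, 0), (0, 1, 2),
                                   face="-x")],
            loads=[Load(face_mask(shape, 0, -1), (0, 0, -3.0), face="+x")])
        sf = assemble_and_solve(labels, {1: pek}, case)
        labels_m = ImageVolume(lab[:, ::-1, :].copy(), (0.5,) * 3)
        case_m = LoadCase(
            dirichlet=[DirichletBC(face_mask(shape, 0, 0), (0, 1, 2),
                                   face="-x")],
            loads=[Load(face_mask(shape, 0, -1), (0, 0, -3.0), face="+x")])
        sf_m = assemble_and_solve(labels_m, {1: pek}, case_m)
        d = sf.displacement
        d_m = sf_m.displacement[:, ::-1, :, :].copy()
        d_m[..., 1] *= -1.0  # y-component flips under the mirror
        np.testing.assert_allclose(d, d_m, atol=1e-9)

    def test_energy_balance(self, pek):
        """External work equals strain energy for a converged solve."""
        shape = (12, 4, 4)
        sf = assemble_and_solve(bar(shape), {1: pek},
                                loaded_bar_case(shape, 50.0))
        assert sf.external_work == pytest.approx(sf.strain_energy,
                                                 rel=1e-6)

    def test_floating_island_detected(self, pek):
        lab = np.ones((10, 3, 3), np.int16)
        lab[5, :, :] = 0  # disconnects the far half from the constraint
        shape = lab.shape
        case = loaded_bar_case(shape, 10.0)
        with pytest.raises(FloatingIslandError):
            assemble_and_solve(ImageVolume(lab, (0.5,) * 3), {1: pek}, case)

    def test_invalid_material_rejected(self):
        with pytest.raises(ValueError):
            MaterialModel("bad", E=-1.0)


class TestInterfaces:
    def test_bonded_series_bar_harmonic_stiffness(self):
        """Two moduli in series combine harmonically (nu = 0 so the
        closed-form 1D solution is exact)."""
        shape = (8, 3, 3)
        lab = np.ones(shape, np.int16)
        lab[4:] = 2
        labels = ImageVolume(lab, (1.0,) * 3)
        mats = {1: MaterialModel("stiff", 12000.0, 0.0),
                2: MaterialModel("soft", 2400.0, 0.0)}
        sf = assemble_and_solve(labels, mats, loaded_bar_case(shape, 90.0))
        tip = sf.displacement[-1, :, :, 0].mean()
        A = 9.0
        expected = 90.0 * (4.0 / (12000.0 * A) + 4.0 / (2400.0 * A))
        assert tip == pytest.approx(expected, rel=1e-9)

    def test_excluded_equals_voided(self, pek, bone):
        """EXCLUDED material yields the identical system to voiding it."""
        shape = (8, 3, 3)
        lab = np.ones(shape, np.int16)
        lab[4:] = 2
        case = uniaxial_bar_case(shape)
        case.loads.append(Load(face_mask(shape, 0, 3), (90.0, 0, 0),
                               face="+x"))
        case.interface_mode = {2: EXCLUDED}
        mats = {1: bone, 2: pek}
        sf_a = assemble_and_solve(ImageVolume(lab, (1.0,) * 3), mats, case)
        lab_v = lab.copy()
        lab_v[4:] = 0
        sf_b = assemble_and_solve(ImageVolume(lab_v, (1.0,) * 3), mats, case)
        np.testing.assert_array_equal(sf_a.stress, sf_b.stress)
        np.testing.assert_array_equal(sf_a.displacement, sf_b.displacement)

    def test_frictional_transmits_no_tension(self, pek, bone):
        """Pulling the halves apart across a frictional interface
        transmits orders of magnitude less force than the bonded tie."""
        shape = (8, 3, 3)
        lab = np.ones(shape, np.int16)
        lab[4:] = 2
        labels = ImageVolume(lab, (1.0,) * 3)
        mats = {1: bone, 2: pek}

        def pull_apart(mode):
            case = LoadCase(
                dirichlet=[
                    DirichletBC(face_mask(shape, 0, 0), (0, 1, 2), face="-x"),
                    DirichletBC(face_mask(shape, 0, -1), (0, 1, 2),
                                value=(0.1, 0.0, 0.0), face="+x"),
                ],
                interface_mode={frozenset({1, 2}): mode})
            sf = assemble_and_solve(labels, mats, case)
            # axial stress carried across the interface
            return abs(sf.stress[sf.elem_labels == 1][:, 0]).max()

        s_bonded = pull_apart(BONDED)
        s_fric = pull_apart(frictional(0.1))
        assert s_fric < 1e-4 * s_bonded

    def test_frictional_transmits_compression(self, pek, bone):
        """Pushing the halves together transmits the full load."""
        shape = (8, 3, 3)
        lab = np.ones(shape, np.int16)
        lab[4:] = 2
        labels = ImageVolume(lab, (1.0,) * 3)
        case = LoadCase(
            dirichlet=[DirichletBC(face_mask(shape, 0, 0), (0, 1, 2),
                                   face="-x")],
            loads=[Load(face_mask(shape, 0, -1), (-90.0, 0, 0), face="+x")],
            interface_mode={frozenset({1, 2}): frictional(0.1)})
        sf = assemble_and_solve(labels, {1: bone, 2: pek}, case)
        assert sf.stress[:, 0].mean() == pytest.approx(-10.0, rel=0.01)


class TestCrackInitiation:
    def _field(self, s1_values, labels, spacing=1.0):
        n = len(s1_values)
        stress = np.zeros((n, 6))
        stress[:, 0] = s1_values  # uniaxial: sigma_1 = sigma_xx
        return StressField(shape=(n, 1, 1), spacing=(spacing,) * 3,
                           elems=np.array([[i, 0, 0] for i in range(n)]),
                           elem_labels=np.asarray(labels),
                           stress=stress,
                           displacement=np.zeros((n + 1, 2, 2, 3)),
                           external_work=0.0, strain_energy=0.0)

    def test_ratio_and_strict_exceedance(self, pek, bone):
        """f = sigma_1/sigma_max; flag only on strict exceedance; no
        initiation in compression."""
        mats = {1: bone, 2: pek}
        field = self._field([75.0, 80.0, -40.0, 80.000001],
                            [1, 2, 2, 2])
        flags, f = crack_initiation(field, mats)
        assert f[0] == pytest.approx(0.5)       # 75/150 in bone
        assert f[1] == pytest.approx(1.0)       # exactly at strength
        assert list(flags) == [False, False, False, True]
        assert f[2] == 0.0                      # compression never initiates

    def test_material_without_strength_never_fails(self):
        mats = {1: MaterialModel("ceramic", 15000.0, 0.3)}
        field = self._field([1e4], [1])
        flags, f = crack_initiation(field, mats)
        assert not flags.any() and f[0] == 0.0


class TestCrackPropagation:
    def test_notched_plate_grows_perpendicular(self, pek):
        """The crack extends along the notch plane, perpendicular to the
        tensile load."""
        shape = (10, 10, 2)
        lab = np.ones(shape, np.int16)
        lab[0:2, 5, :] = 0
        labels = ImageVolume(lab, (1.0,) * 3)
        case = LoadCase(
            dirichlet=[
                DirichletBC(face_mask(shape, 1, 0), (1,), face="-y"),
                DirichletBC(face_mask(shape, 0, 0), (0,), face="-x"),
                DirichletBC(face_mask(shape, 2, 0), (2,), face="-z")],
            loads=[Load(face_mask(shape, 1, -1), (0.0, 4000.0, 0.0),
                        face="+y")])
        res = propagate_crack(labels, {1: pek}, case,
                              [1000.0, 2000.0, 4000.0, 8000.0],
                              use_toughness_arrest=False)
        assert res.failure_load is not None
        early = res.path[:6]
        assert all(p[1] == 5 for p in early)  # stays in the notch plane
        assert [p[0] for p in early[::2]] == sorted(
            p[0] for p in early[::2])  # marches away from the notch

    def test_weaker_material_fails_first(self, pek, bone):
        """Equal stress, unequal strength: initiation on the low-strength
        side."""
        shape = (10, 4, 2)
        lab = np.ones(shape, np.int16)
        lab[5:] = 2
        labels = ImageVolume(lab, (1.0,) * 3)
        mats = {1: MaterialModel("bone", 12000.0, 0.3, sigma_max=150.0),
                2: MaterialModel("pek", 12000.0, 0.3, sigma_max=80.0)}
        case = uniaxial_bar_case(shape)
        case.loads.append(Load(face_mask(shape, 0, -1), (900.0, 0, 0),
                               face="+x"))
        sf = assemble_and_solve(labels, mats, case)
        flags, _ = crack_initiation(sf, mats)
        assert flags.any()
        assert set(sf.elem_labels[flags].tolist()) == {2}

    def test_path_matches_brute_force_erosion_oracle(self, pek):
        """The eroded sequence equals an independent loop that re-solves
        after every removal and always strips the max-ratio element."""
        shape = (8, 8, 2)
        lab = np.ones(shape, np.int16)
        lab[0:2, 4, :] = 0
        labels = ImageVolume(lab, (1.0,) * 3)
        mats = {1: pek}
        level = 3000.0
        case = LoadCase(
            dirichlet=[
                DirichletBC(face_mask(shape, 1, 0), (1,), face="-y"),
                DirichletBC(face_mask(shape, 0, 0), (0,), face="-x"),
                DirichletBC(face_mask(shape, 2, 0), (2,), face="-z")],
            loads=[Load(face_mask(shape, 1, -1), (0.0, level, 0.0),
                        face="+y")])
        res = propagate_crack(labels, mats, case, [level],
                              use_toughness_arrest=False,
                              max_eroded_frac=0.5)

        # independent erosion loop
        vals = lab.copy()
        oracle_path = []
        for _ in range(len(res.path)):
            sf = assemble_and_solve(ImageVolume(vals, (1.0,) * 3), mats,
                                    case)
            f = failure_ratios(sf, mats)
            if f.max() <= 1.0:
                break
            worst = tuple(sf.elems[int(np.argmax(f))])
            oracle_path.append(worst)
            vals[worst] = 0
        assert res.path[:len(oracle_path)] == oracle_path

    def test_non_monotone_schedule_rejected(self, pek):
        labels = ImageVolume(np.ones((4, 4, 2), np.int16), (1.0,) * 3)
        with pytest.raises(ValueError):
            propagate_crack(labels, {1: pek}, uniaxial_bar_case((4, 4, 2)),
                            [2.0, 1.0])


class TestStiffnessFromCurve:
    def test_exact_line(self):
        d = np.linspace(0, 2, 9)
        assert stiffness_from_curve(500.0 * d, d) == pytest.approx(500.0)

    def test_bar_stiffness_closed_form(self, pek):
        """The FE bar traces F = (EA/L) d: slope 960 N/mm."""
        shape = (20, 4, 4)
        forces, disps = [], []
        for F in (0.0, 32.0, 64.0, 96.0):
            sf = assemble_and_solve(bar(shape), {1: pek},
                                    loaded_bar_case(shape, F))
            forces.append(F)
            disps.append(sf.displacement[-1, :, :, 0].mean())
        k = stiffness_from_curve(np.array(forces), np.array(disps))
        assert k == pytest.approx(2400.0 * 4.0 / 10.0, rel=0.01)

    def test_noisy_curve_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        d = np.sort(rng.uniform(0, 1, 30))
        F = 700.0 * d + rng.normal(0, 5.0, 30)
        k = stiffness_from_curve(F, d)
        X = np.column_stack([d, np.ones_like(d)])
        beta = np.linalg.solve(X.T @ X, X.T @ F)
        assert k == pytest.approx(beta[0], rel=1e-10)

    def test_constant_displacement_rejected(self):
        with pytest.raises(ValueError):
            stiffness_from_curve(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
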