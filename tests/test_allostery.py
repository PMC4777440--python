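import numpy as np
import pytest

from allofep import (
    BindingSite,
    Residue,
    ResidueKey,
    Structure,
    allosteric_free_energy,
    apply_restraints,
    build_harmonic_model,
    compute_modes,
    global_free_energy,
    global_modulation,
    group_homologous_chains,
    hessian,
    make_fixture,
    modulation_free_energy,
    monomer_average,
    protein_free_energy,
    residue_intensities,
    site_free_energy,
    site_summary,
    tube_radii,
)
from allofep.allostery import DEFAULT_KT, AllostericProfile
from allofep.fixtures import oracle_intensity, oracle_partition
from allofep.modes import ModeSet

from conftest import random_rotation


def _pipeline(s, sites, alpha=100.0, n_modes=10, k0=1.0, kT=DEFAULT_KT):
    m = build_harmonic_model(s, k0=k0)
    free = compute_modes(hessian(m), n_modes=n_modes)
    bound = compute_modes(
        hessian(apply_restraints(m, sites, alpha=alpha)), n_modes=n_modes
    )
    eps_f = residue_intensities(free, s)
    eps_b = residue_intensities(bound, s)
    return allosteric_free_energy(eps_f, eps_b, kT=kT), free, bound


def _fake_modes(vectors):
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    return ModeSet(
        eigenvalues=np.ones(len(v)), vectors=v, n_removed_rigid=6
    )


class TestIntensities:
    def test_pure_translation_mode_gives_zero(self, globule):
        s, _ = globule
        n = len(s)
        t = np.zeros(3 * n)
        t[0::3] = 1.0 / np.sqrt(n)
        table = residue_intensities(_fake_modes([t]), s)
        assert np.abs(table.eps).max() == 0.0

    def test_two_residue_antisymmetric_mode(self):
        residues = [
            Residue(ResidueKey("A", 1), "ALA", np.array([0.0, 0.0, 0.0])),
            Residue(ResidueKey("A", 2), "GLY", np.array([5.0, 0.0, 0.0])),
        ]
        s = Structure(residues)
        e = np.array([1.0, 0, 0, -1.0, 0, 0]) / np.sqrt(2)
        table = residue_intensities(_fake_modes([e]), s, c=1.0, d_c=11.0)
        # ‖e_1 − e_2‖² = (2/√2)² = 2, so ε = 2c on both residues
        np.testing.assert_allclose(table.eps[0], [2.0, 2.0], rtol=1e-12)

    def test_matches_double_loop_oracle(self, hinge_profile):
        s = hinge_profile["structure"]
        ms = hinge_profile["free_modes"]
        table = hinge_profile["free_eps"]
        np.testing.assert_allclose(
            table.eps, oracle_intensity(ms, s), atol=1e-10, rtol=0
        )

    def test_isolated_residue_flagged(self):
        residues = [
            Residue(ResidueKey("A", 1), "ALA", np.array([0.0, 0.0, 0.0])),
            Residue(ResidueKey("A", 2), "GLY", np.array([5.0, 0.0, 0.0])),
            Residue(ResidueKey("A", 3), "SER", np.array([50.0, 0.0, 0.0])),
        ]
        s = Structure(residues)
        e = np.zeros(9)
        e[0] = 1.0
        table = residue_intensities(_fake_modes([e]), s)
        assert list(table.zero_neighbor_mask) == [False, False, True]


class TestFreeEnergy:
    def test_alpha_zero_gives_identically_zero(self, hinge):
        s, _, site = hinge
        profile, _, _ = _pipeline(s, [site], alpha=0.0)
        assert np.nanmax(np.abs(profile.dg)) < 1e-12

    def test_single_mode_log_ratio_unit(self, globule):
        s, _ = globule
        ms = compute_modes(hessian(build_harmonic_model(s)), n_modes=1)
        eps_f = residue_intensities(ms, s)
        eps_b = residue_intensities(ms, s)
        eps_b.eps = eps_f.eps * np.e**2  # ε_bound = e²·ε_free
        profile = allosteric_free_energy(eps_f, eps_b, kT=DEFAULT_KT)
        np.testing.assert_allclose(profile.dg, DEFAULT_KT, rtol=1e-12)

    def test_agrees_with_partition_function_oracle(self):
        s, manifest = make_fixture("symmetric_dimer", 16, seed=13)
        site = BindingSite("s", frozenset(s.keys[:3]))
        n_modes = 3
        m = build_harmonic_model(s)
        free = compute_modes(hessian(m), n_modes=n_modes)
        bound = compute_modes(
            hessian(apply_restraints(m, [site], alpha=100.0)), n_modes=n_modes
        )
        eps_f = residue_intensities(free, s)
        eps_b = residue_intensities(bound, s)
        profile = allosteric_free_energy(eps_f, eps_b, kT=DEFAULT_KT)
        for i in (0, 5, 11):
            z_f_quad, z_f_closed = oracle_partition(eps_f.eps[:, i], DEFAULT_KT)
            z_b_quad, z_b_closed = oracle_partition(eps_b.eps[:, i], DEFAULT_KT)
            assert z_f_quad == pytest.approx(z_f_closed, rel=1e-6)
            assert z_b_quad == pytest.approx(z_b_closed, rel=1e-6)
            expected = -DEFAULT_KT * np.log(z_b_quad / z_f_quad)
            assert profile.dg[i] == pytest.approx(expected, rel=1e-6)

    def test_mode_additivity(self, hinge_profile):
        eps_f, eps_b = hinge_profile["free_eps"], hinge_profile["bound_eps"]
        full = allosteric_free_energy(eps_f, eps_b).dg

        def restrict(table, rows):
            import copy

            t = copy.copy(table)
            t.eps = table.eps[rows]
            return t

        head = allosteric_free_energy(
            restrict(eps_f, slice(0, 4)), restrict(eps_b, slice(0, 4))
        ).dg
        tail = allosteric_free_energy(
            restrict(eps_f, slice(4, 10)), restrict(eps_b, slice(4, 10))
        ).dg
        np.testing.assert_allclose(head + tail, full, atol=1e-12)

    def test_scale_invariance_in_k0(self, hinge):
        s, _, site = hinge
        p1, _, _ = _pipeline(s, [site], k0=1.0)
        p2, _, _ = _pipeline(s, [site], k0=7.3)
        np.testing.assert_allclose(p2.dg, p1.dg, atol=1e-9)

    def test_rigid_motion_invariance(self, hinge):
        s, _, site = hinge
        p1, _, _ = _pipeline(s, [site])
        R = random_rotation(17)
        s2 = s.transformed(R, np.array([-4.0, 9.0, 2.0]))
        p2, _, _ = _pipeline(s2, [site])
        np.testing.assert_allclose(p2.dg, p1.dg, atol=1e-6)

    def test_restrained_site_mean_is_stabilizing(self, hinge_profile):
        profile, site = hinge_profile["profile"], hinge_profile["site"]
        assert site_free_energy(profile, site) < 0

    def test_alpha_zero_limit_and_monotonic_growth(self, hinge):
        s, _, site = hinge
        means = []
        for alpha in (1.0, 10.0, 100.0):
            p, _, _ = _pipeline(s, [site], alpha=alpha)
            means.append(abs(site_free_energy(p, site)))
        assert means[0] < means[1] < means[2]


class TestModulation:
    def test_same_system_gives_zero(self, hinge_profile):
        eps_f = hinge_profile["free_eps"]
        eps_b = hinge_profile["bound_eps"]
        ddg = modulation_free_energy(eps_f, eps_b, eps_b).dg
        assert np.nanmax(np.abs(ddg)) < 1e-12

    def test_difference_formula_equals_profile_difference(self, dimer):
        s, _ = dimer
        site_a = BindingSite("a", frozenset(s.keys[i] for i in s.chain_indices("A")[:3]))
        site_b = BindingSite("b", frozenset(s.keys[i] for i in s.chain_indices("B")[:3]))
        m = build_harmonic_model(s)
        free = compute_modes(hessian(m), n_modes=10)
        eps_f = residue_intensities(free, s)
        one = compute_modes(hessian(apply_restraints(m, [site_a])), n_modes=10)
        both = compute_modes(
            hessian(apply_restraints(m, [site_a, site_b])), n_modes=10
        )
        eps_1 = residue_intensities(one, s)
        eps_2 = residue_intensities(both, s)
        ddg = modulation_free_energy(eps_f, eps_1, eps_2).dg
        dg1 = allosteric_free_energy(eps_f, eps_1).dg
        dg2 = allosteric_free_energy(eps_f, eps_2).dg
        np.testing.assert_allclose(ddg, dg2 - dg1, atol=1e-12)
        # the literal log-ratio variant differs by the m-vs-free term
        ddg17 = modulation_free_energy(eps_f, eps_1, eps_2, formula="eq17").dg
        np.testing.assert_allclose(ddg17, dg2 - 2 * dg1, atol=1e-12)

    def test_global_modulation_formulas(self, dimer):
        s, _ = dimer
        site_a = BindingSite("a", frozenset(s.keys[i] for i in s.chain_indices("A")[:3]))
        site_b = BindingSite("b", frozenset(s.keys[i] for i in s.chain_indices("B")[:3]))
        m = build_harmonic_model(s)
        free = compute_modes(hessian(m), n_modes=10)
        one = compute_modes(hessian(apply_restraints(m, [site_a])), n_modes=10)
        both = compute_modes(
            hessian(apply_restraints(m, [site_a, site_b])), n_modes=10
        )
        diff = global_modulation(free, one, both, formula="difference")
        expected = global_free_energy(free, both) - global_free_energy(free, one)
        assert diff == pytest.approx(expected, abs=1e-12)
        printed = global_modulation(free, one, both, formula="as-printed")
        expected17 = global_free_energy(free, both) - 2 * global_free_energy(
            free, one
        )
        assert printed == pytest.approx(expected17, abs=1e-12)


class TestGlobalFreeEnergy:
    def test_identical_systems_give_zero(self, hinge_profile):
        ms = hinge_profile["free_modes"]
        assert global_free_energy(ms, ms) == 0.0

    def test_stiffening_gives_nonnegative_dG(self, hinge_profile):
        dG = global_free_energy(
            hinge_profile["free_modes"], hinge_profile["bound_modes"]
        )
        assert dG >= 0

    def test_matches_brute_force_eigenvalues(self, hinge):
        s, _, site = hinge
        m = build_harmonic_model(s)
        lam_f = np.linalg.eigvalsh(hessian(m).matrix)[6:16]
        lam_b = np.linalg.eigvalsh(
            hessian(apply_restraints(m, [site], alpha=100.0)).matrix
        )[6:16]
        expected = 0.5 * DEFAULT_KT * np.sum(np.log(lam_b / lam_f))
        _, free, bound = _pipeline(s, [site])
        # the softest eigenvalues sit ~1e-9 relative to λ_max, which bounds
        # the achievable agreement between two independent eigensolves
        assert global_free_energy(free, bound) == pytest.approx(expected, rel=1e-6)


class TestAggregates:
    def test_site_mean_of_plus_minus_one_is_zero(self, globule):
        s, _ = globule
        p = AllostericProfile(
            s, np.zeros(len(s)), "t", DEFAULT_KT, 1,
            flags=[set() for _ in range(len(s))],
        )
        p.dg[0], p.dg[1] = 1.0, -1.0
        site = BindingSite("s", frozenset(s.keys[:2]))
        assert site_free_energy(p, site) == pytest.approx(0.0, abs=1e-15)

    def test_whole_protein_site_equals_protein_mean(self, hinge_profile):
        p = hinge_profile["profile"]
        s = hinge_profile["structure"]
        all_site = BindingSite("all", frozenset(s.keys))
        assert site_free_energy(p, all_site) == pytest.approx(
            protein_free_energy(p), abs=1e-12
        )

    def test_site_summary_reports_consistent_means(self, hinge_profile):
        p, site = hinge_profile["profile"], hinge_profile["site"]
        summ = site_summary(p, [site])[0]
        assert summ.dg_site == pytest.approx(site_free_energy(p, site), abs=1e-15)
        assert summ.dg_protein == pytest.approx(protein_free_energy(p), abs=1e-15)
        assert summ.n_site == len(site.members)


class TestMonomerAverage:
    def test_symmetric_dimer_has_vanishing_error_band(self, dimer):
        s, _ = dimer
        site = BindingSite(
            "both",
            frozenset(
                list(s.keys[i] for i in s.chain_indices("A")[:2])
                + list(s.keys[i] for i in s.chain_indices("B")[:2])
            ),
        )
        p, _, _ = _pipeline(s, [site])
        g = group_homologous_chains(s)
        (df,) = monomer_average(p, g)
        assert df["sem_dg"].max() < 1e-8

    def test_planted_offsets_give_known_sem(self):
        rng = np.random.default_rng(21)
        residues = []
        for chain in "ABC":
            base = {"A": 0, "B": 1, "C": 2}[chain] * 40.0
            for i in range(5):
                residues.append(
                    Residue(
                        ResidueKey(chain, i + 1), "ALA",
                        np.array([base + 3.8 * i, 0.0, 0.0]),
                    )
                )
        s = Structure(residues)
        dg = np.zeros(15)
        dg[2], dg[7], dg[12] = 1.0, 1.3, 0.7  # offsets {0, +0.3, −0.3}
        p = AllostericProfile(s, dg, "t", DEFAULT_KT, 1,
                              flags=[set() for _ in range(15)])
        g = group_homologous_chains(s)
        (df,) = monomer_average(p, g)
        row = df[df["position"] == 2].iloc[0]
        assert row["mean_dg"] == pytest.approx(1.0, abs=1e-12)
        assert row["sem_dg"] == pytest.approx(0.3 / np.sqrt(3), abs=1e-9)

    def test_singleton_group_zero_band(self, hinge_profile):
        p = hinge_profile["profile"]
        g = group_homologous_chains(hinge_profile["structure"])
        (df,) = monomer_average(p, g)
        assert (df["sem_dg"] == 0).all()


class TestTubeRadii:
    def _profile(self, dg):
        dg = np.asarray(dg, dtype=float)
        residues = [
            Residue(ResidueKey("A", i + 1), "ALA", np.array([4.0 * i, 0.0, 0.0]))
            for i in range(len(dg))
        ]
        return AllostericProfile(
            Structure(residues), dg, "t", DEFAULT_KT, 1,
            flags=[set() for _ in range(len(dg))],
        )

    def test_min_max_normalization(self):
        rho = tube_radii(self._profile([-1.0, 0.0, 3.0]))
        np.testing.assert_allclose(rho, [0.0, 0.25, 1.0], atol=1e-12)

    def test_constant_profile_maps_to_half(self):
        rho = tube_radii(self._profile([0.7, 0.7, 0.7]))
        np.testing.assert_allclose(rho, 0.5)

    def test_affine_invariance(self):
        dg = np.array([-0.4, 1.2, 0.1, 2.0, -2.2])
        rho1 = tube_radii(self._profile(dg))
        rho2 = tube_radii(self._profile(3.7 * dg + 11.0))
        np.testing.assert_allclose(rho2, rho1, atol=1e-12)


class TestDegeneracy:
    def test_multiplet_intensity_sums_are_basis_invariant(self):
        # a regular octahedron's symmetry forces degenerate eigenvalue
        # multiplets; per-mode ε within a multiplet depends on the basis the
        # solver picks, but the multiplet-summed ε does not
        pts = 6.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        residues = [
            Residue(ResidueKey("A", i + 1), "GLY", p) for i, p in enumerate(pts)
        ]
        s = Structure(residues)
        ms = compute_modes(hessian(build_harmonic_model(s)), n_modes=10)
        lam = ms.eigenvalues
        groups, start = [], 0
        for idx in range(1, len(lam) + 1):
            if idx == len(lam) or not np.isclose(
                lam[idx], lam[start], rtol=1e-8
            ):
                groups.append(list(range(start, idx)))
                start = idx
        assert any(len(g) > 1 for g in groups)  # degeneracy is really there
        rng = np.random.default_rng(3)
        table = residue_intensities(ms, s)
        for g in groups:
            if len(g) == 1:
                continue
            q, _ = np.linalg.qr(rng.normal(size=(len(g), len(g))))
            mixed = ms.vectors.copy()
            mixed[g] = q @ ms.vectors[g]
            mixed_ms = ModeSet(lam.copy(), mixed, ms.n_removed_rigid)
            mixed_table = residue_intensities(mixed_ms, s)
            np.testing.assert_allclose(
                mixed_table.eps[g].sum(axis=0),
                table.eps[g].sum(axis=0),
                atol=1e-10,
            )
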