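"""Divide-and-conquer: cores, bonds, capping, merging, end-to-end runs."""

import numpy as np
import pytest

from lobehf.basis import basis_for_structure
from lobehf.fixtures import make_chain, make_molecule
from lobehf.integrals import ScreeningConfig, build_screened_eris, \
    overlap_matrix
from lobehf.partition import (PartitionConfig, bond_list, build_subsystem,
                              classify_bond, dnc_run, grid_cores,
                              kmeans_cores, merge_density)
from lobehf.scf import atomic_energies, scf_solve
from lobehf.structure import AtomicStructure
from lobehf.units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM


@pytest.fixture()
def water_dimer():
    w1 = make_molecule("H2O")
    w2 = make_molecule("H2O").translated(
        np.array([3.0, 0.0, 0.0]) * BOHR_PER_ANGSTROM)
    return AtomicStructure(w1.elements + w2.elements,
                           np.vstack([w1.coords, w2.coords]))


class TestCoreGeneration:
    def test_kmeans_separates_distant_waters(self):
        w1 = make_molecule("H2O")
        w2 = make_molecule("H2O").translated(
            np.array([25.0, 0.0, 0.0]) * BOHR_PER_ANGSTROM)
        st = AtomicStructure(w1.elements + w2.elements,
                             np.vstack([w1.coords, w2.coords]))
        cores = kmeans_cores(st, 2, seed=0)
        assert sorted(map(sorted, cores)) == [[0, 1, 2], [3, 4, 5]]

    def test_kmeans_singletons(self, h2o):
        cores = kmeans_cores(h2o, h2o.n_atoms, seed=1)
        assert sorted(sum(map(list, cores), [])) == list(range(h2o.n_atoms))
        assert all(len(c) == 1 for c in cores)

    def test_kmeans_wcss_beats_worst_random_restart(self):
        rng = np.random.default_rng(11)
        pts = np.concatenate([rng.normal(loc=c, scale=0.8, size=(10, 3))
                              for c in rng.uniform(-20, 20, size=(12, 3))])
        st = AtomicStructure(["C"] * len(pts), pts)

        def wcss(cores):
            return sum(float(np.sum((st.coords[c]
                                     - st.coords[c].mean(axis=0)) ** 2))
                       for c in cores)

        fitted = wcss(kmeans_cores(st, 12, seed=0))
        worst = max(
            wcss([list(np.flatnonzero(lbl == k)) for k in range(12)
                  if np.any(lbl == k)])
            for lbl in (rng.integers(0, 12, size=len(pts))
                        for _ in range(20)))
        assert fitted <= worst

    def test_kmeans_invalid_k(self, h2o):
        with pytest.raises(ValueError):
            kmeans_cores(h2o, 0, 0)

    def test_grid_three_atoms_on_a_line(self):
        st = AtomicStructure.from_angstrom(["C", "C", "C"],
                                           [[0, 0, 0], [15, 0, 0],
                                            [30, 0, 0]])
        cores = grid_cores(st, 12.5)
        assert len(cores) == 3

    def test_grid_single_cell_covers_all(self, h2o):
        cores = grid_cores(h2o, 50.0)
        assert cores == [[0, 1, 2]]

    def test_grid_cell_count_arithmetic(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 40.0, size=(600, 3))
        st = AtomicStructure.from_angstrom(["C"] * 600, pts)
        cores = grid_cores(st, 12.5)
        span = pts.max(axis=0) - pts.min(axis=0)
        per_axis = np.floor(span / 12.5).astype(int) + 1
        assert len(cores) <= np.prod(per_axis)
        assert sum(len(c) for c in cores) == 600


class TestClassifyBond:
    @pytest.mark.parametrize("e1,e2,d,kind", [
        ("C", "C", 1.34, "double"),
        ("C", "C", 1.54, "single"),
        ("C", "C", 3.00, "none"),
        ("C", "H", 1.09, "single"),
        ("O", "H", 0.96, "single"),
        ("C", "O", 1.23, "double"),
        ("N", "H", 1.01, "single"),
    ])
    def test_table(self, e1, e2, d, kind):
        assert classify_bond(e1, e2, d) == kind

    def test_uncovered_pair_warns_none(self, caplog):
        assert classify_bond("Fe", "C", 1.8) == "none"


class TestBuildSubsystem:
    def test_water_dimer_buffer_no_caps(self, water_dimer):
        sub = build_subsystem([0, 1, 2], water_dimer,
                              PartitionConfig(buffer_cutoff=8.0))
        assert sub.buffer_atoms == [3, 4, 5]
        assert sub.caps == []

    def test_decane_midchain_cut_places_cap_on_bond_vector(self, decane):
        """Cutting a C-C single bond replaces the outside carbon with a cap
        hydrogen at the C-H table length along the former bond."""
        bonds = bond_list(decane)
        # core: first five carbons and their hydrogens (within 1.2 A)
        first5 = set(range(5))
        core = [a for a in range(decane.n_atoms)
                if a in first5 or any(
                    (i in first5 or j in first5) and (a in (i, j))
                    and k == "single" and decane.elements[a] == "H"
                    for i, j, k in bonds)]
        sub = build_subsystem(core, decane,
                              PartitionConfig(buffer_cutoff=0.5))
        # find the cap replacing carbon 5 anchored at carbon 4
        caps = [(p, rep, anc) for p, rep, anc in sub.caps
                if rep == 5 and anc == 4]
        assert caps, sub.caps
        pos, rep, anc = caps[0]
        vec_bond = decane.coords[5] - decane.coords[4]
        vec_cap = pos - decane.coords[4]
        cos = np.dot(vec_bond, vec_cap) / (np.linalg.norm(vec_bond)
                                           * np.linalg.norm(vec_cap))
        assert cos == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(vec_cap) * ANGSTROM_PER_BOHR == pytest.approx(
            1.09, abs=1e-9)
        assert sub.structure.n_electrons % 2 == 0

    def test_double_bond_pulls_both_carbons(self):
        eth = make_molecule("ethylene")
        sub = build_subsystem([0], eth, PartitionConfig(buffer_cutoff=0.5))
        assert 1 in sub.buffer_atoms        # the C=C partner comes along
        assert all(rep != 1 for _, rep, _ in sub.caps)


class TestMergeDensity:
    def test_single_subsystem_identity(self, h2o, basisdef):
        from lobehf.partition import SubsystemResult, Subsystem
        basis = basis_for_structure(h2o, basisdef)
        r = scf_solve(h2o, basis, ScreeningConfig.disabled())
        sub = Subsystem(core_atoms=[0, 1, 2], buffer_atoms=[], caps=[],
                        structure=h2o, parent_map=[0, 1, 2])
        res = SubsystemResult(sub, r, basis, None)
        merged = merge_density([res], basis)
        np.testing.assert_array_equal(merged.matrix, r.density_matrix)
        assert merged.n_uncovered == 0

    def test_two_identical_overlapping_subsystems_mean_equals_either(
            self, h2o, basisdef):
        from lobehf.partition import SubsystemResult, Subsystem
        basis = basis_for_structure(h2o, basisdef)
        r = scf_solve(h2o, basis, ScreeningConfig.disabled())
        subs = []
        for core in ([0], [1, 2]):
            sub = Subsystem(core_atoms=core,
                            buffer_atoms=[a for a in (0, 1, 2)
                                          if a not in core],
                            caps=[], structure=h2o, parent_map=[0, 1, 2])
            subs.append(SubsystemResult(sub, r, basis, None))
        merged = merge_density(subs, basis)
        np.testing.assert_allclose(merged.matrix, r.density_matrix,
                                   atol=1e-14)


class TestDnCRuns:
    def test_water_dimer_two_cores_vs_direct(self, water_dimer, basisdef):
        basis = basis_for_structure(water_dimer, basisdef)
        eris = build_screened_eris(basis, ScreeningConfig())
        direct = scf_solve(water_dimer, basis, eris=eris)
        ae_direct = atomic_energies(direct, basis)
        res = dnc_run(water_dimer,
                      PartitionConfig(mode="kmeans", k=2, buffer_cutoff=8.0))
        assert not res.failures
        np.testing.assert_allclose(res.atomic.energies, ae_direct.energies,
                                   atol=1e-3)

    def test_single_core_equals_direct_scf(self, h2o, basisdef):
        basis = basis_for_structure(h2o, basisdef)
        eris = build_screened_eris(basis, ScreeningConfig())
        direct = scf_solve(h2o, basis, eris=eris)
        res = dnc_run(h2o, PartitionConfig(mode="grid", cell_size=50.0))
        ae = atomic_energies(direct, basis)
        np.testing.assert_allclose(res.atomic.energies, ae.energies,
                                   atol=1e-12)
        np.testing.assert_allclose(res.global_density.matrix,
                                   direct.density_matrix, atol=1e-12)

    def test_run_deterministic_bitwise(self):
        chain = make_chain("alkane", 6)
        pc = PartitionConfig(mode="grid", cell_size=5.0, buffer_cutoff=3.0)
        r1 = dnc_run(chain, pc)
        r2 = dnc_run(chain, pc)
        np.testing.assert_array_equal(r1.atomic.energies, r2.atomic.energies)
        np.testing.assert_array_equal(r1.global_density.matrix,
                                      r2.global_density.matrix)

    def test_buffer_growth_converges_to_full_system(self, decane,
                                                    decane_screened):
        """Core-atom energies approach the full-system values monotonically
        in RMS as the buffer cut-off grows."""
        full, basis, _ = decane_screened
        ae_full = atomic_energies(full, basis)
        rms = []
        for cut in (2.0, 4.0, 8.0):
            res = dnc_run(decane, PartitionConfig(mode="kmeans", k=2,
                                                  buffer_cutoff=cut))
            rms.append(float(np.sqrt(np.mean(
                (res.atomic.energies - ae_full.energies) ** 2))))
        assert rms[0] >= rms[1] >= rms[2]

    def test_merged_density_electron_count_within_1pc(self, decane,
                                                      basisdef):
        res = dnc_run(decane, PartitionConfig(mode="kmeans", k=2,
                                              buffer_cutoff=6.0))
        basis = basis_for_structure(decane, basisdef)
        S = overlap_matrix(basis)
        tr = float(np.sum(res.global_density.matrix * S))
        assert tr == pytest.approx(decane.n_electrons, rel=0.01)
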