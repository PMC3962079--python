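import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from saxskit import (
    Structure, Atom, FormFactorTable, ScatteringProfile,
    debye_exact, debye_partial_rows, build_distance_histogram, debye_binned,
    debye_modulated, default_q_grid, ToySpec, make_toy,
)
from saxskit.debye_core import combine_partials, debye_quadratic_forms
from tests.conftest import table_for


def triple_loop_debye(structure, table):
    """Literal transcription of the double sum — the brute-force oracle."""
    pos = structure.positions()
    F = table.combined
    n = len(structure.atoms)
    out = np.zeros(len(table.q_grid))
    for k, q in enumerate(table.q_grid):
        total = 0.0
        for i in range(n):
            for j in range(n):
                r = math.dist(pos[i], pos[j])
                x = q * r
                sinc = 1.0 if x == 0.0 else math.sin(x) / x
                total += F[i, k] * F[j, k] * sinc
        out[k] = total
    return out


class TestDebyeExact:
    def test_single_atom_is_f_squared(self, q_saxs):
        from saxskit import assign_volumes
        st = assign_volumes(Structure(atoms=[Atom("C", [1.0, 2.0, 3.0])]))
        table = table_for(st, q_saxs)
        prof = debye_exact(st, table)
        np.testing.assert_allclose(prof.intensity, table.combined[0] ** 2,
                                   rtol=1e-14)

    def test_two_atom_closed_form(self, pair5, q_saxs):
        table = table_for(pair5, q_saxs)
        prof = debye_exact(pair5, table)
        F = table.combined[0]
        x = q_saxs * 5.0
        sinc = np.where(x == 0, 1.0, np.sin(np.where(x == 0, 1, x)) / np.where(x == 0, 1, x))
        expected = 2 * F ** 2 * (1 + sinc)
        np.testing.assert_allclose(prof.intensity, expected, rtol=1e-12)

    def test_matches_triple_loop_oracle(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        prof = debye_exact(coil30, table)
        oracle = triple_loop_debye(coil30, table)
        np.testing.assert_allclose(prof.intensity, oracle, rtol=1e-10)

    def test_zero_angle_is_total_charge_squared(self, coil30):
        q = np.linspace(0.0, 0.3, 7)
        table = table_for(coil30, q)
        prof = debye_exact(coil30, table)
        assert prof.intensity[0] == pytest.approx(
            table.combined[:, 0].sum() ** 2, rel=1e-12)

    def test_rigid_motion_invariant(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        base = debye_exact(coil30, table).intensity
        R = Rotation.from_euler("xyz", [17.0, 121.0, -44.0], degrees=True)
        moved = coil30.transformed(rotation=R.as_matrix(),
                                   translation=np.array([10.0, -20.0, 3.0]))
        shifted = debye_exact(moved, table_for(moved, q_saxs)).intensity
        assert np.max(np.abs(shifted - base) / base) < 1e-9


class TestPartialRows:
    def test_full_block_equals_exact(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        exact = debye_exact(coil30, table).intensity
        partial = debye_partial_rows(coil30, table, range(30))
        np.testing.assert_allclose(partial.sum(axis=1), exact, rtol=1e-12)

    def test_two_disjoint_blocks(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        exact = debye_exact(coil30, table).intensity
        a = debye_partial_rows(coil30, table, range(0, 11))
        b = debye_partial_rows(coil30, table, range(11, 30))
        total = combine_partials(30, [(range(0, 11), a), (range(11, 30), b)],
                                 q_saxs)
        np.testing.assert_allclose(total.intensity, exact, rtol=1e-12)

    def test_random_partitions_are_order_free(self, coil30, q_saxs, rng):
        table = table_for(coil30, q_saxs)
        exact = debye_exact(coil30, table).intensity
        for _ in range(10):
            perm = rng.permutation(30)
            cuts = sorted(rng.choice(np.arange(1, 30), size=3, replace=False))
            blocks = np.split(perm, cuts)
            contributions = [
                (blk, debye_partial_rows(coil30, table, blk)) for blk in blocks]
            rng.shuffle(contributions)
            total = combine_partials(30, contributions, q_saxs)
            np.testing.assert_allclose(total.intensity, exact, rtol=1e-12)

    def test_overlapping_blocks_rejected(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        a = debye_partial_rows(coil30, table, range(0, 16))
        b = debye_partial_rows(coil30, table, range(15, 30))
        with pytest.raises(ValueError, match="twice"):
            combine_partials(30, [(range(0, 16), a), (range(15, 30), b)],
                             q_saxs)

    def test_missing_rows_rejected(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        a = debye_partial_rows(coil30, table, range(0, 10))
        with pytest.raises(ValueError, match="missing"):
            combine_partials(30, [(range(0, 10), a)], q_saxs)

    def test_duplicate_rows_in_block_rejected(self, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        with pytest.raises(ValueError, match="duplicate"):
            debye_partial_rows(coil30, table, [0, 1, 1])


class TestDistanceHistogram:
    def test_two_atoms_one_bin(self, pair5):
        h = build_distance_histogram(pair5, n_bins=10)
        assert h.counts.sum() == 1
        assert h.counts[-1] == 1  # r = d_max lands in the last bin
        assert h.d_max == pytest.approx(5.0)

    def test_pair_count_conserved(self):
        st = make_toy(ToySpec("random_coil", 10, 3.8, "C", seed=9))
        h = build_distance_histogram(st, n_bins=100)
        assert h.counts.sum() == 45

    def test_histogram_mean_close_to_true_mean(self, coil100):
        h = build_distance_histogram(coil100, n_bins=100)
        hist_mean = np.average(h.r_centers, weights=h.counts)
        true_mean = pdist(coil100.positions()).mean()
        assert abs(hist_mean - true_mean) <= h.bin_width / 2

    def test_too_few_atoms(self):
        st = Structure(atoms=[Atom("C", [0, 0, 0])])
        with pytest.raises(ValueError):
            build_distance_histogram(st, 10)


class TestDebyeBinned:
    def test_zero_angle_total_charge(self, ring100):
        q = np.linspace(0.0, 0.3, 7)
        table = table_for(ring100, q)
        h = build_distance_histogram(ring100, 100)
        prof = debye_binned(h, table.combined[0], 100, q)
        assert prof.intensity[0] == pytest.approx(
            100 ** 2 * table.combined[0, 0] ** 2, rel=1e-12)

    def test_two_atoms_fine_bins_match_closed_form(self, pair5, q_saxs):
        table = table_for(pair5, q_saxs)
        h = build_distance_histogram(pair5, n_bins=2000)
        prof = debye_binned(h, table.combined[0], 2, q_saxs)
        exact = debye_exact(pair5, table).intensity
        assert np.max(np.abs(prof.intensity - exact) / exact) < 1e-3

    def test_ring_within_documented_tolerance(self, ring100, q_saxs):
        # documented: <= 3% max relative deviation at 100 bins on q <= 0.33
        table = table_for(ring100, q_saxs)
        exact = debye_exact(ring100, table).intensity
        h = build_distance_histogram(ring100, 100)
        prof = debye_binned(h, table.combined[0], 100, q_saxs)
        assert np.max(np.abs(prof.intensity - exact) / exact) < 0.03

    def test_monotone_convergence_on_ring(self, ring100, q_saxs):
        table = table_for(ring100, q_saxs)
        exact = debye_exact(ring100, table).intensity
        errs = []
        for n_bins in (25, 50, 100, 200):
            h = build_distance_histogram(ring100, n_bins)
            prof = debye_binned(h, table.combined[0], 100, q_saxs)
            errs.append(np.max(np.abs(prof.intensity - exact) / exact))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestDebyeModulated:
    def test_zero_angle(self, coil30):
        q = np.linspace(0.0, 0.3, 7)
        f0 = np.full(30, 6.0)
        prof = debye_modulated(coil30, f0, b_param=0.23, q_grid=q)
        assert prof.intensity[0] == pytest.approx((f0.sum()) ** 2, rel=1e-12)

    def test_b_zero_constant_factors_equal_exact(self, coil30, q_saxs):
        f0 = np.full(30, 6.0)
        const_table = FormFactorTable(
            q_grid=q_saxs,
            vacuum=np.full((30, len(q_saxs)), 6.0),
            excluded=np.zeros((30, len(q_saxs))),
            water=np.zeros(len(q_saxs)),
            shell_weight=np.zeros(30),
            solvent=__import__("saxskit").SolventModel())
        exact = debye_exact(coil30, const_table).intensity
        mod = debye_modulated(coil30, f0, b_param=0.0, q_grid=q_saxs).intensity
        np.testing.assert_allclose(mod, exact, rtol=1e-12)

    def test_refit_b_recovers_positive_width(self, coil30, q_saxs):
        """1-D refit of the modulation width against the exact engine."""
        table = table_for(coil30, q_saxs)
        exact = debye_exact(coil30, table).intensity
        f0 = table.combined[:, 0]

        def loss(b):
            m = debye_modulated(coil30, f0, b_param=b, q_grid=q_saxs).intensity
            return float(np.sum((np.log(m) - np.log(exact)) ** 2))

        res = minimize_scalar(loss, bounds=(0.0, 1.0), method="bounded")
        assert 0.0 < res.x < 1.0
        assert loss(res.x) < loss(0.0)


class TestQuadraticForms:
    def test_bilinearity_reconstructs_combined_intensity(self, coil30, q_saxs):
        """I for F = a - c1 b + c2 w from cross sums == direct evaluation."""
        import copy
        st = copy.deepcopy(coil30)
        for i, a in enumerate(st.atoms):
            a.sasa_fraction = (i % 5) / 5.0
        solvent = __import__("saxskit").SolventModel(c1=1.04, c2=1.7)
        table = FormFactorTable.from_structure(st, q_saxs, solvent=solvent)
        direct = debye_exact(st, table).intensity
        Wv, We = table.vacuum, table.excluded
        Ww = table.shell_weight[:, None] * table.water[None, :]
        Q = debye_quadratic_forms(st.positions(), [Wv, We, Ww], q_saxs)
        c1, c2 = 1.04, 1.7
        recon = (Q[0, 0] + c1 * c1 * Q[1, 1] + c2 * c2 * Q[2, 2]
                 - 2 * c1 * Q[0, 1] + 2 * c2 * Q[0, 2] - 2 * c1 * c2 * Q[1, 2])
        np.testing.assert_allclose(recon, direct, rtol=1e-10)


class TestProfileIO:
    def test_dat_roundtrip(self, tmp_path, coil30, q_saxs):
        table = table_for(coil30, q_saxs)
        prof = debye_exact(coil30, table)
        p = tmp_path / "prof.dat"
        prof.write_dat(p, header="test profile")
        back = ScatteringProfile.read_dat(p)
        np.testing.assert_allclose(back.q, prof.q, atol=1e-9)
        np.testing.assert_allclose(back.intensity, prof.intensity,
                                   rtol=1e-5)
        assert back.sigma is None

    def test_csv_dialect_and_sigma(self, tmp_path):
        p = tmp_path / "prof.csv"
        p.write_text("# comment\nq,I,sigma\n0.0,100.0,1.0\n0.1,50.0,0.5\n")
        prof = ScatteringProfile.read_dat(p)
        assert len(prof) == 2
        assert prof.sigma is not None
        assert prof.sigma[1] == pytest.approx(0.5)

    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            ScatteringProfile(q=np.array([0.0, 0.0]), intensity=np.array([1., 1.]))
        with pytest.raises(ValueError):
            default_q_grid(0.0, 10)
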