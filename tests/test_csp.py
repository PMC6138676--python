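"""Amide CSP, Calpha differences, classification and structure mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lamindyn.csp import (
    PerturbationRecord,
    ShiftTable,
    ca_diff,
    classify,
    csp,
    map_to_structure,
)
from lamindyn.synthetic import make_shift_tables


def table(variant, rows):
    """rows: {residue: (dHN, dN, dCA)}"""
    return ShiftTable.from_records(variant, rows)


class TestCsp:
    def test_zero_differences(self):
        a = table("A", {1: (8.0, 120.0, 56.0)})
        b = table("B", {1: (8.0, 120.0, 56.0)})
        (rec,) = csp(a, b)
        assert rec.d_amide == 0.0
        assert rec.d_ca == 0.0

    def test_printed_formula(self):
        # dHN = 0.1, dN = 0.5 -> sqrt(0.01 + 0.01)
        a = table("A", {1: (8.1, 120.5, None)})
        b = table("B", {1: (8.0, 120.0, None)})
        (rec,) = csp(a, b)
        assert rec.d_amide == pytest.approx(0.14142, abs=1e-5)

    def test_symmetric_in_table_order(self):
        a = table("A", {1: (8.3, 121.0, 55.0), 2: (7.9, 118.0, 57.0)})
        b = table("B", {1: (8.0, 120.0, 56.0), 2: (8.1, 119.0, 56.5)})
        fwd = {r.residue: r.d_amide for r in csp(a, b)}
        rev = {r.residue: r.d_amide for r in csp(b, a)}
        assert fwd == pytest.approx(rev)

    def test_missing_assignment_propagates_as_absent(self):
        a = table("A", {1: (8.0, 120.0, 56.0), 2: (None, 118.0, 57.0)})
        b = table("B", {1: (8.1, 120.5, 56.2), 2: (8.0, 118.5, 57.1)})
        records = {r.residue: r for r in csp(a, b)}
        assert records[2].d_amide is None  # never imputed to zero
        assert records[2].d_ca is not None

    def test_no_shared_amide_residues_rejected(self):
        a = table("A", {1: (8.0, 120.0, None)})
        b = table("B", {2: (8.0, 120.0, None)})
        with pytest.raises(ValueError, match="share no residue"):
            csp(a, b)

    @given(
        dhn=st.floats(min_value=-1.0, max_value=1.0),
        dn=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_amide_csp_bounds_components(self, dhn, dn):
        a = table("A", {1: (8.0 + dhn, 120.0 + dn, None)})
        b = table("B", {1: (8.0, 120.0, None)})
        (rec,) = csp(a, b)
        assert rec.d_amide >= abs(dhn) - 1e-12
        assert rec.d_amide >= abs(dn) / 5.0 - 1e-12

    def test_synthetic_tables_match_per_residue_oracle(self):
        a, b = make_shift_tables(
            n_residues=40, perturbed_cluster=(430, 440), baseline_sd=0.05, seed=5
        )
        records = {r.residue: r for r in csp(a, b)}
        for res in a.shifts.index:
            dhn = a.shifts.loc[res, "dHN_ppm"] - b.shifts.loc[res, "dHN_ppm"]
            dn = a.shifts.loc[res, "dN_ppm"] - b.shifts.loc[res, "dN_ppm"]
            assert records[res].d_amide == pytest.approx(
                math.sqrt(dhn**2 + (dn / 5.0) ** 2), rel=1e-12
            )


class TestCaDiff:
    def test_identical_tables(self):
        rows = {i: (8.0, 120.0, 50.0 + i) for i in range(1, 6)}
        diffs, r2 = ca_diff(table("A", rows), table("B", rows))
        assert np.allclose(diffs, 0.0)
        assert r2 == pytest.approx(1.0)

    def test_signed_difference(self):
        a = table("A", {1: (None, None, 56.2), 2: (None, None, 50.0), 3: (None, None, 45.0)})
        b = table("B", {1: (None, None, 56.0), 2: (None, None, 50.5), 3: (None, None, 45.0)})
        diffs, _ = ca_diff(a, b)
        assert diffs.loc[1] == pytest.approx(0.2)
        assert diffs.loc[2] == pytest.approx(-0.5)

    def test_antisymmetric_in_table_order(self):
        a, b = make_shift_tables(
            n_residues=30, perturbed_cluster=(430, 435), baseline_sd=0.1, seed=2
        )
        fwd, _ = ca_diff(a, b)
        rev, _ = ca_diff(b, a)
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_too_few_ca_shifts_gives_absent_r2(self):
        a = table("A", {1: (8.0, 120.0, 56.0), 2: (8.0, 120.0, None)})
        b = table("B", {1: (8.0, 120.0, 56.1), 2: (8.0, 120.0, 50.0)})
        diffs, r2 = ca_diff(a, b)
        assert r2 is None
        assert len(diffs) == 1

    def test_tuned_baseline_noise_reproduces_high_correlation(self):
        """Baseline noise chosen so that Calpha shifts over a 40-65 ppm range
        correlate with r^2 ~ 0.998; verified against a direct Pearson
        implementation."""
        # var(U(40, 65)) = 625/12; sigma for expected r^2 = 0.998 satisfies
        # r^2 = var / (var + sigma^2)
        var = 625.0 / 12.0
        sigma = math.sqrt(var * (1.0 / 0.998 - 1.0))
        a, b = make_shift_tables(n_residues=100, baseline_sd=sigma, seed=8)
        _, r2 = ca_diff(a, b)
        x = a.shifts["dCA_ppm"].to_numpy()
        y = b.shifts["dCA_ppm"].to_numpy()
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r2 == pytest.approx(r_direct**2, rel=1e-12)
        assert r2 == pytest.approx(0.998, abs=2e-3)


class TestClassify:
    def test_strict_threshold_boundary(self):
        records = [
            PerturbationRecord(1, d_amide=0.10),
            PerturbationRecord(2, d_amide=0.15),
            PerturbationRecord(3, d_amide=0.16),
        ]
        flagged = [r.residue for r in classify(records) if r.above_threshold]
        assert flagged == [3]

    def test_all_zero_none_flagged(self):
        records = [PerturbationRecord(i, d_amide=0.0) for i in range(5)]
        assert not any(r.above_threshold for r in classify(records))

    def test_huge_threshold_flags_nothing_tiny_flags_all_nonzero(self):
        records = [PerturbationRecord(i, d_amide=v) for i, v in enumerate([0.0, 0.01, 2.0])]
        assert not any(r.above_threshold for r in classify(records, threshold=1e9))
        flagged = [r.residue for r in classify(records, threshold=1e-12) if r.above_threshold]
        assert flagged == [1, 2]

    def test_planted_cluster_count(self):
        # an 11-residue cluster with 0.3 ppm amide offset over 0.05 ppm
        # baseline noise: exactly the cluster crosses the 0.15 ppm threshold
        a, b = make_shift_tables(
            n_residues=100,
            perturbed_cluster=(470, 480),
            cluster_amplitude=0.3,
            baseline_sd=0.05,
            seed=1,
        )
        flagged = [r.residue for r in classify(csp(a, b)) if r.above_threshold]
        assert flagged == list(range(470, 481))
        assert len(flagged) == 11


class TestMapToStructure:
    def test_bfactor_mapping_and_sentinel(self):
        struc = pytest.importorskip("biotite.structure")
        atoms = struc.AtomArray(4)
        atoms.coord = np.zeros((4, 3))
        atoms.res_id = np.array([451, 451, 452, 453])
        atoms.atom_name = np.array(["N", "CA", "CA", "CA"])
        atoms.res_name = np.array(["PHE", "PHE", "GLY", "GLY"])
        atoms.chain_id = np.array(["A"] * 4)
        atoms.element = np.array(["N", "C", "C", "C"])
        annotated = map_to_structure({451: 0.16, 453: 0.02}, atoms)
        assert np.allclose(annotated.b_factor, [0.16, 0.16, -1.0, 0.02])

    def test_no_overlap_rejected(self):
        struc = pytest.importorskip("biotite.structure")
        atoms = struc.AtomArray(1)
        atoms.coord = np.zeros((1, 3))
        atoms.res_id = np.array([1])
        with pytest.raises(ValueError, match="no structure residue"):
            map_to_structure({999: 0.5}, atoms)

    def test_pdb_round_trip_preserves_values_to_two_decimals(self, tmp_path):
        from lamindyn import io as ldio
        from lamindyn.ensemble import CoordinateEnsemble

        ens = CoordinateEnsemble(
            coords=np.random.default_rng(0).uniform(0, 2, (1, 5, 3)),
            residue_numbers=np.arange(430, 435),
            atom_names=np.array(["CA"] * 5),
        )
        path = tmp_path / "ref.pdb"
        ldio.write_ensemble_pdb(ens, path)
        atoms = ldio.read_structure(path)[0]
        values = {431: 0.16, 433: 1.234}
        out = tmp_path / "annotated.pdb"
        ldio.write_pdb(map_to_structure(values, atoms), out)
        reread = ldio.read_structure(out)[0]
        by_res = dict(zip(reread.res_id.tolist(), reread.b_factor.tolist()))
        assert by_res[431] == pytest.approx(0.16, abs=0.005)
        assert by_res[433] == pytest.approx(1.23, abs=0.005)
        assert by_res[430] == pytest.approx(-1.0, abs=0.005)
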