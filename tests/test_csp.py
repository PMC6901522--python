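"""Chemical-shift perturbation: Eq-style combination, alignment, binning."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_peaklist
from mydgf_nmr.csp import (
    BinScheme,
    CspValue,
    align_to_reference,
    bin_csp,
    compare_conditions,
    compute_csp,
    map_bins_to_structure,
)
from mydgf_nmr.io_formats import Condition, Peak, parse_assignment_label

W77 = parse_assignment_label("W77N-H")
H49 = parse_assignment_label("H49N-H")

finite = st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)


class TestComputeCsp:
    def test_identity_is_zero(self):
        p = Peak(H49, 120.5, 8.2)
        assert compute_csp(p, p).delta_NH == 0.0

    def test_hand_value(self):
        """ddH = 0.03, ddN = 0.20 -> sqrt(0.0009 + 0.0016) = 0.05."""
        a = Peak(H49, 120.0, 8.0)
        b = Peak(H49, 120.2, 8.03)
        v = compute_csp(a, b)
        assert v.delta_H == pytest.approx(0.03)
        assert v.delta_N == pytest.approx(0.20)
        assert v.delta_NH == pytest.approx(0.05)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_csp(Peak(H49, 120, 8), Peak(W77, 129, 10))

    @given(dh=finite, dn=finite)
    def test_symmetric_and_sign_invariant(self, dh, dn):
        a = Peak(H49, 120.0, 8.0)
        b = Peak(H49, 120.0 + dn, 8.0 + dh)
        forward = compute_csp(a, b).delta_NH
        assert forward == pytest.approx(compute_csp(b, a).delta_NH)
        # depends only on magnitudes
        c = Peak(H49, 120.0 - dn, 8.0 - dh)
        assert forward == pytest.approx(compute_csp(a, c).delta_NH)

    @given(dh=finite, dn=finite)
    def test_combined_value_matches_formula(self, dh, dn):
        v = CspValue(H49, delta_H=dh, delta_N=dn)
        assert v.delta_NH == pytest.approx(math.sqrt(dh**2 + (dn / 5.0) ** 2))
        assert v.delta_NH >= 0


class TestAlignment:
    def _lists(self):
        base = {"W77N-H": (129.1, 10.05), "H49N-H": (120.5, 8.20), "E34N-H": (118.2, 8.11)}
        shifted = {k: (dn + 0.10, dh + 0.02) for k, (dn, dh) in base.items()}
        return (
            make_peaklist(base, Condition("a")),
            make_peaklist(shifted, Condition("b")),
        )

    def test_already_aligned_unchanged(self):
        a, _ = self._lists()
        out = align_to_reference([a, a], W77)
        for peak in out[1]:
            assert peak == a[peak.label]

    def test_global_offset_removed(self):
        """A constant offset applied to one spectrum aligns away entirely."""
        a, b = self._lists()
        aligned_a, aligned_b = align_to_reference([a, b], W77)
        for label in a.labels:
            assert compute_csp(aligned_a[label], aligned_b[label]).delta_NH == pytest.approx(
                0.0, abs=1e-12
            )

    def test_reference_csp_exactly_zero(self):
        a, b = self._lists()
        # perturb one non-reference residue so alignment is non-trivial
        b = make_peaklist(
            {"W77N-H": (129.2, 10.07), "H49N-H": (121.5, 8.35), "E34N-H": (118.3, 8.13)},
            Condition("b"),
        )
        out = align_to_reference([a, b], W77)
        assert compute_csp(out[0][W77], out[1][W77]).delta_NH == 0.0

    def test_missing_reference_names_condition(self):
        a, _ = self._lists()
        no_ref = make_peaklist({"H49N-H": (120.5, 8.2)}, Condition("calcium"))
        with pytest.raises(ValueError, match="calcium"):
            align_to_reference([a, no_ref], W77)

    def test_common_additive_offset_invariance(self):
        """Offsetting both spectra identically leaves aligned CSPs unchanged."""
        a, b = self._lists()
        csp_before = {
            lab: compute_csp(*(pl[lab] for pl in align_to_reference([a, b], W77)))
            for lab in a.labels
        }
        a2, b2 = a.shifted(0.5, 2.0), b.shifted(0.5, 2.0)
        aligned = align_to_reference([a2, b2], W77)
        for lab in a.labels:
            after = compute_csp(aligned[0][lab], aligned[1][lab])
            assert after.delta_NH == pytest.approx(csp_before[lab].delta_NH, abs=1e-12)


class TestBinScheme:
    def test_tukey_fence_hand_computed(self):
        """Type-7 quartiles of {0.01..0.04}: Q3 = 0.0325, IQR = 0.015, b = 0.055."""
        scheme = BinScheme.from_reference([0.01, 0.02, 0.03, 0.04])
        assert scheme.first_bound == pytest.approx(0.055)
        assert scheme.bin_of(0.10) == 2

    def test_zero_goes_to_first_bin(self):
        scheme = BinScheme(first_bound=0.02)
        assert scheme.bin_of(0.0) == 1

    def test_all_zero_values_bin_one(self):
        scheme, cmap = bin_csp(
            [CspValue(H49, 0.0, 0.0), CspValue(W77, 0.0, 0.0)], first_bound=0.02
        )
        assert set(cmap.bins.values()) == {1}

    def test_open_top_bin_clamps(self):
        scheme = BinScheme(first_bound=0.01, n_bins=10)
        assert scheme.bin_of(0.5) == 10

    def test_zero_reference_distribution_is_error(self):
        with pytest.raises(ValueError, match="bound"):
            BinScheme.from_reference([0.0, 0.0, 0.0])

    def test_bounds_are_multiples_of_first(self):
        scheme = BinScheme(first_bound=0.03, n_bins=10)
        np.testing.assert_allclose(scheme.bounds, 0.03 * np.arange(1, 10))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    def test_fence_dominates_quartiles(self, values):
        """b >= Q3 >= median for any reference distribution."""
        if max(values) == 0:
            return
        scheme = BinScheme.from_reference(values)
        q3 = np.percentile(values, 75)
        assert scheme.first_bound >= q3 - 1e-12
        assert q3 >= np.median(values) - 1e-12

    @given(
        st.lists(st.floats(min_value=0, max_value=0.5), min_size=2, max_size=30),
    )
    def test_bin_nondecreasing_in_csp(self, values):
        scheme = BinScheme(first_bound=0.02)
        ordered = sorted(values)
        bins = [scheme.bin_of(v) for v in ordered]
        assert bins == sorted(bins)


class TestStructureMapping:
    def test_bins_roundtrip_through_bfactors(self, toy_ensemble):
        from mydgf_nmr.io_formats import read_ensemble

        _, cmap = bin_csp(
            [CspValue(H49, 0.2, 0.0)], first_bound=0.02, missing=[50]
        )
        pdb_buf, table_buf = io.StringIO(), io.StringIO()
        map_bins_to_structure(cmap, toy_ensemble, pdb_buf, table_buf)
        # recover per-residue B-factors from the written PDB
        reread = {}
        for line in pdb_buf.getvalue().splitlines():
            if line.startswith("ATOM"):
                reread.setdefault(int(line[22:26]), float(line[60:66]))
        assert reread[49] == 10.0  # 0.2 ppm with b = 0.02 -> top bin
        assert reread[50] == -1.0  # missing sentinel
        assert "#000000" in table_buf.getvalue()

    def test_no_overlap_is_error(self, toy_ensemble):
        _, cmap = bin_csp([CspValue(parse_assignment_label("A999N-H"), 0.1, 0)], first_bound=0.02)
        with pytest.raises(ValueError, match="overlap"):
            map_bins_to_structure(cmap, toy_ensemble, io.StringIO(), io.StringIO())


class TestCompareConditions:
    def test_identity_unperturbed(self, toy_peaklist):
        report = compare_conditions(toy_peaklist, toy_peaklist, threshold=0.02)
        assert report.verdict == "unperturbed"
        assert report.max_delta_NH == 0.0

    def test_single_moved_residue_reported(self, toy_peaklist):
        moved = make_peaklist(
            {
                "E34N-H": (118.2, 8.11),
                "H49N-H": (120.5, 8.30),  # ddH = 0.1
                "W77N-H": (129.1, 10.05),
                "W95N-H": (122.7, 9.30),
            }
        )
        report = compare_conditions(toy_peaklist, moved, threshold=0.02)
        assert report.verdict == "perturbed"
        assert report.exceeding == [H49]

    def test_subthreshold_shifts_unperturbed(self, rng):
        """Calcium-mimic: every displacement constructed below threshold."""
        base = {f"A{i}N-H": (float(rng.uniform(105, 130)), float(rng.uniform(6, 11))) for i in range(1, 31)}
        wiggled = {
            k: (dn + float(rng.uniform(-0.02, 0.02)), dh + float(rng.uniform(-0.004, 0.004)))
            for k, (dn, dh) in base.items()
        }
        report = compare_conditions(
            make_peaklist(base), make_peaklist(wiggled), threshold=0.02
        )
        assert report.verdict == "unperturbed"

    def test_disjoint_assignments_error(self):
        a = make_peaklist({"A1N-H": (110, 7)})
        b = make_peaklist({"G2N-H": (111, 8)})
        with pytest.raises(ValueError, match="common"):
            compare_conditions(a, b)
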