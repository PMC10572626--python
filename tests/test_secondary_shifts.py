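"""Secondary chemical shifts: parsing, referencing and segment classification."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxaribo.errors import ConfigurationError, ValidationError
from oxaribo.random_coil import AA1, RandomCoilTable, wishart_1995
from oxaribo.secondary_shifts import (
    SegmentClassifier,
    ShiftEntry,
    ShiftTable,
    classify_segments,
    compute_secondary_shifts,
    read_shift_table,
    write_shift_table,
)
from oxaribo.synthetic_data import HELIX_REGION, gen_shift_table

REFS = wishart_1995()


def make_table(types, first=1, ca_offsets=None, cb_offsets=None):
    entries = []
    for i, rtype in enumerate(types):
        shifts = {
            "CA": REFS.ca[rtype] + (ca_offsets[i] if ca_offsets is not None else 0.0)
        }
        if rtype != "G":
            shifts["CB"] = REFS.cb[rtype] + (
                cb_offsets[i] if cb_offsets is not None else 0.0
            )
        entries.append(ShiftEntry(first + i, rtype, shifts))
    return ShiftTable(entries)


class TestShiftTableIO:
    def test_tsv_parse(self, tmp_path):
        path = tmp_path / "shifts.tsv"
        path.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n"
            "1\tA\tCA\t52.5\n1\tA\tCB\t19.1\n"
            "2\tV\tCA\t62.2\n2\tV\tCB\t32.9\n"
            "3\tL\tCA\t55.1\n3\tL\tCB\t42.4\n"
        )
        table = read_shift_table(path, dialect="tsv")
        assert len(table) == 3
        assert all({"CA", "CB"} <= set(e.shifts) for e in table.entries)

    def test_glycine_cb_rejected(self, tmp_path):
        path = tmp_path / "shifts.tsv"
        path.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n1\tG\tCB\t30.0\n"
        )
        with pytest.raises(ValidationError):
            read_shift_table(path)

    def test_duplicate_assignment_rejected(self, tmp_path):
        path = tmp_path / "shifts.tsv"
        path.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n"
            "1\tA\tCA\t52.5\n1\tA\tCA\t52.6\n"
        )
        with pytest.raises(ValidationError):
            read_shift_table(path)

    def test_unknown_residue_rejected(self, tmp_path):
        path = tmp_path / "shifts.tsv"
        path.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n1\tX\tCA\t52.5\n"
        )
        with pytest.raises(ValidationError):
            read_shift_table(path)

    @pytest.mark.parametrize("dialect", ["tsv", "nmrstar"])
    def test_roundtrip(self, tmp_path, rng, dialect):
        types = [AA1[i] for i in rng.integers(0, 20, size=30)]
        table = make_table(types, first=320, ca_offsets=rng.normal(0, 1, 30),
                           cb_offsets=rng.normal(0, 1, 30))
        path = tmp_path / f"shifts.{dialect}"
        write_shift_table(table, path, dialect=dialect)
        back = read_shift_table(path, dialect=dialect)
        assert back.residue_numbers() == table.residue_numbers()
        for a, b in zip(table.entries, back.entries):
            assert a.residue_type == b.residue_type
            assert set(a.shifts) == set(b.shifts)
            for nuc in a.shifts:
                assert a.shifts[nuc] == pytest.approx(b.shifts[nuc], abs=5e-4)


class TestComputeSecondaryShifts:
    def test_identity_gives_zero(self):
        table = make_table("AVLIQ")
        profile = compute_secondary_shifts(table, REFS)
        assert all(d == pytest.approx(0.0, abs=1e-12) for d in profile.deltas)

    def test_ca_additivity(self):
        table = make_table("A", ca_offsets=[3.0], cb_offsets=[0.0])
        profile = compute_secondary_shifts(table, REFS)
        assert profile.deltas[0] == pytest.approx(3.0, abs=1e-12)

    def test_matches_hand_computation(self, rng):
        types = [AA1[i] for i in rng.integers(0, 20, size=50)]
        ca_off = rng.normal(0, 2, 50)
        cb_off = rng.normal(0, 2, 50)
        table = make_table(types, ca_offsets=ca_off, cb_offsets=cb_off)
        profile = compute_secondary_shifts(table, REFS)
        for entry, delta in zip(table.entries, profile.deltas):
            d_ca = entry.shifts["CA"] - REFS.ca[entry.residue_type]
            if entry.residue_type == "G":
                expected = d_ca
            else:
                expected = d_ca - (entry.shifts["CB"] - REFS.cb[entry.residue_type])
            assert delta == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-5, 5, allow_nan=False))
    def test_linearity_under_global_ca_shift(self, offset):
        table = make_table("AVLIQWD")
        base = compute_secondary_shifts(table, REFS)
        shifted = ShiftTable(
            [
                ShiftEntry(e.residue_number, e.residue_type,
                           {**e.shifts, "CA": e.shifts["CA"] + offset})
                for e in table.entries
            ]
        )
        moved = compute_secondary_shifts(shifted, REFS)
        for a, b in zip(base.deltas, moved.deltas):
            assert b - a == pytest.approx(offset, abs=1e-9)

    def test_glycine_and_missing_cb_are_ca_only(self):
        entries = [
            ShiftEntry(1, "G", {"CA": REFS.ca["G"] + 1.0}),
            ShiftEntry(2, "A", {"CA": REFS.ca["A"] + 1.0}),
            ShiftEntry(3, "A", {"N": 120.0}),
        ]
        profile = compute_secondary_shifts(ShiftTable(entries), REFS)
        assert profile.statuses == ["ca_only", "ca_only", "missing"]
        assert profile.deltas[2] is None

    def test_missing_reference_type_is_configuration_error(self):
        broken = RandomCoilTable(ca=dict(REFS.ca), cb=dict(REFS.cb))
        broken.ca.pop("W")  # construction validated; mutate afterwards
        with pytest.raises(ConfigurationError):
            compute_secondary_shifts(make_table("W"), broken)

    def test_pre_proline_correction_applied_when_enabled(self):
        table = make_table("AP")
        off = compute_secondary_shifts(table, REFS, use_neighbor_corrections=False)
        on = compute_secondary_shifts(table, REFS, use_neighbor_corrections=True)
        # built-in correction lowers the pre-proline CA reference by 2 ppm
        assert on.deltas[0] - off.deltas[0] == pytest.approx(2.0, abs=1e-12)
        assert on.deltas[1] == pytest.approx(off.deltas[1], abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            compute_secondary_shifts(ShiftTable([]), REFS)


class TestClassifySegments:
    def _profile(self, deltas, first=320):
        table = make_table("A" * len(deltas), first=first,
                           ca_offsets=list(deltas), cb_offsets=[0.0] * len(deltas))
        return compute_secondary_shifts(table, REFS)

    def test_all_zero_is_single_coil_segment(self):
        segments = classify_segments(self._profile([0.0] * 40))
        assert len(segments) == 1
        assert segments[0].segment_class == "coil"
        assert (segments[0].start_residue, segments[0].end_residue) == (320, 359)

    def test_constant_three_ppm_is_single_stable_helix(self):
        segments = classify_segments(self._profile([3.0] * 40))
        assert [s.segment_class for s in segments] == ["stable_helix"]

    def test_strand_like_negative_profile_is_extended(self):
        segments = classify_segments(self._profile([-1.5] * 40))
        assert [s.segment_class for s in segments] == ["extended"]

    def test_transient_region_in_coil_flanks(self):
        deltas = [0.0] * 22 + [1.5] * 44 + [0.0] * 17
        segments = classify_segments(self._profile(deltas))
        transient = [s for s in segments if s.segment_class == "transient_helix"]
        assert len(transient) == 1
        # smoothing blurs the boundary by at most one residue on each side
        assert abs(transient[0].start_residue - 342) <= 1
        assert abs(transient[0].end_residue - 385) <= 1

    def test_short_bump_absorbed_into_coil(self):
        deltas = [0.0] * 20 + [3.0] * 2 + [0.0] * 20
        segments = classify_segments(self._profile(deltas), window=1)
        assert all(s.segment_class == "coil" for s in segments)

    def test_deterministic(self):
        profile = self._profile([0.3, 1.5, 1.6, 1.4, 1.7, 0.1, 0.0, 0.2] * 6)
        first = classify_segments(profile)
        second = classify_segments(profile)
        assert first == second

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_segments(self._profile([0.0] * 10), window=4)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            SegmentClassifier(stable=0.4, transient=0.5).fit()

    def test_estimator_get_set_params(self):
        clf = SegmentClassifier()
        clf.set_params(window=7, min_length=6)
        assert clf.get_params()["window"] == 7
        assert clf.get_params()["min_length"] == 6


class TestPlantedHelixRecovery:
    def test_transient_helix_recovered_from_default_generator(self, study_config):
        table = gen_shift_table(study_config)
        profile = compute_secondary_shifts(table)
        segments = classify_segments(profile)
        transient = [s for s in segments if s.segment_class == "transient_helix"]
        assert len(transient) == 1
        start, end = HELIX_REGION
        planted = set(range(start, end + 1))
        called = set(range(transient[0].start_residue, transient[0].end_residue + 1))
        assert len(planted & called) >= 0.9 * len(planted)
        assert len(called - planted) <= 5

    def test_generator_noise_respects_seed(self, study_config):
        one = gen_shift_table(study_config)
        two = gen_shift_table(dataclasses.replace(study_config))
        assert one.to_frame().equals(two.to_frame())
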