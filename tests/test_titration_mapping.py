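"""Titration intensity ratios, CSPs and binding-segment calling."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxaribo.errors import FormatError, ValidationError
from oxaribo.synthetic_data import BINDING_SEGMENTS, gen_titration_series
from oxaribo.titration_mapping import (
    IntensityRatioProfile,
    Peak,
    PeakList,
    TitrationPoint,
    TitrationSeries,
    call_binding_segments,
    compute_csp,
    compute_intensity_ratios,
    parse_assignment,
    read_peak_list,
    write_peak_list,
)


def make_list(residues, intensity=1.0e6, h=8.2, n=118.0, types=None):
    return PeakList(
        [
            Peak(r, (types or {}).get(r, "A"), position_h=h, position_n=n,
                 intensity=intensity if np.isscalar(intensity) else intensity[i])
            for i, r in enumerate(residues)
        ]
    )


class TestPeakListIO:
    def test_assignment_token_grammar(self):
        assert parse_assignment("V321N-H") == ("V", 321)
        with pytest.raises(FormatError):
            parse_assignment("V321CA-CB")

    def test_well_formed_rows(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text(
            "  Assignment   w1   w2   Height\n"
            "  V321N-H 120.5 8.20 1.0e6\n"
            "  R322N-H 121.1 8.31 9.5e5\n"
            "  # comment line\n"
            "  S323N-H 116.0 8.10 8.0e5\n"
        )
        peaks = read_peak_list(path)
        assert len(peaks) == 3
        first = peaks.peaks[0]
        assert (first.residue_number, first.residue_type) == (321, "V")
        assert first.position_n == pytest.approx(120.5)
        assert first.position_h == pytest.approx(8.20)

    def test_roundtrip_random_list(self, tmp_path, rng):
        residues = sorted(rng.choice(np.arange(320, 403), size=40, replace=False))
        peaks = PeakList(
            [
                Peak(int(r), "AVLIQ"[i % 5], float(rng.uniform(7.8, 8.5)),
                     float(rng.uniform(108, 130)), float(rng.uniform(1e5, 1e7)))
                for i, r in enumerate(residues)
            ]
        )
        path = tmp_path / "peaks.list"
        write_peak_list(peaks, path)
        back = read_peak_list(path)
        assert len(back) == len(peaks)
        for a, b in zip(peaks.peaks, back.peaks):
            assert (a.residue_number, a.residue_type) == (b.residue_number, b.residue_type)
            assert a.position_h == pytest.approx(b.position_h, abs=1e-4)
            assert a.position_n == pytest.approx(b.position_n, abs=1e-4)
            assert a.intensity == pytest.approx(b.intensity, rel=1e-6)

    def test_duplicate_residue_rejected(self):
        with pytest.raises(ValidationError):
            make_list([321, 321])

    def test_non_numeric_field_names_line(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text("V321N-H 120.5 eight 1.0e6\n")
        with pytest.raises(FormatError, match="line 1"):
            read_peak_list(path)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValidationError):
            make_list([321], intensity=0.0)


class TestIntensityRatios:
    def _series(self, ref_int, point_int, ratios=(10.0,)):
        residues = list(range(320, 340))
        reference = make_list(residues, intensity=ref_int)
        points = [
            TitrationPoint(r, make_list(residues, intensity=point_int))
            for r in ratios
        ]
        return TitrationSeries(reference, points, protein_total=45.0)

    def test_identity_point_gives_unity(self):
        profile = compute_intensity_ratios(self._series(1e6, 1e6))
        assert all(v == pytest.approx(1.0) for v in profile.ratios.values())

    def test_half_intensity_gives_half_ratio(self):
        profile = compute_intensity_ratios(self._series(1e6, 5e5))
        assert all(v == pytest.approx(0.5) for v in profile.ratios.values())

    def test_matches_per_residue_division(self, rng):
        residues = list(range(320, 360))
        ref = make_list(residues, intensity=rng.uniform(1e5, 1e7, len(residues)))
        point = make_list(residues, intensity=rng.uniform(1e4, 1e6, len(residues)))
        series = TitrationSeries(ref, [TitrationPoint(10.0, point)], 45.0)
        profile = compute_intensity_ratios(series)
        ref_by = ref.by_residue()
        for peak in point.peaks:
            expected = peak.intensity / ref_by[peak.residue_number].intensity
            assert profile.ratios[(peak.residue_number, 10.0)] == pytest.approx(
                expected, abs=1e-12
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3, allow_nan=False))
    def test_global_intensity_scale_invariance(self, scale):
        base = self._series(1e6, 4e5)
        scaled = self._series(1e6 * scale, 4e5 * scale)
        a = compute_intensity_ratios(base)
        b = compute_intensity_ratios(scaled)
        for key in a.ratios:
            assert a.ratios[key] == pytest.approx(b.ratios[key], rel=1e-9)

    def test_missing_residue_absent_not_zero(self):
        reference = make_list(range(320, 330))
        point = make_list(range(320, 325))
        series = TitrationSeries(reference, [TitrationPoint(5.0, point)], 45.0)
        profile = compute_intensity_ratios(series)
        assert (327, 5.0) not in profile.ratios

    def test_monotone_attenuation_on_synthetic_series(self, study_config):
        series = gen_titration_series(study_config)
        profile = compute_intensity_ratios(series)
        ratios = profile.molar_ratios()
        for residue in series.reference.residue_numbers():
            values = [
                profile.ratios.get((residue, r))
                for r in ratios
                if (residue, r) in profile.ratios
            ]
            # three-sigma slack on the multiplicative noise
            assert all(b <= a * (1 + 0.35) for a, b in zip(values, values[1:]))


class TestCSP:
    def test_zero_when_identical(self):
        peaks = make_list(range(320, 330))
        csp = compute_csp(peaks, peaks)
        assert all(c == 0.0 for c in csp.csp)
        assert not any(csp.significant)

    def test_h_only_below_threshold(self):
        ref = make_list([321])
        tit = make_list([321], h=8.2 + 0.003)
        csp = compute_csp(ref, tit)
        assert csp.csp[0] == pytest.approx(0.003, abs=1e-12)
        assert not csp.significant[0]

    def test_weighted_combination_hand_value(self):
        ref = make_list([321])
        tit = make_list([321], h=8.2 + 0.004, n=118.0 + 0.05)
        csp = compute_csp(ref, tit, n_weight=0.14)
        assert csp.csp[0] == pytest.approx(math.hypot(0.004, 0.007), abs=1e-9)
        assert csp.csp[0] == pytest.approx(0.00806, abs=5e-5)
        assert csp.significant[0]

    def test_symmetry_under_list_swap(self, rng):
        residues = list(range(320, 340))
        ref = PeakList(
            [Peak(r, "A", float(rng.uniform(7.8, 8.5)), float(rng.uniform(108, 130)),
                  1e6) for r in residues]
        )
        tit = PeakList(
            [Peak(r, "A", float(rng.uniform(7.8, 8.5)), float(rng.uniform(108, 130)),
                  1e6) for r in residues]
        )
        forward = compute_csp(ref, tit)
        backward = compute_csp(tit, ref)
        assert np.allclose(forward.csp, backward.csp)

    def test_disjoint_lists_rejected(self):
        with pytest.raises(ValidationError):
            compute_csp(make_list(range(320, 325)), make_list(range(330, 335)))


class TestBindingSegmentCalling:
    def _profile(self, site_ratio=0.2, off_ratio=0.5, point=10.0):
        ratios = {}
        for r in range(320, 403):
            on_site = any(s <= r <= e for s, e in BINDING_SEGMENTS)
            ratios[(r, point)] = site_ratio if on_site else off_ratio
        return IntensityRatioProfile(ratios)

    def test_planted_contrast_yields_exactly_two_segments(self):
        call = call_binding_segments(self._profile(), calling_point=10.0)
        found = [(s.start_residue, s.end_residue) for s in call.segments]
        assert found == list(BINDING_SEGMENTS)

    def test_uniform_profile_yields_no_segments(self):
        profile = IntensityRatioProfile({(r, 10.0): 1.0 for r in range(320, 360)})
        call = call_binding_segments(profile, calling_point=10.0)
        assert call.segments == []
        assert call.baseline_ratio == pytest.approx(1.0)

    def test_isolated_dip_filtered_by_min_length(self):
        ratios = {(r, 10.0): 0.5 for r in range(320, 360)}
        ratios[(340, 10.0)] = 0.1
        call = call_binding_segments(IntensityRatioProfile(ratios), calling_point=10.0)
        assert call.segments == []

    def test_too_few_residues_rejected(self):
        profile = IntensityRatioProfile({(r, 10.0): 0.5 for r in range(320, 324)})
        with pytest.raises(ValidationError):
            call_binding_segments(profile, calling_point=10.0)

    def test_bad_drop_factor_rejected(self):
        with pytest.raises(ValidationError):
            call_binding_segments(self._profile(), calling_point=10.0, drop_factor=1.5)

    def test_planted_recovery_from_seeded_generator(self, study_config):
        series = gen_titration_series(study_config)
        profile = compute_intensity_ratios(series)
        call = call_binding_segments(profile)
        assert call.calling_ratio_point == 10.0
        assert len(call.segments) == 2
        for seg, (start, end) in zip(call.segments, BINDING_SEGMENTS):
            assert abs(seg.start_residue - start) <= 1
            assert abs(seg.end_residue - end) <= 1

    def test_call_invariant_under_global_intensity_scale(self, study_config):
        series = gen_titration_series(study_config)
        scaled = TitrationSeries(
            reference=PeakList(
                [dataclasses.replace(p, intensity=p.intensity * 7.5)
                 for p in series.reference.peaks]
            ),
            points=[
                TitrationPoint(
                    pt.molar_ratio,
                    PeakList(
                        [dataclasses.replace(p, intensity=p.intensity * 7.5)
                         for p in pt.peaks.peaks]
                    ),
                )
                for pt in series.points
            ],
            protein_total=series.protein_total,
        )
        one = call_binding_segments(compute_intensity_ratios(series))
        two = call_binding_segments(compute_intensity_ratios(scaled))
        assert [(s.start_residue, s.end_residue) for s in one.segments] == [
            (s.start_residue, s.end_residue) for s in two.segments
        ]
        assert one.baseline_ratio == pytest.approx(two.baseline_ratio, rel=1e-9)
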