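"""Stimulus timing, geometry and condition-library tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sqmsim import (
    ConditionSpec,
    Geometry,
    Instruction,
    Reference,
    Stream,
    Variant,
    build_sequence,
    condition_library,
    element_signal,
    frame_onset,
    get_condition,
    sequence_to_table,
)
from sqmsim.conditions import library_from_yaml, library_to_yaml
from sqmsim.stimulus import FLANK_SPACING_ARCMIN, LINE_DURATION_MS


class TestFrameOnset:
    @pytest.mark.parametrize(
        "frame,onset_ms",
        [(0, 0), (1, 50), (2, 90), (3, 130), (5, 210), (7, 290),
         (8, 330), (11, 450), (12, 490), (14, 570)],
    )
    def test_printed_onsets(self, frame, onset_ms):
        assert frame_onset(frame) == onset_ms

    def test_negative_frame_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            frame_onset(-1)

    @given(st.integers(min_value=2, max_value=60))
    def test_consecutive_pairs_separated_by_40ms(self, n):
        assert frame_onset(n) - frame_onset(n - 1) == 40

    def test_first_isi_is_30ms(self):
        assert frame_onset(1) - LINE_DURATION_MS == 30


class TestBuildSequence:
    def test_total_duration_18_pairs(self):
        seq = build_sequence(get_condition("V"))
        assert seq.duration_ms == 750

    def test_total_duration_20_pairs(self):
        seq = build_sequence(get_condition("C5"), Geometry.constant())
        assert seq.duration_ms == 830

    def test_element_count(self):
        seq = build_sequence(get_condition("V"))
        assert len(seq.elements) == 1 + 2 * 18

    def test_offsets_only_on_attended_stream(self):
        seq = build_sequence(get_condition("V-AV8"))
        assert seq.element_at(-8).offset_sign == -1  # attended left stream
        assert seq.element_at(8).offset_sign == 0
        assert seq.element_at(0).offset_sign == 1

    def test_diverging_eccentricity_grows_with_frame(self):
        seq = build_sequence(get_condition("V"))
        ecc = [seq.element_at(-n).eccentricity for n in range(0, 19)]
        assert ecc[0] == 0.0
        assert np.all(np.diff(ecc) > 0)
        assert ecc[1] == pytest.approx(FLANK_SPACING_ARCMIN)

    def test_printed_separations(self):
        # frames 8 and 12 are 13.3' apart; center to frame 8 is 26.7'
        seq = build_sequence(get_condition("V-AV8-PV12"))
        e8 = seq.element_at(-8).eccentricity
        e12 = seq.element_at(-12).eccentricity
        assert e12 - e8 == pytest.approx(13.3, abs=0.05)
        assert e8 == pytest.approx(26.7, abs=0.05)

    def test_converging_variant_reverses_after_frame_10(self):
        seq = build_sequence(get_condition("C1"), Geometry.constant())
        ecc = [seq.element_at(-n).eccentricity for n in range(1, 21)]
        assert np.all(np.diff(ecc[:10]) > 0)
        assert np.all(np.diff(ecc[10:]) < 0)

    def test_growing_lengths(self):
        seq = build_sequence(get_condition("V"), Geometry.growing())
        assert seq.element_at(-1).length == pytest.approx(11.7)
        assert seq.element_at(-2).length == pytest.approx(13.4)
        assert seq.element_at(0).length == pytest.approx(10.0)

    def test_constant_lengths(self):
        seq = build_sequence(get_condition("PV8-AV12"), Geometry.constant())
        assert {seq.element_at(-n).length for n in range(1, 19)} == {20.0}

    def test_offset_frame_beyond_n_pairs_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ConditionSpec(name="bad", offsets={25: 1}, n_pairs=18)

    def test_mirror_symmetry_of_streams(self):
        spec = get_condition("V-AV8")
        left = build_sequence(spec)
        import dataclasses

        right = build_sequence(dataclasses.replace(spec, attended_stream=Stream.RIGHT))
        for n in range(1, 19):
            el, er = left.element_at(-n), right.element_at(n)
            assert el.onset == er.onset
            assert el.offset_sign == er.offset_sign
            assert el.eccentricity == er.eccentricity


class TestElementSignal:
    def test_central_vernier_signal(self):
        seq = build_sequence(get_condition("V"))
        sig = element_signal(seq, 0)
        assert sig(0) == 1.0 and sig(19.9) == 1.0
        assert sig(20) == 0.0 and sig(-1) == 0.0

    def test_aligned_flank_signal_is_zero(self):
        seq = build_sequence(get_condition("V"))
        sig = element_signal(seq, -3)
        assert sig.abs_area_ms() == 0.0

    def test_anti_vernier_frame8_signal(self):
        seq = build_sequence(get_condition("V-AV8"))
        sig = element_signal(seq, -8)
        assert sig(330) == -1.0 and sig(349.9) == -1.0
        assert sig(329.9) == 0.0 and sig(350) == 0.0

    def test_unknown_location_rejected(self):
        seq = build_sequence(get_condition("V"))
        with pytest.raises(KeyError):
            element_signal(seq, 99)

    def test_signal_conservation(self):
        # total |signal| area = 20 ms per offset element
        for name, n_offsets in [("V", 1), ("V-AV8-PV12", 3), ("C5", 6)]:
            spec = get_condition(name)
            seq = build_sequence(spec, Geometry.constant())
            area = sum(
                element_signal(seq, loc).abs_area_ms()
                for loc in seq.attended_location_ids
            )
            assert area == pytest.approx(20.0 * n_offsets)

    def test_all_aligned_condition_has_zero_signals(self):
        spec = ConditionSpec(name="blank", offsets={}, n_pairs=18)
        seq = build_sequence(spec)
        assert all(
            element_signal(seq, loc).abs_area_ms() == 0.0
            for loc in seq.attended_location_ids
        )


class TestConditionLibrary:
    def test_three_offset_condition(self):
        spec = get_condition("V-AV8-PV12")
        assert dict(spec.offsets) == {0: 1, 8: -1, 12: 1}

    def test_single_vernier_condition(self):
        assert dict(get_condition("V").offsets) == {0: 1}

    def test_all_results_conditions_present(self):
        lib = condition_library()
        expected = (
            ["V", "AV", "V-AV8", "V-AV12", "V-AV8-PV12",
             "PV8-PV12", "PV8-AV12", "PV1-AV5"]
            + [f"V-AV{n}" for n in (1, 2, 3, 5, 7, 11, 14)]
            + [f"V-PV{n}" for n in (1, 2, 3, 5, 7, 11, 14)]
            + [f"C{k}" for k in range(1, 6)]
        )
        assert set(expected) <= set(lib)

    def test_extended_conditions_use_converging_variant(self):
        for k in range(1, 6):
            spec = get_condition(f"C{k}")
            assert spec.variant is Variant.DIVERGING_THEN_CONVERGING
            assert spec.n_pairs == 20

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError, match="unknown condition"):
            get_condition("V-XY99")

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "conditions.yaml"
        library_to_yaml(path)
        restored = library_from_yaml(path)
        lib = condition_library()
        assert set(restored) == set(lib)
        for name in lib:
            assert dict(restored[name].offsets) == dict(lib[name].offsets)
            assert restored[name].n_pairs == lib[name].n_pairs
            assert restored[name].reference is lib[name].reference


class TestReferenceSign:
    def test_central_reference(self):
        assert get_condition("V-AV12").reference_sign() == 1

    def test_central_fallback_without_central_offset(self):
        # flank-only conditions express dominance against the pro direction
        assert get_condition("AV").reference_sign(Reference.CENTRAL) == 1

    def test_first_and_second_vernier(self):
        spec = get_condition("PV8-AV12")
        assert spec.reference_sign(Reference.FIRST) == 1
        assert spec.reference_sign(Reference.SECOND) == -1


def test_sequence_table_schema():
    seq = build_sequence(get_condition("V-AV8"))
    df = sequence_to_table(seq)
    assert list(df.columns) == [
        "location_id", "onset_ms", "duration_ms",
        "eccentricity_arcmin", "length_arcmin", "offset_sign",
    ]
    assert len(df) == 37
    assert df.loc[df.location_id == -8, "offset_sign"].item() == -1
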