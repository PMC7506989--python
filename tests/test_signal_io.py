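"""Readers, hypnogram dialects and stage-label schemes."""

import numpy as np
import pytest

import imbef
from imbef.signal_io import AASM, EXCLUDED, RK, Hypnogram, LabelScheme


class TestLoadRecording:
    def test_reads_synthetic_edf_fixture(self, fixture_edf):
        em, edf_path, _ = fixture_edf
        rec = imbef.load_recording(edf_path, "EEG synth")
        assert rec.fs == 128.0
        assert rec.n_samples == em.n_epochs * em.samples_per_epoch

    def test_signal_recovered_within_quantization(self, fixture_edf):
        from imbef._edf import quantization_step

        em, edf_path, _ = fixture_edf
        rec = imbef.load_recording(edf_path, "EEG synth")
        flat = em.epochs.reshape(-1)
        assert np.max(np.abs(rec.samples - flat)) <= quantization_step(flat)

    def test_channel_matching_ignores_case_and_space(self, fixture_edf):
        _, edf_path, _ = fixture_edf
        rec = imbef.load_recording(edf_path, "  eeg SYNTH ")
        assert rec.channel == "EEG synth"

    def test_missing_channel_lists_available(self, fixture_edf):
        _, edf_path, _ = fixture_edf
        with pytest.raises(ValueError, match="EEG synth"):
            imbef.load_recording(edf_path, "EEG Cz-A1")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            imbef.load_recording(tmp_path / "nope.edf", "x")


class TestHypnogramDialects:
    def test_dreams_tokens_one_label_per_line(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("W\nW\nR\n1\n2\n3\n")
        hyp = imbef.load_hypnogram(p, "dreams_txt", epoch_seconds=20)
        assert hyp.labels == ("Awa", "Awa", "REM", "S1", "S2", "S3")
        assert hyp.standard == RK

    def test_unknown_code_becomes_excluded(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("W\n9\nR\n")
        hyp = imbef.load_hypnogram(p, "dreams_txt", epoch_seconds=20)
        assert hyp.labels[1] == EXCLUDED

    def test_unrecognized_code_raises_with_position(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("W\nZZ\n")
        with pytest.raises(ValueError, match="'ZZ'.*:2"):
            imbef.load_hypnogram(p, "dreams_txt", epoch_seconds=20)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="zero labels"):
            imbef.load_hypnogram(p, "dreams_txt", epoch_seconds=20)

    def test_isruc_numeric_codes_are_aasm(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("0\n5\n1\n2\n3\n")
        hyp = imbef.load_hypnogram(p, "isruc_txt", epoch_seconds=30)
        assert hyp.labels == ("Awa", "REM", "N1", "N2", "N3")
        assert hyp.standard == AASM

    @pytest.mark.parametrize("dialect,standard,labels", [
        ("dreams_txt", RK, ("Awa", "REM", "S1", "S2", "S3", "S4", EXCLUDED)),
        ("dreams_txt", AASM, ("Awa", "REM", "N1", "N2", "N3", EXCLUDED)),
        ("isruc_txt", AASM, ("Awa", "REM", "N1", "N2", "N3", EXCLUDED)),
        ("edfplus", RK, ("Awa", "REM", "S1", "S2", "S3", "S4", EXCLUDED)),
        ("edfplus", AASM, ("Awa", "N1", "N2", "N3", "REM")),
    ])
    def test_round_trip_each_dialect(self, tmp_path, dialect, standard, labels):
        hyp = Hypnogram(labels, 30.0, standard)
        path = tmp_path / ("h.edf" if dialect == "edfplus" else "h.txt")
        imbef.save_hypnogram(hyp, path, dialect)
        back = imbef.load_hypnogram(path, dialect, epoch_seconds=30,
                                    standard=standard)
        assert back.labels == labels

    def test_edfplus_30s_stage_events(self, tmp_path):
        hyp = Hypnogram(("Awa", "Awa", "REM"), 30.0, RK)
        path = tmp_path / "h.edf"
        imbef.save_hypnogram(hyp, path, "edfplus")
        back = imbef.load_hypnogram(path, "edfplus", epoch_seconds=30)
        assert back.labels == ("Awa", "Awa", "REM")


class TestLabelSchemes:
    def test_rk_four_class_merges_light_and_deep(self):
        scheme = LabelScheme.rk(4)
        hyp = Hypnogram(("Awa", "REM", "S1", "S2", "S3", "S4"), 30.0, RK)
        classes, keep = imbef.map_labels(hyp, scheme)
        assert classes.tolist() == [0, 1, 2, 2, 3, 3]
        assert keep.all()

    def test_aasm_two_class_wake_vs_asleep(self):
        scheme = LabelScheme.aasm(2)
        hyp = Hypnogram(("Awa", "REM", "N1", "N2", "N3"), 30.0, AASM)
        classes, _ = imbef.map_labels(hyp, scheme)
        assert classes.tolist() == [0, 1, 1, 1, 1]

    def test_excluded_epochs_masked_not_merged(self):
        scheme = LabelScheme.rk(6)
        hyp = Hypnogram(("Awa", EXCLUDED, "REM"), 30.0, RK)
        classes, keep = imbef.map_labels(hyp, scheme)
        assert keep.tolist() == [True, False, True]
        assert classes.tolist() == [0, 1]
        assert int(keep.sum()) + int((~keep).sum()) == len(hyp)

    def test_standard_mismatch_raises(self):
        hyp = Hypnogram(("Awa", "N1"), 30.0, AASM)
        with pytest.raises(ValueError, match="AASM"):
            imbef.map_labels(hyp, LabelScheme.rk(6))

    @pytest.mark.parametrize("maker,n_classes,stages", [
        (LabelScheme.rk, n, ("Awa", "REM", "S1", "S2", "S3", "S4"))
        for n in (2, 3, 4, 5, 6)
    ] + [
        (LabelScheme.aasm, n, ("Awa", "REM", "N1", "N2", "N3"))
        for n in (2, 3, 4, 5)
    ])
    def test_image_is_contiguous_class_range(self, maker, n_classes, stages):
        scheme = maker(n_classes)
        hyp = Hypnogram(stages, 30.0, scheme.standard)
        classes, _ = imbef.map_labels(hyp, scheme)
        assert set(classes.tolist()) == set(range(n_classes))
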