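"""mzML and CSV round-trips through the I/O layer."""
import gzip

import pytest

from umrm import msio
from umrm.records import (
    NEGATIVE,
    POSITIVE,
    QUALIFIER,
    QUANTIFIER,
    SpectrumRecord,
    TransitionRow,
)


def _spectra_12():
    """4 MS1 survey scans + 8 MS2 scans with explicit collision energies."""
    spectra = []
    for i in range(4):
        spectra.append(
            SpectrumRecord(
                scan_id=f"scan={2*i+1}",
                ms_level=1,
                rt_min=1.0 + i,
                polarity=POSITIVE,
                peaks=[(200.0 + i, 5000.0), (300.0 + i, 800.0)],
            )
        )
        for j, ce in enumerate((0.0, 20.0)):
            spectra.append(
                SpectrumRecord(
                    scan_id=f"scan={2*i+1}_{j}",
                    ms_level=2,
                    rt_min=1.0 + i + 0.01 * (j + 1),
                    polarity=POSITIVE if i % 2 == 0 else NEGATIVE,
                    peaks=[(100.5, 300.0), (150.25, 900.0)],
                    precursor_mz=200.0 + i,
                    collision_energy_ev=ce,
                )
            )
    return spectra


class TestMzml:
    def test_empty_file_roundtrip(self, tmp_path):
        path = tmp_path / "empty.mzML"
        msio.write_mzml([], path)
        assert msio.read_mzml(path) == []

    def test_writer_reader_roundtrip(self, tmp_path):
        spectra = _spectra_12()
        path = tmp_path / "run.mzML"
        msio.write_mzml(spectra, path)
        back = msio.read_mzml(path)
        assert len(back) == 12
        assert sum(1 for s in back if s.ms_level == 2) == 8
        # MS1 count is preserved exactly (no silent drops)
        assert sum(1 for s in back if s.ms_level == 1) == 4
        for orig, rec in zip(spectra, back):
            assert rec.ms_level == orig.ms_level
            assert rec.polarity == orig.polarity
            assert rec.rt_min == pytest.approx(orig.rt_min, abs=1e-6)
            assert rec.peaks == pytest.approx(orig.peaks)
            if orig.ms_level == 2:
                assert rec.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)

    def test_collision_energy_passthrough(self, tmp_path):
        path = tmp_path / "ce.mzML"
        msio.write_mzml(_spectra_12(), path)
        ces = [s.collision_energy_ev for s in msio.read_mzml(path) if s.ms_level == 2]
        assert ces == [0.0, 20.0] * 4

    def test_gzip_reading(self, tmp_path):
        plain = tmp_path / "run.mzML"
        msio.write_mzml(_spectra_12(), plain)
        gz = tmp_path / "run.mzML.gz"
        gz.write_bytes(gzip.compress(plain.read_bytes()))
        assert len(msio.read_mzml(gz)) == 12

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(IOError):
            msio.read_mzml(tmp_path / "nope.mzML")

    def test_ce_cycle_fills_missing_energies(self, tmp_path):
        spectra = _spectra_12()
        for s in spectra:
            s.collision_energy_ev = None
        path = tmp_path / "nocycle.mzML"
        msio.write_mzml(spectra, path)
        back = msio.read_mzml(path, ce_cycle=[0.0, 10.0, 20.0, 40.0])
        ces = [s.collision_energy_ev for s in back if s.ms_level == 2]
        assert ces == [0.0, 10.0, 20.0, 40.0, 0.0, 10.0, 20.0, 40.0]


class TestFeatureTable:
    def test_header_only(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("mz,rt,intensity,polarity\n")
        assert msio.read_feature_table(p) == []

    def test_invalid_rows_rejected_with_diagnostics(self, tmp_path, caplog):
        p = tmp_path / "f.csv"
        p.write_text(
            "mz,rt,intensity,polarity\n"
            "180.1,2.0,0,positive\n"      # zero intensity -> rejected
            "181.2,2.1,500,positive\n"
        )
        with caplog.at_level("WARNING"):
            feats = msio.read_feature_table(p)
        assert len(feats) == 1
        assert feats[0].mz == pytest.approx(181.2)
        assert any("rejected" in r.message for r in caplog.records)

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text(
            "mz,rt,intensity,polarity\n"
            "300.1,3.0,100,positive\n"
            "100.2,1.0,200,negative\n"
            "200.3,2.0,300,positive\n"
        )
        feats = msio.read_feature_table(p)
        assert [f.mz for f in feats] == pytest.approx([300.1, 100.2, 200.3])

    def test_missing_column_is_fatal(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("mz,rt,intensity\n100.0,1.0,50\n")
        with pytest.raises(msio.SchemaError):
            msio.read_feature_table(p)

    def test_column_mapping(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("MZ_obs,RT_obs,Height,Mode\n150.5,4.2,999,positive\n")
        feats = msio.read_feature_table(
            p, columns={"mz": "MZ_obs", "rt": "RT_obs", "intensity": "Height", "polarity": "Mode"}
        )
        assert len(feats) == 1 and feats[0].intensity == 999


def _row(label="cmpd1", frag=184.0733, role=QUANTIFIER, ce=22.5):
    return TransitionRow(
        compound_label=label,
        precursor_mz=760.5851,
        fragment_mz=frag,
        polarity=POSITIVE,
        collision_energy_ev=ce,
        rt_min=6.54,
        rt_window_min=0.3,
        role=role,
    )


class TestTransitionCsv:
    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "t.csv"
        msio.write_transition_csv([], p)
        assert p.read_text().strip() == ",".join(msio.TRANSITION_COLUMNS)
        assert msio.read_transition_csv(p) == []

    def test_roundtrip_single_row(self, tmp_path):
        p = tmp_path / "t.csv"
        row = _row()
        msio.write_transition_csv([row], p)
        (back,) = msio.read_transition_csv(p)
        assert back.precursor_mz == pytest.approx(row.precursor_mz, abs=5e-5)
        assert back.fragment_mz == pytest.approx(row.fragment_mz, abs=5e-5)
        assert back.collision_energy_ev == pytest.approx(row.collision_energy_ev, abs=5e-2)
        assert back.rt_min == pytest.approx(row.rt_min, abs=5e-3)
        assert back.role == QUANTIFIER

    def test_invariant_violation_is_fatal(self, tmp_path):
        bad_ce = _row(ce=3.0)  # below the 5 eV floor
        with pytest.raises(msio.SchemaError):
            msio.write_transition_csv([bad_ce], tmp_path / "t.csv")
        two_quants = [_row(), _row(frag=150.0)]
        with pytest.raises(msio.SchemaError):
            msio.write_transition_csv(two_quants, tmp_path / "t.csv")

    def test_500_rows_compact_file(self, tmp_path):
        rows = []
        for i in range(250):
            rows.append(_row(label=f"c{i}"))
            rows.append(_row(label=f"c{i}", frag=150.0 + i * 0.1, role=QUALIFIER))
        p = tmp_path / "big.csv"
        msio.write_transition_csv(rows, p)
        assert p.stat().st_size < 200_000
        assert len(msio.read_transition_csv(p)) == 500
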