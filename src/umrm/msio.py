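"""File-format I/O: mzML reading/writing and the CSV tables.

All format knowledge lives here.  mzML is read with an accession-driven
:mod:`lxml` parser covering the parts of the standard that LC–MS/MS
workflows touch (centroid spectra, polarity, scan start time, selected
precursor m/z, collision energy; 32/64-bit float arrays, zlib or no
compression, plain or indexed documents, optionally gzipped).  A minimal
standards-conformant mzML writer is provided for the synthetic fixture
generator.  The transition table is a fixed-column CSV designed to
round-trip losslessly at method-editor precision (4 decimals m/z, 2 RT,
1 CE).
"""
from __future__ import annotations

import base64
import csv
import gzip
import logging
import struct
import zlib
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from lxml import etree

from .records import (
    NEGATIVE,
    POSITIVE,
    FeatureRecord,
    SpectrumRecord,
    TransitionRow,
    validate_transition_rows,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

TRANSITION_COLUMNS = [
    "compound",
    "precursor_mz",
    "fragment_mz",
    "polarity",
    "ce_ev",
    "rt_min",
    "rt_window_min",
    "role",
    "peak_area",
]


class SchemaError(ValueError):
    """Raised when a table is missing mandatory columns or violates invariants."""


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

# cvParam accessions (PSI-MS / UO ontologies)
ACC_MS_LEVEL = "MS:1000511"
ACC_POSITIVE = "MS:1000130"
ACC_NEGATIVE = "MS:1000129"
ACC_SCAN_START = "MS:1000016"
ACC_SELECTED_MZ = "MS:1000744"
ACC_COLLISION_ENERGY = "MS:1000045"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"
ACC_FLOAT64 = "MS:1000523"
ACC_FLOAT32 = "MS:1000521"
ACC_ZLIB = "MS:1000574"
ACC_SECOND = "UO:0000010"


def _localname(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def _cv_params(el) -> dict[str, dict]:
    """All cvParams in a subtree, keyed by accession."""
    out: dict[str, dict] = {}
    for cv in el.iter():
        if _localname(cv) == "cvParam":
            out[cv.get("accession", "")] = dict(cv.attrib)
    return out


def _decode_binary_array(bda) -> Optional[tuple[str, np.ndarray]]:
    params = _cv_params(bda)
    kind = "mz" if ACC_MZ_ARRAY in params else (
        "intensity" if ACC_INTENSITY_ARRAY in params else None
    )
    if kind is None:
        return None
    binary = None
    for child in bda.iter():
        if _localname(child) == "binary":
            binary = child.text or ""
            break
    if binary is None:
        return None
    raw = base64.b64decode(binary)
    if ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if ACC_FLOAT32 in params else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(el, index: int) -> Optional[SpectrumRecord]:
    params = _cv_params(el)
    ms_level = int(float(params.get(ACC_MS_LEVEL, {}).get("value", 1)))
    polarity = NEGATIVE if ACC_NEGATIVE in params else POSITIVE
    rt = 0.0
    if ACC_SCAN_START in params:
        p = params[ACC_SCAN_START]
        rt = float(p.get("value", 0.0))
        unit = p.get("unitAccession", "") or p.get("unitName", "")
        if unit in (ACC_SECOND, "second"):
            rt /= 60.0
    arrays: dict[str, np.ndarray] = {}
    pmz: Optional[float] = None
    ce: Optional[float] = None
    for child in el.iter():
        name = _localname(child)
        if name == "binaryDataArray":
            decoded = _decode_binary_array(child)
            if decoded:
                arrays[decoded[0]] = decoded[1]
        elif name == "selectedIon":
            sp = _cv_params(child)
            if ACC_SELECTED_MZ in sp:
                pmz = float(sp[ACC_SELECTED_MZ]["value"])
        elif name == "activation":
            ap = _cv_params(child)
            if ACC_COLLISION_ENERGY in ap:
                ce = float(ap[ACC_COLLISION_ENERGY]["value"])
    mzs = arrays.get("mz", np.empty(0))
    intens = arrays.get("intensity", np.empty(0))
    n = min(len(mzs), len(intens))
    rec = SpectrumRecord(
        scan_id=str(el.get("id", f"index={index}")),
        ms_level=ms_level,
        rt_min=rt,
        polarity=polarity,
        peaks=list(zip(mzs[:n].tolist(), intens[:n].tolist())),
    )
    rec.precursor_mz = pmz
    rec.collision_energy_ev = ce
    return rec


def read_mzml(path: PathLike, ce_cycle: Optional[list[float]] = None) -> list[SpectrumRecord]:
    """Read an mzML run (optionally gzip-compressed) into SpectrumRecords.

    Spectra are returned in acquisition order.  MS2 spectra lacking a
    precursor m/z are skipped with a warning.  ``ce_cycle``, if given,
    assigns collision energies to MS2 scans lacking one by MS2 scan index
    modulo the cycle length (stepped-energy acquisitions that do not
    encode CE per scan).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mzML file not found: {path}")
    records: list[SpectrumRecord] = []
    ms2_index = 0
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        for _, el in etree.iterparse(fh, events=("end",), tag="{*}spectrum"):
            rec = _parse_spectrum(el, len(records))
            el.clear()
            while el.getprevious() is not None:
                del el.getparent()[0]
            if rec is None:
                continue
            if rec.ms_level >= 2:
                if rec.precursor_mz is None:
                    log.warning(
                        "MS2 spectrum %s lacks a precursor m/z; skipped", rec.scan_id
                    )
                    continue
                if rec.collision_energy_ev is None and ce_cycle:
                    rec.collision_energy_ev = ce_cycle[ms2_index % len(ce_cycle)]
                ms2_index += 1
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# mzML writing (minimal, for synthetic runs)
# ---------------------------------------------------------------------------

def _binary_block(values: list[float], kind: str) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    enc = base64.b64encode(raw).decode("ascii")
    if kind == "mz":
        name_cv = '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
    else:
        name_cv = '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
    return (
        f'<binaryDataArray encodedLength="{len(enc)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
        f"{name_cv}<binary>{enc}</binary></binaryDataArray>"
    )


def write_mzml(spectra: list[SpectrumRecord], path: PathLike) -> None:
    """Write centroid spectra as minimal mzML readable by standard parsers.

    Supports exactly what the synthetic fixture generator needs: MS1 and
    MS2 centroid spectra with polarity, scan start time in minutes, and,
    for MS2, the selected precursor m/z and collision energy.
    """
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>'
        "</cvList>"
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>'
        "</fileContent></fileDescription>"
        '<softwareList count="1"><software id="umrm" version="0.1.0">'
        '<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="umrm"/>'
        "</software></softwareList>"
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1">'
        '<cvParam cvRef="MS" accession="MS:1000031" name="instrument model"/>'
        "</instrumentConfiguration></instrumentConfigurationList>"
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="umrm">'
        '<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML"/>'
        "</processingMethod></dataProcessing></dataProcessingList>"
        '<run id="synthetic_run" defaultInstrumentConfigurationRef="IC1">'
        f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="DP1">'
    )
    for i, sp in enumerate(spectra):
        mzs = [p[0] for p in sp.peaks]
        intens = [p[1] for p in sp.peaks]
        pol_cv = (
            '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan"/>'
            if sp.polarity == POSITIVE
            else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan"/>'
        )
        level_cv = (
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
            if sp.ms_level == 1
            else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>'
        )
        s = [
            f'<spectrum index="{i}" id="{sp.scan_id}" defaultArrayLength="{len(mzs)}">',
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{sp.ms_level}"/>',
            level_cv,
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>',
            pol_cv,
            '<scanList count="1"><scan>',
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{sp.rt_min:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>',
            "</scan></scanList>",
        ]
        if sp.ms_level >= 2 and sp.precursor_mz is not None:
            act = ""
            if sp.collision_energy_ev is not None:
                act = (
                    f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
                    f'value="{sp.collision_energy_ev:g}" unitCvRef="UO" unitAccession="UO:0000266" unitName="electronvolt"/>'
                )
            s.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{sp.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
                "</selectedIon></selectedIonList>"
                "<activation>"
                '<cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation"/>'
                f"{act}</activation></precursor></precursorList>"
            )
        s.append('<binaryDataArrayList count="2">')
        s.append(_binary_block(mzs, "mz"))
        s.append(_binary_block(intens, "intensity"))
        s.append("</binaryDataArrayList></spectrum>")
        parts.append("".join(s))
    parts.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_COLUMNS = {
    "feature_id": "feature_id",
    "mz": "mz",
    "rt": "rt",
    "intensity": "intensity",
    "polarity": "polarity",
    "charge": "charge",
}


def read_feature_table(
    path: PathLike, columns: Optional[dict[str, str]] = None
) -> list[FeatureRecord]:
    """Read an MS1 feature table CSV into FeatureRecords.

    ``columns`` maps canonical names (mz, rt, intensity, polarity, and
    optionally feature_id, charge) to the file's column headers; vendor
    exports vary.  Rows violating invariants (non-positive m/z or
    intensity, negative RT, unknown polarity) are rejected with
    row-numbered diagnostics in the log.
    """
    colmap = dict(DEFAULT_FEATURE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    mandatory = ["mz", "rt", "intensity", "polarity"]
    missing = [colmap[c] for c in mandatory if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"feature table {path} missing mandatory column(s): {missing}")
    records: list[FeatureRecord] = []
    for i, row in df.iterrows():
        fid = (
            str(row[colmap["feature_id"]])
            if colmap["feature_id"] in df.columns
            else f"F{i:05d}"
        )
        charge = None
        if colmap["charge"] in df.columns and pd.notna(row[colmap["charge"]]):
            charge = int(row[colmap["charge"]])
        rec = FeatureRecord(
            feature_id=fid,
            mz=float(row[colmap["mz"]]),
            rt_min=float(row[colmap["rt"]]),
            intensity=float(row[colmap["intensity"]]),
            polarity=str(row[colmap["polarity"]]).strip().lower(),
            charge=charge,
        )
        problems = rec.validate()
        if problems:
            log.warning("feature table row %d rejected: %s", i + 2, "; ".join(problems))
            continue
        records.append(rec)
    return records


def write_feature_table(features: list[FeatureRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["feature_id", "mz", "rt", "intensity", "polarity", "charge"])
        for f in features:
            w.writerow(
                [
                    f.feature_id,
                    f"{f.mz:.6f}",
                    f"{f.rt_min:.4f}",
                    f"{f.intensity:.2f}",
                    f.polarity,
                    "" if f.charge is None else f.charge,
                ]
            )


# ---------------------------------------------------------------------------
# Transition tables
# ---------------------------------------------------------------------------

def write_transition_csv(rows: list[TransitionRow], path: PathLike) -> None:
    """Write the transition table with fixed columns and precision.

    m/z at 4 decimals, RT at 2, CE at 1 — method-editor precision; the
    read-back round-trips within half an ulp of each printed field.
    Invariant violations abort before anything is written.
    """
    problems = validate_transition_rows(rows)
    if problems:
        raise SchemaError(
            "transition table validation failed:\n  " + "\n  ".join(problems)
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRANSITION_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.compound_label,
                    f"{r.precursor_mz:.4f}",
                    f"{r.fragment_mz:.4f}",
                    r.polarity,
                    f"{r.collision_energy_ev:.1f}",
                    f"{r.rt_min:.2f}",
                    f"{r.rt_window_min:.2f}",
                    r.role,
                    "" if r.peak_area is None else f"{r.peak_area:.1f}",
                ]
            )


def read_transition_csv(path: PathLike) -> list[TransitionRow]:
    """Read a transition table written by :func:`write_transition_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns and c != "peak_area"]
    if missing:
        raise SchemaError(f"transition table {path} missing column(s): {missing}")
    rows: list[TransitionRow] = []
    for _, r in df.iterrows():
        area = None
        if "peak_area" in df.columns and pd.notna(r["peak_area"]):
            area = float(r["peak_area"])
        rows.append(
            TransitionRow(
                compound_label=str(r["compound"]),
                precursor_mz=float(r["precursor_mz"]),
                fragment_mz=float(r["fragment_mz"]),
                polarity=str(r["polarity"]),
                collision_energy_ev=float(r["ce_ev"]),
                rt_min=float(r["rt_min"]),
                rt_window_min=float(r["rt_window_min"]),
                role=str(r["role"]),
                peak_area=area,
            )
        )
    return rows


DYNAMIC_MRM_COLUMNS = [
    "compound",
    "precursor_mz",
    "fragment_mz",
    "polarity",
    "ce_ev",
    "rt_min",
    "rt_start_min",
    "rt_stop_min",
    "role",
]


def write_dynamic_mrm_csv(rows: list[TransitionRow], path: PathLike) -> None:
    """Vendor-neutral dynamic-MRM export with explicit start/stop RT columns.

    Start/stop are derived from the scheduled RT +/- the window half-width
    (start clamped at 0); otherwise identical content and precision to
    :func:`write_transition_csv`.
    """
    problems = validate_transition_rows(rows)
    if problems:
        raise SchemaError(
            "transition table validation failed:\n  " + "\n  ".join(problems)
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DYNAMIC_MRM_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.compound_label,
                    f"{r.precursor_mz:.4f}",
                    f"{r.fragment_mz:.4f}",
                    r.polarity,
                    f"{r.collision_energy_ev:.1f}",
                    f"{r.rt_min:.2f}",
                    f"{max(r.rt_min - r.rt_window_min, 0.0):.2f}",
                    f"{r.rt_min + r.rt_window_min:.2f}",
                    r.role,
                ]
            )
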