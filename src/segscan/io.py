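"""Format adapters: delimited-text spectra, a minimal mzML writer/reader,
waveform export and feature tables.

Tab-delimited text is the canonical interchange format; mzML support is an
adapter for interoperability with external viewers.  The mzML writer emits a
minimal but standards-shaped document (64-bit, uncompressed, base64 binary
arrays with the usual CV accessions); the reader handles the common spectrum
encodings (32/64-bit floats, optional zlib) via the PSI cvParam accessions.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
from pathlib import Path

import zlib

import numpy as np

from .segments import Spectrum
from .swift import SwiftWaveform

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_waveform",
    "read_waveform",
]

_META_PREFIX = "#meta "


class SpectrumParseError(ValueError):
    """Malformed spectrum file; message carries line context."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "mzml" if path.suffix.lower() == ".mzml" else "tsv"


def write_spectrum(s: Spectrum, path: str | Path, fmt: str | None = None) -> None:
    """Write a spectrum as two-column TSV (m/z, intensity) or minimal mzML.

    TSV carries acquisition metadata on a ``#meta`` JSON header line.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(_META_PREFIX + json.dumps(_jsonable(s.metadata)) + "\n")
            fh.write("mz\tintensity\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f}\t{i:.6f}\n")
    elif fmt == "mzml":
        _write_mzml(s, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


def read_spectrum(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum` (TSV or mzML)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


def _read_tsv(path: Path) -> Spectrum:
    meta: dict = {}
    mzs, ints = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(_META_PREFIX):
                meta = json.loads(line[len(_META_PREFIX):])
                continue
            if line.startswith("#") or line.startswith("mz\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two tab-separated columns, "
                    f"got {len(parts)}: {line!r}"
                )
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from exc
    return Spectrum(np.asarray(mzs), np.asarray(ints), meta)


# ---------------------------------------------------------------------------
# minimal mzML

_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def _cv(parent, accession, name, value=""):
    ET.SubElement(
        parent,
        "cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=str(value),
    )


def _write_mzml(s: Spectrum, path: Path) -> None:
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    cv_list = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cv_list, "cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, "run", id="segscan_run")
    slist = ET.SubElement(run, "spectrumList", count="1", defaultDataProcessingRef="dp")
    spec = ET.SubElement(
        slist, "spectrum", index="0", id="scan=1",
        defaultArrayLength=str(len(s)),
    )
    _cv(spec, "MS:1000511", "ms level", 1)
    _cv(spec, "MS:1000128", "profile spectrum")
    if s.metadata.get("polarity") == "positive":
        _cv(spec, "MS:1000130", "positive scan")
    else:
        _cv(spec, "MS:1000129", "negative scan")
    bal = ET.SubElement(spec, "binaryDataArrayList", count="2")
    for accession, name, values in (
        ("MS:1000514", "m/z array", s.mz),
        ("MS:1000515", "intensity array", s.intensity),
    ):
        encoded = _encode_array(values)
        arr = ET.SubElement(bal, "binaryDataArray", encodedLength=str(len(encoded)))
        _cv(arr, "MS:1000523", "64-bit float")
        _cv(arr, "MS:1000576", "no compression")
        _cv(arr, accession, name)
        ET.SubElement(arr, "binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _decode_binary(arr_elem) -> np.ndarray:
    accs = {cv.get("accession") for cv in arr_elem.iter(f"{{{_NS}}}cvParam")}
    binary = arr_elem.find(f"{{{_NS}}}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> Spectrum:
    """Read the first spectrum of an mzML file.

    Covers the common encodings (32/64-bit floats, optional zlib, base64) by
    parsing the PSI cvParam accessions directly with ElementTree.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc
    spec = root.find(f".//{{{_NS}}}spectrum")
    if spec is None:
        raise SpectrumParseError(f"{path}: no spectrum element found")
    accs = {cv.get("accession") for cv in spec.findall(f"{{{_NS}}}cvParam")}
    mz = intensity = None
    for arr in spec.iter(f"{{{_NS}}}binaryDataArray"):
        arr_accs = {cv.get("accession")
                    for cv in arr.findall(f"{{{_NS}}}cvParam")}
        if "MS:1000514" in arr_accs:
            mz = _decode_binary(arr)
        elif "MS:1000515" in arr_accs:
            intensity = _decode_binary(arr)
    if mz is None or intensity is None:
        raise SpectrumParseError(f"{path}: missing m/z or intensity array")
    meta = {
        "polarity": "positive" if "MS:1000130" in accs else "negative",
        "scan_mode": "full",
    }
    return Spectrum(mz, intensity, meta)


# ---------------------------------------------------------------------------
# waveforms


def write_waveform(w: SwiftWaveform, path: str | Path) -> None:
    """Export a SWIFT waveform: two-column TSV (time s, amplitude) plus a
    JSON design sidecar (``<path>.json``) holding notch band and sample rate."""
    path = Path(path)
    t = np.arange(len(w.samples)) / w.sample_rate
    with open(path, "w") as fh:
        fh.write("time_s\tamplitude\n")
        for ti, ai in zip(t, w.samples):
            fh.write(f"{ti:.9e}\t{ai:.9e}\n")
    sidecar = {
        "sample_rate_hz": w.sample_rate,
        "notch_low_hz": w.notch_low,
        "notch_high_hz": w.notch_high,
        "passband_low_hz": w.passband_low,
        "passband_high_hz": w.passband_high,
        "n_samples": len(w.samples),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_waveform(path: str | Path) -> SwiftWaveform:
    """Read a waveform exported by :func:`write_waveform`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        side = json.load(fh)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return SwiftWaveform(
        samples=data[:, 1],
        sample_rate=side["sample_rate_hz"],
        notch_low=side["notch_low_hz"],
        notch_high=side["notch_high_hz"],
        passband_low=side["passband_low_hz"],
        passband_high=side["passband_high_hz"],
    )
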