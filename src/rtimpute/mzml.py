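"""Minimal mzML 1.1 reading and writing.

Both directions are implemented directly on the XML (via lxml): the reader
streams ``<spectrum>`` elements and keeps, for each spectrum, the scan start
time (converted to minutes), MS level, precursor isolation window, and the
peak arrays; the writer emits a small but standards-conformant plain mzML
document (64-bit float arrays; no compression on write, zlib accepted on
read). The subset of controlled-vocabulary terms handled covers what DIA
quantitation needs — scan times, isolation windows, m/z and intensity
arrays — not the full PSI vocabulary.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

from .chrom import Chromatogram, Spectrum, Transition, extract_xic
from .errors import FormatError

__all__ = ["read_spectra", "write_mzml", "MzMLRun"]

_NS = "http://psi.hupo.org/ms/mzml"

# accessions understood by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


def _cv_params(element) -> dict[str, tuple[str, str]]:
    """accession -> (value, unitName) over all nested cvParam elements."""
    out = {}
    for cv in element.iter(f"{{{_NS}}}cvParam"):
        out[cv.get("accession")] = (cv.get("value", ""), cv.get("unitName", ""))
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find(f"{{{_NS}}}binary")
    if binary is None or not (binary.text or "").strip():
        return np.array([])
    raw = base64.b64decode(binary.text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    if _ACC_32BIT in params:
        fmt, size = "f", 4
    else:  # 64-bit float is both our writer's choice and the common default
        fmt, size = "d", 8
    n = len(raw) // size
    return np.asarray(struct.unpack(f"<{n}{fmt}", raw[: n * size]), dtype=float)


def _parse_spectrum(el) -> Spectrum:
    params = _cv_params(el)
    if _ACC_SCAN_START not in params:
        raise FormatError("spectrum without a scan start time")
    value, unit = params[_ACC_SCAN_START]
    time_min = float(value) / 60.0 if unit == "second" else float(value)
    ms_level = int(params.get(_ACC_MS_LEVEL, ("1", ""))[0])

    iso_target = iso_lo = iso_hi = None
    iso = el.find(
        f"{{{_NS}}}precursorList/{{{_NS}}}precursor/{{{_NS}}}isolationWindow"
    )
    if iso is not None:
        iso_params = _cv_params(iso)
        if _ACC_ISO_TARGET in iso_params:
            iso_target = float(iso_params[_ACC_ISO_TARGET][0])
            if _ACC_ISO_LOWER in iso_params and _ACC_ISO_UPPER in iso_params:
                iso_lo = iso_target - float(iso_params[_ACC_ISO_LOWER][0])
                iso_hi = iso_target + float(iso_params[_ACC_ISO_UPPER][0])

    mz = np.array([])
    inten = np.array([])
    for bda in el.iter(f"{{{_NS}}}binaryDataArray"):
        params = _cv_params(bda)
        if _ACC_MZ_ARRAY in params:
            mz = _decode_binary_array(bda)
        elif _ACC_INT_ARRAY in params:
            inten = _decode_binary_array(bda)
    if mz.size != inten.size:
        raise FormatError("m/z and intensity arrays differ in length")
    order = np.argsort(mz, kind="stable")
    return Spectrum(
        time_min=time_min,
        ms_level=ms_level,
        mz=mz[order],
        intensity=inten[order],
        isolation_lower=iso_lo,
        isolation_upper=iso_hi,
        isolation_target=iso_target,
    )


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Load all spectra of an mzML file (plain or indexed) into memory."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mzML file: {path}")
    out: list[Spectrum] = []
    try:
        for _, el in etree.iterparse(str(path), tag=f"{{{_NS}}}spectrum"):
            out.append(_parse_spectrum(el))
            el.clear()
            while el.getprevious() is not None:
                del el.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not a well-formed mzML file: {path}: {exc}") from exc
    out.sort(key=lambda s: s.time_min)
    return out


class MzMLRun:
    """A spectrum source backed by an mzML file, loaded once into memory."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self.spectra = read_spectra(path)

    def xic(self, transition: Transition, ppm_tol: float) -> Chromatogram:
        return extract_xic(self.spectra, transition, ppm_tol)


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent,
        f"{{{_NS}}}cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=value,
        **attrs,
    )


def _binary_array(parent, values: np.ndarray, kind: str) -> None:
    data = base64.b64encode(
        struct.pack(f"<{values.size}d", *values.astype(float))
    ).decode("ascii")
    bda = etree.SubElement(
        parent, f"{{{_NS}}}binaryDataArray", encodedLength=str(len(data))
    )
    _cv(bda, _ACC_64BIT, "64-bit float")
    _cv(bda, _ACC_NOCOMP, "no compression")
    if kind == "mz":
        _cv(bda, _ACC_MZ_ARRAY, "m/z array", unitCvRef="MS",
            unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(bda, _ACC_INT_ARRAY, "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    etree.SubElement(bda, f"{{{_NS}}}binary").text = data


def write_mzml(spectra: Sequence[Spectrum], path: str | Path, run_id: str = "run") -> None:
    """Write spectra to a plain mzML 1.1 document."""
    nsmap = {None: _NS}
    root = etree.Element(f"{{{_NS}}}mzML", nsmap=nsmap, version="1.1.0")
    cvlist = etree.SubElement(root, f"{{{_NS}}}cvList", count="1")
    etree.SubElement(
        cvlist, f"{{{_NS}}}cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = etree.SubElement(root, f"{{{_NS}}}fileDescription")
    fcontent = etree.SubElement(fdesc, f"{{{_NS}}}fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    softlist = etree.SubElement(root, f"{{{_NS}}}softwareList", count="1")
    soft = etree.SubElement(softlist, f"{{{_NS}}}software", id="rtimpute", version="0.1.0")
    _cv(soft, "MS:1000799", "custom unreleased software tool", value="rtimpute simulator")
    iclist = etree.SubElement(root, f"{{{_NS}}}instrumentConfigurationList", count="1")
    ic = etree.SubElement(iclist, f"{{{_NS}}}instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dplist = etree.SubElement(root, f"{{{_NS}}}dataProcessingList", count="1")
    dp = etree.SubElement(dplist, f"{{{_NS}}}dataProcessing", id="DP1")
    pm = etree.SubElement(dp, f"{{{_NS}}}processingMethod", order="1", softwareRef="rtimpute")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run = etree.SubElement(
        root, f"{{{_NS}}}run", id=run_id, defaultInstrumentConfigurationRef="IC1"
    )
    slist = etree.SubElement(
        run, f"{{{_NS}}}spectrumList", count=str(len(spectra)),
        defaultDataProcessingRef="DP1",
    )
    for i, sp in enumerate(sorted(spectra, key=lambda s: s.time_min)):
        order = np.argsort(sp.mz, kind="stable")
        mz, inten = np.asarray(sp.mz)[order], np.asarray(sp.intensity)[order]
        el = etree.SubElement(
            slist, f"{{{_NS}}}spectrum", index=str(i),
            id=f"scan={i + 1}", defaultArrayLength=str(mz.size),
        )
        _cv(el, "MS:1000580", "MSn spectrum")
        _cv(el, _ACC_MS_LEVEL, "ms level", value=str(sp.ms_level))
        _cv(el, "MS:1000127", "centroid spectrum")
        scanlist = etree.SubElement(el, f"{{{_NS}}}scanList", count="1")
        _cv(scanlist, "MS:1000795", "no combination")
        scan = etree.SubElement(scanlist, f"{{{_NS}}}scan")
        _cv(scan, _ACC_SCAN_START, "scan start time", value=f"{sp.time_min:.8f}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if sp.ms_level >= 2 and sp.isolation_target is not None:
            plist = etree.SubElement(el, f"{{{_NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{_NS}}}precursor")
            iso = etree.SubElement(prec, f"{{{_NS}}}isolationWindow")
            _cv(iso, _ACC_ISO_TARGET, "isolation window target m/z",
                value=f"{sp.isolation_target:.4f}", unitCvRef="MS",
                unitAccession="MS:1000040", unitName="m/z")
            if sp.isolation_lower is not None and sp.isolation_upper is not None:
                _cv(iso, _ACC_ISO_LOWER, "isolation window lower offset",
                    value=f"{sp.isolation_target - sp.isolation_lower:.4f}",
                    unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
                _cv(iso, _ACC_ISO_UPPER, "isolation window upper offset",
                    value=f"{sp.isolation_upper - sp.isolation_target:.4f}",
                    unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            silist = etree.SubElement(prec, f"{{{_NS}}}selectedIonList", count="1")
            si = etree.SubElement(silist, f"{{{_NS}}}selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z",
                value=f"{sp.isolation_target:.4f}", unitCvRef="MS",
                unitAccession="MS:1000040", unitName="m/z")
            act = etree.SubElement(prec, f"{{{_NS}}}activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        bdal = etree.SubElement(
            el, f"{{{_NS}}}binaryDataArrayList", count="2"
        )
        _binary_array(bdal, mz, "mz")
        _binary_array(bdal, inten, "intensity")
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
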