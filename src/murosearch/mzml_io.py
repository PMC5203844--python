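"""Reading and writing centroided mzML 1.1 runs.

Both directions are handled by a small purpose-built (de)serialiser on lxml
covering the subset of mzML this package produces and consumes: centroided
MS1/MS2 spectra with retention time, precursor selected-ion m/z and charge,
HCD/ETD activation annotation, and 64-bit binary arrays (uncompressed or
zlib).  The files are standard mzML 1.1 and round-trip through independent
readers (e.g. Bioconductor's mzR), which the test suite uses as the oracle
for the writer.
"""

from __future__ import annotations

import base64
import zlib
from typing import Sequence

import numpy as np
from lxml import etree

from .identification import SpectrumRecord

__all__ = ["write_mzml", "read_mzml"]

_NS = "http://psi.hupo.org/ms/mzml"

_ACTIVATION_CV = {
    "HCD": ("MS:1000422", "beam-type collision-induced dissociation"),
    "ETD": ("MS:1000598", "electron transfer dissociation"),
}


def _cv(parent, accession, name, value="", unit=None):
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "MS")
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", str(value))
    if unit is not None:
        unit_acc, unit_name = unit
        el.set("unitCvRef", "UO")
        el.set("unitAccession", unit_acc)
        el.set("unitName", unit_name)
    return el


def _binary_array(parent, values: np.ndarray, kind: str) -> None:
    data = np.asarray(values, dtype="<f8").tobytes()
    encoded = base64.b64encode(data).decode("ascii")
    arr = etree.SubElement(parent, "binaryDataArray")
    arr.set("encodedLength", str(len(encoded)))
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(arr, "MS:1000514", "m/z array", unit=("MS:1000040", "m/z"))
    else:
        _cv(
            arr,
            "MS:1000515",
            "intensity array",
            unit=("MS:1000131", "number of detector counts"),
        )
    etree.SubElement(arr, "binary").text = encoded


def write_mzml(spectra: Sequence[SpectrumRecord], path) -> None:
    """Serialise spectra to an mzML 1.1 file (centroided, uncompressed f64)."""
    root = etree.Element("mzML", nsmap={None: _NS})
    root.set("version", "1.1.0")
    cv_list = etree.SubElement(root, "cvList")
    cv_list.set("count", "2")
    for cid, uri in (
        ("MS", "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"),
        ("UO", "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"),
    ):
        cv = etree.SubElement(cv_list, "cv")
        cv.set("id", cid)
        cv.set("fullName", cid)
        cv.set("URI", uri)
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")

    run = etree.SubElement(root, "run")
    run.set("id", "synthetic_run")
    spec_list = etree.SubElement(run, "spectrumList")
    spec_list.set("count", str(len(spectra)))
    spec_list.set("defaultDataProcessingRef", "dp")

    for index, spec in enumerate(spectra):
        el = etree.SubElement(spec_list, "spectrum")
        el.set("index", str(index))
        el.set("id", f"scan={spec.scan_id}")
        el.set("defaultArrayLength", str(spec.n_peaks))
        _cv(el, "MS:1000511", "ms level", spec.ms_level)
        _cv(
            el,
            "MS:1000579" if spec.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if spec.ms_level == 1 else "MSn spectrum",
        )
        _cv(el, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(el, "scanList")
        scan_list.set("count", "1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            repr(float(spec.retention_time)),
            unit=("UO:0000031", "minute"),
        )
        if spec.ms_level >= 2:
            plist = etree.SubElement(el, "precursorList")
            plist.set("count", "1")
            prec = etree.SubElement(plist, "precursor")
            ion_list = etree.SubElement(prec, "selectedIonList")
            ion_list.set("count", "1")
            ion = etree.SubElement(ion_list, "selectedIon")
            _cv(
                ion,
                "MS:1000744",
                "selected ion m/z",
                repr(float(spec.precursor_mz)),
                unit=("MS:1000040", "m/z"),
            )
            _cv(ion, "MS:1000041", "charge state", int(spec.precursor_charge))
            act = etree.SubElement(prec, "activation")
            acc, name = _ACTIVATION_CV[(spec.activation or "HCD").upper()]
            _cv(act, acc, name)
        arrays = etree.SubElement(el, "binaryDataArrayList")
        arrays.set("count", "2")
        _binary_array(arrays, spec.mz, "mz")
        _binary_array(arrays, spec.intensity, "intensity")

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _q(tag: str) -> str:
    return f"{{{_NS}}}{tag}"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("name"): cv.get("value", "")
        for cv in element.iter(_q("cvParam"))
    }


def _decode_arrays(spectrum_el) -> tuple[np.ndarray, np.ndarray]:
    mz = intensity = np.array([], dtype=float)
    for arr in spectrum_el.iter(_q("binaryDataArray")):
        params = _cv_params(arr)
        binary = arr.find(_q("binary"))
        raw = base64.b64decode(binary.text or "")
        if "zlib compression" in params:
            raw = zlib.decompress(raw)
        dtype = "<f4" if "32-bit float" in params else "<f8"
        values = np.frombuffer(raw, dtype=dtype).astype(float)
        if "m/z array" in params:
            mz = values
        elif "intensity array" in params:
            intensity = values
    return mz, intensity


def read_mzml(path) -> list[SpectrumRecord]:
    """Load an mzML run into SpectrumRecords (retention time in minutes)."""
    spectra = []
    for _, el in etree.iterparse(str(path), tag=_q("spectrum")):
        params = _cv_params(el)
        ms_level = int(params.get("ms level", 1))
        rt_min = 0.0
        for scan in el.iter(_q("scan")):
            for cv in scan.iter(_q("cvParam")):
                if cv.get("name") == "scan start time":
                    rt_min = float(cv.get("value"))
                    if "second" in (cv.get("unitName") or ""):
                        rt_min /= 60.0
        precursor_mz = None
        charge = None
        activation = None
        if ms_level >= 2:
            for ion in el.iter(_q("selectedIon")):
                ion_params = _cv_params(ion)
                if "selected ion m/z" in ion_params:
                    precursor_mz = float(ion_params["selected ion m/z"])
                if ion_params.get("charge state"):
                    charge = int(float(ion_params["charge state"]))
            for act in el.iter(_q("activation")):
                act_params = _cv_params(act)
                if "electron transfer dissociation" in act_params:
                    activation = "ETD"
                elif "beam-type collision-induced dissociation" in act_params:
                    activation = "HCD"
        mz, intensity = _decode_arrays(el)
        scan_id = el.get("id", str(el.get("index")))
        if "scan=" in scan_id:
            scan_id = scan_id.split("scan=")[-1]
        spectra.append(
            SpectrumRecord(
                scan_id=scan_id,
                retention_time=rt_min,
                ms_level=ms_level,
                mz=mz,
                intensity=intensity,
                precursor_mz=precursor_mz,
                precursor_charge=charge,
                activation=activation,
            )
        )
        el.clear(keep_tail=True)
    spectra.sort(key=lambda s: s.retention_time)
    return spectra
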