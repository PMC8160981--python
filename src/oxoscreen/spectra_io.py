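"""Uniform spectrum model and mzML/MGF readers and writers.

Spectra are assumed centroided (Orbitrap-style workflows); no centroiding
is performed. Duplicate m/z values within one spectrum are merged by
summing their intensities so downstream intensity ranking is deterministic.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = ["Spectrum", "read_spectra", "write_spectra"]

FRAGMENTATION_METHODS = ("HCD", "CID", "EThcD", "unknown")

_SCAN_RE = re.compile(r"scan=(\d+)")


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum.

    ``mz`` and ``intensity`` are parallel float arrays with ``mz`` strictly
    ascending (duplicates merged by intensity sum at construction).
    """

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    charge: Optional[int] = None
    method: str = "unknown"
    scan: Optional[int] = None

    @classmethod
    def from_peaks(
        cls,
        spectrum_id: str,
        mz: Sequence[float],
        intensity: Sequence[float],
        precursor_mz: Optional[float] = None,
        charge: Optional[int] = None,
        method: str = "unknown",
        scan: Optional[int] = None,
    ) -> "Spectrum":
        """Build a spectrum, sorting peaks and merging duplicate m/z."""
        mz_arr = np.asarray(mz, dtype=float)
        int_arr = np.asarray(intensity, dtype=float)
        if mz_arr.shape != int_arr.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if mz_arr.size:
            if np.any(mz_arr <= 0):
                raise ValueError("all m/z values must be positive")
            if np.any(int_arr < 0):
                raise ValueError("intensities must be non-negative")
            order = np.argsort(mz_arr, kind="stable")
            mz_arr, int_arr = mz_arr[order], int_arr[order]
            uniq, inverse = np.unique(mz_arr, return_inverse=True)
            if uniq.size != mz_arr.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, int_arr)
                mz_arr, int_arr = uniq, summed
        if method not in FRAGMENTATION_METHODS:
            method = "unknown"
        if scan is None:
            m = _SCAN_RE.search(spectrum_id)
            scan = int(m.group(1)) if m else None
        return cls(
            spectrum_id=spectrum_id,
            mz=mz_arr,
            intensity=int_arr,
            precursor_mz=precursor_mz,
            charge=charge,
            method=method,
            scan=scan,
        )

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def peaks_between(self, lo: float, hi: float) -> Tuple[np.ndarray, np.ndarray]:
        """Peaks with ``lo <= m/z <= hi`` (inclusive)."""
        i = np.searchsorted(self.mz, lo, side="left")
        j = np.searchsorted(self.mz, hi, side="right")
        return self.mz[i:j], self.intensity[i:j]


def _detect_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mgf":
        return "mgf"
    if ext == ".mzml":
        return "mzml"
    raise ValueError(f"cannot detect spectrum format from extension of {path!r}")


class _IdRegistry:
    """Deterministically deduplicates spectrum IDs within a file."""

    def __init__(self) -> None:
        self._seen: dict = {}

    def claim(self, sid: str) -> str:
        n = self._seen.get(sid, 0)
        self._seen[sid] = n + 1
        if n == 0:
            return sid
        logger.warning("duplicate spectrum ID %r; suffixing", sid)
        return f"{sid}__dup{n}"


def _method_from_mgf_params(params: dict) -> str:
    raw = str(params.get("fragmentation", "unknown")).strip()
    for m in FRAGMENTATION_METHODS:
        if raw.lower() == m.lower():
            return m
    return "unknown"


_MZML_ACTIVATION_MAP = (
    # (required keys subset, method); checked in order
    (("electron transfer dissociation", "supplemental beam-type collision-induced dissociation"), "EThcD"),
    (("electron transfer dissociation", "beam-type collision-induced dissociation"), "EThcD"),
    (("electron transfer dissociation",), "EThcD"),
    (("beam-type collision-induced dissociation",), "HCD"),
    (("collision-induced dissociation",), "CID"),
)


def _method_from_activation(activation: dict) -> str:
    keys = set(activation)
    for required, method in _MZML_ACTIVATION_MAP:
        if all(k in keys for k in required):
            return method
    return "unknown"


def _iter_mgf(path: str) -> Iterator[Spectrum]:
    registry = _IdRegistry()
    with _mgf.MGF(path, convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            sid = str(params.get("title") or f"index={i}")
            pepmass = params.get("pepmass")
            prec = float(pepmass[0]) if pepmass and pepmass[0] else None
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            yield Spectrum.from_peaks(
                registry.claim(sid),
                entry.get("m/z array", []),
                entry.get("intensity array", []),
                precursor_mz=prec,
                charge=charge,
                method=_method_from_mgf_params(params),
            )


# mzML is parsed directly with lxml: only the subset of the PSI schema the
# pipeline needs (spectrum id, ms level, centroid/profile flag, precursor
# selected ion, activation, and uncompressed/zlib 32- or 64-bit float peak
# arrays) is interpreted; cvParams are matched by name, namespace-agnostic.


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _cv_names(element) -> dict:
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("name", "")] = child.get("value", "")
    return out


def _decode_binary_array(bda) -> Optional[Tuple[str, np.ndarray]]:
    """Decode one <binaryDataArray>; returns (array name, values) or None."""
    params = _cv_names(bda)
    kind = None
    if "m/z array" in params:
        kind = "mz"
    elif "intensity array" in params:
        kind = "intensity"
    if kind is None:
        return None
    dtype = np.float64 if "64-bit float" in params else np.float32
    payload = b""
    for child in bda:
        if _local(child.tag) == "binary" and child.text:
            payload = base64.b64decode(child.text)
    if "zlib compression" in params:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(np.float64)


def _parse_mzml_spectrum(elem) -> Optional[dict]:
    params = _cv_names(elem)
    ms_level = int(params.get("ms level", 1) or 1)
    if ms_level < 2:
        return None
    info = {
        "id": elem.get("id", ""),
        "profile": "profile spectrum" in params,
        "mz": np.empty(0),
        "intensity": np.empty(0),
        "precursor_mz": None,
        "charge": None,
        "activation": {},
    }
    for node in elem.iter():
        name = _local(node.tag)
        if name == "selectedIon":
            ion = _cv_names(node)
            if "selected ion m/z" in ion:
                info["precursor_mz"] = float(ion["selected ion m/z"])
            if ion.get("charge state"):
                info["charge"] = int(float(ion["charge state"]))
        elif name == "activation":
            info["activation"] = _cv_names(node)
        elif name == "binaryDataArray":
            decoded = _decode_binary_array(node)
            if decoded is not None:
                info[decoded[0]] = decoded[1]
    return info


def _iter_mzml(path: str) -> Iterator[Spectrum]:
    registry = _IdRegistry()
    warned_profile = False
    for _, elem in etree.iterparse(path, events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        info = _parse_mzml_spectrum(elem)
        elem.clear()
        if info is None:
            continue
        if info["profile"] and not warned_profile:
            logger.warning("profile-mode spectra in %s; processed as-is", path)
            warned_profile = True
        yield Spectrum.from_peaks(
            registry.claim(info["id"]),
            info["mz"],
            info["intensity"],
            precursor_mz=info["precursor_mz"],
            charge=info["charge"],
            method=_method_from_activation(info["activation"]),
        )


def read_spectra(path: str, fmt: str = "auto") -> Iterator[Spectrum]:
    """Stream MS2+ spectra from an mzML or MGF file.

    Spectrum IDs come from the native ID (mzML) or TITLE, falling back to
    ``index=<n>`` (MGF); within one file duplicate IDs are suffixed
    deterministically. Peaks are sorted ascending in m/z.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "mgf":
        return _iter_mgf(path)
    if fmt == "mzml":
        return _iter_mzml(path)
    raise ValueError(f"unsupported spectrum format {fmt!r}")


def write_spectra(spectra: Iterable[Spectrum], path: str, fmt: str = "mgf") -> int:
    """Write spectra to MGF; returns the number of spectra written.

    TITLE carries the spectrum ID; PEPMASS, CHARGE and a FRAGMENTATION
    header are emitted when known.
    """
    if fmt != "mgf":
        raise ValueError("only MGF output is supported")
    count = 0
    entries = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.charge is not None:
            params["charge"] = f"{s.charge}+"
        if s.method != "unknown":
            params["fragmentation"] = s.method
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
        count += 1
    with open(path, "w") as fh:
        _mgf.write(entries, fh)
    return count
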