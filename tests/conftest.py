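"""Shared fixtures: tiny in-memory spectra and a minimal mzML writer."""

from __future__ import annotations

import base64
import struct

import numpy as np
import pytest

from oxoscreen import Spectrum


def _encode(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="1">
  <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
 </cvList>
 <run id="run1">
  <spectrumList count="{count}">
{spectra}
  </spectrumList>
 </run>
</mzML>
"""

_MZML_SPECTRUM = """   <spectrum index="{index}" id="{sid}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
{precursor}    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{lmz}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{bmz}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{lint}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{bint}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""

_MZML_PRECURSOR = """    <precursorList count="1">
     <precursor>
      <selectedIonList count="1">
       <selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{mz}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
        <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{charge}"/>
       </selectedIon>
      </selectedIonList>
      <activation>
{activation}      </activation>
     </precursor>
    </precursorList>
"""

_ACTIVATION_CV = {
    "HCD": '       <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>\n',
    "CID": '       <cvParam cvRef="MS" accession="MS:1000133" name="collision-induced dissociation" value=""/>\n',
    "EThcD": (
        '       <cvParam cvRef="MS" accession="MS:1000598" name="electron transfer dissociation" value=""/>\n'
        '       <cvParam cvRef="MS" accession="MS:1002631" name="supplemental beam-type collision-induced dissociation" value=""/>\n'
    ),
}


def write_mini_mzml(path, spectra):
    """Write a minimal but standards-shaped mzML file.

    ``spectra`` is a list of dicts with keys: id, ms_level, mz, intensity,
    and optionally precursor_mz, charge, method.
    """
    blocks = []
    for i, s in enumerate(spectra):
        bmz, bint = _encode(s["mz"]), _encode(s["intensity"])
        precursor = ""
        if s.get("ms_level", 2) >= 2 and s.get("precursor_mz") is not None:
            precursor = _MZML_PRECURSOR.format(
                mz=s["precursor_mz"],
                charge=s.get("charge", 2),
                activation=_ACTIVATION_CV.get(s.get("method", "HCD"), ""),
            )
        blocks.append(
            _MZML_SPECTRUM.format(
                index=i,
                sid=s["id"],
                n=len(s["mz"]),
                ms_level=s.get("ms_level", 2),
                precursor=precursor,
                bmz=bmz,
                bint=bint,
                lmz=len(bmz),
                lint=len(bint),
            )
        )
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra), spectra="".join(blocks)))
    return path


@pytest.fixture
def mini_mzml(tmp_path):
    """mzML with one MS1 and two MS2 spectra (HCD and EThcD)."""
    path = tmp_path / "mini.mzml"
    write_mini_mzml(
        path,
        [
            {
                "id": "controllerType=0 controllerNumber=1 scan=1",
                "ms_level": 1,
                "mz": [400.0, 500.0],
                "intensity": [1e6, 2e6],
            },
            {
                "id": "controllerType=0 controllerNumber=1 scan=2",
                "ms_level": 2,
                "mz": [138.0550, 144.0655, 204.0866],
                "intensity": [1000.0, 900.0, 5e4],
                "precursor_mz": 491.5502,
                "charge": 4,
                "method": "HCD",
            },
            {
                "id": "controllerType=0 controllerNumber=1 scan=3",
                "ms_level": 2,
                "mz": [619.3725, 673.4145],
                "intensity": [2e4, 1e4],
                "precursor_mz": 491.5502,
                "charge": 4,
                "method": "EThcD",
            },
        ],
    )
    return path


def make_spectrum(sid="s1", peaks=None, **kwargs):
    peaks = peaks or [(204.0866, 5e4)]
    mz, inten = zip(*peaks)
    return Spectrum.from_peaks(sid, mz, inten, **kwargs)
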