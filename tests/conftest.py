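import base64
import struct
import zlib

import numpy as np
import pytest

from crambederep.library import default_library
from crambederep.reference import load_reference


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def reference():
    return load_reference()


def _b64(values, compress=True):
    raw = struct.pack(f"<{len(values)}d", *values)
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def _binary_array(values, kind):
    accession = "MS:1000514" if kind == "mz" else "MS:1000515"
    name = "m/z array" if kind == "mz" else "intensity array"
    return f"""<binaryDataArray>
  <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
  <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
  <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>
  <binary>{_b64(values)}</binary>
</binaryDataArray>"""


def make_mzml(ms1=(), ms2=(), mode="centroid") -> str:
    """Render a minimal mzML document (text) from scan descriptions.

    ms1: iterable of (rt_minutes, mz_list, intensity_list)
    ms2: iterable of (rt_minutes, precursor_mz, z, mz_list, intensity_list)
    """
    mode_cv = (
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        if mode == "centroid"
        else '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
    )
    chunks = []
    idx = 0
    for rt, mz, inten in ms1:
        chunks.append(f"""<spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{len(mz)}">
  <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
  {mode_cv}
  <scanList count="1"><scan>
    <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitName="minute"/>
  </scan></scanList>
  <binaryDataArrayList count="2">{_binary_array(mz, "mz")}{_binary_array(inten, "int")}</binaryDataArrayList>
</spectrum>""")
        idx += 1
    for rt, pmz, z, mz, inten in ms2:
        charge = (
            f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{z}"/>'
            if z
            else ""
        )
        chunks.append(f"""<spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{len(mz)}">
  <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
  {mode_cv}
  <scanList count="1"><scan>
    <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitName="minute"/>
  </scan></scanList>
  <precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
    <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{pmz}"/>
    {charge}
  </selectedIon></selectedIonList></precursor></precursorList>
  <binaryDataArrayList count="2">{_binary_array(mz, "mz")}{_binary_array(inten, "int")}</binaryDataArrayList>
</spectrum>""")
        idx += 1
    body = "\n".join(chunks)
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1"><spectrumList count="{idx}">
{body}
  </spectrumList></run>
</mzML>
"""


@pytest.fixture()
def mzml_factory(tmp_path):
    def build(ms1=(), ms2=(), mode="centroid", name="test.mzml"):
        path = tmp_path / name
        path.write_text(make_mzml(ms1, ms2, mode))
        return path

    return build


def brute_force_modified_cosine(a, b, tol=0.02):
    """Exhaustive-enumeration oracle for the modified cosine (<= ~8 peaks)."""
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa = np.sqrt(np.clip(a.intensity, 0, None))
    wb = np.sqrt(np.clip(b.intensity, 0, None))
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na > 0:
        wa = wa / na
    if nb > 0:
        wb = wb / nb
    shift = a.precursor_mz - b.precursor_mz
    cands = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a.mz[i] - b.mz[j]) <= tol or abs(a.mz[i] - b.mz[j] - shift) <= tol
    ]
    best = [0.0, 0]

    def rec(k, used_i, used_j, score, matched):
        if score > best[0] + 1e-15 or (abs(score - best[0]) <= 1e-15 and matched > best[1]):
            best[0], best[1] = score, matched
        for idx in range(k, len(cands)):
            i, j = cands[idx]
            if i in used_i or j in used_j:
                continue
            rec(idx + 1, used_i | {i}, used_j | {j}, score + wa[i] * wb[j], matched + 1)

    rec(0, frozenset(), frozenset(), 0.0, 0)
    return min(best[0], 1.0), best[1]
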