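"""Programmatic mzML fixture writer (test-only; the package never writes mzML)."""

import base64
import struct
import zlib

import numpy as np

_HEADER = '<?xml version="1.0" encoding="utf-8"?>\n<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'


def _encode(values, dtype="d", compress=False):
    raw = struct.pack(f"<{len(values)}{dtype}", *[float(v) for v in values])
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def _binary_array(values, kind, time_unit="minute", dtype="d", compress=False):
    unit_acc = {"minute": "UO:0000031", "second": "UO:0000010"}[time_unit]
    dtype_acc = "MS:1000523" if dtype == "d" else "MS:1000521"
    comp_acc = "MS:1000574" if compress else "MS:1000576"
    if kind == "time":
        kind_cv = (
            f'<cvParam cvRef="MS" accession="MS:1000595" name="time array" '
            f'unitAccession="{unit_acc}" unitName="{time_unit}"/>'
        )
    else:
        kind_cv = '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>'
    return (
        "<binaryDataArray>"
        f'<cvParam cvRef="MS" accession="{dtype_acc}" name="float"/>'
        f'<cvParam cvRef="MS" accession="{comp_acc}" name="compression"/>'
        f"{kind_cv}"
        f"<binary>{_encode(values, dtype, compress)}</binary>"
        "</binaryDataArray>"
    )


def srm_chromatogram_xml(
    cid,
    q1,
    q3,
    times,
    intensities,
    polarity="positive",
    ce=33.0,
    time_unit="minute",
    compress=False,
    include_polarity=True,
):
    pol_acc = "MS:1000130" if polarity == "positive" else "MS:1000129"
    parts = [
        f'<chromatogram id="{cid}" defaultArrayLength="{len(times)}">',
        '<cvParam cvRef="MS" accession="MS:1001473" '
        'name="selected reaction monitoring chromatogram"/>',
    ]
    if include_polarity:
        parts.append(f'<cvParam cvRef="MS" accession="{pol_acc}" name="{polarity} scan"/>')
    parts.append("<precursor><isolationWindow>")
    parts.append(
        f'<cvParam cvRef="MS" accession="MS:1000827" '
        f'name="isolation window target m/z" value="{q1}"/>'
    )
    parts.append("</isolationWindow>")
    if ce is not None:
        parts.append(
            "<activation>"
            f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{ce}"/>'
            "</activation>"
        )
    parts.append("</precursor><product><isolationWindow>")
    parts.append(
        f'<cvParam cvRef="MS" accession="MS:1000827" '
        f'name="isolation window target m/z" value="{q3}"/>'
    )
    parts.append("</isolationWindow></product>")
    parts.append('<binaryDataArrayList count="2">')
    parts.append(_binary_array(times, "time", time_unit=time_unit, compress=compress))
    parts.append(_binary_array(intensities, "intensity", compress=compress))
    parts.append("</binaryDataArrayList></chromatogram>")
    return "".join(parts)


def tic_chromatogram_xml(times, intensities):
    return (
        f'<chromatogram id="TIC" defaultArrayLength="{len(times)}">'
        '<cvParam cvRef="MS" accession="MS:1000235" name="total ion current chromatogram"/>'
        '<binaryDataArrayList count="2">'
        + _binary_array(times, "time")
        + _binary_array(intensities, "intensity")
        + "</binaryDataArrayList></chromatogram>"
    )


def write_mzml(path, chromatogram_xmls, scan_settings_polarity=None):
    parts = [_HEADER]
    if scan_settings_polarity:
        acc = "MS:1000130" if scan_settings_polarity == "positive" else "MS:1000129"
        parts.append(
            '<scanSettingsList count="1"><scanSettings id="ss1">'
            f'<cvParam cvRef="MS" accession="{acc}" name="{scan_settings_polarity} scan"/>'
            "</scanSettings></scanSettingsList>"
        )
    parts.append('<run id="run1">')
    parts.append(f'<chromatogramList count="{len(chromatogram_xmls)}">')
    parts.extend(chromatogram_xmls)
    parts.append("</chromatogramList></run></mzML>")
    with open(path, "w") as fh:
        fh.write("".join(parts))
    return path


def default_times():
    return np.round(np.linspace(0.0, 2.0, 21), 6)
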