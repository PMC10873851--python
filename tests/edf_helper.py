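"""Minimal EDF writer for constructing test fixtures at run time.

Writes a single-record EDF file (16-bit samples).  Only what the tests
need: channel labels, sampling rate, one continuous segment.
"""

from __future__ import annotations

import numpy as np


def write_minimal_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    n_ch, n_samp = data.shape
    dur = n_samp / fs
    pmin, pmax = data.min(axis=1), data.max(axis=1)
    pmax = np.where(pmax <= pmin, pmin + 1, pmax)
    dmin, dmax = -32768, 32767
    with open(path, "wb") as f:
        hdr = b"0".ljust(8)
        hdr += b"X".ljust(80)  # patient id
        hdr += b"X".ljust(80)  # recording id
        hdr += b"01.01.00" + b"00.00.00"
        hdr += str(256 * (1 + n_ch)).encode().ljust(8)
        hdr += b"".ljust(44)
        hdr += b"1".ljust(8)  # one data record
        hdr += ("%g" % dur).encode().ljust(8)
        hdr += str(n_ch).encode().ljust(4)
        f.write(hdr)

        def field(vals, width):
            f.write(b"".join(str(v).encode().ljust(width) for v in vals))

        field(labels, 16)
        field([""] * n_ch, 80)  # transducer
        field(["uV"] * n_ch, 8)
        field(["%.6g" % v for v in pmin], 8)
        field(["%.6g" % v for v in pmax], 8)
        field([dmin] * n_ch, 8)
        field([dmax] * n_ch, 8)
        field([""] * n_ch, 80)  # prefiltering
        field([n_samp] * n_ch, 8)
        field([""] * n_ch, 32)
        for c in range(n_ch):
            scale = (dmax - dmin) / (pmax[c] - pmin[c])
            dig = np.clip(
                np.round((data[c] - pmin[c]) * scale) + dmin, dmin, dmax
            ).astype("<i2")
            f.write(dig.tobytes())
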