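"""Signal conditioning: filtering, referencing, downsampling, GFP.

The microstate substrate is the average-referenced, band-limited signal
and the topographies at local maxima of the global field power (GFP).
Filters are zero-phase (applied forward-backward), since phase
distortion would shift topographic timing.  Artifact handling is purely
mask-based: masked samples are carried through the filters but excluded
from peak detection and all later stages.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import GfpSeries, Recording

__all__ = [
    "bandpass",
    "notch",
    "downsample",
    "average_reference",
    "compute_gfp",
    "detect_gfp_peaks",
    "gfp_peak_maps",
]

#: Stopband attenuation (dB) for the Kaiser-window FIR designs.
KAISER_ATTEN_DB = 60.0
#: Transition bandwidth (Hz) for the band-pass edges.
KAISER_WIDTH_HZ = 2.0
#: Quality factor of the IIR notch.
NOTCH_Q = 30.0


def _kaiser_fir(fs: float, cutoff, pass_zero) -> np.ndarray:
    numtaps, beta = sps.kaiserord(KAISER_ATTEN_DB, KAISER_WIDTH_HZ / (0.5 * fs))
    numtaps |= 1  # odd length keeps a symmetric, type-I filter
    return sps.firwin(
        numtaps, cutoff, window=("kaiser", beta), pass_zero=pass_zero, fs=fs
    )


def _filtfilt(data: np.ndarray, b, a=1.0) -> np.ndarray:
    n = data.shape[1]
    ntaps = len(b) if np.ndim(b) else 1
    padlen = min(3 * ntaps, n - 1)
    return sps.filtfilt(b, a, data, axis=1, padlen=padlen)


def bandpass(rec: Recording, lo: float, hi: float) -> Recording:
    """Zero-phase Kaiser-window FIR band-pass; removes DC; mask unchanged.

    Designed for 60 dB stopband attenuation with a 2 Hz transition width,
    applied forward-backward (so effective attenuation doubles).
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= rec.fs / 2:
        raise ValueError(f"high edge {hi} Hz must be below Nyquist {rec.fs / 2} Hz")
    b = _kaiser_fir(rec.fs, [lo, hi], pass_zero=False)
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=_filtfilt(data, b))


def notch(rec: Recording, f0: float = 50.0) -> Recording:
    """Zero-phase IIR notch (Q = 30) suppressing power-line interference."""
    if not 0 < f0 < rec.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must be below Nyquist")
    b, a = sps.iirnotch(f0, NOTCH_Q, fs=rec.fs)
    n = rec.data.shape[1]
    padlen = min(3 * max(len(a), len(b)), n - 1)
    data = sps.filtfilt(b, a, rec.data, axis=1, padlen=padlen)
    return rec.copy_with(data=data)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filter then decimate by an integer factor.

    The artifact mask is decimated with a logical OR over each decimation
    window, so any artifact sample taints its output sample.
    """
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"target_fs {target_fs} must divide fs {rec.fs} by an integer factor"
        )
    if q == 1:
        return rec.copy_with()
    # low-pass at 80% of the target Nyquist
    b = _kaiser_fir(rec.fs, 0.8 * target_fs / 2.0, pass_zero=True)
    data = _filtfilt(rec.data, b)[:, ::q]
    n = rec.mask.size
    n_out = int(np.ceil(n / q))
    padded = np.zeros(n_out * q, dtype=bool)
    padded[:n] = rec.mask
    mask = padded.reshape(n_out, q).any(axis=1)
    return rec.copy_with(data=data, fs=target_fs, mask=mask)


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: channel mean is zero per sample."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def compute_gfp(rec: Recording) -> GfpSeries:
    """Global field power: per-sample population standard deviation across
    channels (equals the RMS once average-referenced)."""
    return GfpSeries(values=rec.data.std(axis=0, ddof=0))


def detect_gfp_peaks(gfp: GfpSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Indices of strict interior local maxima of the GFP.

    A flat (plateau) maximum contributes its first sample only; series
    endpoints are never peaks; peaks landing on masked samples are
    dropped.
    """
    v = gfp.values
    if v.size < 3:
        return np.empty(0, dtype=int)
    idx, props = sps.find_peaks(v, plateau_size=1)
    peaks = props["left_edges"]
    # find_peaks' left edge can be index 0 for a plateau starting at the
    # boundary; exclude endpoints explicitly
    peaks = peaks[(peaks > 0) & (peaks < v.size - 1)]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        peaks = peaks[~mask[peaks]]
    return peaks.astype(int)


def gfp_peak_maps(rec: Recording) -> np.ndarray:
    """Topographies at unmasked GFP peaks, shape (n_peaks, n_channels)."""
    gfp = compute_gfp(rec)
    peaks = detect_gfp_peaks(gfp, rec.mask)
    return rec.data[:, peaks].T
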