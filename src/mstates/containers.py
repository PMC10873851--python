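"""Core data containers shared across the pipeline.

The analysis passes a small set of typed objects between stages:

``Montage``       electrode names and unit-sphere positions
``Recording``     channels x samples potentials with sampling rate,
                  montage, artifact mask and free-form metadata
``GfpSeries``     global field power trace plus detected peak indices
``TemplateSet``   K zero-mean, unit-norm topographies (cluster maps)
``Segmentation``  per-sample winner-takes-all class labels
``TemporalParams`` per-class mean duration and time coverage
``TestResult``    a single statistical test outcome

All containers validate their invariants on construction; numerical
payloads are plain numpy arrays so every stage stays vectorizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "Recording",
    "GfpSeries",
    "TemplateSet",
    "Segmentation",
    "TemporalParams",
    "TestResult",
    "UNLABELED",
]

#: Label used in ``Segmentation.labels`` for masked (artifact) samples.
UNLABELED: int = -1


@dataclass(frozen=True)
class Montage:
    """Electrode layout: unique channel labels and unit-sphere 3D positions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), each row unit norm

    def __init__(self, labels: Sequence[str], positions: np.ndarray) -> None:
        labels = tuple(str(x) for x in labels)
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValueError("positions must be an (n_channels, 3) array")
        if len(labels) != positions.shape[0]:
            raise ValueError(
                f"{len(labels)} labels but {positions.shape[0]} positions"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if len(labels) < 8:
            raise ValueError("a montage needs at least 8 channels")
        norms = np.linalg.norm(positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", positions)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Montage):
            return NotImplemented
        return self.labels == other.labels and np.allclose(
            self.positions, other.positions
        )


@dataclass
class Recording:
    """A continuous multichannel EEG segment.

    Parameters
    ----------
    data
        Potentials in microvolts, shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    montage
        Electrode layout; its channel count must match ``data``.
    mask
        Per-sample boolean artifact mask, ``True`` = artifact (excluded).
        Defaults to all-clean.
    meta
        Free-form metadata (subject id, condition, epoch id, ...).
    """

    data: np.ndarray
    fs: float
    montage: Montage
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.data.shape[1],):
                raise ValueError("mask length must equal the sample count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw: Any) -> "Recording":
        args = dict(
            data=self.data, fs=self.fs, montage=self.montage,
            mask=self.mask.copy(), meta=dict(self.meta),
        )
        args.update(kw)
        return Recording(**args)


@dataclass
class GfpSeries:
    """Global field power trace and the indices of its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.values.ndim != 1:
            raise ValueError("GFP values must be 1-D")
        if (self.values < -1e-12).any():
            raise ValueError("GFP values must be nonnegative")
        if self.peak_indices.size and (
            np.diff(self.peak_indices) <= 0
        ).any():
            raise ValueError("peak indices must be strictly increasing")


@dataclass
class TemplateSet:
    """K cluster topographies, each zero-mean across channels and unit L2 norm."""

    maps: np.ndarray  # (K, n_channels)
    class_labels: tuple[str, ...] | None = None
    gev: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (K, n_channels)")
        means = self.maps.mean(axis=1)
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(means, 0.0, atol=1e-8):
            raise ValueError("template maps must be zero-mean across channels")
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("template maps must have unit L2 norm")
        if self.class_labels is not None:
            self.class_labels = tuple(self.class_labels)
            if len(self.class_labels) != self.maps.shape[0]:
                raise ValueError("one class label per map required")
        if self.gev is not None and not (-1e-9 <= self.gev <= 1 + 1e-9):
            raise ValueError("gev must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def label_of(self, idx: int) -> str:
        if self.class_labels is not None:
            return self.class_labels[idx]
        return chr(ord("A") + idx) if idx < 26 else f"M{idx}"


@dataclass
class Segmentation:
    """Winner-takes-all labeling of a recording by a template set.

    ``labels[t]`` is the winning class index, or ``UNLABELED`` for masked
    samples; ``fit_corr[t]`` is the absolute spatial correlation with the
    winning template (0 where unlabeled).
    """

    labels: np.ndarray
    fit_corr: np.ndarray
    fs: float
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.fit_corr = np.asarray(self.fit_corr, dtype=float)
        if self.labels.shape != self.fit_corr.shape or self.labels.ndim != 1:
            raise ValueError("labels and fit_corr must be equal-length 1-D")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lab = self.labels[self.labels != UNLABELED]
        if lab.size and (lab.min() < 0 or lab.max() >= self.n_classes):
            raise ValueError("label out of range")
        fc = self.fit_corr
        if ((fc < -1e-9) | (fc > 1 + 1e-9)).any():
            raise ValueError("fit_corr must lie in [0, 1]")

    @property
    def labeled(self) -> np.ndarray:
        return self.labels != UNLABELED


@dataclass
class TemporalParams:
    """Per-class temporal parameters of a segmentation.

    ``mean_duration_ms[c]`` averages interior (uncensored) runs only and is
    NaN for classes never observed; for classes observed only in
    edge-censored runs it falls back to the full labeled stretch length and
    ``censored[c]`` is set.  ``time_coverage`` fractions sum to one over the
    labeled samples.
    """

    classes: np.ndarray  # class indices, shape (K,)
    mean_duration_ms: np.ndarray
    time_coverage: np.ndarray
    n_runs: np.ndarray  # interior runs counted toward duration
    labeled_time_s: float
    censored: np.ndarray  # True where duration fell back to censored runs

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        self.mean_duration_ms = np.asarray(self.mean_duration_ms, float)
        self.time_coverage = np.asarray(self.time_coverage, float)
        self.n_runs = np.asarray(self.n_runs, int)
        self.censored = np.asarray(self.censored, bool)
        tot = self.time_coverage.sum()
        if self.labeled_time_s > 0 and abs(tot - 1.0) > 1e-9:
            raise ValueError(f"coverages sum to {tot}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "mean_duration_ms": self.mean_duration_ms,
                "time_coverage": self.time_coverage,
                "n_runs": self.n_runs,
                "censored": self.censored,
            }
        )


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    df: tuple[float, ...] | float
    p: float
    effect_size: float | None = None
    method: str = ""
    corrected: bool = False
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (-1e-12 <= self.p <= 1 + 1e-12):
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect_size": self.effect_size,
            "method": self.method,
            "corrected": self.corrected,
        }
        d.update(self.extra)
        return d
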