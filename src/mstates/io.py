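"""Readers, writers and pipeline configuration.

On-disk formats are plain text throughout:

* montage — TSV with columns label, x, y, z (unit-sphere positions);
* recording — one TSV per subject x condition (rows = channels, first
  column the channel label, epochs concatenated) plus a JSON sidecar
  with fs, condition, trait score, epoch boundaries and the artifact
  mask as run-length (start, length) pairs;
* templates — TSV (channels x K) plus JSON sidecar;
* ground truth / parameters / test results — tidy TSV.

EDF files are also accepted for recordings (read through MNE, channels
aligned to the montage by label).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import Montage, Recording, Segmentation, TemplateSet, UNLABELED

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_montage",
    "write_montage",
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_cohort",
    "split_epochs",
    "read_templates",
    "write_templates",
    "write_segmentation",
    "read_segmentation",
    "write_results_table",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline settings."""

    data_dir: str
    out_dir: str
    montage_file: str = "montage.tsv"
    conditions: tuple[str, str] = ("neutral", "fear")
    # Band-pass/notch belong to raw-recording conditioning; cohorts that
    # are already band-limited (e.g. simulated ones) skip them, since
    # zero-phase filtering of abrupt topography switches smears state
    # transitions and biases duration estimates.
    apply_bandpass: bool = False
    band_lo: float = 1.0
    band_hi: float = 40.0
    notch_hz: float | None = None
    target_fs: float | None = 200.0
    k: int | None = 4
    k_min: int = 1
    k_max: int = 12
    n_restarts: int = 50
    n_perm: int = 10_000
    alpha: float = 0.05
    bonferroni_alpha: float | None = None
    fdr: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if len(self.conditions) != 2:
            raise ValueError("exactly two condition names required")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("need 0 < band_lo < band_hi")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.k is not None and not self.k_min <= self.k <= self.k_max:
            raise ValueError("k outside [k_min, k_max]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_restarts < 1 or self.n_perm < 1:
            raise ValueError("n_restarts and n_perm must be positive")

    def hash(self) -> str:
        """Digest of the analysis settings (the output location is not
        part of the analysis identity)."""
        d = asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def write_montage(montage: Montage, path: str | Path) -> None:
    df = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
    df.insert(0, "label", montage.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_montage(path: str | Path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: montage TSV needs columns {sorted(required)}")
    return Montage(df["label"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy())


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append([int(i), int(j - i)])
            i = j
        else:
            i += 1
    return runs


def _runs_to_mask(runs: Sequence[Sequence[int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, length in runs:
        mask[start : start + length] = True
    return mask


def write_recording(
    recordings: Recording | Sequence[Recording], path: str | Path
) -> None:
    """Write one or more epochs of a subject x condition session.

    ``path`` is the data TSV; a sidecar JSON is written next to it.
    Multiple recordings are concatenated with their boundaries recorded.
    """
    recs = [recordings] if isinstance(recordings, Recording) else list(recordings)
    if not recs:
        raise ValueError("nothing to write")
    fs = recs[0].fs
    montage = recs[0].montage
    if any(r.fs != fs or r.montage != montage for r in recs):
        raise ValueError("epochs must share fs and montage")
    data = np.hstack([r.data for r in recs])
    mask = np.concatenate([r.mask for r in recs])
    path = Path(path)
    df = pd.DataFrame(data)
    df.insert(0, "label", montage.labels)
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.8g")

    bounds, start = [], 0
    for r in recs:
        bounds.append(
            {"epoch": r.meta.get("epoch", len(bounds)), "start": start,
             "n_samples": r.n_samples}
        )
        start += r.n_samples
    meta = {
        "fs": fs,
        "n_channels": montage.n_channels,
        "subject": recs[0].meta.get("subject"),
        "condition": recs[0].meta.get("condition"),
        "trait": recs[0].meta.get("trait"),
        "epochs": bounds,
        "mask_runs": _mask_to_runs(mask),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path, montage_path: str | Path) -> Recording:
    """Read a recording (cohort TSV format or EDF) against a montage.

    Channels are aligned to the montage by label; a channel-count or
    label mismatch raises with both sides named.  For the TSV format the
    sidecar JSON supplies fs, metadata, epoch boundaries (kept in
    ``meta['epochs']``) and the artifact mask.
    """
    path = Path(path)
    montage = read_montage(montage_path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, montage)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"{path}: missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t", header=None)
    labels = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    if len(labels) != montage.n_channels:
        raise ValueError(
            f"{path}: file has {len(labels)} channels but montage "
            f"{montage_path} has {montage.n_channels}"
        )
    order = _align_channels(labels, montage, str(path))
    data = data[order]
    mask = _runs_to_mask(meta.get("mask_runs", []), data.shape[1])
    rec_meta = {
        k: meta.get(k) for k in ("subject", "condition", "trait") if meta.get(k) is not None
    }
    rec_meta["epochs"] = meta.get(
        "epochs", [{"epoch": 0, "start": 0, "n_samples": data.shape[1]}]
    )
    return Recording(
        data=data, fs=float(meta["fs"]), montage=montage, mask=mask, meta=rec_meta
    )


def _align_channels(labels: list[str], montage: Montage, what: str) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [lab for lab in montage.labels if lab not in index]
    if missing:
        raise ValueError(
            f"{what}: channels missing for montage labels {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    return np.array([index[lab] for lab in montage.labels])


def _read_edf(path: Path, montage: Montage) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if len(labels) != montage.n_channels:
        raise ValueError(
            f"{path}: EDF has {len(labels)} channels but montage has "
            f"{montage.n_channels}"
        )
    order = _align_channels(labels, montage, str(path))
    data = raw.get_data() * 1e6  # MNE returns volts; store microvolts
    return Recording(
        data=data[order], fs=float(raw.info["sfreq"]), montage=montage,
        meta={"source": str(path)},
    )


def split_epochs(rec: Recording) -> list[Recording]:
    """Split a concatenated session back into per-epoch recordings."""
    bounds = rec.meta.get("epochs")
    if not bounds:
        return [rec]
    out = []
    for b in bounds:
        s, n = int(b["start"]), int(b["n_samples"])
        meta = {k: v for k, v in rec.meta.items() if k != "epochs"}
        meta["epoch"] = b.get("epoch")
        out.append(
            Recording(
                data=rec.data[:, s : s + n], fs=rec.fs, montage=rec.montage,
                mask=rec.mask[s : s + n], meta=meta,
            )
        )
    return out


def write_cohort(
    recordings: Sequence[Recording],
    truth: pd.DataFrame | None,
    out_dir: str | Path,
) -> None:
    """Write a simulated cohort: montage, one TSV+JSON per subject x
    condition (epochs concatenated) and the ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not recordings:
        raise ValueError("empty cohort")
    write_montage(recordings[0].montage, out / "montage.tsv")
    groups: dict[tuple[Any, Any], list[Recording]] = {}
    for rec in recordings:
        key = (rec.meta.get("subject"), rec.meta.get("condition"))
        groups.setdefault(key, []).append(rec)
    for (subj, cond), recs in groups.items():
        recs.sort(key=lambda r: r.meta.get("epoch", 0))
        write_recording(recs, out / f"sub-{subj:02d}_{cond}.tsv")
    if truth is not None:
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def read_cohort(data_dir: str | Path, montage_file: str = "montage.tsv") -> list[Recording]:
    """Read every subject x condition session TSV in a cohort directory."""
    data_dir = Path(data_dir)
    montage_path = data_dir / montage_file
    recs = []
    for path in sorted(data_dir.glob("sub-*.tsv")):
        recs.append(read_recording(path, montage_path))
    if not recs:
        raise ValueError(f"no sub-*.tsv recordings found in {data_dir}")
    return recs


# ---------------------------------------------------------------------------
# Templates, segmentations, results
# ---------------------------------------------------------------------------

def write_templates(ts: TemplateSet, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        ts.maps.T, columns=[ts.label_of(i) for i in range(ts.k)]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {"k": ts.k, "gev": ts.gev, "class_labels": list(ts.class_labels or [])}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TemplateSet(
        maps=df.to_numpy(dtype=float).T,
        class_labels=tuple(meta["class_labels"]) if meta.get("class_labels") else tuple(df.columns),
        gev=meta.get("gev"),
    )


def write_segmentation(seg: Segmentation, path: str | Path) -> None:
    """Run-length-encoded segmentation TSV: start_sample, length, class
    (-1 for masked stretches), mean_fit_corr."""
    rows = []
    lab = seg.labels
    i = 0
    while i < lab.size:
        j = i
        while j < lab.size and lab[j] == lab[i]:
            j += 1
        rows.append(
            {
                "start_sample": i,
                "length": j - i,
                "class": int(lab[i]),
                "mean_fit_corr": float(seg.fit_corr[i:j].mean()),
            }
        )
        i = j
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    Path(path).with_suffix(".json").write_text(
        json.dumps({"fs": seg.fs, "n_classes": seg.n_classes, "n_samples": int(lab.size)})
    )


def read_segmentation(path: str | Path) -> Segmentation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    n = int(meta["n_samples"])
    labels = np.full(n, UNLABELED, dtype=int)
    fit = np.zeros(n)
    for _, row in df.iterrows():
        s, l = int(row["start_sample"]), int(row["length"])
        labels[s : s + l] = int(row["class"])
        fit[s : s + l] = row["mean_fit_corr"]
    return Segmentation(
        labels=labels, fit_corr=fit, fs=float(meta["fs"]),
        n_classes=int(meta["n_classes"]),
    )


def write_results_table(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Write a list of TestResult objects as a tidy TSV; returns the frame."""
    df = pd.DataFrame([r.to_dict() for r in results])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
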