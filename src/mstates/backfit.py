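"""Winner-takes-all backfitting and temporal parameters.

Group templates are fitted back to the continuous recording: every
unmasked sample gets the class whose template has the largest absolute
spatial correlation with the instantaneous topography.  The label
sequence is then summarized per class by

* mean duration (ms): the average length of maximal constant-label runs.
  Runs truncated by an epoch edge or an artifact-mask boundary censor
  the true dwell time and are excluded from the mean; a class observed
  only in censored runs reports their mean length with a ``censored``
  flag.
* time coverage: the fraction of labeled (unmasked) samples the class
  occupies; coverages sum to one by construction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import UNLABELED, Recording, Segmentation, TemplateSet, TemporalParams
from .cluster import assign_maps

__all__ = [
    "backfit_labels",
    "temporal_params",
    "split_half_params",
    "params_frame",
]


def backfit_labels(
    rec: Recording, templates: TemplateSet, peaks_only: bool = False
) -> Segmentation:
    """Label every unmasked sample with its best-matching template.

    Ties break to the lowest class index.  Samples with zero topographic
    variance get class 0 with fit 0.  With ``peaks_only`` the labels are
    computed at GFP peaks and propagated to the nearest peak's label
    (sensitivity-analysis mode; per-sample fitting is the default).
    """
    if rec.n_channels != templates.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels, templates "
            f"{templates.n_channels}"
        )
    x = rec.data - rec.data.mean(axis=0, keepdims=True)
    n = rec.n_samples
    labels = np.zeros(n, dtype=int)
    fit = np.zeros(n)
    norms = np.linalg.norm(x, axis=0)
    ok = norms > 1e-12
    if peaks_only:
        from .preprocess import compute_gfp, detect_gfp_peaks

        pk = detect_gfp_peaks(compute_gfp(rec), rec.mask)
        if pk.size == 0:
            raise ValueError("no GFP peaks available for peaks-only backfit")
        pk_ok = pk[ok[pk]]
        lab_pk, fit_pk = assign_maps(x[:, pk_ok].T, templates)
        nearest = np.abs(np.arange(n)[:, None] - pk_ok[None, :]).argmin(axis=1)
        labels = lab_pk[nearest]
        fit = fit_pk[nearest]
    else:
        if ok.any():
            lab_ok, fit_ok = assign_maps(x[:, ok].T, templates)
            labels[ok] = lab_ok
            fit[ok] = fit_ok
    labels[rec.mask] = UNLABELED
    fit[rec.mask] = 0.0
    return Segmentation(labels=labels, fit_corr=fit, fs=rec.fs, n_classes=templates.k)


def _runs(labels: np.ndarray) -> Iterable[tuple[int, int, int, bool]]:
    """Yield (class, start, length, interior) for maximal constant-label
    runs within contiguous unmasked stretches.  ``interior`` is False for
    runs abutting a stretch boundary (epoch edge or mask edge)."""
    n = labels.size
    i = 0
    while i < n:
        if labels[i] == UNLABELED:
            i += 1
            continue
        # contiguous unmasked stretch [i, j)
        j = i
        while j < n and labels[j] != UNLABELED:
            j += 1
        s = i
        while s < j:
            e = s
            while e < j and labels[e] == labels[s]:
                e += 1
            interior = s != i and e != j
            yield int(labels[s]), s, e - s, interior
            s = e
        i = j


def temporal_params(
    segs: Segmentation | Sequence[Segmentation], n_classes: int | None = None
) -> TemporalParams:
    """Per-class mean duration and time coverage of one or more
    segmentations (epochs of the same recording session).

    Runs never cross epoch boundaries; interior runs from all epochs are
    pooled for the duration estimate, and coverage is computed over all
    labeled samples.
    """
    if isinstance(segs, Segmentation):
        segs = [segs]
    if not segs:
        raise ValueError("no segmentations given")
    if n_classes is None:
        n_classes = segs[0].n_classes
    fs = segs[0].fs
    if any(s.fs != fs for s in segs):
        raise ValueError("segmentations must share a sampling rate")

    counts = np.zeros(n_classes)
    run_sum = np.zeros(n_classes)
    run_n = np.zeros(n_classes, dtype=int)
    cens_sum = np.zeros(n_classes)
    cens_n = np.zeros(n_classes, dtype=int)
    labeled = 0
    for seg in segs:
        lab = seg.labels
        labeled += int((lab != UNLABELED).sum())
        for cls, _, length, interior in _runs(lab):
            counts[cls] += length
            if interior:
                run_sum[cls] += length
                run_n[cls] += 1
            else:
                cens_sum[cls] += length
                cens_n[cls] += 1
    if labeled == 0:
        raise ValueError("no labeled samples in the segmentation(s)")

    coverage = counts / labeled
    duration = np.full(n_classes, np.nan)
    censored = np.zeros(n_classes, dtype=bool)
    has_interior = run_n > 0
    duration[has_interior] = run_sum[has_interior] / run_n[has_interior] * 1000.0 / fs
    only_censored = ~has_interior & (cens_n > 0)
    duration[only_censored] = (
        cens_sum[only_censored] / cens_n[only_censored] * 1000.0 / fs
    )
    censored[only_censored] = True
    return TemporalParams(
        classes=np.arange(n_classes),
        mean_duration_ms=duration,
        time_coverage=coverage,
        n_runs=run_n,
        labeled_time_s=labeled / fs,
        censored=censored,
    )


def _split_segmentation(seg: Segmentation) -> tuple[Segmentation, Segmentation]:
    half = seg.labels.size // 2
    return (
        Segmentation(seg.labels[:half], seg.fit_corr[:half], seg.fs, seg.n_classes),
        Segmentation(seg.labels[half:], seg.fit_corr[half:], seg.fs, seg.n_classes),
    )


def split_half_params(
    per_subject_segs: Mapping[object, Sequence[Segmentation]],
    n_classes: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split-half reliability of the temporal parameters.

    Each epoch's segmentation is split at its midpoint; parameters are
    computed per subject on the pooled first halves and pooled second
    halves, and the across-subject Pearson r is reported per class and
    parameter.

    Returns ``(first_half, second_half, reliability)`` data frames; the
    reliability frame has columns class, parameter, r.
    """
    subjects = sorted(per_subject_segs.keys(), key=str)
    if not subjects:
        raise ValueError("no subjects")
    rows_a, rows_b = [], []
    for subj in subjects:
        segs = per_subject_segs[subj]
        firsts, seconds = zip(*(_split_segmentation(s) for s in segs))
        for rows, part in ((rows_a, firsts), (rows_b, seconds)):
            tp = temporal_params(list(part), n_classes)
            df = tp.to_frame()
            df.insert(0, "subject", subj)
            rows.append(df)
    a = pd.concat(rows_a, ignore_index=True)
    b = pd.concat(rows_b, ignore_index=True)

    rel_rows = []
    for cls in sorted(a["class"].unique()):
        for param in ("mean_duration_ms", "time_coverage"):
            xa = a.loc[a["class"] == cls, param].to_numpy()
            xb = b.loc[b["class"] == cls, param].to_numpy()
            good = np.isfinite(xa) & np.isfinite(xb)
            if good.sum() >= 3 and xa[good].std() > 0 and xb[good].std() > 0:
                r = float(sstats.pearsonr(xa[good], xb[good])[0])
            else:
                r = np.nan
            rel_rows.append({"class": cls, "parameter": param, "r": r})
    return a, b, pd.DataFrame(rel_rows)


def params_frame(
    segmentations: Mapping[tuple[object, str], Sequence[Segmentation]],
    n_classes: int | None = None,
) -> pd.DataFrame:
    """Tidy per-(subject, condition, class) parameter table.

    ``segmentations`` maps (subject, condition) to that session's epoch
    segmentations.  Columns: subject, condition, class, mean_duration_ms,
    time_coverage.
    """
    rows = []
    for (subj, cond), segs in sorted(segmentations.items(), key=lambda x: (str(x[0][0]), x[0][1])):
        tp = temporal_params(list(segs), n_classes)
        df = tp.to_frame()[["class", "mean_duration_ms", "time_coverage"]]
        df.insert(0, "condition", cond)
        df.insert(0, "subject", subj)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
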