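"""End-to-end analysis driver.

``analyze_cohort`` runs the full in-memory sequence on a list of
recordings: preprocessing, per-subject and group clustering per
condition, cross-condition class pairing with a TANOVA check,
winner-takes-all backfitting, temporal parameters, condition contrasts
and trait correlations.  ``run_pipeline`` wraps it with file I/O, a run
directory and full provenance (config hash + seed in every summary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import backfit as bf
from . import cluster as cl
from . import preprocess as pp
from . import stats as st
from .containers import Recording, Segmentation, TemplateSet
from .io import (
    PipelineConfig,
    read_cohort,
    split_epochs,
    write_results_table,
    write_segmentation,
    write_templates,
)

__all__ = ["CohortResults", "analyze_cohort", "run_pipeline", "preprocess_recording"]


@dataclass
class CohortResults:
    """Bundle of everything the pipeline computes on one cohort."""

    group_templates: dict[str, TemplateSet]
    subject_templates: dict[str, dict[Any, TemplateSet]]
    pairing: np.ndarray  # class i of condition A pairs with pairing[i] of B
    pairing_corr: np.ndarray
    tanova: list
    segmentations: dict[tuple[Any, str], list[Segmentation]]
    params: pd.DataFrame  # subject, condition, class, parameters, trait
    anova: dict[str, tuple]
    contrasts: list
    correlations: list
    reliability: pd.DataFrame
    chosen_k: int
    fit_report: cl.ClusterFitReport | None = None
    meta: dict[str, Any] = field(default_factory=dict)


def preprocess_recording(rec: Recording, config: PipelineConfig) -> Recording:
    """Apply the configured conditioning chain to one epoch."""
    out = rec
    if config.apply_bandpass:
        out = pp.bandpass(out, config.band_lo, config.band_hi)
        if config.notch_hz:
            out = pp.notch(out, config.notch_hz)
    if config.target_fs and config.target_fs != out.fs:
        out = pp.downsample(out, config.target_fs)
    return pp.average_reference(out)


def _subject_class_map(
    recs: Sequence[Recording], segs: Sequence[Segmentation], cls: int,
    template: np.ndarray,
) -> np.ndarray | None:
    """Polarity-aligned mean topography of one subject's class samples."""
    acc = np.zeros(recs[0].n_channels)
    count = 0
    for rec, seg in zip(recs, segs):
        sel = seg.labels == cls
        if not sel.any():
            continue
        maps = rec.data[:, sel]
        signs = np.sign(template @ maps)
        signs[signs == 0] = 1.0
        acc += (maps * signs).sum(axis=1)
        count += int(sel.sum())
    if count == 0:
        return None
    m = acc / count
    m = m - m.mean()
    return m


def analyze_cohort(
    recordings: Sequence[Recording],
    config: PipelineConfig | None = None,
    truth: pd.DataFrame | None = None,
    reference_templates: TemplateSet | None = None,
) -> CohortResults:
    """Run the complete analysis on in-memory recordings.

    Recordings carry subject / condition / epoch metadata (one Recording
    per epoch).  If ``reference_templates`` is given (e.g. generative
    ground truth), group classes are reordered to match it, so class
    indices in every output align with the reference classes.
    ``truth`` only supplies the per-subject trait scores when recordings
    lack them.
    """
    if config is None:
        config = PipelineConfig(data_dir=".", out_dir=".")
    cond_a, cond_b = config.conditions
    rng = np.random.default_rng(config.seed)

    sessions: dict[tuple[Any, str], list[Recording]] = {}
    for rec in recordings:
        key = (rec.meta.get("subject"), rec.meta.get("condition"))
        if key[0] is None or key[1] is None:
            raise ValueError("recordings must carry subject and condition metadata")
        sessions.setdefault(key, []).append(preprocess_recording(rec, config))
    subjects = sorted({s for s, _ in sessions})
    for s in subjects:
        for cond in (cond_a, cond_b):
            if (s, cond) not in sessions:
                raise ValueError(f"subject {s} lacks condition {cond!r}")

    # GFP-peak maps per subject x condition
    peaks: dict[tuple[Any, str], np.ndarray] = {}
    for key, recs in sessions.items():
        pk = [pp.gfp_peak_maps(r) for r in recs]
        peaks[key] = np.vstack([p for p in pk if p.size])

    # model order
    fit_report = None
    if config.k is None:
        pooled = np.vstack([peaks[key] for key in sorted(peaks, key=str)])
        fit_report = cl.choose_k(
            pooled, range(config.k_min, config.k_max + 1),
            seed=config.seed, n_restarts=config.n_restarts,
        )
        k = fit_report.chosen_k
    else:
        k = config.k

    # two-level clustering per condition
    group_templates: dict[str, TemplateSet] = {}
    subject_templates: dict[str, dict[Any, TemplateSet]] = {}
    for ci, cond in enumerate((cond_a, cond_b)):
        per_subj = {s: peaks[(s, cond)] for s in subjects}
        group, subj_sets = cl.two_level_clustering(
            per_subj, k, seed=config.seed + 7919 * ci, n_restarts=config.n_restarts
        )
        group_templates[cond] = group
        subject_templates[cond] = subj_sets

    # align classes: reference (or condition A) defines the class order
    if reference_templates is not None:
        if reference_templates.k != k:
            raise ValueError("reference template count differs from fitted k")
        order_a, _ = cl.pair_conditions(reference_templates, group_templates[cond_a])
        group_templates[cond_a] = _reorder(
            group_templates[cond_a], order_a, reference_templates.class_labels
        )
    pairing, pairing_corr = cl.pair_conditions(
        group_templates[cond_a], group_templates[cond_b]
    )
    group_templates[cond_b] = _reorder(
        group_templates[cond_b], pairing, group_templates[cond_a].class_labels
    )
    pairing_final, pairing_corr = cl.pair_conditions(
        group_templates[cond_a], group_templates[cond_b]
    )

    # backfit each condition's recordings with that condition's classes
    segmentations: dict[tuple[Any, str], list[Segmentation]] = {}
    for key, recs in sessions.items():
        templates = group_templates[key[1]]
        segmentations[key] = [bf.backfit_labels(r, templates) for r in recs]

    # TANOVA per paired class on subject mean maps
    tanova_results = []
    for cls in range(k):
        maps_a, maps_b = [], []
        for s in subjects:
            ma = _subject_class_map(
                sessions[(s, cond_a)], segmentations[(s, cond_a)], cls,
                group_templates[cond_a].maps[cls],
            )
            mb = _subject_class_map(
                sessions[(s, cond_b)], segmentations[(s, cond_b)], cls,
                group_templates[cond_b].maps[cls],
            )
            if ma is not None and mb is not None:
                maps_a.append(ma)
                maps_b.append(mb)
        if len(maps_a) >= 3:
            res = st.tanova(
                np.array(maps_a), np.array(maps_b), n_perm=config.n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            res.name = f"tanova[class {cls}]"
            res.extra["class"] = cls
            tanova_results.append(res)

    # temporal parameters
    params = bf.params_frame(segmentations, n_classes=k)
    traits = _trait_table(recordings, truth)
    if traits is not None:
        params = params.merge(traits, on="subject", how="left")

    # statistics
    anova = {}
    for param in ("mean_duration_ms", "time_coverage"):
        try:
            anova[param] = st.rm_anova_2x4(params, param)
        except ValueError:
            pass
    contrasts = st.paired_contrasts(
        params, conditions=(cond_a, cond_b), alpha=config.alpha,
        family_alpha=config.bonferroni_alpha,
    )
    correlations = []
    if traits is not None and len(traits) >= 4 and traits["trait"].std() > 0:
        family = {}
        for cond in (cond_a, cond_b):
            sub = params[params["condition"] == cond]
            for cls in range(k):
                cell = sub[sub["class"] == cls].set_index("subject")
                for param in ("mean_duration_ms", "time_coverage"):
                    vals = cell.loc[traits["subject"], param].to_numpy()
                    if np.isfinite(vals).all() and np.std(vals) > 0:
                        family[f"{param}[class {cls}, {cond}]"] = vals
        if family:
            correlations = st.pearson_with_fdr(
                traits["trait"].to_numpy(), family, alpha=config.alpha
            )

    per_subject = {
        s: [seg for cond in (cond_a, cond_b) for seg in segmentations[(s, cond)]]
        for s in subjects
    }
    _, _, reliability = bf.split_half_params(per_subject, n_classes=k)

    return CohortResults(
        group_templates=group_templates,
        subject_templates=subject_templates,
        pairing=pairing_final,
        pairing_corr=pairing_corr,
        tanova=tanova_results,
        segmentations=segmentations,
        params=params,
        anova=anova,
        contrasts=contrasts,
        correlations=correlations,
        reliability=reliability,
        chosen_k=k,
        fit_report=fit_report,
        meta={"config_hash": config.hash(), "seed": config.seed},
    )


def _reorder(
    ts: TemplateSet, order: np.ndarray, labels: tuple[str, ...] | None
) -> TemplateSet:
    return TemplateSet(maps=ts.maps[np.asarray(order)], class_labels=labels, gev=ts.gev)


def _trait_table(
    recordings: Sequence[Recording], truth: pd.DataFrame | None
) -> pd.DataFrame | None:
    rows = {}
    for rec in recordings:
        subj = rec.meta.get("subject")
        trait = rec.meta.get("trait")
        if subj is not None and trait is not None:
            rows[subj] = float(trait)
    if not rows and truth is not None and "trait" in truth.columns:
        rows = truth.groupby("subject")["trait"].first().to_dict()
    if not rows:
        return None
    return pd.DataFrame(
        {"subject": sorted(rows), "trait": [rows[s] for s in sorted(rows)]}
    )


def run_pipeline(config: PipelineConfig) -> CohortResults:
    """File-based end-to-end run: read a cohort directory, analyze it and
    write every stage's outputs plus a provenance summary to the run
    directory.  Reruns with the same config are bit-identical."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = read_cohort(config.data_dir, config.montage_file)
    recordings = [ep for sess in sessions for ep in split_epochs(sess)]
    truth_path = Path(config.data_dir) / "ground_truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None

    results = analyze_cohort(recordings, config, truth=truth)

    for cond, ts in results.group_templates.items():
        write_templates(ts, out / f"templates_{cond}.tsv")
    for (subj, cond), segs in sorted(results.segmentations.items(), key=str):
        for e, seg in enumerate(segs):
            write_segmentation(seg, out / f"seg_sub-{subj:02d}_{cond}_ep{e:02d}.tsv")
    results.params.to_csv(out / "params.tsv", sep="\t", index=False)
    write_results_table(
        results.tanova + results.contrasts + results.correlations,
        out / "results.tsv",
    )
    results.reliability.to_csv(out / "reliability.tsv", sep="\t", index=False)

    summary: dict[str, Any] = {
        "schema_version": 1,
        "config_hash": config.hash(),
        "seed": config.seed,
        "chosen_k": results.chosen_k,
        "conditions": list(config.conditions),
        "gev": {c: t.gev for c, t in results.group_templates.items()},
        "pairing": results.pairing.tolist(),
        "tanova_p": {r.name: r.p for r in results.tanova},
        "anova": {
            param: {
                "interaction_F": inter.statistic,
                "interaction_df": list(inter.df),
                "interaction_p": inter.p,
            }
            for param, (inter, _) in results.anova.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return results
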