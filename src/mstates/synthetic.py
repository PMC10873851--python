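"""Synthetic EEG cohorts with known microstate ground truth.

The generator emulates the statistical structure microstate analysis
assumes: a small set of quasi-stable scalp topographies alternating as a
semi-Markov state sequence, each state expressed through an oscillatory
carrier whose topographic polarity flips every half-cycle, plus spatially
smooth sensor noise.  A cohort layer adds per-subject condition effects
(a "fear" vs "neutral" resting-state contrast acting on classes C and D)
and a personality-trait covariate (a neuroticism-like score in [8, 40])
that shifts the same two classes, so that every downstream stage —
clustering, backfitting, temporal parameters, condition contrasts and
trait correlations — can be checked by parameter recovery.

Defaults mirror a resting-state study design: 36 subjects, 12 epochs of
45 s each (6 per condition) sampled at 200 Hz, 4 microstate classes with
75 ms mean dwell time and equal time coverage, a 10 Hz carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Montage, Recording, TemplateSet

__all__ = [
    "GroundTruth",
    "CohortSpec",
    "spherical_montage",
    "make_templates",
    "sample_state_sequence",
    "render_eeg",
    "simulate_cohort",
    "default_ground_truth",
    "CONDITIONS",
]

#: Condition labels, baseline first.  Effects apply to the second one.
CONDITIONS: tuple[str, str] = ("neutral", "fear")

#: Class indices carrying condition/trait effects (canonical classes C, D).
CLASS_C, CLASS_D = 2, 3

#: Pairwise spatial correlation between generated template maps.
TEMPLATE_MUTUAL_CORR = 0.25

#: Spatial smoothing length (chord distance on the unit sphere) for both
#: template construction and sensor noise.
SMOOTHNESS = 0.6


@dataclass
class GroundTruth:
    """Generative microstate parameters.

    Parameters
    ----------
    templates
        The K true topographies.
    mean_durations_ms
        Expected dwell time per class, milliseconds.
    coverages
        Target long-run fraction of time per class; must sum to 1.
    carrier_freq
        Oscillation frequency (Hz) of the amplitude carrier.
    snr
        Signal-to-noise amplitude ratio (signal RMS / noise RMS across
        channels and time).  ``inf`` disables noise, ``0`` yields pure
        noise.
    """

    templates: TemplateSet
    mean_durations_ms: np.ndarray
    coverages: np.ndarray
    carrier_freq: float = 10.0
    snr: float = 12.0

    def __post_init__(self) -> None:
        self.mean_durations_ms = np.asarray(self.mean_durations_ms, float)
        self.coverages = np.asarray(self.coverages, float)
        k = self.templates.k
        if k < 1:
            raise ValueError("need at least one class")
        if self.mean_durations_ms.shape != (k,) or self.coverages.shape != (k,):
            raise ValueError("per-class parameter shapes must match K")
        if (self.mean_durations_ms <= 0).any():
            raise ValueError("mean durations must be positive")
        if (self.coverages <= 0).any():
            raise ValueError("coverages must be positive")
        if abs(self.coverages.sum() - 1.0) > 1e-9:
            raise ValueError("coverages must sum to 1")
        if self.carrier_freq <= 0:
            raise ValueError("carrier frequency must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")

    @property
    def k(self) -> int:
        return self.templates.k

    def with_params(
        self, mean_durations_ms: np.ndarray, coverages: np.ndarray
    ) -> "GroundTruth":
        return GroundTruth(
            templates=self.templates,
            mean_durations_ms=mean_durations_ms,
            coverages=coverages,
            carrier_freq=self.carrier_freq,
            snr=self.snr,
        )


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    ``effect_c``/``effect_d`` are relative shifts applied to class C/D
    mean duration and coverage in the "fear" condition only (e.g. -0.15
    lowers class-C parameters by 15%).  ``trait_slope_c``/``trait_slope_d``
    are relative shifts per unit of the mean-centered trait score, applied
    in both conditions.  ``subject_sd`` is the relative inter-individual
    spread of the baseline parameters (lognormal multiplicative jitter per
    subject and class, shared across conditions) — resting-state studies
    show stable individual differences in all classes, which is what makes
    split-half reliabilities high.  Coverages are renormalized after
    perturbation by scaling the untargeted classes proportionally.
    """

    n_subjects: int = 36
    n_epochs_per_condition: int = 6
    epoch_s: float = 45.0
    fs: float = 200.0
    trait_scores: np.ndarray | None = None
    effect_c: float = -0.15
    effect_d: float = 0.15
    trait_slope_c: float = 0.005
    trait_slope_d: float = -0.008
    subject_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_epochs_per_condition < 1:
            raise ValueError("cohort must have subjects and epochs")
        n_samp = self.epoch_s * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_s x fs must be an integral sample count")
        if self.trait_scores is not None:
            self.trait_scores = np.asarray(self.trait_scores, float)
            if self.trait_scores.shape != (self.n_subjects,):
                raise ValueError("one trait score per subject required")
            if ((self.trait_scores < 8) | (self.trait_scores > 40)).any():
                raise ValueError("trait scores must lie in [8, 40]")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_s * self.fs))


# ---------------------------------------------------------------------------
# Montage and template construction
# ---------------------------------------------------------------------------

def spherical_montage(n_channels: int = 32) -> Montage:
    """Electrodes on the upper-hemisphere cap of the unit sphere.

    Uses a Fibonacci lattice restricted to z >= 0, mimicking a scalp net;
    channel count is configurable (8..256).
    """
    if not 8 <= n_channels <= 256:
        raise ValueError("n_channels must be in [8, 256]")
    i = np.arange(n_channels)
    # golden-angle spiral over the cap z in [0.05, 1)
    z = 1.0 - (i + 0.5) / n_channels * 0.95
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = [f"E{j + 1}" for j in i]
    return Montage(labels, pos)


def _smoothing_matrix(montage: Montage, scale: float = SMOOTHNESS) -> np.ndarray:
    """Gaussian spatial smoother over chord distances between electrodes."""
    p = montage.positions
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * scale**2))
    return w / w.sum(axis=1, keepdims=True)


def _smooth_fields(
    montage: Montage, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n spatially smooth zero-mean random fields, rows of shape (n, C)."""
    w = _smoothing_matrix(montage)
    f = rng.standard_normal((n, montage.n_channels)) @ w.T
    return f - f.mean(axis=1, keepdims=True)


def make_templates(
    montage: Montage,
    k: int,
    seed: int,
    mutual_corr: float = TEMPLATE_MUTUAL_CORR,
) -> TemplateSet:
    """K zero-mean unit-norm topographies with controlled overlap.

    Smooth random fields are orthonormalized and then blended with one
    shared component so every template pair has spatial correlation
    ``mutual_corr`` (default 0.25, well under the 0.5 separability bound).
    Deterministic for a fixed seed.
    """
    c = montage.n_channels
    if k > c:
        raise ValueError(f"k={k} exceeds channel count {c}")
    if not 0.0 <= mutual_corr <= 0.5:
        raise ValueError("mutual_corr must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    # zero-mean subspace has dimension c - 1; fall back to orthogonal
    # templates when there is no room for the shared component
    use_common = mutual_corr > 0 and (k + 1) <= (c - 1)
    n_fields = k + 1 if use_common else k
    if n_fields > c - 1:
        raise ValueError(f"k={k} does not fit the zero-mean subspace of {c} channels")
    fields = _smooth_fields(montage, n_fields, rng)
    # orthonormalize within the zero-mean subspace
    q, _ = np.linalg.qr(fields.T)
    q = q.T[:n_fields]
    q -= q.mean(axis=1, keepdims=True)  # QR preserves zero-mean; re-assert
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    if use_common:
        shared, basis = q[0], q[1:]
        maps = np.sqrt(1.0 - mutual_corr) * basis + np.sqrt(mutual_corr) * shared
    else:
        maps = q
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    labels = tuple(chr(ord("A") + j) if j < 26 else f"M{j}" for j in range(k))
    return TemplateSet(maps=maps, class_labels=labels)


def default_ground_truth(
    montage: Montage | None = None,
    k: int = 4,
    seed: int = 0,
    mean_duration_ms: float = 75.0,
    carrier_freq: float = 10.0,
    snr: float = 12.0,
) -> GroundTruth:
    """Convenience: equal-coverage K-class ground truth on a 32-channel cap."""
    if montage is None:
        montage = spherical_montage(32)
    templates = make_templates(montage, k, seed)
    return GroundTruth(
        templates=templates,
        mean_durations_ms=np.full(k, float(mean_duration_ms)),
        coverages=np.full(k, 1.0 / k),
        carrier_freq=carrier_freq,
        snr=snr,
    )


# ---------------------------------------------------------------------------
# State sequence (semi-Markov)
# ---------------------------------------------------------------------------

def _dwell_samples(
    mean_samples: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Discrete gamma-shaped dwell times (shape 2), minimum one sample."""
    g = rng.gamma(shape=2.0, scale=mean_samples / 2.0, size=size)
    return np.maximum(1, np.rint(g)).astype(int)


def _transition_weights(
    visit_target: np.ndarray, n_iter: int = 200, tol: float = 1e-12
) -> np.ndarray:
    """Weights w such that the no-self-transition chain with
    P[i, j] proportional to w[j] (j != i) has stationary visit
    distribution ``visit_target``.  Solved by multiplicative fixed point.
    """
    k = visit_target.size
    w = visit_target.copy()
    for _ in range(n_iter):
        p = np.tile(w, (k, 1))
        np.fill_diagonal(p, 0.0)
        p /= p.sum(axis=1, keepdims=True)
        evals, evecs = np.linalg.eig(p.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat = np.abs(stat) / np.abs(stat).sum()
        if np.max(np.abs(stat - visit_target)) < tol:
            break
        w *= visit_target / np.maximum(stat, 1e-300)
        w /= w.sum()
    return w


def sample_state_sequence(
    gt: GroundTruth, n_samples: int, fs: float, seed: int
) -> np.ndarray:
    """Semi-Markov class-label sequence with the generative dwell means
    and long-run coverages.

    Dwell times are discrete gamma (shape 2) with the per-class mean;
    consecutive states always differ (for K >= 2).  Transition weights are
    solved so the embedded chain's stationary visit rates reproduce the
    target coverages; with K = 2 visits necessarily alternate, so coverage
    is then governed by the dwell-time ratio alone.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    k = gt.k
    if k == 1:
        return np.zeros(n_samples, dtype=int)
    rng = np.random.default_rng(seed)
    d = gt.mean_durations_ms * fs / 1000.0  # mean dwell in samples
    visit = gt.coverages / d
    visit /= visit.sum()
    if k == 2:
        w = visit
    else:
        w = _transition_weights(visit)
    p = np.tile(w, (k, 1))
    np.fill_diagonal(p, 0.0)
    p /= p.sum(axis=1, keepdims=True)
    cum_p = np.cumsum(p, axis=1)

    labels = np.empty(n_samples, dtype=int)
    state = int(rng.choice(k, p=visit))
    pos = 0
    # draw dwells in blocks to stay vectorized
    while pos < n_samples:
        dwell = int(_dwell_samples(d[state], 1, rng)[0])
        end = min(pos + dwell, n_samples)
        labels[pos:end] = state
        pos = end
        state = int(np.searchsorted(cum_p[state], rng.random(), side="right"))
    return labels


# ---------------------------------------------------------------------------
# Signal rendering
# ---------------------------------------------------------------------------

def render_eeg(
    labels: np.ndarray,
    gt: GroundTruth,
    montage: Montage,
    fs: float,
    seed: int,
    amplitude: float = 10.0,
    meta: dict | None = None,
) -> Recording:
    """Render a label sequence into a multichannel recording.

    ``signal(t) = amplitude * |carrier(t)| * s(t) * template[label(t)]``
    with a sinusoidal carrier whose polarity ``s(t)`` flips every
    half-cycle (so each state's topography is constant up to sign, as
    microstate analysis assumes), plus zero-mean spatially smooth noise
    scaled to the requested signal-to-noise amplitude ratio.  The carrier
    phase is offset by half a sample step so envelope zeros fall between
    sample instants.  Output is average-referenced.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if labels.max() >= gt.k or labels.min() < 0:
        raise ValueError("label out of range for the ground-truth classes")
    if montage.n_channels != gt.templates.n_channels:
        raise ValueError("montage channel count does not match templates")
    rng = np.random.default_rng(seed)
    n = labels.size
    t = np.arange(n) / fs
    # half-sample phase offset keeps envelope zeros off the sample grid
    phase0 = np.pi * gt.carrier_freq / fs
    carrier = np.sin(2.0 * np.pi * gt.carrier_freq * t + phase0)
    signal = gt.templates.maps[labels].T * (amplitude * carrier)  # (C, n)

    if gt.snr == 0.0:
        sig_rms = amplitude / np.sqrt(2.0 * montage.n_channels)
        data = _smooth_noise(montage, n, rng, rms=sig_rms)
    elif np.isinf(gt.snr):
        data = signal
    else:
        sig_rms = float(np.sqrt(np.mean(signal**2)))
        data = signal + _smooth_noise(montage, n, rng, rms=sig_rms / gt.snr)
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=fs, montage=montage, meta=meta or {})


def _smooth_noise(
    montage: Montage, n_samples: int, rng: np.random.Generator, rms: float
) -> np.ndarray:
    """Temporally white, spatially smooth noise with the given overall RMS."""
    w = _smoothing_matrix(montage)
    noise = w @ rng.standard_normal((montage.n_channels, n_samples))
    noise -= noise.mean(axis=0, keepdims=True)
    cur = np.sqrt(np.mean(noise**2))
    return noise * (rms / cur) if cur > 0 else noise


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _perturbed_params(
    base_dur: np.ndarray, base_cov: np.ndarray, rel_c: float, rel_d: float
) -> tuple[np.ndarray, np.ndarray]:
    """Apply relative shifts to classes C and D; renormalize coverages by
    scaling the untargeted classes proportionally."""
    k = base_dur.size
    dur = base_dur.copy()
    cov = base_cov.copy()
    targeted = []
    if k > CLASS_C:
        dur[CLASS_C] *= 1.0 + rel_c
        cov[CLASS_C] *= 1.0 + rel_c
        targeted.append(CLASS_C)
    if k > CLASS_D:
        dur[CLASS_D] *= 1.0 + rel_d
        cov[CLASS_D] *= 1.0 + rel_d
        targeted.append(CLASS_D)
    if targeted:
        others = np.setdiff1d(np.arange(k), targeted)
        targeted_sum = cov[targeted].sum()
        if targeted_sum >= 1.0 or (dur <= 0).any() or (cov <= 0).any():
            raise ValueError("perturbation drives parameters out of range")
        if others.size:
            cov[others] *= (1.0 - targeted_sum) / cov[others].sum()
    cov /= cov.sum()
    return dur, cov


def simulate_cohort(
    spec: CohortSpec, gt: GroundTruth, montage: Montage | None = None
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full cohort and return (recordings, ground-truth table).

    One Recording per subject x condition x epoch (meta carries subject,
    condition, epoch, trait).  The table holds the realized per-subject,
    per-condition generative parameters: columns subject, condition,
    class, class_label, mean_duration_ms, time_coverage, trait.
    """
    if montage is None:
        montage = spherical_montage(32)
    if montage.n_channels != gt.templates.n_channels:
        raise ValueError("montage channel count does not match templates")
    rng = np.random.default_rng(spec.seed)
    if spec.trait_scores is None:
        traits = rng.integers(8, 41, size=spec.n_subjects).astype(float)
    else:
        traits = spec.trait_scores
    trait_c = traits - traits.mean()

    recordings: list[Recording] = []
    rows = []
    for s in range(spec.n_subjects):
        # stable individual baseline, shared by both conditions
        jit_d = np.exp(spec.subject_sd * rng.standard_normal(gt.k))
        jit_c = np.exp(spec.subject_sd * rng.standard_normal(gt.k))
        base_dur = gt.mean_durations_ms * jit_d
        base_cov = gt.coverages * jit_c
        base_cov = base_cov / base_cov.sum()
        for cond in CONDITIONS:
            is_fear = cond == CONDITIONS[1]
            rel_c = spec.trait_slope_c * trait_c[s] + (
                spec.effect_c if is_fear else 0.0
            )
            rel_d = spec.trait_slope_d * trait_c[s] + (
                spec.effect_d if is_fear else 0.0
            )
            dur, cov = _perturbed_params(base_dur, base_cov, rel_c, rel_d)
            sub_gt = gt.with_params(dur, cov)
            for cls in range(gt.k):
                rows.append(
                    {
                        "subject": s,
                        "condition": cond,
                        "class": cls,
                        "class_label": gt.templates.label_of(cls),
                        "mean_duration_ms": dur[cls],
                        "time_coverage": cov[cls],
                        "trait": traits[s],
                    }
                )
            for e in range(spec.n_epochs_per_condition):
                seq_seed, render_seed = rng.integers(0, 2**31 - 1, size=2)
                seq = sample_state_sequence(
                    sub_gt, spec.epoch_samples, spec.fs, int(seq_seed)
                )
                rec = render_eeg(
                    seq,
                    sub_gt,
                    montage,
                    spec.fs,
                    int(render_seed),
                    meta={
                        "subject": s,
                        "condition": cond,
                        "epoch": e,
                        "trait": float(traits[s]),
                    },
                )
                recordings.append(rec)
    truth = pd.DataFrame(rows)
    return recordings, truth
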