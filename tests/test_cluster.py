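"""Clustering checks, including brute-force partition oracles."""

from itertools import product

import numpy as np
import pytest

import mstates as ms
from mstates.cluster import _normalize


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def _principal_eigvec(x):
    s = x.T @ x
    w, v = np.linalg.eigh(s)
    u = v[:, -1]
    u = u - u.mean()
    return u / np.linalg.norm(u)


def oracle_gev(maps, templates, labels):
    """Direct evaluation of the GEV formula, independent of the package."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp = maps.std(axis=1)
    num = 0.0
    for t in range(maps.shape[0]):
        u = maps[t] / np.linalg.norm(maps[t])
        a = templates[labels[t]]
        a = (a - a.mean()) / np.linalg.norm(a - a.mean())
        num += (gfp[t] * float(u @ a)) ** 2
    return num / float(np.sum(gfp**2))


def oracle_best_2partition_gev(maps):
    """Exhaustive optimum over all 2-partitions with eigenvector centroids."""
    n = maps.shape[0]
    maps = maps - maps.mean(axis=1, keepdims=True)
    best = -1.0
    for bits in product([0, 1], repeat=n - 1):
        labels = np.array((0,) + bits)
        if len(set(labels)) < 2:
            continue
        templates = np.array(
            [_principal_eigvec(maps[labels == j]) for j in (0, 1)]
        )
        # evaluate with free reassignment? no: fixed partition centroids,
        # then winner-takes-all assignment as the algorithm scores it
        c = np.abs(_normalize(maps) @ templates.T)
        lab = c.argmax(axis=1)
        best = max(best, oracle_gev(maps, templates, lab))
    return best


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestSpatialCorrelation:
    def test_self_and_flip(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=12)
        assert ms.spatial_correlation(u, u) == pytest.approx(1.0)
        assert ms.spatial_correlation(u, -u) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        assert ms.spatial_correlation(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ms.spatial_correlation(np.ones(5), np.arange(5.0))


class TestModifiedKmeans:
    def test_noiseless_two_template_recovery(self, montage32):
        rng = np.random.default_rng(1)
        ts = ms.make_templates(montage32, 2, seed=4, mutual_corr=0.0)
        signs = rng.choice([-1.0, 1.0], size=60)
        amps = rng.uniform(0.5, 2.0, size=60)
        labels = rng.integers(0, 2, size=60)
        maps = signs[:, None] * amps[:, None] * ts.maps[labels]
        fit = ms.modified_kmeans(maps, 2, seed=0)
        _, corr = ms.pair_conditions(ts, fit)
        pairing, corr = ms.pair_conditions(ts, fit)
        assert np.abs(corr[np.arange(2), pairing] - 1.0).max() < 1e-6
        assert fit.gev == pytest.approx(1.0, abs=1e-6)

    def test_k1_on_sign_flipped_copies(self, montage32):
        ts = ms.make_templates(montage32, 1, seed=5)
        maps = np.vstack([ts.maps[0], -ts.maps[0], ts.maps[0] * 2.0])
        fit = ms.modified_kmeans(maps, 1, seed=0)
        assert abs(ms.spatial_correlation(fit.maps[0], ts.maps[0])) == pytest.approx(1.0)
        assert fit.gev == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_partition_oracle(self, montage16):
        """Restarted k-means attains the brute-force optimum (k=2, n<=8)."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = rng.integers(4, 9)
            maps = rng.normal(size=(n, 16))
            fit = ms.modified_kmeans(maps, 2, seed=3, subsample=1.0)
            lab, _ = ms.assign_maps(maps, fit)
            got = ms.gev(maps, fit, lab)
            want = oracle_best_2partition_gev(maps)
            assert got >= want - 1e-9

    def test_polarity_and_scale_invariance(self, montage32, gt4):
        seq = ms.sample_state_sequence(gt4, 2000, 200.0, seed=6)
        rec = ms.render_eeg(seq, gt4, montage32, 200.0, seed=7)
        maps = ms.gfp_peak_maps(rec)
        rng = np.random.default_rng(8)
        flip = rng.choice([-1.0, 1.0], size=maps.shape[0])[:, None]
        base = ms.modified_kmeans(maps, 4, seed=9)
        flipped = ms.modified_kmeans(maps * flip * 2.5, 4, seed=9)
        _, corr = ms.pair_conditions(base, flipped)
        pairing, corr = ms.pair_conditions(base, flipped)
        assert np.abs(corr[np.arange(4), pairing] - 1.0).max() < 1e-6
        lab_a, _ = ms.assign_maps(maps, base)
        lab_b, _ = ms.assign_maps(maps * flip * 2.5, base)
        assert np.array_equal(lab_a, lab_b)

    def test_too_few_maps_rejected(self):
        with pytest.raises(ValueError):
            ms.modified_kmeans(np.random.default_rng(0).normal(size=(3, 16)), 4)


class TestGev:
    def test_perfect_and_orthogonal(self, montage16):
        ts = ms.make_templates(montage16, 2, seed=1, mutual_corr=0.0)
        maps = np.vstack([ts.maps[0], -ts.maps[0], ts.maps[1]])
        assert ms.gev(maps, ts, np.array([0, 0, 1])) == pytest.approx(1.0)
        # a template orthogonal to every map explains nothing
        other = ms.make_templates(montage16, 2, seed=1, mutual_corr=0.0)
        q = other.maps[1] - (other.maps[1] @ ts.maps[0]) * ts.maps[0]
        q = q - q.mean()
        q /= np.linalg.norm(q)
        orth = ms.TemplateSet(maps=q[None, :])
        maps0 = np.vstack([ts.maps[0], -2 * ts.maps[0]])
        assert ms.gev(maps0, orth, np.array([0, 0])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(3, 10))
        tpl = rng.normal(size=(1, 10))
        tpl = tpl - tpl.mean()
        tpl /= np.linalg.norm(tpl)
        ts = ms.TemplateSet(maps=tpl)
        labels = np.zeros(3, dtype=int)
        assert ms.gev(maps, ts, labels) == pytest.approx(
            oracle_gev(maps, ts.maps, labels), abs=1e-12
        )


class TestChooseK:
    def test_recovers_four_classes(self, montage32, gt4):
        seq = ms.sample_state_sequence(gt4, 6000, 200.0, seed=10)
        rec = ms.render_eeg(seq, gt4, montage32, 200.0, seed=11)
        maps = ms.gfp_peak_maps(rec)
        report = ms.choose_k(maps, range(1, 9), seed=0, n_restarts=10)
        assert report.chosen_k == 4

    def test_single_template_selects_one(self, montage32):
        ts = ms.make_templates(montage32, 1, seed=2)
        gt1 = ms.GroundTruth(ts, np.array([75.0]), np.array([1.0]), snr=np.inf)
        rec = ms.render_eeg(np.zeros(1500, int), gt1, montage32, 200.0, seed=1)
        maps = ms.gfp_peak_maps(rec)
        report = ms.choose_k(maps, range(1, 6), seed=0, n_restarts=5)
        assert report.chosen_k == 1

    def test_gev_nondecreasing(self, montage32, gt4):
        seq = ms.sample_state_sequence(gt4, 3000, 200.0, seed=12)
        rec = ms.render_eeg(seq, gt4, montage32, 200.0, seed=13)
        maps = ms.gfp_peak_maps(rec)
        report = ms.choose_k(maps, range(1, 7), seed=1, n_restarts=10)
        assert (np.diff(report.gev_per_k) > -1e-3).all()

    def test_force_k_override(self, montage32, gt4):
        seq = ms.sample_state_sequence(gt4, 2000, 200.0, seed=14)
        rec = ms.render_eeg(seq, gt4, montage32, 200.0, seed=15)
        maps = ms.gfp_peak_maps(rec)
        report = ms.choose_k(maps, range(1, 6), seed=0, n_restarts=5, force_k=3)
        assert report.chosen_k == 3


class TestTwoLevelAndPairing:
    def test_noiseless_group_recovery_with_subject_sign_flips(
        self, montage32, noiseless_gt4
    ):
        subject_peaks = {}
        for s in range(3):
            seq = ms.sample_state_sequence(noiseless_gt4, 2500, 200.0, seed=20 + s)
            rec = ms.render_eeg(seq, noiseless_gt4, montage32, 200.0, seed=30 + s)
            maps = ms.gfp_peak_maps(rec)
            if s == 1:  # polarity of a whole subject must not matter
                maps = -maps
            subject_peaks[s] = maps
        group, per_subject = ms.two_level_clustering(subject_peaks, 4, seed=0)
        pairing, corr = ms.pair_conditions(noiseless_gt4.templates, group)
        assert corr[np.arange(4), pairing].min() > 1 - 1e-6
        assert len(per_subject) == 3

    def test_pairing_identity_and_permutation(self, montage32):
        ts = ms.make_templates(montage32, 4, seed=6)
        pairing, corr = ms.pair_conditions(ts, ts)
        assert pairing.tolist() == [0, 1, 2, 3]
        assert np.allclose(np.diag(corr), 1.0)
        perm = np.array([2, 0, 3, 1])
        permuted = ms.TemplateSet(maps=ts.maps[perm])
        pairing, _ = ms.pair_conditions(ts, permuted)
        assert (perm[pairing] == np.arange(4)).all()
        flipped = ms.TemplateSet(maps=-ts.maps)
        pairing, corr = ms.pair_conditions(ts, flipped)
        assert pairing.tolist() == [0, 1, 2, 3]
        assert np.allclose(corr[np.arange(4), pairing], 1.0)
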