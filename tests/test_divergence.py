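"""Symmetrized KLD: closed forms, estimator agreement, profile localization."""

import math

import numpy as np
import pytest

from cryact.errors import AlignmentError, EstimationError, GridError, ShapeError
from cryact.divergence import (
    KLDProfile,
    PositionDistribution,
    aggregate_profiles,
    common_grid,
    estimate_from_samples,
    kld_profile,
    profiles_from_ensemble,
    symmetrized_kld,
)
from cryact.superpose_rmsd import superpose_to_reference
from cryact.synthetic_data import (
    RegionKinetics,
    SynthSpec,
    build_toy_structure,
    generate_ensemble,
    generate_reference,
)


def gaussian_dist(mean, cov, residue=1):
    return PositionDistribution(residue_index=residue, kind="gaussian",
                                mean=np.asarray(mean, float),
                                cov=np.asarray(cov, float))


class TestSymmetrizedKLD:
    def test_identical_gaussians_give_zero(self):
        P = gaussian_dist([0, 0, 0], np.eye(3))
        assert symmetrized_kld(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        # N(0, I) vs N(e_x, I): each direction contributes 1/2, symmetrized 0.5
        P = gaussian_dist([0, 0, 0], np.eye(3))
        Q = gaussian_dist([1, 0, 0], np.eye(3))
        assert symmetrized_kld(P, Q) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        P = gaussian_dist(rng.normal(size=3), A @ A.T + np.eye(3))
        Q = gaussian_dist(rng.normal(size=3), 2 * np.eye(3))
        assert symmetrized_kld(P, Q) == symmetrized_kld(Q, P)

    def test_estimator_tag_mismatch(self):
        P = gaussian_dist([0, 0, 0], np.eye(3))
        samples = np.random.default_rng(1).normal(size=(100, 3))
        Q = estimate_from_samples(samples, estimator="histogram")
        with pytest.raises(GridError):
            symmetrized_kld(P, Q)

    def test_histogram_grid_mismatch(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(100, 3))
        b = rng.normal(size=(100, 3))
        P = estimate_from_samples(a, estimator="histogram",
                                  grid=common_grid(a, a))
        Q = estimate_from_samples(b, estimator="histogram",
                                  grid=common_grid(b, b))
        with pytest.raises(GridError):
            symmetrized_kld(P, Q)

    def test_histogram_monte_carlo_matches_closed_form(self):
        # sampled N(0,I) vs N(e_x,I) on a shared grid reproduces 0.5 nats
        rng = np.random.default_rng(3)
        a = rng.normal(size=(100_000, 3))
        b = rng.normal(size=(100_000, 3)) + [1.0, 0, 0]
        grid = common_grid(a, b)  # default 1 A cubic cells, 2 A padding
        P = estimate_from_samples(a, estimator="histogram", grid=grid)
        Q = estimate_from_samples(b, estimator="histogram", grid=grid)
        assert symmetrized_kld(P, Q) == pytest.approx(0.5, rel=0.05)

    def test_estimator_concordance_on_gaussian_data(self):
        # histogram and gaussian estimates agree for moderate divergences;
        # the pseudo-count tail bias grows with separation, so 1e5 samples
        # cover divergences up to ~2 nats at the default grid
        rng = np.random.default_rng(4)
        for shift in (0.5, 1.0, 2.0):
            a = rng.normal(size=(100_000, 3))
            b = rng.normal(size=(100_000, 3)) + [shift, 0, 0]
            grid = common_grid(a, b)
            hist = symmetrized_kld(
                estimate_from_samples(a, estimator="histogram", grid=grid),
                estimate_from_samples(b, estimator="histogram", grid=grid))
            gauss = symmetrized_kld(
                estimate_from_samples(a, estimator="gaussian"),
                estimate_from_samples(b, estimator="gaussian"))
            assert 0.1 <= gauss <= 5.0
            assert hist == pytest.approx(gauss, rel=0.10)


class TestEstimateDistribution:
    def test_gaussian_sampling_recovery(self):
        rng = np.random.default_rng(5)
        true_mean = np.array([1.0, -2.0, 0.5])
        samples = rng.normal(size=(10_000, 3)) + true_mean
        P = estimate_from_samples(samples, estimator="gaussian")
        se = 1.0 / math.sqrt(10_000)
        assert np.all(np.abs(P.mean - true_mean) < 3 * se)
        assert np.all(np.abs(np.diag(P.cov) - 1.0) < 0.1)

    def test_single_point_histogram_mass_in_one_cell(self):
        samples = np.tile([1.0, 2.0, 3.0], (500, 1))
        P = estimate_from_samples(samples, estimator="histogram")
        # all mass (minus pseudo-counts) concentrated in a single cell
        assert P.probs.max() > 1.0 - 1e-4
        assert (P.probs > 1e-4).sum() == 1

    def test_min_frames_enforced(self):
        samples = np.zeros((10, 3))
        with pytest.raises(EstimationError):
            estimate_from_samples(samples, min_frames=100)


def _aligned_pair(spec, seed_rp=0, seed_ds=1, n_frames_ref=None):
    rp, truth = generate_ensemble(spec, seed=seed_rp)
    ds = generate_reference(spec, seed=seed_ds, n_frames=n_frames_ref or spec.n_frames)
    bb = rp.topology.bb_indices
    target = ds.coordinates.mean(axis=(0, 1))
    return (superpose_to_reference(rp, target, bb, label="DS-mean"),
            superpose_to_reference(ds, target, bb, label="DS-mean"), truth)


class TestKLDProfile:
    def test_unaligned_ensembles_rejected(self):
        spec = SynthSpec(n_replicas=1, n_frames=30, dt=0.1, n_residues=80)
        rp, _ = generate_ensemble(spec, seed=0)
        ds = generate_reference(spec, seed=1, n_frames=30)
        with pytest.raises(AlignmentError):
            kld_profile(rp, ds)

    def test_replica_equals_reference_gives_zero(self):
        spec = SynthSpec(n_replicas=1, n_frames=60, dt=0.1, n_residues=80)
        ds = generate_reference(spec, seed=2, n_frames=60)
        bb = ds.topology.bb_indices
        target = ds.coordinates.mean(axis=(0, 1))
        a = superpose_to_reference(ds, target, bb, label="DS-mean")
        prof = kld_profile(a, a, estimator="gaussian")
        assert np.allclose(prof.values, 0.0, atol=1e-9)

    def test_profile_localizes_displaced_region(self):
        # displacement only in EEE: maxima inside EEE, near-zero in REF
        kin = {"background": RegionKinetics(0.0),
               "EEE": RegionKinetics(3.0, 1.0, 0.0, 1.0, 2.0)}
        spec = SynthSpec(n_replicas=1, n_frames=300, dt=0.1, n_residues=80,
                         sigma=0.1, tau_flip=math.inf, kinetics=kin,
                         coupling_groups={})
        rp_al, ds_al, _ = _aligned_pair(spec)
        prof = kld_profile(rp_al, ds_al, estimator="gaussian")
        lo, hi = spec.regions.ranges["EEE"]
        eee = prof.values[lo - 1:hi]
        rlo, rhi = spec.regions.ranges["REF"]
        ref = prof.values[rlo - 1:rhi]
        assert prof.values.argmax() + 1 in range(lo, hi + 1)
        assert eee.mean() > 20 * ref.mean()

    def test_doubling_displacement_increases_divergence(self):
        means = []
        for delta in (1.5, 3.0):
            kin = {"background": RegionKinetics(0.0),
                   "EEE": RegionKinetics(delta, 1.0, 0.0, 1.0, 2.0)}
            spec = SynthSpec(n_replicas=1, n_frames=200, dt=0.1, n_residues=80,
                             sigma=0.1, tau_flip=math.inf, kinetics=kin,
                             coupling_groups={})
            rp_al, ds_al, _ = _aligned_pair(spec)
            prof = kld_profile(rp_al, ds_al, estimator="gaussian")
            lo, hi = spec.regions.ranges["EEE"]
            means.append(prof.values[lo - 1:hi].mean())
        assert means[1] > means[0]

    def test_histogram_profile_localizes_displaced_region(self):
        # the histogram estimator, at cells comparable to the fluctuation
        # width, also places the profile maximum inside the displaced region
        kin = {"background": RegionKinetics(0.0),
               "EEE": RegionKinetics(3.0, 1.0, 0.0, 1.0, 2.0)}
        spec = SynthSpec(n_replicas=1, n_frames=300, dt=0.1, n_residues=80,
                         sigma=0.5, tau_flip=math.inf, kinetics=kin,
                         coupling_groups={})
        rp_al, ds_al, _ = _aligned_pair(spec)
        prof = kld_profile(rp_al, ds_al, estimator="histogram", spacing=0.5)
        lo, hi = spec.regions.ranges["EEE"]
        assert prof.values.argmax() + 1 in range(lo, hi + 1)
        inside = prof.values[lo - 1:hi].mean()
        outside = np.delete(prof.values, np.arange(lo - 1, hi)).mean()
        assert inside > 3 * outside


class TestAggregateProfiles:
    def test_identical_profiles_have_zero_std(self):
        p = KLDProfile(values=np.array([1.0, 2.0, 3.0]), source="0")
        mean, std = aggregate_profiles([p, p, p])
        np.testing.assert_allclose(std, 0.0)
        np.testing.assert_allclose(mean, p.values)

    def test_two_profile_mean(self):
        a = KLDProfile(values=np.array([0.0, 2.0]), source="0")
        b = KLDProfile(values=np.array([2.0, 0.0]), source="1")
        mean, _ = aggregate_profiles([a, b])
        np.testing.assert_allclose(mean, [1.0, 1.0])

    def test_empty_list_rejected(self):
        with pytest.raises(ShapeError):
            aggregate_profiles([])

    def test_length_mismatch_rejected(self):
        a = KLDProfile(values=np.zeros(3), source="0")
        b = KLDProfile(values=np.zeros(4), source="1")
        with pytest.raises(ShapeError):
            aggregate_profiles([a, b])

    def test_replica_mean_matches_single_replica_expectation(self):
        spec = SynthSpec(n_replicas=8, n_frames=100, dt=0.1, n_residues=80,
                         coupling_groups={})
        rp_al, ds_al, _ = _aligned_pair(spec)
        profiles = profiles_from_ensemble(rp_al, ds_al, estimator="gaussian")
        mean, std = aggregate_profiles(profiles)
        single = profiles[0].values
        # replica profiles share the deterministic displacement field
        mask = mean > 1.0
        assert np.all(np.abs(single[mask] - mean[mask]) / mean[mask] < 0.5)

    def test_normalized_profile_has_unit_max(self):
        p = KLDProfile(values=np.array([1.0, 4.0, 2.0]), source="0")
        assert p.normalized().max() == pytest.approx(1.0)
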