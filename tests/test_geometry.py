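"""Distances, dihedrals, flip detection vs brute force, censored lifetimes."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cryact.errors import NoEventsError, SelectionError, ShapeError
from cryact.geometry import (
    DistanceTrace,
    FlipRecord,
    com_distance,
    detect_flip,
    dihedral_series,
    fit_lifetime,
    hexbin_density,
    split_by_flip,
)
from cryact.synthetic_data import SynthSpec, generate_ensemble

from conftest import make_ensemble


def trace(values, dt=0.02, replica=0, label=""):
    values = np.asarray(values, dtype=float)
    return DistanceTrace(replica_id=replica, label=label,
                         times=np.arange(len(values)) * dt, values=values)


class TestComDistance:
    def test_single_bead_pair(self):
        coords = np.zeros((1, 2, 2, 3))
        coords[:, :, 1] = [3.0, 4.0, 0.0]
        ens = make_ensemble(coords)
        traces = com_distance(ens, [0], [1])
        assert traces[0].values == pytest.approx([5.0, 5.0])

    def test_centroid_of_group(self):
        coords = np.zeros((1, 1, 3, 3))
        coords[0, 0, 0] = [0, 0, 0]
        coords[0, 0, 1] = [2, 0, 0]
        coords[0, 0, 2] = [1, 1, 0]
        ens = make_ensemble(coords)
        traces = com_distance(ens, [0, 1], [2])
        assert traces[0].values[0] == pytest.approx(1.0)

    def test_mass_weighted_option(self):
        coords = np.zeros((1, 1, 3, 3))
        coords[0, 0, 1] = [4, 0, 0]
        coords[0, 0, 2] = [2, 0, 0]
        ens = make_ensemble(coords)
        # weighted centroid of beads 0,1 with weights 3:1 sits at x = 1
        t = com_distance(ens, [0, 1], [2], weights_a=[3.0, 1.0])
        assert t[0].values[0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        ens = make_ensemble(np.zeros((1, 2, 3, 3)) + np.arange(3)[None, None, :, None])
        with pytest.raises(SelectionError):
            com_distance(ens, [], [1])

    def test_overlapping_groups_rejected(self):
        ens = make_ensemble(np.ones((1, 2, 3, 3)))
        with pytest.raises(SelectionError):
            com_distance(ens, [0, 1], [1, 2])

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(1, 9, size=(1, 4, 6, 3))
        ens = make_ensemble(coords)
        d0 = com_distance(ens, [0, 1], [4, 5])[0].values
        a = math.radians(63.0)
        R = np.array([[math.cos(a), -math.sin(a), 0],
                      [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])
        ens2 = make_ensemble(coords @ R.T + [7.0, -2.0, 1.0])
        d1 = com_distance(ens2, [0, 1], [4, 5])[0].values
        np.testing.assert_allclose(d0, d1, atol=1e-10)

    def test_tetrad_order_before_flip(self):
        spec = SynthSpec(n_replicas=2, n_frames=40, dt=0.1, n_residues=80,
                         sigma=0.05, tau_flip=math.inf)
        rp, _ = generate_ensemble(spec, seed=1)
        topo = rp.topology
        fla = topo.fla_indices
        tetrad = spec.regions.residue_sets["tetrad"]
        means = []
        for label in ("Trp_A", "Trp_B", "Trp_C", "Trp_D"):
            traces = com_distance(rp, fla, topo.residue_beads(tetrad[label]))
            means.append(np.mean([t.values.mean() for t in traces]))
        assert means == sorted(means)


class TestDihedral:
    @staticmethod
    def quad_ensemble(p0, p1, p2, p3):
        coords = np.array([[[p0, p1, p2, p3]]], dtype=float)
        return make_ensemble(coords)

    def test_planar_cis_is_zero(self):
        ens = self.quad_ensemble([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0])
        ang = dihedral_series(ens, (0, 1, 2, 3))
        assert ang[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        ens = self.quad_ensemble([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0])
        ang = dihedral_series(ens, (0, 1, 2, 3))
        assert abs(ang[0, 0]) == pytest.approx(180.0, abs=1e-10)

    def test_right_hand_sign(self):
        ens = self.quad_ensemble([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 0, 1])
        ang = dihedral_series(ens, (0, 1, 2, 3))
        # n1 rotates onto n2 by +90 degrees about the middle bond (+x)
        assert ang[0, 0] == pytest.approx(90.0, abs=1e-9)

    def test_matches_brute_force_normal_vector_construction(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(4, 3)) * 3
        ens = self.quad_ensemble(*pts)
        ang = dihedral_series(ens, (0, 1, 2, 3))[0, 0]

        # independent construction: signed angle between plane normals
        b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
        n1 = np.cross(b1, b2) / np.linalg.norm(np.cross(b1, b2))
        n2 = np.cross(b2, b3) / np.linalg.norm(np.cross(b2, b3))
        cosang = np.clip(n1 @ n2, -1, 1)
        sign = np.sign(np.cross(n1, n2) @ b2)
        oracle = math.degrees(sign * math.acos(cosang))
        assert ang == pytest.approx(oracle, abs=1e-9)

    def test_collinear_reported_as_gap(self):
        ens = self.quad_ensemble([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])
        with pytest.warns(UserWarning, match="collinear"):
            ang = dihedral_series(ens, (0, 1, 2, 3))
        assert np.isnan(ang[0, 0])

    def test_duplicate_beads_rejected(self):
        ens = make_ensemble(np.zeros((1, 1, 4, 3)))
        with pytest.raises(SelectionError):
            dihedral_series(ens, (0, 1, 1, 3))


def brute_force_flip_scan(above: np.ndarray, persistence: int) -> int | None:
    """Exhaustive oracle: first i with above[i:i+p] all True (full window)."""
    n = len(above)
    for i in range(n - persistence + 1):
        if above[i:i + persistence].all():
            return i
    return None


class TestDetectFlip:
    def test_never_flipped_is_censored(self):
        c = trace(np.full(100, 5.0))
        d = trace(np.full(100, 8.0))
        rec = detect_flip(c, d, persistence=10)
        assert not rec.flipped
        assert rec.flip_time == pytest.approx(c.times[-1])

    def test_step_swap_at_frame_500(self):
        n = 1001
        d_c = np.full(n, 9.5)
        d_d = np.full(n, 11.5)
        d_c[500:], d_d[500:] = 11.5, 9.5
        rec = detect_flip(trace(d_c), trace(d_d), persistence=50)
        assert rec.flipped
        assert rec.flip_time == pytest.approx(10.0)

    def test_short_back_crossings_ignored(self):
        n = 1001
        d_c = np.full(n, 9.5)
        d_d = np.full(n, 11.5)
        d_c[500:], d_d[500:] = 11.5, 9.5
        # three transient reversions shorter than the persistence window
        for k in (600, 700, 800):
            d_c[k:k + 5], d_d[k:k + 5] = 9.5, 11.5
        rec = detect_flip(trace(d_c), trace(d_d), persistence=50)
        above = d_c > d_d
        oracle = brute_force_flip_scan(above, 50)
        assert rec.flipped
        assert rec.flip_time == pytest.approx(oracle * 0.02)
        assert rec.flip_time == pytest.approx(10.0)

    def test_pre_flipped_marked(self):
        c = trace(np.full(50, 12.0))
        d = trace(np.full(50, 9.0))
        rec = detect_flip(c, d, persistence=5)
        assert rec.pre_flipped and rec.flipped and rec.flip_time == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            detect_flip(trace(np.ones(5)), trace(np.ones(6)))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_noisy_steps(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        swap = rng.integers(50, 400)  # may exceed n: censored case
        d_c = np.full(n, 10.0)
        d_d = np.full(n, 12.0)
        if swap < n:
            d_c[swap:], d_d[swap:] = 12.0, 10.0
        noise = rng.normal(0, 1.2, size=(2, n))  # large noise forces crossings
        d_c = np.clip(d_c + noise[0], 0.1, None)
        d_d = np.clip(d_d + noise[1], 0.1, None)
        persistence = int(rng.integers(1, 40))
        above = d_c > d_d
        if above[0]:
            return  # pre-flipped branch tested separately
        rec = detect_flip(trace(d_c), trace(d_d), persistence=persistence)
        oracle = brute_force_flip_scan(above, persistence)
        if oracle is None:
            assert not rec.flipped
        else:
            assert rec.flipped
            assert rec.flip_time == pytest.approx(oracle * 0.02)


class TestFitLifetime:
    @staticmethod
    def record(t, flipped, duration=20.0, rid=0):
        return FlipRecord(replica_id=rid, flipped=flipped,
                          flip_time=t, duration=duration)

    def test_uncensored_mle_is_sample_mean(self):
        recs = [self.record(t, True, rid=i) for i, t in enumerate((2.0, 4.0, 6.0))]
        fit = fit_lifetime(recs)
        assert fit.tau == pytest.approx(4.0)
        assert fit.n_events == 3

    def test_censored_closed_form(self):
        recs = [self.record(5.0, True), self.record(20.0, False, rid=1)]
        fit = fit_lifetime(recs)
        assert fit.tau == pytest.approx(25.0)

    def test_zero_events_error_with_lower_bound(self):
        recs = [self.record(20.0, False, rid=i) for i in range(3)]
        with pytest.raises(NoEventsError) as exc:
            fit_lifetime(recs)
        assert exc.value.lower_bound == pytest.approx(60.0)

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        times = rng.exponential(7.5, size=200)
        observed = times <= 20.0
        clipped = np.minimum(times, 20.0)
        recs = [self.record(t, bool(o), rid=i)
                for i, (t, o) in enumerate(zip(clipped, observed))]
        fit = fit_lifetime(recs)
        ef = lifelines.ExponentialFitter().fit(clipped, observed)
        assert fit.tau == pytest.approx(float(ef.lambda_), rel=1e-6)

    def test_recovery_within_twenty_percent(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(7.5, size=200)
        recs = [self.record(min(t, 20.0), t <= 20.0, rid=i)
                for i, t in enumerate(times)]
        fit = fit_lifetime(recs)
        assert fit.tau == pytest.approx(7.5, rel=0.20)
        assert fit.se == pytest.approx(fit.tau / math.sqrt(fit.n_events))


class TestHexbin:
    def test_identical_points_single_bin(self):
        c = trace(np.full(200, 9.5))
        d = trace(np.full(200, 11.5))
        df = hexbin_density([c], [d])
        assert len(df) == 1
        assert df["count"].iloc[0] == 200

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        c = trace(rng.uniform(8, 12, 500))
        d = trace(rng.uniform(9, 13, 500))
        df = hexbin_density([c], [d])
        assert df["count"].sum() == 500

    def test_flip_split_shows_bimodality(self):
        # flipped replicas populate the swapped corner of the (d_C, d_D) plane
        n = 400
        c_no = trace(np.full(n, 9.5) )
        d_no = trace(np.full(n, 11.5))
        c_fl = np.full(n, 9.5); c_fl[n // 2:] = 11.5
        d_fl = np.full(n, 11.5); d_fl[n // 2:] = 9.5
        df_no = hexbin_density([c_no], [d_no])
        df_fl = hexbin_density([trace(c_fl)], [trace(d_fl)])
        assert len(df_no) == 1       # unimodal
        assert len(df_fl) == 2       # bimodal


class TestSplitByFlip:
    def test_twelve_eight_split(self):
        spec = SynthSpec(n_replicas=20, n_frames=101, dt=0.2, n_residues=80,
                         forced_flip_count=12)
        rp, truth = generate_ensemble(spec, seed=5)
        recs = [FlipRecord(replica_id=i, flipped=t is not None,
                           flip_time=t if t is not None else rp.duration,
                           duration=rp.duration)
                for i, t in enumerate(truth.flip_times)]
        split = split_by_flip(rp, recs)
        assert split.flipped.n_replicas == 12
        assert split.not_flipped.n_replicas == 8
        # disjoint cover
        assert sorted(split.flipped_ids + split.not_flipped_ids) == list(range(20))

    def test_all_flipped_flags_empty_subset(self):
        ens = make_ensemble(np.ones((3, 4, 2, 3)))
        recs = [FlipRecord(replica_id=i, flipped=True, flip_time=1.0, duration=3.0)
                for i in range(3)]
        with pytest.warns(UserWarning, match="one-sided"):
            split = split_by_flip(ens, recs)
        assert split.not_flipped is None
        assert split.flipped.n_replicas == 3

    def test_record_mismatch_rejected(self):
        ens = make_ensemble(np.ones((3, 4, 2, 3)))
        recs = [FlipRecord(replica_id=0, flipped=True, flip_time=1.0, duration=3.0)]
        with pytest.raises(ShapeError):
            split_by_flip(ens, recs)
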