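"""Group aggregation: mean profiles, jackknife, pooling, splits, KS."""

import numpy as np
import pytest

from netstab import (
    Feature,
    Recording,
    compare_best_windows,
    group_mean_profile,
    intra_group_stability,
    jackknife_envelope,
    stability_at_window,
    stability_profile,
    upsample_split,
)
from netstab.networks import reconstruct
from netstab.synthetic import PlantedPair, SyntheticSpec, generate_group

GRID = [20.0, 50.0, 120.0]
LINK = Feature.strongest_link()


def noise_rec(seed, n=5, l=3000):
    rng = np.random.default_rng(seed)
    return Recording(f"s{seed}", rng.standard_normal((n, l)), 500.0, [f"c{i}" for i in range(n)])


class TestGroupMeanProfile:
    def test_identical_subjects_mean_and_zero_width_envelope(self):
        prof = stability_profile(noise_rec(1), LINK, GRID)
        gp = group_mean_profile([prof, prof, prof], group="g")
        np.testing.assert_allclose(gp.mean_ln_pi, prof.ln_pi)
        assert gp.envelope["best_window_ms"] == (prof.best_window_ms, prof.best_window_ms)
        assert gp.envelope["min_ln_pi"] == (prof.min_ln_pi, prof.min_ln_pi)

    def test_pointwise_mean_of_two_curves(self):
        p1 = stability_profile(noise_rec(1), LINK, GRID)
        p2 = stability_profile(noise_rec(2), LINK, GRID)
        gp = group_mean_profile([p1, p2], group="g")
        np.testing.assert_allclose(gp.mean_ln_pi, (p1.ln_pi + p2.ln_pi) / 2)

    def test_matches_external_averaging_oracle(self):
        profs = [stability_profile(noise_rec(s), LINK, GRID) for s in range(10)]
        gp = group_mean_profile(profs, group="g")
        manual = np.mean([p.ln_pi for p in profs], axis=0)
        np.testing.assert_allclose(gp.mean_ln_pi, manual)
        i = int(np.argmin(manual))
        assert gp.best_window_ms == GRID[i]
        assert gp.min_ln_pi == pytest.approx(manual[i])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_mean_profile([], group="g")

    def test_mismatched_grids_rejected(self):
        p1 = stability_profile(noise_rec(1), LINK, GRID)
        p2 = stability_profile(noise_rec(2), LINK, [20.0, 50.0])
        with pytest.raises(ValueError, match="share"):
            group_mean_profile([p1, p2])


class TestJackknife:
    def test_explicit_leave_one_out_oracle(self):
        profs = [stability_profile(noise_rec(s), LINK, GRID) for s in range(5)]
        env = jackknife_envelope(profs)
        curves = np.vstack([p.ln_pi for p in profs])
        bests, mins = [], []
        for leave in range(5):
            mean = curves[[i for i in range(5) if i != leave]].mean(axis=0)
            bests.append(GRID[int(np.argmin(mean))])
            mins.append(mean.min())
        assert env["best_window_ms"] == (min(bests), max(bests))
        assert env["min_ln_pi"] == pytest.approx((min(mins), max(mins)))

    def test_envelope_brackets_full_group(self):
        profs = [stability_profile(noise_rec(s), LINK, GRID) for s in range(6)]
        gp = group_mean_profile(profs, group="g")
        for key, full in (("min_ln_pi", gp.min_ln_pi), ("best_window_ms", gp.best_window_ms)):
            lo, hi = gp.envelope[key]
            assert lo - 1e-12 <= full <= hi + 1e-12

    def test_single_subject_rejected(self):
        prof = stability_profile(noise_rec(1), LINK, GRID)
        with pytest.raises(ValueError, match="2 subjects"):
            jackknife_envelope([prof])


class TestIntraGroup:
    def test_single_subject_bit_identical_to_per_subject(self):
        rec = noise_rec(3)
        ig = intra_group_stability([rec], LINK, GRID)
        for (g, pooled) in ig.grid:
            solo = stability_at_window(reconstruct(rec, g), LINK)
            assert (pooled.k, pooled.n, pooled.p) == (solo.k, solo.n, solo.p)
            assert pooled.ln_pi == solo.ln_pi
            assert pooled.modal_identity == solo.modal_identity

    def test_pooled_n_conservation(self):
        recs = [noise_rec(s, l=1000 + 400 * s) for s in range(3)]
        ig = intra_group_stability(recs, LINK, [40.0])
        w = int(40.0 * 500 / 1000)
        assert ig.grid[0][1].n == sum(r.n_samples // w for r in recs)

    def test_shared_planted_link_pools_far_below_single_subject(self):
        template = SyntheticSpec(
            n_channels=6, duration_s=8.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(1, 4, rho=0.9, q=1.0, epoch_ms=40.0),), seed=7,
        )
        cohort = generate_group(6, template, shared_structure=True)
        recs = [rec for rec, _ in cohort]
        pooled = intra_group_stability(recs, LINK, [40.0]).grid[0][1]
        assert pooled.modal_identity == (1, 4)
        singles = [stability_at_window(reconstruct(r, 40.0), LINK).ln_pi for r in recs]
        assert pooled.ln_pi < min(singles) - 10

    def test_shared_identities_pool_deeper_than_random_identities(self):
        template = SyntheticSpec(
            n_channels=8, duration_s=6.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(0, 1, rho=0.9, q=1.0, epoch_ms=40.0),), seed=11,
        )
        shared = [r for r, _ in generate_group(5, template, shared_structure=True)]
        random = [r for r, _ in generate_group(5, template, shared_structure=False)]
        lp_shared = intra_group_stability(shared, LINK, [40.0]).grid[0][1].ln_pi
        lp_random = intra_group_stability(random, LINK, [40.0]).grid[0][1].ln_pi
        assert lp_shared < lp_random - 50


class TestUpsampleSplit:
    def test_eight_minute_recording_splits_into_five(self, rng):
        rec = Recording("s", rng.standard_normal((3, 240000)), 500.0, list("abc"))
        parts = upsample_split(rec, 5)
        assert len(parts) == 5
        assert all(p.n_samples == 48000 for p in parts)
        assert [p.subject_id for p in parts] == [f"s_part{i}" for i in range(1, 6)]

    def test_remainder_discarded(self, rng):
        rec = Recording("s", rng.standard_normal((3, 11)), 500.0, list("abc"))
        parts = upsample_split(rec, 5)
        assert [p.n_samples for p in parts] == [2] * 5
        np.testing.assert_array_equal(parts[4].data, rec.data[:, 8:10])

    def test_too_short_rejected(self, rng):
        rec = Recording("s", rng.standard_normal((3, 8)), 500.0, list("abc"))
        with pytest.raises(ValueError, match="too short"):
            upsample_split(rec, 5)

    def test_parts_agree_with_whole_on_planted_data(self):
        spec = SyntheticSpec(
            n_channels=6, duration_s=40.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(2, 5, rho=0.9, q=0.9, epoch_ms=30.0),), seed=5,
        )
        from netstab.synthetic import generate_planted

        rec, _ = generate_planted(spec)
        grid = [12.0, 24.0, 48.0, 96.0]
        whole = stability_profile(rec, LINK, grid)
        parts = [stability_profile(p, LINK, grid) for p in upsample_split(rec, 5)]
        step = grid.index(whole.best_window_ms)
        for prof in parts:
            assert abs(grid.index(prof.best_window_ms) - step) <= 1


class TestCompareBestWindows:
    def test_identical_samples(self):
        stat, p = compare_best_windows([20, 30, 40], [20, 30, 40])
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        stat, _ = compare_best_windows(np.arange(50), np.arange(100, 150))
        assert stat == 1.0

    def test_matches_manual_ecdf_oracle(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.7, 1, 55)
        stat, _ = compare_best_windows(a, b)
        xs = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), xs, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), xs, side="right") / len(b)
        assert stat == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)))

    def test_insufficient_samples(self):
        with pytest.raises(ValueError):
            compare_best_windows([1.0], [2.0, 3.0])
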