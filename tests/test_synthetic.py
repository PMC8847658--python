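"""Synthetic generator: determinism, null statistics, planted recovery."""

import numpy as np
import pytest

from netstab import Feature, reconstruct, stability_at_window
from netstab.stability import feature_sequence
from netstab.synthetic import (
    PlantedHub,
    PlantedPair,
    SyntheticSpec,
    generate_group,
    generate_null,
    generate_planted,
)

from _oracles import multinomial_max_counts


class TestSpecValidation:
    def test_defaults_emulate_eight_minute_session(self):
        spec = SyntheticSpec()
        assert spec.n_channels == 32
        assert spec.sampling_rate_hz == 500.0
        assert spec.n_samples == 240000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_channels=2),
            dict(planted_pairs=(PlantedPair(0, 0),)),
            dict(planted_pairs=(PlantedPair(0, 99),)),
            dict(planted_pairs=(PlantedPair(0, 1, rho=1.5),)),
            dict(planted_pairs=(PlantedPair(0, 1, q=0.0),)),
            dict(planted_pairs=(PlantedPair(0, 1), PlantedPair(1, 2))),
            dict(planted_hub=PlantedHub(0, ())),
            dict(planted_hub=PlantedHub(0, (0, 1))),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(n_channels=kwargs.pop("n_channels", 8), duration_s=1.0, **kwargs).validate()


class TestNull:
    def test_seed_determinism(self):
        spec = SyntheticSpec(n_channels=4, duration_s=1.0, seed=42)
        a = generate_null(spec)
        b = generate_null(spec)
        np.testing.assert_array_equal(a.data, b.data)
        c = generate_null(SyntheticSpec(n_channels=4, duration_s=1.0, seed=43))
        assert not np.array_equal(a.data, c.data)

    def test_pairwise_correlations_small(self):
        # under independence |r| over w=1000 samples is below ~3.3/√w ≈ 0.104
        # for ≈99.9% of pairs; check the 99% bar across many windowed pairs
        spec = SyntheticSpec(n_channels=10, duration_s=20.0, sampling_rate_hz=500.0, seed=1)
        rec = generate_null(spec)
        series = reconstruct(rec, 2000.0)  # windows of 1000 samples
        iu = np.triu_indices(10, 1)
        r = series.weights[:, iu[0], iu[1]].ravel()
        assert np.quantile(r, 0.99) < 0.1

    def test_planted_spec_rejected(self):
        spec = SyntheticSpec(n_channels=4, duration_s=1.0, planted_pairs=(PlantedPair(0, 1),))
        with pytest.raises(ValueError, match="without planted"):
            generate_null(spec)

    def test_modal_count_consistent_with_multinomial_max(self):
        # strongest links under the null are iid uniform over L pairs, so the
        # modal count follows the max cell of a uniform multinomial
        n_rep, n_win, n_chan = 120, 150, 6
        L = n_chan * (n_chan - 1) // 2
        ks = []
        for i in range(n_rep):
            rec = generate_null(
                SyntheticSpec(n_channels=n_chan, duration_s=6.0, sampling_rate_hz=500.0, seed=100 + i)
            )
            series = reconstruct(rec, 40.0)  # 150 windows of 20 samples
            seq = feature_sequence(series, Feature.strongest_link())
            ks.append(max(seq.count(x) for x in set(seq)))
        oracle = multinomial_max_counts(n_win, L, 40000, np.random.default_rng(0))
        from scipy.stats import ks_2samp

        stat = ks_2samp(ks, oracle).statistic
        crit = 1.628 * np.sqrt((n_rep + 40000) / (n_rep * 40000))  # 1% level
        assert stat < crit


class TestPlanted:
    def test_fully_persistent_pair_dominates(self):
        spec = SyntheticSpec(
            n_channels=8, duration_s=12.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(2, 5, rho=0.95, q=1.0, epoch_ms=30.0),), seed=3,
        )
        rec, truth = generate_planted(spec)
        series = reconstruct(rec, 30.0)
        seq = feature_sequence(series, Feature.strongest_link())
        assert seq.count((2, 5)) / len(seq) >= 0.95
        assert truth.active_masks[(2, 5)].all()

    def test_within_epoch_correlation_near_rho(self):
        spec = SyntheticSpec(
            n_channels=4, duration_s=60.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(0, 1, rho=0.6, q=0.5, epoch_ms=200.0),), seed=9,
        )
        rec, truth = generate_planted(spec)
        mask = truth.active_masks[(0, 1)]
        r_active = np.corrcoef(rec.data[0, mask], rec.data[1, mask])[0, 1]
        r_inactive = np.corrcoef(rec.data[0, ~mask], rec.data[1, ~mask])[0, 1]
        assert r_active == pytest.approx(0.6, abs=0.05)
        assert abs(r_inactive) < 0.05
        assert mask.mean() == pytest.approx(0.5, abs=0.1)

    def test_vanishing_coupling_looks_like_null(self):
        spec = SyntheticSpec(
            n_channels=6, duration_s=10.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(0, 1, rho=1e-6, q=1.0, epoch_ms=30.0),), seed=7,
        )
        rec, _ = generate_planted(spec)
        res = stability_at_window(reconstruct(rec, 40.0), Feature.strongest_link())
        # modal share indistinguishable from a 15-way uniform draw
        assert res.k / res.n < 0.25

    def test_hub_is_modal_max_strength_node(self):
        spec = SyntheticSpec(
            n_channels=10, duration_s=12.0, sampling_rate_hz=500.0,
            planted_hub=PlantedHub(3, (0, 1, 5, 7, 9), rho=0.9), seed=4,
        )
        rec, _ = generate_planted(spec)
        res = stability_at_window(reconstruct(rec, 60.0), Feature.max_strength_node())
        assert res.modal_identity == 3
        assert res.k / res.n > 0.8

    def test_requires_planted_structure(self):
        with pytest.raises(ValueError, match="at least one"):
            generate_planted(SyntheticSpec(n_channels=4, duration_s=1.0))


class TestGroup:
    def test_single_subject_matches_generate_planted_with_derived_seed(self):
        template = SyntheticSpec(
            n_channels=5, duration_s=2.0, sampling_rate_hz=500.0,
            planted_pairs=(PlantedPair(0, 1),), seed=21,
        )
        (rec, _), = generate_group(1, template)
        seed = int(np.random.SeedSequence(21).generate_state(2)[0] % 2**31)
        from dataclasses import replace

        rec2, _ = generate_planted(replace(template, seed=seed))
        np.testing.assert_array_equal(rec.data, rec2.data)

    def test_distinct_master_seeds_distinct_cohorts(self):
        t1 = SyntheticSpec(n_channels=4, duration_s=1.0, planted_pairs=(PlantedPair(0, 1),), seed=1)
        t2 = SyntheticSpec(n_channels=4, duration_s=1.0, planted_pairs=(PlantedPair(0, 1),), seed=2)
        a = generate_group(3, t1)
        b = generate_group(3, t2)
        assert not np.array_equal(a[0][0].data, b[0][0].data)

    def test_random_identities_differ_across_subjects(self):
        template = SyntheticSpec(
            n_channels=12, duration_s=1.0, planted_pairs=(PlantedPair(0, 1, rho=0.9),), seed=8,
        )
        cohort = generate_group(8, template, shared_structure=False)
        pairs = {(t.planted_pairs[0].j, t.planted_pairs[0].k) for _, t in cohort}
        assert len(pairs) > 1
        for _, t in cohort:
            p = t.planted_pairs[0]
            assert 0 <= p.j < p.k < 12
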