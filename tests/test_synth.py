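"""Synthetic-data generators: designs, spaces, listings, BOLD, stimuli."""

import numpy as np
import pytest

from conftest import brute_force_corr_rdm
from slrsa import glm, rdm, synth


class TestSemanticSpace:
    def test_study_scale_dimensions(self):
        space = synth.make_semantic_space(n_concepts=58, n_dims=400, seed=0)
        assert space.vectors.shape == (58, 400)
        assert len(space.concepts) == 58

    def test_rank_one_space_has_all_zero_rdm(self):
        space = synth.make_semantic_space(6, 30, n_latent=1, noise_sd=0.0,
                                          seed=3)
        d = rdm.correlation_distance_rdm(space.vectors).d
        # rows are scalar multiples of one latent vector: |r| = 1, but sign
        # flips give distance 2; all cells are at a correlation extreme
        assert np.all((np.abs(d) < 1e-10) | (np.abs(d - 2) < 1e-10))

    def test_rdm_matches_brute_force_oracle(self):
        space = synth.make_semantic_space(6, 40, n_latent=2, noise_sd=0.1,
                                          seed=5)
        got = rdm.correlation_distance_rdm(space.vectors).d
        expected = brute_force_corr_rdm(space.vectors)
        assert np.abs(got - expected).max() < 1e-12

    @pytest.mark.parametrize("kwargs", [
        {"n_concepts": 1}, {"n_dims": 0}, {"n_latent": 0},
        {"n_latent": 99, "n_dims": 10}, {"noise_sd": -1.0},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        args = {"n_concepts": 6, "n_dims": 10, "n_latent": 2,
                "noise_sd": 0.1, "seed": 0, **kwargs}
        with pytest.raises(ValueError):
            synth.make_semantic_space(**args)

    def test_seed_reproducibility(self):
        a = synth.make_semantic_space(6, 10, seed=1)
        b = synth.make_semantic_space(6, 10, seed=1)
        c = synth.make_semantic_space(6, 10, seed=2)
        assert np.array_equal(a.vectors, b.vectors)
        assert not np.array_equal(a.vectors, c.vectors)


class TestPropertyListings:
    def test_mean_properties_per_cell(self):
        pl = synth.make_property_listings(20, 58, mean_props=3.5, seed=0)
        totals = pl.counts.sum(axis=2)
        assert totals.size >= 1000
        assert 3.0 <= totals.mean() <= 4.0

    def test_no_missing_when_rate_zero(self):
        pl = synth.make_property_listings(5, 10, missing_rate=0.0, seed=0)
        assert pl.missing == frozenset()

    def test_missing_rate_binomial(self):
        pl = synth.make_property_listings(51, 58, missing_rate=0.05, seed=4)
        n_cells = 51 * 58
        frac = len(pl.missing) / n_cells
        se = np.sqrt(0.05 * 0.95 / n_cells)
        assert abs(frac - 0.05) < 3 * se

    def test_category_axis_fixed_at_eleven(self):
        pl = synth.make_property_listings(3, 4, seed=0)
        assert len(pl.categories) == 11
        assert pl.counts.shape == (3, 4, 11)

    def test_tsv_round_trip_preserves_missing(self, tmp_path):
        pl = synth.make_property_listings(6, 8, missing_rate=0.2, seed=9)
        path = tmp_path / "pl.tsv"
        pl.to_tsv(path)
        back = synth.PropertyListings.from_tsv(path)
        assert back.missing == pl.missing
        assert np.array_equal(back.counts, pl.counts)


class TestEventDesign:
    def test_trial_duration(self):
        d = synth.make_event_design({"word": 8, "pseudoword": 8}, seed=0)
        assert np.allclose(d.durations, 2.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_max_run_constraint_on_full_design(self, seed):
        d = synth.make_event_design({"word": 64, "pseudoword": 64},
                                    max_run=3, seed=seed)
        assert synth.sequence_ok(list(d.conditions), 3)
        assert np.sum(d.conditions == "word") == 64
        assert np.sum(d.conditions == "pseudoword") == 64

    def test_iti_distribution_mean(self):
        itis = synth.draw_itis(10_000, 3173.0, 3435.0, rng=0)
        se = itis.std(ddof=1) / np.sqrt(itis.size)
        assert abs(itis.mean() - 3.173) < 3 * se
        assert itis.min() > 0

    def test_unsatisfiable_counts_fail(self):
        with pytest.raises(ValueError, match="max_run"):
            synth.make_event_design({"word": 10, "pseudoword": 1}, max_run=2,
                                    seed=0)

    def test_onsets_strictly_increasing_and_within_run(self):
        d = synth.make_event_design({"word": 16, "pseudoword": 16}, seed=2)
        assert np.all(np.diff(d.onsets) > 0)
        assert d.onsets[-1] + d.durations[-1] <= d.run_length

    def test_tsv_round_trip(self, tmp_path):
        d = synth.make_event_design({"word": 4, "pseudoword": 4}, seed=0)
        path = tmp_path / "events.tsv"
        d.to_tsv(path)
        back = synth.EventDesign.from_tsv(path, tr=d.tr,
                                          run_length=d.run_length)
        assert np.allclose(back.onsets, d.onsets)
        assert list(back.conditions) == list(d.conditions)


class TestBlockDesign:
    def test_visual_protocol(self):
        d = synth.make_block_design("visual")
        assert d.n_events == 6
        assert np.allclose(d.durations, 24.0)
        gaps = np.diff(d.onsets) - 24.0
        assert np.allclose(gaps, 27.8)

    def test_motor_protocol(self):
        d = synth.make_block_design("motor")
        assert d.n_events == 8
        assert np.allclose(d.durations, 26.0)
        assert np.allclose(np.diff(d.onsets), 52.0)  # 26 s task + 26 s rest

    def test_emotional_protocol(self):
        d = synth.make_block_design("emotional")
        assert d.n_events == 12
        assert np.allclose(d.durations, 23.8)
        labels = list(d.conditions)
        assert labels.count("emotional") == 6
        assert labels.count("neutral") == 6

    def test_unknown_protocol(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            synth.make_block_design("auditory")


class TestEmbedGeometry:
    def test_all_ones_similarity_realizes_zero_rdm(self):
        target = rdm.RDM(labels=list("abc"), d=np.zeros((3, 3)))
        pat = synth.embed_geometry(target, 20, np.arange(20), seed=0)
        realized = brute_force_corr_rdm(pat.patterns)
        assert np.abs(realized).max() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_realized_rdm_equals_target(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((5, 30))
        target = rdm.correlation_distance_rdm(m)
        pat = synth.embed_geometry(target, 60, np.arange(60), seed=seed)
        realized = brute_force_corr_rdm(pat.patterns)
        assert np.abs(realized - target.d).max() < 1e-8

    def test_out_of_range_distance_rejected(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            rdm.RDM(labels=["a", "b"], d=d)

    def test_non_psd_target_rejected(self):
        # distances implying pairwise correlation -0.9 among 3 conditions
        # cannot come from any real-valued patterns
        d = np.full((3, 3), 1.9)
        np.fill_diagonal(d, 0.0)
        target = rdm.RDM(labels=list("abc"), d=d)
        with pytest.raises(ValueError, match="not correlation-realizable"):
            synth.embed_geometry(target, 30, np.arange(30), seed=0)


class TestSimulateBold:
    def test_default_tr_is_two_seconds(self):
        d = synth.make_event_design({"word": 4, "pseudoword": 4}, seed=0)
        assert d.tr == 2.0
        vol = synth.simulate_bold(d, None, shape=(8, 8, 8), noise_sd=0.1,
                                  seed=0)
        assert vol.tr == 2.0

    def test_noise_free_data_is_exact_design_times_pattern(self):
        shape = (8, 8, 8)
        mask = np.ones(shape, dtype=bool)
        labels = [f"w{i}" for i in range(4)]
        target = synth.grouped_rdm(4, n_groups=2, labels=labels)
        roi = np.arange(30)
        pat = synth.embed_geometry(target, 30, roi, seed=1)
        design = synth.EventDesign(
            onsets=np.arange(4) * 20.0 + 4.0,
            durations=np.full(4, 2.4),
            conditions=np.array(labels, dtype=object),
            run_length=100.0, tr=2.0,
        )
        vol = synth.simulate_bold(design, pat, shape=shape, mask=mask,
                                  noise_sd=0.0, seed=0)
        x = glm.task_regressors(design, labels, 50, 2.0)
        expected = np.zeros((512, 50))
        expected[roi] = (x @ pat.patterns).T
        assert np.abs(vol.data.reshape(512, 50) - expected).max() < 1e-12

    def test_ar1_noise_lag_one_autocorrelation(self):
        noise = synth.ar1_noise(10_000, 1, phi=0.4, sd=1.0, rng=0)[:, 0]
        r = np.corrcoef(noise[1:], noise[:-1])[0, 1]
        se = 1.0 / np.sqrt(noise.size)  # asymptotic SE of a lag-1 autocorr
        assert abs(r - 0.4) < 3 * se

    def test_seed_reproducibility(self):
        d = synth.make_block_design("visual")
        a = synth.simulate_bold(d, None, shape=(6, 6, 6), seed=5)
        b = synth.simulate_bold(d, None, shape=(6, 6, 6), seed=5)
        c = synth.simulate_bold(d, None, shape=(6, 6, 6), seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


class TestPseudowords:
    @pytest.mark.parametrize("word", ["melancholie", "Flashback",
                                      "Konditionierung"])
    def test_length_preserved_and_two_substitutions(self, word):
        pw = synth.generate_pseudoword(word, seed=1)
        assert len(pw) == len(word)
        diffs = [i for i, (a, b) in enumerate(zip(word, pw)) if a != b]
        assert len(diffs) == 2
        classes = sorted(
            "vowel" if word[i].lower() in synth.VOWELS else "consonant"
            for i in diffs
        )
        assert classes == ["consonant", "vowel"]
        # substitutions stay within their letter class
        for i in diffs:
            assert (word[i].lower() in synth.VOWELS) == \
                (pw[i].lower() in synth.VOWELS)

    def test_word_without_consonant_fails(self):
        with pytest.raises(ValueError, match="consonant"):
            synth.generate_pseudoword("aaa", seed=0)


class TestSequenceOk:
    @pytest.mark.parametrize("labels,max_run,expected", [
        (["W", "W", "W", "W"], 3, False),
        (["W", "P", "W", "P"], 3, True),
        (["W", "W", "W", "P"], 3, True),
        ([], 3, True),
    ])
    def test_examples(self, labels, max_run, expected):
        assert synth.sequence_ok(labels, max_run) is expected


class TestLengthMatch:
    def test_identical_lists_give_zero(self):
        res = synth.length_match_test([3, 4, 5], [3, 4, 5])
        assert res.t == 0.0

    def test_closed_form_oracle(self):
        a, b = np.array([3.0, 4.0, 5.0]), np.array([4.0, 5.0, 6.0])
        res = synth.length_match_test(a, b)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert abs(res.t - t_hand) < 1e-12
        assert res.df == 4

    def test_zero_variance_equal_means_convention(self):
        res = synth.length_match_test([5, 5, 5], [5, 5])
        assert res.t == 0.0
        assert res.p == 1.0
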