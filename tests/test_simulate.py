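"""Generator tests: schedule constraints, RT model, items, ratings."""

import numpy as np
import pandas as pd
import pytest

from rtcit import DesignSpec, TraitModelConfig, simulate_cohort
from rtcit.scales import cronbach_alpha
from rtcit.simulate import (BIS11, LSRP_SECONDARY, ScaleDefinition,
                            default_latent_correlation, disattenuate,
                            generate_item_responses, generate_ratings,
                            generate_rts, generate_schedule, sample_traits)


def _no_adjacent_repeats(items: np.ndarray) -> bool:
    return not np.any(items[1:] == items[:-1])


class TestSchedule:
    @pytest.mark.parametrize("seed", range(10))
    def test_default_schedule_structure(self, seed, default_design):
        sched = generate_schedule(default_design, np.random.default_rng(seed))
        assert len(sched) == 336
        assert sched["item_id"].nunique() == 14
        per_block = sched.groupby(["block", "item_id"]).size()
        assert (per_block == 6).all()
        assert _no_adjacent_repeats(sched["item_id"].to_numpy())
        assert sched["isi_ms"].isin(default_design.isi_options_ms).all()
        assert (sched["trial_index"] == np.arange(1, 337)).all()

    def test_single_rep_schedule(self):
        d = DesignSpec(reps_per_block=1, n_blocks=1)
        sched = generate_schedule(d, np.random.default_rng(0))
        assert len(sched) == 14
        assert sched["item_id"].is_unique

    def test_infeasible_design_raises(self):
        d = DesignSpec(n_probes=1, n_irrelevants=0, n_targets=0, n_nogo=0,
                       reps_per_block=3)
        with pytest.raises((ValueError, RuntimeError)):
            generate_schedule(d, np.random.default_rng(0))

    def test_reproducible(self, default_design):
        a = generate_schedule(default_design, np.random.default_rng(9))
        b = generate_schedule(default_design, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)


class TestTraits:
    def test_identity_latents_uncorrelated(self):
        cfg = TraitModelConfig(latent_correlation=np.eye(4))
        traits = sample_traits(10_000, cfg, np.random.default_rng(1))
        z = np.array([[t.z_primary, t.z_secondary, t.z_impulsivity,
                       t.z_inhibition] for t in traits])
        off = np.corrcoef(z.T) - np.eye(4)
        assert np.abs(off).max() < 0.04  # ~4 / sqrt(n)

    def test_disattenuation_formula(self):
        assert disattenuate(0.516, 0.63, 0.84) == pytest.approx(0.7093, abs=5e-4)
        with pytest.raises(ValueError):
            disattenuate(0.9, 0.3, 0.3)

    def test_default_latent_matrix_valid(self):
        m = default_latent_correlation()
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() > 0
        assert m[1, 2] == pytest.approx(0.7093, abs=5e-4)

    def test_probe_shift_distribution(self):
        traits = sample_traits(2000, rng=np.random.default_rng(3))
        shifts = np.array([t.probe_shift_ms for t in traits])
        se = 32.43 / np.sqrt(len(shifts))
        assert abs(shifts.mean() - 54.91) < 3 * se
        assert shifts.std(ddof=1) == pytest.approx(32.43, rel=0.1)

    def test_probe_shift_independent_of_latents_by_default(self):
        traits = sample_traits(10_000, rng=np.random.default_rng(4))
        shifts = np.array([t.probe_shift_ms for t in traits])
        for attr in ("z_secondary", "z_impulsivity", "z_inhibition"):
            z = np.array([getattr(t, attr) for t in traits])
            assert abs(np.corrcoef(shifts, z)[0, 1]) < 0.04

    def test_non_psd_matrix_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ValueError):
            TraitModelConfig(latent_correlation=bad)


class TestReactionTimes:
    def test_exgaussian_mean_is_mu_plus_tau(self, default_design):
        # huge deadline removes truncation; mean go RT must equal mu + tau
        cfg = TraitModelConfig(probe_shift_mean_ms=0, probe_shift_sd_ms=1e-9,
                               error_prob_go=0.0)
        traits = sample_traits(1, cfg, np.random.default_rng(5))[0]
        d = DesignSpec(stim_duration_ms=1e7, deadline_ms=1e6, n_blocks=4)
        rng = np.random.default_rng(6)
        rts = []
        for _ in range(40):
            sched = generate_schedule(d, rng)
            out = generate_rts(sched, traits, d, rng)
            rts.append(out.loc[out["stim_type"] == "irrelevant", "rt_ms"])
        rt = pd.concat(rts)
        expected = traits.base_mu_ms + traits.base_tau_ms
        assert rt.mean() == pytest.approx(expected, abs=3 * rt.std() / np.sqrt(len(rt)))
        within_sd = np.hypot(traits.base_sigma_ms, traits.base_tau_ms)
        assert rt.std() == pytest.approx(within_sd, rel=0.05)

    def test_null_probe_shift_gives_null_effect(self):
        cfg = TraitModelConfig(probe_shift_mean_ms=0.0, probe_shift_sd_ms=1e-9)
        cohort = simulate_cohort(150, config=cfg, seed=31)
        t = cohort["trials"]
        go = t[t["rt_ms"].notna()]
        probe = go.loc[go["stim_type"] == "probe", "rt_ms"]
        irr = go.loc[go["stim_type"] == "irrelevant", "rt_ms"]
        se = np.hypot(probe.std() / np.sqrt(len(probe)),
                      irr.std() / np.sqrt(len(irr)))
        assert abs(probe.mean() - irr.mean()) < 3 * se

    def test_trial_record_contract(self, small_cohort, default_design):
        t = small_cohort["trials"]
        # rt present iff a response was recorded; rt within (0, stim duration]
        assert (t["rt_ms"].notna() == (t["response"] != "none")).all()
        pressed = t["rt_ms"].dropna()
        assert (pressed > 0).all()
        assert (pressed <= default_design.stim_duration_ms).all()
        # correctness rules per stimulus type
        nogo = t[t["stim_type"] == "nogo"]
        assert (nogo["correct"] == (nogo["response"] == "none")).all()
        tgt = t[t["stim_type"] == "target"]
        assert (tgt["correct"] == (tgt["response"] == "familiar")).all()

    def test_commission_rate_tracks_trait(self):
        cohort = simulate_cohort(200, seed=77)
        t, traits = cohort["trials"], cohort["traits"]
        nogo = t[t["stim_type"] == "nogo"]
        rate = (nogo.groupby("participant_id")["rt_ms"]
                .apply(lambda s: s.notna().mean()))
        merged = traits.set_index("participant_id").join(rate.rename("rate"))
        # empirical commission rate follows the latent probability
        assert np.corrcoef(merged["commission_prob"], merged["rate"])[0, 1] > 0.8


class TestItemResponses:
    def test_near_parallel_items_high_alpha(self):
        scale = ScaleDefinition("toy", 10, "secondary", alpha=0.98)
        traits = sample_traits(2000, rng=np.random.default_rng(8))
        items = generate_item_responses(traits, scale, np.random.default_rng(8))
        assert cronbach_alpha(items.drop(columns="participant_id")) > 0.9

    def test_independent_items_zero_alpha(self):
        scale = ScaleDefinition("toy", 10, "secondary", alpha=0.02)
        traits = sample_traits(3000, rng=np.random.default_rng(9))
        items = generate_item_responses(traits, scale, np.random.default_rng(9))
        assert abs(cronbach_alpha(items.drop(columns="participant_id"))) < 0.15

    @pytest.mark.parametrize("scale,target", [(LSRP_SECONDARY, 0.63),
                                              (BIS11, 0.84)])
    def test_alpha_recovery(self, scale, target):
        traits = sample_traits(5000, rng=np.random.default_rng(10))
        items = generate_item_responses(traits, scale, np.random.default_rng(10))
        alpha = cronbach_alpha(items.drop(columns="participant_id"))
        assert alpha == pytest.approx(target, abs=0.05)

    def test_responses_in_likert_range(self, small_cohort):
        q = small_cohort["questionnaire"]
        items = q[[c for c in q.columns if "_item_" in c]]
        assert items.min().min() >= 1 and items.max().max() <= 4
        assert len([c for c in q.columns if c.startswith("lsrp_item_")]) == 26
        assert len([c for c in q.columns if c.startswith("bis_item_")]) == 30


class TestRatings:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ratings_within_scales(self, seed):
        traits = sample_traits(300, rng=np.random.default_rng(seed))
        r = generate_ratings(traits, np.random.default_rng(seed))
        assert r["rating_probe_significance"].between(1, 9).all()
        assert r["rating_irrelevant_significance"].between(1, 9).all()
        assert r["rating_motivation"].between(1, 10).all()
        assert r["rating_impulsivity"].between(1, 10).all()

    def test_probe_significance_mean(self):
        traits = sample_traits(5000, rng=np.random.default_rng(13))
        r = generate_ratings(traits, np.random.default_rng(13))
        x = r["rating_probe_significance"]
        # latent mean is calibrated so the observed mean hits the target
        assert x.mean() == pytest.approx(8.58, abs=3 * x.std() / np.sqrt(len(x)))

    def test_equal_means_give_null_difference(self):
        cfg = TraitModelConfig(rating_probe_significance=(5.0, 1.0),
                               rating_irrelevant_significance=(5.0, 1.0))
        traits = sample_traits(4000, rng=np.random.default_rng(14))
        r = generate_ratings(traits, np.random.default_rng(14), cfg)
        diff = (r["rating_probe_significance"]
                - r["rating_irrelevant_significance"])
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff))


def test_cohort_reproducible():
    a = simulate_cohort(5, seed=99)
    b = simulate_cohort(5, seed=99)
    for key in ("trials", "questionnaire", "traits"):
        pd.testing.assert_frame_equal(a[key], b[key])
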