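"""Synthetic sentences, cohorts and transcripts with known ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as spsig

from speechrestore import (CohortSpec, KeywordList, RestorationModel,
                           ScoringRules, SentenceSpec, score_response,
                           simulate_cohort, simulate_transcripts,
                           simulate_trial_logs, synth_sentence,
                           synthetic_dst_norms)
from speechrestore.cognitive import score_trial_log
from speechrestore.simulate import ABILITIES, CONDITIONS, DEFAULT_BETAS


class TestSynthSentence:
    def test_length_and_rate(self):
        audio, kl = synth_sentence(SentenceSpec(duration_s=1.5, sample_rate=8000.0))
        assert len(audio) == 12000
        assert audio.sample_rate == 8000.0
        assert len(kl.keywords) >= 4

    def test_seed_determinism(self):
        a, ka = synth_sentence(SentenceSpec(seed=5))
        b, kb = synth_sentence(SentenceSpec(seed=5))
        c, _ = synth_sentence(SentenceSpec(seed=6))
        assert np.array_equal(a.samples, b.samples)
        assert ka.keywords == kb.keywords
        assert not np.array_equal(a.samples, c.samples)

    def test_psd_peaks_near_formants(self):
        spec = SentenceSpec(duration_s=4.0, seed=1)
        audio, _ = synth_sentence(spec)
        freqs, psd = spsig.welch(audio.samples, audio.sample_rate, nperseg=4096)
        for f in spec.formants_hz:
            window = (freqs > f - 150) & (freqs < f + 150)
            peak = freqs[window][np.argmax(psd[window])]
            assert abs(peak - f) < 50.0

    def test_invalid_spectral_layout_rejected(self):
        with pytest.raises(ValueError):
            SentenceSpec(f0_hz=600.0, formants_hz=(500.0,))
        with pytest.raises(ValueError):
            SentenceSpec(formants_hz=(9000.0,), sample_rate=16000.0)


class TestSimulateCohort:
    def test_null_betas_give_no_ability_score_correlation(self):
        spec = CohortSpec(n=2000, betas={c: [0.0] * 4 for c in CONDITIONS}, seed=9)
        df = simulate_cohort(spec)
        for cond in CONDITIONS:
            r = np.corrcoef(df["z_rst"], df[cond])[0, 1]
            assert abs(r) < 0.1

    def test_latent_correlation_structure_recovered(self):
        spec = CohortSpec(n=5000, seed=2)
        df = simulate_cohort(spec)
        z = df[[f"z_{a}" for a in ABILITIES]].to_numpy()
        sample_corr = np.corrcoef(z.T)
        assert np.max(np.abs(sample_corr - spec.ability_corr)) < 0.05

    def test_scores_bounded_and_complete(self):
        df = simulate_cohort(CohortSpec(n=63, seed=3))
        for cond in CONDITIONS:
            assert df[cond].between(0, 100).all()
        assert not df.isna().any().any()
        assert len(df) == 63

    def test_parameter_recovery_within_two_se(self):
        """OLS on generated cohorts recovers each beta within 2 SE >= 93%.

        200 replicates at the default cohort size; each replicate's target
        is the generative effect expressed per sample SD of the observed
        measure (the parameterization a z-scored regression estimates).
        """
        from speechrestore.simulate import _MEASURE_MAPS

        cond = "rspin_high_silent"
        predictors = ["rst_percent", "stroop_interference",
                      "stroop_speed_ms", "lextale_percent"]
        true_beta = dict(zip(predictors, DEFAULT_BETAS[cond]))
        map_sd = {v[0]: v[2] for v in _MEASURE_MAPS.values()}
        hits = {p: 0 for p in predictors}
        n_reps = 200
        for seed in range(n_reps):
            df = simulate_cohort(CohortSpec(n=63, seed=seed))
            fit = RestorationModel.from_dataframe(df, cond, predictors).fit()
            for p in predictors:
                target = true_beta[p] * df[p].std(ddof=1) / map_sd[p]
                if abs(fit.params[p] - target) <= 2.0 * fit.bse[p]:
                    hits[p] += 1
        for p, h in hits.items():
            assert h / n_reps >= 0.93, f"{p}: coverage {h / n_reps:.3f}"

    def test_non_positive_definite_correlation_rejected(self):
        bad = np.array([
            [1.0, 0.99, -0.99, 0.0],
            [0.99, 1.0, 0.99, 0.0],
            [-0.99, 0.99, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ])
        with pytest.raises(ValueError):
            CohortSpec(ability_corr=bad)


class TestSimulateTranscripts:
    KLS = [KeywordList(f"s{i}", ("attack", "garden", "don't", "ball"))
           for i in range(60)]

    def _mean_score(self, p_report, p_typo, seed=0):
        df = simulate_transcripts(self.KLS, p_report, p_typo, seed)
        total = correct = 0
        for row, kl in zip(df.itertuples(), self.KLS):
            res = score_response(kl, row.transcript, ScoringRules())
            total += res.n_keywords
            correct += res.n_correct
        return 100.0 * correct / total

    def test_full_report_no_typos_scores_100(self):
        assert self._mean_score(1.0, 0.0) == pytest.approx(100.0)

    def test_zero_report_scores_0(self):
        assert self._mean_score(0.0, 0.5) == pytest.approx(0.0)

    def test_generator_scorer_rule_closure(self):
        """Typos never cost points: score depends only on p_report."""
        assert self._mean_score(1.0, 1.0) == pytest.approx(100.0)

    def test_binomial_expectation(self):
        # 60 sentences x 4 keywords = 240 Bernoulli(0.6) draws
        score = self._mean_score(0.6, 0.5, seed=4)
        se = 100.0 * np.sqrt(0.6 * 0.4 / 240)
        assert score == pytest.approx(60.0, abs=4 * se)

    def test_seed_determinism(self):
        a = simulate_transcripts(self.KLS, 0.5, 0.3, seed=7)
        b = simulate_transcripts(self.KLS, 0.5, 0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_transcripts(self.KLS, 1.5, 0.0, seed=0)


class TestSimulateTrialLogs:
    def test_scoring_recovers_cohort_measures(self):
        """The task scorers applied to generated logs reproduce the table."""
        cohort = simulate_cohort(CohortSpec(n=8, seed=11))
        logs = simulate_trial_logs(cohort, seed=13)
        norms = synthetic_dst_norms()
        scored = score_trial_log(logs, norms)
        merged = scored.join(cohort, rsuffix="_true")
        assert np.allclose(merged["rst_percent"], merged["rst_percent_true"], atol=2.0)
        assert np.allclose(merged["stroop_speed_ms"], merged["stroop_speed_ms_true"], atol=1e-6)
        assert np.allclose(merged["stroop_interference"],
                           merged["stroop_interference_true"], atol=1e-9)
        assert np.allclose(merged["flanker_interference_ms"],
                           merged["flanker_interference_ms_true"], atol=1e-6)
        assert np.allclose(merged["lextale_percent"], merged["lextale_percent_true"], atol=2.0)
        # percentile comes back through the norm table: nearest entry
        assert np.allclose(merged["dst_percentile"], merged["dst_percentile_true"], atol=8.0)

    def test_qualitative_condition_ordering(self):
        """Noise beats silent within a set; high beats low context (means)."""
        df = simulate_cohort(CohortSpec(n=63, seed=21))
        assert df["rspin_high_noise"].mean() > df["rspin_high_silent"].mean()
        assert df["rspin_low_noise"].mean() > df["rspin_low_silent"].mean()
        assert df["presto_noise"].mean() > df["presto_silent"].mean()
        assert df["rspin_high_silent"].mean() > df["rspin_low_silent"].mean()
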