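"""Noisy label filter: stopping rule, flagging, outcome policies."""

import pytest

from screensieve import (
    Corpus,
    Label,
    ModelSpec,
    NLFConfig,
    Record,
    SynthConfig,
    apply_outcome,
    generate,
    oracle_screener,
    run_nlf,
)
from screensieve.nlf import ScreenerError


def all_irrelevant(record):
    return Label.IRRELEVANT


def _noisy_corpus(n=120, n_relevant=5, seed=0, planted=0, s=0.0):
    return generate(SynthConfig(
        n_records=n, n_relevant=n_relevant, signal_strength=s,
        n_planted_additional_relevant=planted, seed=seed,
    ))


class TestStoppingRule:
    def test_all_irrelevant_oracle_stops_at_exactly_x(self):
        corpus, _ = _noisy_corpus(n=200)
        cfg = NLFConfig(consecutive_irrelevant_stop=50,
                        model=ModelSpec("naive_bayes"), seed=1)
        result = run_nlf(corpus, cfg, all_irrelevant)
        assert len(result.trace.steps) == 50
        assert result.stop_reason == "consecutive_irrelevant"
        assert all(lab is Label.IRRELEVANT for _, lab in result.trace.steps)

    def test_small_pool_exhausts(self):
        corpus, _ = _noisy_corpus(n=35, n_relevant=5)  # 30 noisy - 5 priors
        cfg = NLFConfig(consecutive_irrelevant_stop=50, seed=1)
        result = run_nlf(corpus, cfg, all_irrelevant)
        assert result.stop_reason == "pool_exhausted"
        assert len(result.trace.steps) == 25

    def test_budget_stop(self):
        corpus, _ = _noisy_corpus(n=200)
        cfg = NLFConfig(consecutive_irrelevant_stop=50, record_budget=10, seed=1)
        result = run_nlf(corpus, cfg, all_irrelevant)
        assert result.stop_reason == "budget"
        assert len(result.trace.steps) == 10

    def test_rule_is_tight_and_resets_on_relevant(self):
        """A relevant label resets the run; truncating the trace by one
        record never satisfies the rule."""
        corpus, truth = _noisy_corpus(n=300, planted=2, s=0.9, seed=4)
        x = 30
        cfg = NLFConfig(consecutive_irrelevant_stop=x,
                        model=ModelSpec("naive_bayes"), seed=4)
        result = run_nlf(corpus, cfg, oracle_screener(truth))
        assert result.stop_reason == "consecutive_irrelevant"
        labels = [lab for _, lab in result.trace.steps]
        assert all(lab is Label.IRRELEVANT for lab in labels[-x:])
        # no earlier point satisfies the rule
        run = 0
        for lab in labels[:-1]:
            run = 0 if lab is Label.RELEVANT else run + 1
            assert run < x
        assert len(result.trace.steps) >= x

    def test_trace_never_shorter_than_x_when_rule_fires(self):
        for seed in range(3):
            corpus, truth = _noisy_corpus(n=250, planted=3, s=0.8, seed=seed)
            cfg = NLFConfig(consecutive_irrelevant_stop=20, seed=seed)
            result = run_nlf(corpus, cfg, oracle_screener(truth))
            if result.stop_reason == "consecutive_irrelevant":
                assert len(result.trace.steps) >= 20


class TestTrainingSetConstruction:
    def test_requires_relevant_records(self):
        corpus = Corpus([Record("a", title="x", label=Label.NOISY),
                         Record("b", title="y", label=Label.NOISY)])
        with pytest.raises(ValueError, match="RELEVANT"):
            run_nlf(corpus, NLFConfig(seed=0), all_irrelevant)

    def test_requires_noisy_records(self):
        corpus = Corpus([Record("a", title="x", label=Label.RELEVANT)])
        with pytest.raises(ValueError, match="NOISY"):
            run_nlf(corpus, NLFConfig(seed=0), all_irrelevant)

    def test_priors_never_screened_never_promoted(self):
        corpus, _ = _noisy_corpus(n=150)
        cfg = NLFConfig(n_random_irrelevant_priors=5,
                        consecutive_irrelevant_stop=30, seed=2)
        result = run_nlf(corpus, cfg, all_irrelevant)
        assert len(result.presumed_irrelevant_priors) == 5
        screened = {rid for rid, _ in result.trace.steps}
        assert screened.isdisjoint(result.presumed_irrelevant_priors)
        # priors keep their NOISY label in the output corpus (unscreened)
        for rid in result.presumed_irrelevant_priors:
            assert result.output_corpus[rid].label is Label.NOISY

    def test_screener_failure_preserves_partial_trace(self):
        corpus, _ = _noisy_corpus(n=100)
        calls = []

        def flaky(record):
            if len(calls) >= 3:
                raise RuntimeError("screener went home")
            calls.append(record.record_id)
            return Label.IRRELEVANT

        with pytest.raises(ScreenerError) as exc_info:
            run_nlf(corpus, NLFConfig(seed=3), flaky)
        assert len(exc_info.value.partial_steps) == 3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NLFConfig(consecutive_irrelevant_stop=0)
        with pytest.raises(ValueError):
            NLFConfig(n_random_irrelevant_priors=0)


class TestPlantedRecovery:
    def test_planted_relevant_flagged_before_stop(self):
        """Planted signal-carrying records surface before the rule fires."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            corpus, truth = generate(SynthConfig(
                n_records=400, n_relevant=10, signal_strength=0.6,
                n_planted_additional_relevant=3, seed=seed,
            ))
            cfg = NLFConfig(consecutive_irrelevant_stop=50,
                            model=ModelSpec("naive_bayes", seed=seed),
                            seed=seed)
            result = run_nlf(corpus, cfg, oracle_screener(truth))
            if set(result.flagged_relevant) \
                    == set(truth.planted_additional_relevant_ids):
                hits += 1
        assert hits >= n_seeds - 1


class TestApplyOutcome:
    def _result(self, planted=2, seed=5):
        corpus, truth = _noisy_corpus(n=200, n_relevant=6, planted=planted,
                                      s=0.9, seed=seed)
        cfg = NLFConfig(consecutive_irrelevant_stop=25, seed=seed)
        return run_nlf(corpus, cfg, oracle_screener(truth)), corpus

    def test_all_noisy_resolved(self):
        result, corpus = self._result()
        out = apply_outcome(result, {rid: "mark_irrelevant"
                                     for rid in result.flagged_relevant})
        counts = out.label_counts()
        assert counts[Label.NOISY] == 0
        assert len(out) == len(corpus)

    def test_mark_irrelevant_bookkeeping(self):
        """Flagged records marked irrelevant leave relevant count unchanged."""
        result, corpus = self._result()
        n_rel = len(corpus.ids_with_label(Label.RELEVANT))
        out = apply_outcome(result, {rid: "mark_irrelevant"
                                     for rid in result.flagged_relevant})
        counts = out.label_counts()
        assert counts[Label.RELEVANT] == n_rel
        assert counts[Label.IRRELEVANT] == len(corpus) - n_rel

    def test_keep_relevant_increments(self):
        result, corpus = self._result()
        assert result.flagged_relevant
        n_rel = len(corpus.ids_with_label(Label.RELEVANT))
        out = apply_outcome(result, {rid: "keep_relevant"
                                     for rid in result.flagged_relevant})
        assert len(out.ids_with_label(Label.RELEVANT)) \
            == n_rel + len(result.flagged_relevant)

    def test_remove_drops_records(self):
        result, corpus = self._result()
        out = apply_outcome(result, {rid: "remove"
                                     for rid in result.flagged_relevant})
        assert len(out) == len(corpus) - len(result.flagged_relevant)
        assert all(rid not in out for rid in result.flagged_relevant)

    def test_zero_flagged_all_noisy_to_irrelevant(self):
        corpus, _ = _noisy_corpus(n=150)
        cfg = NLFConfig(consecutive_irrelevant_stop=20, seed=6)
        result = run_nlf(corpus, cfg, all_irrelevant)
        assert result.flagged_relevant == []
        out = apply_outcome(result, {})
        counts = out.label_counts()
        assert counts[Label.NOISY] == 0
        assert counts[Label.RELEVANT] \
            == len(corpus.ids_with_label(Label.RELEVANT))

    def test_policy_must_cover_flagged(self):
        result, _ = self._result()
        assert result.flagged_relevant
        with pytest.raises(ValueError, match="policy missing"):
            apply_outcome(result, {})

    def test_case_study_bookkeeping(self):
        """A 1053-record corpus with 20 relevant and 4 flagged-irrelevant
        resolves to 20 relevant / 1033 irrelevant."""
        corpus, truth = generate(SynthConfig(
            n_records=1053, n_relevant=20, signal_strength=0.8,
            n_planted_additional_relevant=4, seed=8,
        ))
        cfg = NLFConfig(consecutive_irrelevant_stop=50,
                        model=ModelSpec("naive_bayes", seed=8), seed=8)
        result = run_nlf(corpus, cfg, oracle_screener(truth))
        out = apply_outcome(result, {rid: "mark_irrelevant"
                                     for rid in result.flagged_relevant})
        counts = out.label_counts()
        assert counts[Label.RELEVANT] == 20
        assert counts[Label.IRRELEVANT] == 1033
        assert counts[Label.NOISY] == 0
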