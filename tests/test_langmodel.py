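"""Stratified n-gram model: counts, back-off recursion, perplexity, sampling."""

import json
import math

import numpy as np
import pytest
from scipy.stats import chisquare

import chemdesign as cd
from chemdesign.chemstring import TokenSequence

# ---------------------------------------------------------------------------
# Independent oracle: a from-scratch recount with its own contraction and
# condition logic (batch, quadratic), against which cond_prob is checked.
# ---------------------------------------------------------------------------


def _oracle_condition(seq, upto):
    branch = 0
    open_marks = 0
    for i in range(upto):
        tok = seq.tokens[i]
        if tok == "(":
            branch += 1
        elif tok == ")":
            branch -= 1
        elif tok.endswith("&"):
            # a mark is open iff its partner lies outside the prefix
            j = seq.ring_pairs.get(i)
            if j is None or j >= upto:
                open_marks += 1
    return (branch > 0, min(open_marks, 9))


def _oracle_contract(tokens):
    """Batch contraction: innermost-first reduction of closed paren groups."""
    toks = list(tokens)
    changed = True
    while changed:
        changed = False
        stack = []
        for i, t in enumerate(toks):
            if t == "(":
                stack.append(i)
            elif t == ")" and stack:
                start = stack.pop()
                if i - start > 2:  # more than one inner token: reduce
                    toks = toks[: start + 2] + toks[i:]
                    changed = True
                    break
    return toks


def _oracle_cond_prob(corpus, n_max, next_tok, prefix_seq, vocab):
    for n in range(n_max, 0, -1):
        ctx = tuple((["^"] * (n - 1) + _oracle_contract(prefix_seq.tokens))[-(n - 1):]) if n > 1 else ()
        cond = _oracle_condition(prefix_seq, len(prefix_seq))
        hits = {}
        for seq in corpus:
            for i, tok in enumerate(seq.tokens):
                c = _oracle_condition(seq, i)
                sctx = tuple((["^"] * (n - 1) + _oracle_contract(seq.tokens[:i]))[-(n - 1):]) if n > 1 else ()
                if c == cond and sctx == ctx:
                    hits[tok] = hits.get(tok, 0) + 1
        total = sum(hits.values())
        if total > 0:
            return hits.get(next_tok, 0) / total
    return 1.0 / len(vocab)


class TestCounts:
    def test_bigram_hand_count(self):
        model = cd.fit_from_smiles(["CC", "CO"], 2)
        c = cd.TokenSequence(["C"])
        assert model.cond_prob("C", c) == pytest.approx(1 / 3)
        assert model.cond_prob("O", c) == pytest.approx(1 / 3)
        assert model.cond_prob("$", c) == pytest.approx(1 / 3)

    def test_single_string_chain_is_deterministic(self):
        model = cd.fit_from_smiles(["CC"], 3)
        assert model.cond_prob("C", cd.TokenSequence([])) == 1.0
        assert model.cond_prob("C", cd.TokenSequence(["C"])) == 1.0
        assert model.cond_prob("$", cd.TokenSequence(["C", "C"])) == 1.0

    def test_unigram_model_is_frequency_table(self):
        model = cd.fit_from_smiles(["CC", "CO"], 1)
        # six tokens total in "CC$", "CO$": C x3, O x1, $ x2
        empty = cd.TokenSequence([])
        assert model.cond_prob("C", empty) == pytest.approx(3 / 6)
        assert model.cond_prob("$", empty) == pytest.approx(2 / 6)

    def test_requires_complete_sequences(self):
        with pytest.raises(ValueError):
            cd.fit_ngram([TokenSequence(["C", "C"])], 2)
        with pytest.raises(ValueError):
            cd.fit_ngram([], 2)


class TestCondProb:
    def test_matches_bruteforce_oracle(self, toy_corpus):
        corpus = [cd.tokenize(s) for s in toy_corpus[:20]]
        for n_max in (2, 3, 5):
            model = cd.fit_ngram(corpus, n_max)
            rng = np.random.default_rng(n_max)
            for _ in range(25):
                seq = corpus[rng.integers(len(corpus))]
                cut = int(rng.integers(0, len(seq)))
                prefix = seq.truncate(cut)
                tok = model.vocab[rng.integers(len(model.vocab))]
                got = model.cond_prob(tok, prefix)
                want = _oracle_cond_prob(corpus, n_max, tok, prefix, model.vocab)
                assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("smoothing", ["backoff", "kneser_ney"])
    def test_normalization(self, toy_tokens, smoothing):
        """Conditional distributions sum to one in every stratum and order."""
        model = cd.fit_ngram(toy_tokens[:200], 4, smoothing=smoothing)
        rng = np.random.default_rng(0)
        for _ in range(200):
            seq = toy_tokens[rng.integers(200)]
            prefix = seq.truncate(int(rng.integers(0, len(seq))))
            _, dist = model.conditional_distribution(prefix)
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)
            assert (dist >= 0).all()

    def test_unseen_context_uniform_base_case(self):
        model = cd.fit_from_smiles(["CC"], 2)
        # context 'O' never seen at any order/stratum in any condition with
        # rings open -> uniform over the 2-token vocabulary {C, $}
        weird = cd.tokenize("C1CC1").truncate(2)  # has an open ring mark
        for tok in model.vocab:
            assert model.cond_prob(tok, weird) == pytest.approx(1 / len(model.vocab))

    def test_out_of_vocab_token_warns_and_is_zero(self, lm_n5):
        with pytest.warns(UserWarning):
            assert lm_n5.cond_prob("[Xe]", cd.TokenSequence(["C"])) == 0.0

    def test_backoff_consistency_dropping_top_order(self, toy_tokens):
        """Clearing the order-n table reproduces the order-(n-1) model exactly."""
        corpus = toy_tokens[:100]
        m4 = cd.fit_ngram(corpus, 4)
        m3 = cd.fit_ngram(corpus, 3)
        m4.tables[3] = {}
        m4._rebuild_caches()
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = corpus[rng.integers(len(corpus))]
            prefix = seq.truncate(int(rng.integers(0, len(seq))))
            tok = m4.vocab[rng.integers(len(m4.vocab))]
            assert m4.cond_prob(tok, prefix) == m3.cond_prob(tok, prefix)

    def test_kneser_ney_no_zero_for_vocabulary(self, toy_tokens):
        model = cd.fit_ngram(toy_tokens[:100], 3, smoothing="kneser_ney")
        _, dist = model.conditional_distribution(cd.TokenSequence(["C", "C"]))
        assert (dist > 0).all()


class TestSequenceProb:
    def test_memorized_string_has_probability_one(self):
        model = cd.fit_from_smiles(["CC"], 3)
        assert model.sequence_logprob(cd.tokenize("CC")) == pytest.approx(0.0)
        assert model.perplexity([cd.tokenize("CC")]) == pytest.approx(1.0)

    def test_prob_is_exp_of_logprob(self, lm_n5, toy_tokens):
        seq = toy_tokens[0]
        assert lm_n5.sequence_prob(seq) == pytest.approx(
            math.exp(lm_n5.sequence_logprob(seq))
        )

    def test_chain_rule_sums_over_one_token_extensions(self, lm_n5, toy_tokens):
        """P(prefix) mass splits exactly across all one-token continuations."""
        seq = toy_tokens[3]
        prefix = seq.truncate(4)
        _, dist = lm_n5.conditional_distribution(prefix)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unseen_string_flagged_minus_inf(self):
        model = cd.fit_from_smiles(["CC"], 2)
        with pytest.warns(UserWarning):
            lp = model.sequence_logprob(cd.tokenize("CON"))
        assert lp == -math.inf
        with pytest.warns(UserWarning):
            assert model.perplexity([cd.tokenize("CC"), cd.tokenize("CON")]) == math.inf

    def test_perplexity_is_per_string_average(self, toy_tokens):
        model = cd.fit_ngram(toy_tokens[:50], 3)
        logps = [model.sequence_logprob(s) for s in toy_tokens[:50]]
        assert model.perplexity(toy_tokens[:50]) == pytest.approx(
            math.exp(-np.mean(logps))
        )


class TestGeneration:
    def test_deterministic_corpus_reproduced(self):
        model = cd.fit_from_smiles(["CC"], 3)
        seq = model.generate(None, 10, np.random.default_rng(0))
        assert seq.tokens == ["C", "C", "$"]

    def test_max_tokens_zero_returns_seed(self, lm_n5):
        seed = cd.TokenSequence(["C", "C"])
        out = lm_n5.generate(seed, 0, np.random.default_rng(0))
        assert out.tokens == ["C", "C"]

    def test_seeded_reproducibility(self, lm_n5):
        a = lm_n5.generate(None, 60, np.random.default_rng(9)).tokens
        b = lm_n5.generate(None, 60, np.random.default_rng(9)).tokens
        assert a == b

    def test_unigram_sampling_matches_training_frequencies(self, toy_tokens):
        """n=1 generation reproduces the corpus unigram distribution (chi^2)."""
        model = cd.fit_ngram(toy_tokens[:200], 1)
        # training unigram distribution of the no-branch/no-ring stratum, the
        # stratum an empty prefix activates (counted independently)
        counts = {}
        for seq in toy_tokens[:200]:
            for i, tok in enumerate(seq.tokens):
                if _oracle_condition(seq, i) == (False, 0):
                    counts[tok] = counts.get(tok, 0) + 1
        total = sum(counts.values())
        rng = np.random.default_rng(2)
        draws = {t: 0 for t in model.vocab}
        n_draws = 10_000
        tracker_seed = cd.TokenSequence([])
        for _ in range(n_draws):
            seq = model.generate(tracker_seed, 1, rng)
            draws[seq.tokens[-1]] += 1
        # compare against expected frequencies; pool rare tokens
        obs, exp = [], []
        for tok in model.vocab:
            e = n_draws * counts.get(tok, 0) / total
            if e >= 5:
                obs.append(draws[tok])
                exp.append(e)
        if n_draws - sum(exp) > 1e-9:
            obs.append(n_draws - sum(obs))
            exp.append(n_draws - sum(exp))
        stat, p = chisquare(obs, np.asarray(exp) * sum(obs) / sum(exp))
        assert p > 1e-3

    def test_syntax_error_rate_bounds_and_chain_support(self):
        model = cd.fit_from_smiles(["CC", "CCC"], 3)
        rng = np.random.default_rng(0)
        assert model.syntax_error_rate(200, 30, rng) == 0.0

    def test_error_rate_shrinks_with_order_on_ring_corpus(self, toy_corpus):
        rates = {}
        for n in (2, 6):
            model = cd.fit_from_smiles(toy_corpus[:400], n)
            rates[n] = model.syntax_error_rate(300, 100, np.random.default_rng(4))
        assert rates[6] <= rates[2]


class TestSerialization:
    def test_json_round_trip_preserves_probabilities(self, toy_tokens):
        model = cd.fit_ngram(toy_tokens[:50], 4)
        clone = cd.LanguageModel.from_json(json.loads(json.dumps(model.to_json())))
        rng = np.random.default_rng(0)
        for _ in range(30):
            seq = toy_tokens[rng.integers(50)]
            prefix = seq.truncate(int(rng.integers(0, len(seq))))
            tok = model.vocab[rng.integers(len(model.vocab))]
            assert clone.cond_prob(tok, prefix) == model.cond_prob(tok, prefix)

    def test_file_round_trip(self, tmp_path, toy_tokens):
        model = cd.fit_ngram(toy_tokens[:20], 3)
        path = tmp_path / "lm.json"
        model.save(path)
        clone = cd.LanguageModel.load(path)
        assert clone.vocab == model.vocab
        assert clone.n_max == model.n_max

    def test_wrong_container_rejected(self):
        with pytest.raises(ValueError):
            cd.LanguageModel.from_json({"format": "something-else"})
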