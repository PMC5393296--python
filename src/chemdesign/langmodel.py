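"""Stratified n-gram chemical language model with back-off smoothing.

The model factorizes the probability of a tokenized SMILES string as a chain
of conditional probabilities.  Each conditional is estimated within one of 20
strata — indexed by (branch open?, open ring marks 0..9) of the preceding
prefix — and conditions on the substring-selector output (the last n-1 tokens
of the branch-contracted prefix) rather than the raw string suffix.

Two smoothing schemes are provided:

``backoff``
    Plain back-off: use the relative frequency at the deepest order whose
    context has been observed; otherwise recurse to the next-shorter context,
    bottoming out at the uniform distribution over the vocabulary.  This is
    the default and the scheme used for molecular design.
``kneser_ney``
    Interpolated Kneser–Ney with a fixed absolute discount (0.75), applied
    within each stratum; lower orders use continuation counts.

Counts are stored sparsely per (order, stratum, context).  Begin-of-string
padding uses the ``^`` marker, which is never a predicted token; every
complete string ends with ``$``, which is.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemstring import (
    BEGIN,
    TERMINAL,
    ContextCondition,
    PrefixTracker,
    TokenSequence,
    grammar_check,
    to_smiles,
    tokenize,
)

_SERIAL_VERSION = 1

Key = tuple[ContextCondition, tuple[str, ...]]


@dataclass
class LanguageModel:
    n_max: int
    smoothing: str = "backoff"  # "backoff" | "kneser_ney"
    discount: float = 0.75
    vocab: list[str] = field(default_factory=list)
    # tables[n-1][(condition, context)] -> {token: count}; len(context) == n-1
    tables: list[dict[Key, dict[str, int]]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.smoothing not in ("backoff", "kneser_ney"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if not self.tables:
            self.tables = [dict() for _ in range(self.n_max)]
        self._rebuild_caches()

    # -- internal caches ---------------------------------------------------
    def _rebuild_caches(self) -> None:
        self._totals = [
            {k: sum(c.values()) for k, c in tab.items()} for tab in self.tables
        ]
        self._vocab_pos = {tok: i for i, tok in enumerate(self.vocab)}
        if self.smoothing == "kneser_ney":
            self._build_continuation()
        else:
            self._cont = None
            self._cont_totals = None

    def _build_continuation(self) -> None:
        """Continuation counts: distinct one-longer contexts per (ctx, token)."""
        self._cont: list[dict[Key, dict[str, int]]] = [
            dict() for _ in range(self.n_max)
        ]
        for n in range(2, self.n_max + 1):
            lower = self._cont[n - 2]
            for (cond, ctx), counter in self.tables[n - 1].items():
                key = (cond, ctx[1:])
                slot = lower.setdefault(key, {})
                for tok in counter:
                    slot[tok] = slot.get(tok, 0) + 1
        self._cont_totals = [
            {k: sum(c.values()) for k, c in tab.items()} for tab in self._cont
        ]

    # -- probability -------------------------------------------------------
    def _padded(self, contracted: list[str]) -> list[str]:
        pad = self.n_max - 1
        return [BEGIN] * pad + contracted if pad else list(contracted)

    def _context_at(self, padded: list[str], n: int) -> tuple[str, ...]:
        return tuple(padded[len(padded) - (n - 1) :]) if n > 1 else ()

    def _dist_from_state(self, cond: ContextCondition, contracted: list[str]) -> np.ndarray:
        """Full conditional distribution over the vocabulary."""
        padded = self._padded(contracted)
        if self.smoothing == "backoff":
            for n in range(self.n_max, 0, -1):
                key = (cond, self._context_at(padded, n))
                tot = self._totals[n - 1].get(key, 0)
                if tot > 0:
                    counter = self.tables[n - 1][key]
                    probs = np.zeros(len(self.vocab))
                    for tok, c in counter.items():
                        probs[self._vocab_pos[tok]] = c / tot
                    return probs
            return np.full(len(self.vocab), 1.0 / len(self.vocab))
        return self._kn_dist(cond, padded, self.n_max, use_raw=True)

    def _kn_dist(
        self, cond: ContextCondition, padded: list[str], n: int, use_raw: bool
    ) -> np.ndarray:
        if n == 0:
            return np.full(len(self.vocab), 1.0 / len(self.vocab))
        tab = self.tables if use_raw else self._cont
        totals = self._totals if use_raw else self._cont_totals
        key = (cond, self._context_at(padded, n))
        tot = totals[n - 1].get(key, 0)
        if tot == 0:
            # unseen context: pure back-off (raw stays raw so that the
            # deepest observed order contributes undiscounted frequencies)
            return self._kn_dist(cond, padded, n - 1, use_raw)
        counter = tab[n - 1][key]
        d = self.discount
        probs = np.zeros(len(self.vocab))
        for tok, c in counter.items():
            probs[self._vocab_pos[tok]] = max(c - d, 0.0) / tot
        lam = d * len(counter) / tot
        return probs + lam * self._kn_dist(cond, padded, n - 1, use_raw=False)

    def conditional_distribution(self, prefix) -> tuple[list[str], np.ndarray]:
        """Vocabulary and conditional probabilities given a prefix."""
        tracker = _as_tracker(prefix)
        return self.vocab, self._dist_from_state(tracker.condition(), tracker.contracted)

    def cond_prob(self, next_token: str, prefix) -> float:
        """P(next token | prefix) under the stratified back-off model."""
        if next_token not in self._vocab_pos:
            warnings.warn(
                f"token {next_token!r} is outside the trained vocabulary; "
                "probability 0",
                stacklevel=2,
            )
            return 0.0
        tracker = _as_tracker(prefix)
        dist = self._dist_from_state(tracker.condition(), tracker.contracted)
        return float(dist[self._vocab_pos[next_token]])

    def sequence_logprob(self, seq: TokenSequence) -> float:
        """log P(S) of a complete sequence, including the terminal factor."""
        if not seq.complete:
            raise ValueError("sequence_logprob requires a complete ('$'-ended) sequence")
        tracker = PrefixTracker()
        total = 0.0
        for i, tok in enumerate(seq.tokens):
            if tok not in self._vocab_pos:
                warnings.warn(f"token {tok!r} outside vocabulary; log-prob -inf", stacklevel=2)
                return -math.inf
            dist = self._dist_from_state(tracker.condition(), tracker.contracted)
            p = dist[self._vocab_pos[tok]]
            if p <= 0.0:
                return -math.inf
            total += math.log(p)
            tracker.append(tok, ring_partner=seq.ring_pairs.get(i))
        return total

    def sequence_prob(self, seq: TokenSequence) -> float:
        return math.exp(self.sequence_logprob(seq))

    def perplexity(self, corpus: list[TokenSequence]) -> float:
        """exp of the negative mean per-string log-probability."""
        if not corpus:
            raise ValueError("empty test corpus")
        logps = []
        for seq in corpus:
            lp = self.sequence_logprob(seq)
            if lp == -math.inf:
                warnings.warn(
                    f"string {seq.text!r} has probability 0; perplexity is infinite",
                    stacklevel=2,
                )
                return math.inf
            logps.append(lp)
        return math.exp(-float(np.mean(logps)))

    # -- generation --------------------------------------------------------
    def sample_next(self, tracker: PrefixTracker, rng) -> str:
        """Draw one token by cumulative-probability inversion."""
        dist = self._dist_from_state(tracker.condition(), tracker.contracted)
        u = rng.random()
        idx = int(np.searchsorted(np.cumsum(dist), u * dist.sum(), side="right"))
        idx = min(idx, len(self.vocab) - 1)
        return self.vocab[idx]

    def generate(
        self, seed_prefix: TokenSequence | None, max_tokens: int, rng
    ) -> TokenSequence:
        """Elongate a prefix token-by-token until '$' or the length cap."""
        if max_tokens < 0:
            raise ValueError("max_tokens must be >= 0")
        tracker = PrefixTracker(seed_prefix) if seed_prefix is not None else PrefixTracker()
        for _ in range(max_tokens):
            tok = self.sample_next(tracker, rng)
            tracker.append(tok)
            if tok == TERMINAL:
                break
        return tracker.sequence()

    def syntax_error_rate(self, n_samples: int, max_tokens: int, rng) -> float:
        """Fraction of generated strings that fail decoding or the grammar check."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        bad = 0
        for _ in range(n_samples):
            seq = self.generate(None, max_tokens, rng)
            if not seq.complete:
                bad += 1
                continue
            try:
                smi = to_smiles(seq)
            except ValueError:
                bad += 1
                continue
            if not grammar_check(smi):
                bad += 1
        return bad / n_samples

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        entries = []
        for n, tab in enumerate(self.tables, start=1):
            for (cond, ctx), counter in tab.items():
                entries.append(
                    [n, int(cond.branch_open), cond.rings_open, list(ctx), counter]
                )
        return {
            "format": "chemdesign-langmodel",
            "version": _SERIAL_VERSION,
            "n_max": self.n_max,
            "smoothing": self.smoothing,
            "discount": self.discount,
            "vocab": self.vocab,
            "entries": entries,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "LanguageModel":
        if payload.get("format") != "chemdesign-langmodel":
            raise ValueError("not a chemdesign language-model container")
        model = cls(
            n_max=payload["n_max"],
            smoothing=payload["smoothing"],
            discount=payload["discount"],
            vocab=list(payload["vocab"]),
        )
        for n, branch, rings, ctx, counter in payload["entries"]:
            key = (ContextCondition(bool(branch), int(rings)), tuple(ctx))
            model.tables[n - 1][key] = {t: int(c) for t, c in counter.items()}
        model._rebuild_caches()
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path) -> "LanguageModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _as_tracker(prefix) -> PrefixTracker:
    if isinstance(prefix, PrefixTracker):
        return prefix
    if isinstance(prefix, TokenSequence):
        return PrefixTracker(prefix)
    return PrefixTracker(TokenSequence(list(prefix)))


def fit_ngram(
    corpus: list[TokenSequence],
    n_max: int,
    smoothing: str = "backoff",
    discount: float = 0.75,
) -> LanguageModel:
    """Count stratified n-grams of all orders 1..n_max over a corpus.

    Every position of every training string increments one count per order:
    the key is (stratum of the prefix, last n-1 tokens of the contracted
    prefix, next token), with '^' padding for short prefixes.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    model = LanguageModel(n_max=n_max, smoothing=smoothing, discount=discount)
    vocab: set[str] = {TERMINAL}
    pad = n_max - 1
    for seq in corpus:
        if not seq.complete:
            raise ValueError(f"training sequence {seq.text!r} is not '$'-terminated")
        tracker = PrefixTracker()
        for i, tok in enumerate(seq.tokens):
            vocab.add(tok)
            cond = tracker.condition()
            padded = [BEGIN] * pad + tracker.contracted
            for n in range(1, n_max + 1):
                ctx = tuple(padded[len(padded) - (n - 1) :]) if n > 1 else ()
                slot = model.tables[n - 1].setdefault((cond, ctx), {})
                slot[tok] = slot.get(tok, 0) + 1
            tracker.append(tok, ring_partner=seq.ring_pairs.get(i))
    model.vocab = sorted(vocab)
    model._rebuild_caches()
    return model


def fit_from_smiles(
    smiles_list: list[str], n_max: int, smoothing: str = "backoff", discount: float = 0.75
) -> LanguageModel:
    """Convenience wrapper: tokenize raw SMILES then fit."""
    return fit_ngram([tokenize(s) for s in smiles_list], n_max, smoothing, discount)
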