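"""Backward prediction: tempered sequential Monte Carlo over SMILES strings.

The sampler targets a sequence of tempered distributions

    gamma_t(S)  proportional to  p(Y in U | S)^beta_t  p(S)

with a non-decreasing inverse-temperature ladder beta_t rising from ~0.2 to 1.
A population of R particles (token sequences) evolves by:

1. *mutation* — with probability kappa a grammatically valid particle is
   rewritten from a uniformly chosen root atom; then m ~ Binomial(L, eta)
   rightmost tokens are deleted and up to L - m new tokens are appended from
   the chemical language model (stopping early on the terminal symbol);
2. *weighting* — particle weights proportional to likelihood^beta_t (the
   prior cancels because elongation proposes from the language model itself);
3. *resampling* — systematic resampling, triggered adaptively when the
   effective sample size 1/sum(w^2) falls below a threshold.

Partial strings (open rings/branches) are repaired by temporarily removing
the unmatched marks before the likelihood is evaluated; structures that
still fail to parse receive likelihood zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemstring import (
    TERMINAL,
    PrefixTracker,
    SanitizeError,
    TokenSequence,
    grammar_check,
    reorder,
    sanitize_partial,
    to_smiles,
    tokenize,
)
from .forward import PropertyRegion, QSPRModel, region_likelihood
from .langmodel import LanguageModel

logger = logging.getLogger(__name__)

#: consecutive all-invalid populations tolerated before aborting
_MAX_INVALID_STREAK = 50


class DesignAbort(RuntimeError):
    """The whole population stayed unparseable for too many iterations."""


@dataclass
class SMCConfig:
    """Run parameters of the design loop (defaults follow the reference setup)."""

    region: PropertyRegion
    seeds: tuple[str, ...] = ("c1ccccc1O",)
    R: int = 100
    T: int = 500
    kappa: float = 0.2
    eta: float = 0.5
    L: int = 5
    ess_threshold: float = 50.0
    beta_base: float = 5.0
    beta_decay: float = 0.95
    beta_plateau: int = 251
    literal_schedule: bool = False
    fixed_beta: float | None = None
    include_prior_weight: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.R < 1 or self.T < 0 or self.L < 1:
            raise ValueError("R >= 1, T >= 0 and L >= 1 required")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie in (0, 1)")
        if self.ess_threshold > self.R:
            raise ValueError("ess_threshold cannot exceed the population size")
        if not self.seeds:
            raise ValueError("at least one seed SMILES required")


def beta_schedule(t: int, cfg: SMCConfig) -> float:
    """Inverse temperature at iteration t.

    Default: beta_t = base^(-decay^(t-1)) for t below the plateau, then 1 —
    a monotone rise from base^-1 (0.2 for base 5) toward 1.  The literal
    variant base^(+decay^(t-1)), which instead starts at ``base`` and decays,
    is available behind ``literal_schedule``.
    """
    if t < 1:
        raise ValueError("iterations are numbered from 1")
    if cfg.fixed_beta is not None:
        return cfg.fixed_beta
    if t >= cfg.beta_plateau:
        return 1.0
    expo = cfg.beta_decay ** (t - 1)
    return cfg.beta_base ** (expo if cfg.literal_schedule else -expo)


def mutate(
    seq: TokenSequence,
    lm: LanguageModel,
    kappa: float,
    eta: float,
    L: int,
    rng,
) -> TokenSequence:
    """One pass of the structure-manipulation kernel G_theta.

    (i) optional atom reordering of grammatically valid strings;
    (ii) deletion of m ~ Binomial(L, eta) rightmost tokens (terminal symbol
    removed first; at least one token always survives);
    (iii) elongation by up to L - m tokens sampled from the language model.
    """
    work = seq
    if rng.random() < kappa and seq.complete:
        try:
            smi = to_smiles(seq)
            if grammar_check(smi):
                work = tokenize(reorder(smi, rng))
        except ValueError:
            pass
    tokens_len = len(work)
    if work.complete:
        tokens_len -= 1  # strip '$' before deletion
    m = int(rng.binomial(L, eta))
    keep = max(tokens_len - m, 1) if tokens_len > 0 else 0
    tracker = PrefixTracker(work.truncate(keep))
    for _ in range(L - m):
        tok = lm.sample_next(tracker, rng)
        tracker.append(tok)
        if tok == TERMINAL:
            break
    return tracker.sequence()


def compute_weights(likelihoods, beta: float) -> np.ndarray:
    """Normalized selection weights W proportional to likelihood^beta."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    lik = np.asarray(likelihoods, dtype=np.float64)
    w = np.ones_like(lik) if beta == 0.0 else np.power(lik, beta)
    total = w.sum()
    if total <= 0.0:
        logger.warning("all particle likelihoods are zero; falling back to uniform weights")
        return np.full(len(lik), 1.0 / len(lik))
    return w / total


def ess(weights) -> float:
    """Effective sample size 1 / sum(w^2) of normalized weights."""
    w = np.asarray(weights, dtype=np.float64)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    return float(1.0 / np.sum(w * w))


def systematic_resample(weights, rng) -> np.ndarray:
    """Systematic resampling: offspring counts within one of R * w_r."""
    w = np.asarray(weights, dtype=np.float64)
    R = len(w)
    positions = (rng.random() + np.arange(R)) / R
    return np.searchsorted(np.cumsum(w), positions).clip(max=R - 1)


@dataclass
class IterationRecord:
    t: int
    beta: float
    ess: float
    resampled: bool
    smiles: list[str]  # repaired/decoded structure per particle ('' if invalid)
    likelihoods: np.ndarray


@dataclass
class DesignTrace:
    """Per-iteration record of a design run."""

    records: list[IterationRecord] = field(default_factory=list)
    config: SMCConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            lik = rec.likelihoods
            rows.append(
                {
                    "t": rec.t,
                    "beta": rec.beta,
                    "ess": rec.ess,
                    "resampled": rec.resampled,
                    "mean_likelihood": float(lik.mean()),
                    "median_likelihood": float(np.median(lik)),
                    "max_likelihood": float(lik.max()),
                    "frac_valid": float(np.mean([s != "" for s in rec.smiles])),
                }
            )
        return pd.DataFrame(rows)

    def candidates(self, from_t: int = 1) -> tuple[list[str], np.ndarray]:
        """Distinct structures from iterations >= from_t with their best scores."""
        best: dict[str, float] = {}
        for rec in self.records:
            if rec.t < from_t:
                continue
            for smi, lik in zip(rec.smiles, rec.likelihoods):
                if smi and lik > best.get(smi, -1.0):
                    best[smi] = float(lik)
        items = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        return [s for s, _ in items], np.array([v for _, v in items])

    def top_molecules(
        self, k: int = 10, tanimoto_threshold: float = 0.9, from_t: int = 1
    ) -> list[tuple[str, float]]:
        smiles, scores = self.candidates(from_t)
        keep = nonredundant_top_k(smiles, scores, k, tanimoto_threshold)
        return keep


def _particle_eval(seq: TokenSequence, models, region) -> tuple[str, float]:
    """Decode (sanitizing if needed) and score one particle."""
    smi = None
    if seq.complete:
        try:
            cand = to_smiles(seq)
            if grammar_check(cand):
                smi = cand
        except ValueError:
            smi = None
    if smi is None:
        try:
            smi = sanitize_partial(seq)
        except SanitizeError:
            return "", 0.0
    return smi, region_likelihood(models, smi, region)


def design(cfg: SMCConfig, lm: LanguageModel, models: list[QSPRModel]) -> DesignTrace:
    """Run the tempered SMC design loop and return the full trace."""
    if len(models) != len(cfg.region):
        raise ValueError("one QSPR model per property interval required")
    rng = np.random.default_rng(cfg.seed)
    particles = [tokenize(cfg.seeds[r % len(cfg.seeds)]) for r in range(cfg.R)]
    cache: dict[str, tuple[str, float]] = {}
    trace = DesignTrace(config=cfg)
    invalid_streak = 0
    for t in range(1, cfg.T + 1):
        beta = beta_schedule(t, cfg)
        particles = [mutate(p, lm, cfg.kappa, cfg.eta, cfg.L, rng) for p in particles]
        evals = []
        for p in particles:
            key = p.text
            if key not in cache:
                cache[key] = _particle_eval(p, models, cfg.region)
            evals.append(cache[key])
        smiles = [e[0] for e in evals]
        liks = np.array([e[1] for e in evals])
        if cfg.include_prior_weight:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                priors = np.array(
                    [
                        np.exp(lm.sequence_logprob(p)) if p.complete else 1.0
                        for p in particles
                    ]
                )
            weights = compute_weights(np.power(liks, beta) * priors, 1.0)
        else:
            weights = compute_weights(liks, beta)
        e = ess(weights)
        resampled = e < cfg.ess_threshold
        if resampled:
            idx = systematic_resample(weights, rng)
            particles = [particles[i].copy() for i in idx]
        trace.records.append(IterationRecord(t, beta, e, resampled, smiles, liks))
        if all(s == "" for s in smiles):
            invalid_streak += 1
            if invalid_streak >= _MAX_INVALID_STREAK:
                raise DesignAbort(
                    f"population fully unparseable for {invalid_streak} consecutive "
                    f"iterations (t={t}); check the language model and seeds"
                )
        else:
            invalid_streak = 0
        if t % 50 == 0:
            logger.info(
                "t=%d beta=%.3f ess=%.1f median_lik=%.3g", t, beta, e, np.median(liks)
            )
    return trace


_TANIMOTO_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=1024)


def nonredundant_top_k(
    smiles_list: list[str],
    scores,
    k: int = 10,
    tanimoto_threshold: float = 0.9,
) -> list[tuple[str, float]]:
    """Greedy score-descending scan dropping near-duplicates.

    A molecule is discarded when its Tanimoto coefficient against any
    already-kept molecule reaches the threshold; at most k survivors are
    returned as (smiles, score) pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(smiles_list) != len(scores):
        raise ValueError("smiles and scores must have equal length")
    if not 0.0 < tanimoto_threshold <= 1.0:
        raise ValueError("tanimoto threshold must lie in (0, 1]")
    order = np.argsort(-scores, kind="stable")
    kept: list[tuple[str, float]] = []
    kept_fps = []
    for i in order:
        mol = Chem.MolFromSmiles(smiles_list[i])
        if mol is None:
            continue
        fp = _TANIMOTO_GEN.GetFingerprint(mol)
        if kept_fps and max(DataStructs.BulkTanimotoSimilarity(fp, kept_fps)) >= tanimoto_threshold:
            continue
        kept.append((smiles_list[i], float(scores[i])))
        kept_fps.append(fp)
        if len(kept) == k:
            break
    return kept
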