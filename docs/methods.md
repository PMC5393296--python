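# Methods

This note documents the models, conventions and numerical choices behind
`chemdesign`, and what the synthetic fixtures do and do not demonstrate.

## Token grammar

A SMILES string is handled as a sequence of grammar units:

* organic-subset atoms (`C`, `N`, `O`, …, two-letter `Cl`/`Br`, aromatic
  lowercase) and whole bracket atoms (`[nH]`) are single tokens;
* `=`/`#` fuse with the following unit (`=O`, `#N`), so a bond never dangles;
* every ring-closure digit (`1`–`9`, `%nn`) becomes the anonymous mark `&`;
* a terminal `$` ends each complete string, giving the generator a stopping
  symbol; `^` is begin-of-string padding and is never predicted.

Only the neutral, achiral, single-component dialect is supported. Strings
containing `+`, `-`, `@`, `.`, `/`, `\` or `:` are rejected everywhere,
matching the filtering of the training corpora; isomeric SMILES, charges and
isotopes are out of scope.

**Ring-mark pairing.** The `&` notation erases digit identity, so pairing is
tracked as metadata. When a known SMILES is tokenized, each mark keeps the
pairing implied by its original digit — fused and even bridged (crossing)
systems therefore round-trip exactly. A mark whose closure is truncated away
carries an explicit *known-open* flag (a sentinel partner index) so that
later operations never re-pair it spuriously. Marks generated by the
language model follow a deterministic stack rule: a new `&` closes the most
recently opened ring if one is open, otherwise it opens one. Consequence:
the generator itself cannot emit fused rings (a second ring cannot open
while one is pending); decoding such generated strings is always
unambiguous, and anything that still fails the RDKit parse/kekulization
check counts as a syntax error. Decoding assigns each ring the smallest
closure digit not currently in use, reusing digits after closure.

## Stratified n-gram language model

The probability of a string factorizes over tokens. Each conditional is
estimated within one of 20 strata given by (branch open?, open ring marks
clamped to 0–9) of the prefix, and conditions on the last n−1 tokens of the
*contracted* prefix: every outermost closed parenthesis group `(t₁…t_q)` is
reduced to `(t₁)` (nested closed groups collapse with it; unclosed groups
are left intact), so conditioning follows graph adjacency. Contraction keeps
the surrounding parentheses — the branch point remains visible to the model.

Training increments one count per order 1…n_max at every position, with `^`
padding for short prefixes. Two smoothing schemes:

* **Back-off (default).** At query time, use the relative frequency at the
  deepest order whose (stratum, context) has been observed; otherwise
  recurse to the next-shorter context; with nothing observed anywhere, fall
  back to the uniform distribution over the vocabulary. This literal
  fallback assigns probability zero to a token unseen *within an observed
  context*, so held-out perplexity can be infinite on small corpora; such
  strings are flagged, and perplexity is reported as the exponential of the
  negative mean **per-string** log-probability.
* **Kneser–Ney (optional).** Interpolated absolute discounting with a fixed
  discount D = 0.75 within each stratum; lower orders use continuation
  counts and the chain bottoms out at the uniform distribution, so every
  vocabulary token keeps positive mass. Provided for perplexity comparisons;
  design runs use back-off with n = 10.

Generation samples tokens by cumulative-probability inversion on a seeded
uniform stream and stops at `$` or a length cap. Models serialize to a JSON
container (version tag, vocabulary, per-order sparse counts).

## Forward prediction

Each property is a Bayesian linear regression on a binary descriptor
ψ(S) ∈ {0,1}^d, the concatenation of hashed fingerprint families: `path`
(linear/branched paths to length 7), `layered` (ring/atom-layer aware),
`circular` (Morgan radius 3, ECFP6-like), and the fixed 167-bit `maccs`
substructure keys. These are the RDKit equivalents of the classical CDK
families; exact bit-level agreement with other toolkits is not expected, so
cross-toolkit accuracy comparisons carry a ±20% relative tolerance.

With priors `w ~ N(0, σ²V)` and `σ² ~ IG(a, b)`:

```
V* = (V⁻¹ + ΨᵀΨ)⁻¹          w* = V* Ψᵀy
a* = a + N/2                 b* = b + ½ yᵀ(I + ΨVΨᵀ)⁻¹ y
```

and the predictive distribution at ψ is Student t with 2a* degrees of
freedom, mean `w*ᵀψ` and squared scale `(b*/a*)(1 + ψᵀV*ψ)`. Note the b*
quadratic form is taken in `y`, not in the residual: since
`(I + ΨVΨᵀ)⁻¹y = y − Ψw*`, it reduces to `b + ½ (y − Ψw*)ᵀy` and needs no
N×N inverse. (A variant sometimes quoted with the residual on *both* sides
of the inverse understates b* and makes the predictive intervals
anti-conservative — measured ≈86% coverage of nominal 90% intervals on
well-specified synthetic data versus ≈90% for the form above, which the
test suite checks.) Defaults are `V = I`, `(a, b) = (0, 0)`; the improper
limit is handled directly by the closed forms, and the predictive mean then
equals the ridge estimate. A perfect interpolating fit would give scale
zero; the CDF degenerates to a step at the mean in that case.

The design likelihood of a molecule is the product over properties of the
predictive t mass on each closed interval of the target box, computed with
SciPy's t CDF; intervals are treated as measure-equivalent half-open sets.
Unparseable structures get likelihood zero.

## Backward prediction

The sampler targets `γ_t(S) ∝ p(Y ∈ U | S)^{β_t} p(S)`. The inverse
temperature follows `β_t = 5^(−0.95^(t−1))` for t ≤ 250 and `β_t = 1`
afterwards — a monotone rise from 0.2 to 1. (The variant `5^(+0.95^(t−1))`,
which starts at 5 and *decays*, contradicts the requirement of a
non-decreasing ladder starting near zero; it is selectable via
`literal_schedule` but not the default.)

Each iteration, every particle is mutated: (i) with probability κ = 0.2 a
grammatically valid particle is re-rooted at a uniformly chosen atom
(RDKit's rooted, non-canonical writer, seeded); (ii) the terminal `$` is
stripped and m ~ Binomial(L = 5, η = 0.5) rightmost tokens are deleted,
clamped so one token survives; (iii) up to L − m tokens are appended from
the language model, stopping early at `$`. Weights are `likelihood^{β_t}`
normalized — the prior cancels because elongation proposes from the language
model itself; an explicit-prior variant is available behind
`include_prior_weight`. Systematic resampling triggers adaptively when
ESS = 1/Σw² < E (default E = R/2 = 50). Defaults R = 100, T = 500, phenol
seed. If every weight is zero the weights fall back to uniform with a
warning; fifty consecutive fully-unparseable populations abort the run.

Incomplete particles are scored after repair: unmatched `(`, stray `)` and
unpaired ring marks are removed before decoding; repair failures score zero.
Likelihood evaluations are cached per token string within a run, which
leaves the trace unchanged but shortens runtime substantially. Runs are
single-process and byte-reproducible given the configuration seed.

A known kernel property: because elongation adds at most L − m tokens per
step, complete strings observed under selection-free drift are biased
slightly short relative to unconstrained language-model generation
(measured ≈17% shorter mean length on the toy corpus). The sampler is a
genetic-algorithm-style explorer of the tempered posterior, not an exact
sampler from it.

Reported designs are de-duplicated by a greedy score-descending scan that
drops any molecule whose Morgan-fingerprint Tanimoto coefficient against an
already-kept molecule reaches 0.9, keeping the top k = 10.

## Synthetic fixtures

The toy corpus generator emits 3–18 heavy-atom molecules from a stochastic
grammar: aliphatic chains over a configurable alphabet, single 5/6-membered
aliphatic or aromatic rings (including `[nH]` azoles), and branches to depth
2 attached only at aliphatic carbons. Candidates failing RDKit sanitization
are rejected and the output is deduplicated, so every fixture molecule is
grammar-valid and LIFO-decodable by construction. Defaults (2,000 molecules,
ring probability 0.35, branch probability 0.25) give roughly two thirds of
molecules a ring and a mean string length of ~13 characters — small
drug-fragment-like territory. The fixtures do **not** reproduce fused or
bridged ring systems, charged/stereochemical chemistry, functional-group
statistics of real screening libraries, or the property distributions of
DFT data; tests passing on them validate the machinery (counting,
closed-form updates, sampler mechanics), not chemical realism.

Synthetic properties are `y = wᵀψ(S) + N(0, σ²)` with a seeded sparse `w` —
exactly the forward model's assumed form. Parameter-recovery tests use the
sparse draw; the coverage test uses a dense draw with `weight_scale =
noise_sd` so the prior `w ~ N(0, σ²I)` is correctly specified, which is the
regime in which nominal calibration is a meaningful expectation.

## Numerical and design choices

* Posterior solves use a Cholesky factorization of `V⁻¹ + ΨᵀΨ`; `V = None`
  short-circuits to the identity without forming an inverse.
* Sampling ties are resolved by cumulative-probability inversion on a single
  seeded `numpy.random.Generator` stream per run; all CLI subcommands take
  explicit seeds and record them in run manifests.
* `rings_open` clamps at 9, so deeply nested ring openings share the last
  stratum rather than growing the stratum set.
* Deletion in the mutation kernel never empties a particle (m is clamped to
  length − 1).
* The trial-length parameter is L = 5 with η = 0.5, making the expected
  length change of a mutation zero.
* Problem sizes in the test suite and acceptance script (500–2,600-molecule
  corpora, 128–256-bit fingerprints, R = 20–50, T = 200–250) are chosen so
  the full pipeline remains a desk-scale computation while preserving each
  measured effect; all quantities they assert are computed at run time.

## Known limitations

* The generator cannot propose fused-ring systems (stack-rule ring pairing);
  training and round-tripping of fused/bridged molecules is unaffected.
* Plain back-off yields infinite held-out perplexity whenever a test string
  contains a continuation unseen in an observed context; use Kneser–Ney for
  perplexity comparisons on small corpora.
* Validation of designed molecules is by the trained QSPR models only; no
  quantum-chemistry or database-novelty checking is included, and predicted
  properties inherit all biases of the training data and descriptors.
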