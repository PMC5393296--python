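import numpy as np
import pytest

import chemdesign as cd


@pytest.fixture(scope="session")
def toy_corpus():
    """Synthetic ring/branch-rich training corpus (deterministic)."""
    return cd.make_toy_corpus(cd.ToyCorpusSpec(n_molecules=800, seed=7))


@pytest.fixture(scope="session")
def toy_tokens(toy_corpus):
    return [cd.tokenize(s) for s in toy_corpus]


@pytest.fixture(scope="session")
def lm_n5(toy_tokens):
    """Mid-order back-off model on the toy corpus."""
    return cd.fit_ngram(toy_tokens, n_max=5)


@pytest.fixture(scope="session")
def small_fp_spec():
    return cd.FingerprintSpec(("circular",), n_bits=128)


@pytest.fixture(scope="session")
def synthetic_gap(toy_corpus, small_fp_spec):
    """Linear-in-fingerprint property with known ground truth."""
    rng = np.random.default_rng(42)
    spec = cd.SyntheticPropertySpec(
        fingerprint=small_fp_spec, noise_sd=0.2, name="gap"
    )
    return cd.make_synthetic_property(toy_corpus, spec, rng)


@pytest.fixture(scope="session")
def gap_model(synthetic_gap, small_fp_spec):
    tab = synthetic_gap.table
    return cd.QSPRModel.fit(
        tab.smiles.tolist()[:500], tab.gap.values[:500], small_fp_spec, name="gap"
    )
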