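"""Synthetic fixtures: toy SMILES corpora and linear-in-fingerprint properties.

The toy corpus generator emits small organic molecules from a stochastic
grammar — aliphatic chains, single 5/6-membered (optionally aromatic)
rings and branches up to depth 2 — restricted to the neutral, achiral
SMILES dialect the rest of the package supports.  Every emitted string
passes the grammar check, contains only LIFO-decodable ring closures, and
the generator is fully deterministic given its seed.  It stands in for a
large public compound corpus in tests and demonstrations; it does not
reproduce the size, functional-group diversity or fused-ring systems of
real screening libraries.

The synthetic property generator draws a sparse ground-truth weight vector
and produces values y = w^T psi(S) + N(0, sigma^2) — exactly the form the
forward model assumes — so that parameter recovery and coverage can be
tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemstring import grammar_check, tokenize
from .forward import FingerprintSpec, featurize_many


@dataclass
class ToyCorpusSpec:
    """Study conditions for the synthetic training corpus."""

    n_molecules: int = 2000
    max_heavy_atoms: int = 18
    ring_probability: float = 0.35
    branch_probability: float = 0.25
    alphabet: tuple[str, ...] = ("C", "N", "O", "S", "c", "n", "o")
    seed: int = 0


# ring templates; '{d}' is replaced by the allocated ring-closure digit
_AROMATIC_RINGS = [
    "c{d}ccccc{d}",
    "c{d}ccncc{d}",
    "c{d}cccnc{d}",
    "c{d}cco{d}",
    "c{d}cc[nH]c{d}",
    "c{d}ccoc{d}",
]
_ALIPHATIC_RINGS = [
    "C{d}CCCCC{d}",
    "C{d}CCCC{d}",
    "C{d}CCOCC{d}",
    "C{d}CCNCC{d}",
    "C{d}CCOC{d}",
]
_RING_COST = 6


def _heteroatom_ok(tpl: str, alphabet: set[str]) -> bool:
    letters = {ch for ch in tpl if ch.isalpha() and ch not in "dH"}
    return letters <= alphabet


def make_toy_corpus(spec: ToyCorpusSpec) -> list[str]:
    """Generate a deduplicated corpus of grammar-valid synthetic molecules."""
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    alphabet = set(spec.alphabet)
    aliphatic = [a for a in spec.alphabet if a.isupper()]
    if not aliphatic:
        raise ValueError("alphabet must contain at least one aliphatic element")
    # carbon-heavy weights keep valence rejections rare
    weights = np.array([3.0 if a == "C" else 1.0 for a in aliphatic])
    weights /= weights.sum()
    aromatic_ok = "c" in alphabet
    ring_templates = [
        t
        for t in (_AROMATIC_RINGS if aromatic_ok else []) + _ALIPHATIC_RINGS
        if _heteroatom_ok(t, alphabet | {"C"} if False else alphabet)
    ]
    # aliphatic carbon rings are always expressible
    if not ring_templates:
        ring_templates = [t for t in _ALIPHATIC_RINGS if set(t) & alphabet or True]
        ring_templates = ["C{d}CCCCC{d}", "C{d}CCCC{d}"]

    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts, max_attempts = 0, 200 * spec.n_molecules

    def chain(n_atoms: int, depth: int, ring_counter: list[int]) -> str:
        s = ""
        remaining = n_atoms
        prev_branchable = False
        while remaining > 0:
            if (
                spec.ring_probability > 0
                and remaining >= _RING_COST
                and rng.random() < spec.ring_probability
            ):
                d = ring_counter[0] % 9 + 1
                ring_counter[0] += 1
                s += ring_templates[rng.integers(len(ring_templates))].format(d=d)
                remaining -= _RING_COST
                prev_branchable = False
            else:
                atom = aliphatic[int(rng.choice(len(aliphatic), p=weights))]
                s += atom
                remaining -= 1
                prev_branchable = atom == "C"
            if (
                prev_branchable
                and depth < 2
                and remaining >= 1
                and rng.random() < spec.branch_probability
            ):
                k = int(rng.integers(1, min(4, remaining + 1)))
                s += "(" + chain(k, depth + 1, ring_counter) + ")"
                remaining -= k
        return s

    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        n_atoms = int(rng.integers(3, spec.max_heavy_atoms + 1))
        smi = chain(n_atoms, 0, [0])
        if not smi or smi in seen:
            continue
        if not grammar_check(smi):
            continue
        try:
            tokenize(smi)
        except ValueError:
            continue
        seen.add(smi)
        out.append(smi)
    if len(out) < spec.n_molecules:
        raise RuntimeError(
            f"could not generate {spec.n_molecules} molecules under this spec "
            f"(got {len(out)} after {attempts} attempts)"
        )
    return out


@dataclass
class SyntheticPropertySpec:
    """Ground-truth linear model for a synthetic molecular property."""

    fingerprint: FingerprintSpec = field(
        default_factory=lambda: FingerprintSpec(("circular",), n_bits=256)
    )
    density: float = 0.05  # fraction of nonzero ground-truth weights
    weight_scale: float = 1.0
    noise_sd: float = 0.1
    name: str = "property"
    units: str = ""


@dataclass
class SyntheticProperty:
    """A generated property table plus the ground truth behind it."""

    table: pd.DataFrame
    true_w: np.ndarray
    spec: SyntheticPropertySpec
    descriptors: np.ndarray
    noiseless: np.ndarray


def make_synthetic_property(
    smiles_list: list[str], spec: SyntheticPropertySpec, rng
) -> SyntheticProperty:
    """Property values drawn from y = w^T psi(S) + N(0, sigma^2)."""
    if not smiles_list:
        raise ValueError("empty SMILES list")
    X, kept = featurize_many(smiles_list, spec.fingerprint)
    if not kept:
        raise ValueError("no molecule could be featurized")
    d = spec.fingerprint.dim
    w = np.zeros(d)
    n_active = max(1, int(round(spec.density * d)))
    active = rng.choice(d, size=n_active, replace=False)
    w[active] = rng.normal(0.0, spec.weight_scale, size=n_active)
    noiseless = X @ w
    values = noiseless + rng.normal(0.0, spec.noise_sd, size=len(kept))
    table = pd.DataFrame(
        {"smiles": [smiles_list[i] for i in kept], spec.name or "value": values}
    )
    return SyntheticProperty(table, w, spec, X, noiseless)


@dataclass
class DropReport:
    n_rows: int
    n_bad_smiles: int
    n_bad_values: int

    @property
    def n_kept(self) -> int:
        return self.n_rows - self.n_bad_smiles - self.n_bad_values


def read_property_csv(
    path,
    smiles_col: str = "smiles",
    property_cols: tuple[str, ...] = ("gap_ev", "energy_kcal_mol"),
) -> tuple[list[str], np.ndarray, DropReport]:
    """Read a structure-property CSV, dropping unusable rows with a count.

    Rows whose SMILES fails the grammar check or whose property entries are
    not numeric are dropped; the report records how many of each.
    """
    df = pd.read_csv(path)
    missing = [c for c in (smiles_col, *property_cols) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    if len(df) == 0:
        raise ValueError(f"empty property table {path}")
    n_rows = len(df)
    vals = df[list(property_cols)].apply(pd.to_numeric, errors="coerce")
    bad_values = vals.isna().any(axis=1)
    ok_smiles = df[smiles_col].astype(str).map(grammar_check)
    n_bad_smiles = int((~ok_smiles).sum())
    n_bad_values = int((bad_values & ok_smiles).sum())
    keep = ok_smiles & ~bad_values
    return (
        df.loc[keep, smiles_col].astype(str).tolist(),
        vals.loc[keep].to_numpy(dtype=np.float64),
        DropReport(n_rows, n_bad_smiles, n_bad_values),
    )
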