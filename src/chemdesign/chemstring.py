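"""SMILES encoding under a modified token grammar for chemical language modelling.

A molecule is handled as a sequence of grammar units rather than raw characters:

* two-letter elements (``Cl``, ``Br``) and bracket atoms (``[nH]``) are single
  tokens;
* a double/triple bond fuses with the unit that follows it (``=O``, ``#N``);
* every ring-closure digit (``1``–``9``, ``%nn``) is replaced by the anonymous
  ring mark ``&``;
* a terminal ``$`` closes every complete sequence so that recursive string
  elongation has a well-defined stopping symbol.

The module also provides the context machinery the language model conditions
on: the 20 strata defined by (branch open?, number of open rings in 0..9) and
the substring selector that contracts closed branches to their first atom so
that conditioning follows graph adjacency instead of raw string adjacency.

Only the neutral, achiral, single-component SMILES dialect is supported:
strings containing ``+``, ``-``, ``@``, ``.``, ``/``, ``\\`` or ``:`` are
rejected, mirroring the filtering applied to the training corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

TERMINAL = "$"
RING_MARK = "&"
BEGIN = "^"

#: sentinel partner index for a ring mark that is known to be open (its
#: closure truncated away or never written); compares >= any token index
OPEN_PARTNER = 1 << 30

#: characters excluded everywhere (ionic, stereo, multi-component dialects)
FORBIDDEN_CHARS = frozenset("+-@./\\:*~")

_TWO_LETTER = ("Cl", "Br")
_ONE_LETTER = frozenset("BCNOSPFI")
_AROMATIC = frozenset("bcnosp")
_BONDS = frozenset("=#")
_DIGITS = frozenset("0123456789")


class TokenizeError(ValueError):
    """The input string is not in the supported SMILES dialect."""


class PartialStringError(ValueError):
    """The token sequence has unmatched branch or ring marks."""


class SanitizeError(ValueError):
    """A partial sequence could not be repaired into a parseable structure."""


class ContextCondition(NamedTuple):
    """One of the 20 strata conditioning the language model."""

    branch_open: bool
    rings_open: int


def all_conditions() -> list[ContextCondition]:
    """Enumerate the full set of 20 (= 2 x 10) context strata."""
    return [ContextCondition(b, r) for b in (False, True) for r in range(10)]


def _is_ring_token(tok: str) -> bool:
    return tok == RING_MARK or (len(tok) == 2 and tok[0] in _BONDS and tok[1] == RING_MARK)


@dataclass
class TokenSequence:
    """A tokenized SMILES string, optionally carrying ring-mark pairing.

    ``ring_pairs`` maps the token index of a ring mark to the index of its
    partner (symmetric).  The ``&`` notation erases digit identity, so the
    pairing recovered from the original digits is kept alongside the tokens;
    marks without a stored partner are matched by the LIFO stack rule at
    decode time.  A partner index at or beyond ``len(tokens)`` marks a ring
    that is *known open* (its closure was truncated away or never written):
    such marks are never re-paired by the stack rule.
    """

    tokens: list[str]
    ring_pairs: dict[int, int] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return bool(self.tokens) and self.tokens[-1] == TERMINAL

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def copy(self) -> "TokenSequence":
        return TokenSequence(list(self.tokens), dict(self.ring_pairs))

    def truncate(self, k: int) -> "TokenSequence":
        """First ``k`` tokens; ring pairs crossing the cut become open marks."""
        pairs = {i: j for i, j in self.ring_pairs.items() if i < k}
        return TokenSequence(self.tokens[:k], pairs)


def tokenize(smiles: str) -> TokenSequence:
    """Encode a SMILES string into the modified grammar.

    Ring-closure digits are replaced by ``&`` (pairing retained as metadata),
    ``=``/``#`` fuse with the following unit, bracket atoms stay whole, and a
    terminal ``$`` is appended.
    """
    if not smiles:
        raise TokenizeError("empty SMILES string")
    bad = FORBIDDEN_CHARS.intersection(smiles)
    if bad:
        raise TokenizeError(
            f"characters {sorted(bad)} are outside the supported dialect: {smiles!r}"
        )

    tokens: list[str] = []
    pairs: dict[int, int] = {}
    open_by_label: dict[str, int] = {}

    def close_or_open(label: str, idx: int) -> None:
        if label in open_by_label:
            j = open_by_label.pop(label)
            pairs[j] = idx
            pairs[idx] = j
        else:
            open_by_label[label] = idx

    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        bond = ""
        if ch in _BONDS:
            bond = ch
            i += 1
            if i >= n:
                raise TokenizeError(f"dangling bond symbol in {smiles!r}")
            ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizeError(f"unclosed bracket in {smiles!r}")
            tokens.append(bond + smiles[i : j + 1])
            i = j + 1
        elif smiles.startswith(_TWO_LETTER, i):
            tokens.append(bond + smiles[i : i + 2])
            i += 2
        elif ch in _ONE_LETTER or ch in _AROMATIC:
            tokens.append(bond + ch)
            i += 1
        elif ch in _DIGITS:
            close_or_open(ch, len(tokens))
            tokens.append(bond + RING_MARK)
            i += 1
        elif ch == "%":
            if i + 2 >= n or smiles[i + 1] not in _DIGITS or smiles[i + 2] not in _DIGITS:
                raise TokenizeError(f"malformed %nn ring closure in {smiles!r}")
            close_or_open(smiles[i + 1 : i + 3], len(tokens))
            tokens.append(bond + RING_MARK)
            i += 3
        elif ch in "()":
            if bond:
                raise TokenizeError(f"bond before parenthesis in {smiles!r}")
            tokens.append(ch)
            i += 1
        else:
            raise TokenizeError(f"unsupported character {ch!r} in {smiles!r}")

    tokens.append(TERMINAL)
    for idx in open_by_label.values():  # unclosed digits stay known-open
        pairs[idx] = OPEN_PARTNER
    return TokenSequence(tokens, pairs)


def _complete_ring_pairs(seq: TokenSequence) -> dict[int, int]:
    """Extend stored pairing with LIFO matching of the remaining ring marks.

    Marks flagged as known-open (partner index beyond the sequence) are left
    unpaired rather than fed to the stack rule.
    """
    n = len(seq.tokens)
    pairs = {i: j for i, j in seq.ring_pairs.items() if j < n}
    known_open = {i for i, j in seq.ring_pairs.items() if j >= n}
    stack: list[int] = []
    for i, tok in enumerate(seq.tokens):
        if not _is_ring_token(tok) or i in pairs or i in known_open:
            continue
        if stack:
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        else:
            stack.append(i)
    return pairs


def to_smiles(seq: TokenSequence) -> str:
    """Decode a token sequence back to a SMILES string.

    Ring marks are rewritten to the smallest closure digit not currently in
    use; digits are reused once their ring closes.  Raises
    :class:`PartialStringError` if branches or ring marks are unmatched —
    callers holding generated fragments should :func:`sanitize_partial` first.
    """
    pairs = _complete_ring_pairs(seq)
    depth = 0
    for i, tok in enumerate(seq.tokens):
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise PartialStringError("unmatched ')' in token sequence")
        elif _is_ring_token(tok) and i not in pairs:
            raise PartialStringError("unpaired ring mark in token sequence")
    if depth != 0:
        raise PartialStringError("unmatched '(' in token sequence")

    digit_of: dict[int, str] = {}
    in_use: set[int] = set()
    out: list[str] = []
    for i, tok in enumerate(seq.tokens):
        if tok == TERMINAL:
            continue
        if _is_ring_token(tok):
            j = pairs[i]
            if i < j:  # opening mark: allocate a digit
                d = 1
                while d in in_use:
                    d += 1
                in_use.add(d)
                digit_of[i] = digit_of[j] = str(d) if d < 10 else f"%{d:02d}"
                label = digit_of[i]
            else:  # closing mark: release the digit
                label = digit_of[i]
                d = int(label.lstrip("%"))
                in_use.discard(d)
            out.append(tok[:-1] + label)
        else:
            out.append(tok)
    return "".join(out)


class PrefixTracker:
    """Incremental state of a growing token prefix.

    Maintains, token by token: the net branch depth, the stack of open ring
    marks, the LIFO/known ring pairing, and the contracted string used by the
    substring selector.  This is the workhorse behind training, conditional
    probabilities and sequential generation.
    """

    def __init__(self, seq: TokenSequence | None = None):
        self.tokens: list[str] = []
        self.ring_pairs: dict[int, int] = {}
        self._open_rings: list[int] = []
        self._branch_net = 0
        self.contracted: list[str] = []
        self._paren_stack: list[int] = []
        if seq is not None:
            for i, tok in enumerate(seq.tokens):
                self.append(tok, ring_partner=seq.ring_pairs.get(i))

    def append(self, tok: str, ring_partner: int | None = None) -> None:
        i = len(self.tokens)
        self.tokens.append(tok)
        if tok == "(":
            self._branch_net += 1
            self.contracted.append("(")
            self._paren_stack.append(len(self.contracted) - 1)
            return
        if tok == ")":
            self._branch_net -= 1
            if self._paren_stack:
                p = self._paren_stack.pop()
                # collapse the closed group to '(' + its first unit + ')'
                keep = self.contracted[p + 1 : p + 2]
                del self.contracted[p + 1 :]
                self.contracted.extend(keep)
                self.contracted.append(")")
            else:
                self.contracted.append(")")
            return
        if _is_ring_token(tok):
            if ring_partner is not None:
                if ring_partner < i:
                    self.ring_pairs[i] = ring_partner
                    self.ring_pairs[ring_partner] = i
                    try:
                        self._open_rings.remove(ring_partner)
                    except ValueError:
                        pass
                else:
                    self._open_rings.append(i)
            elif self._open_rings:
                j = self._open_rings.pop()
                self.ring_pairs[i] = j
                self.ring_pairs[j] = i
            else:
                self._open_rings.append(i)
        self.contracted.append(tok)

    def condition(self) -> ContextCondition:
        return ContextCondition(self._branch_net > 0, min(len(self._open_rings), 9))

    def context(self, n: int) -> tuple[str, ...]:
        """The last n-1 tokens of the contracted prefix, '^'-padded."""
        if n <= 1:
            return ()
        want = n - 1
        tail = self.contracted[-want:]
        if len(tail) < want:
            return (BEGIN,) * (want - len(tail)) + tuple(tail)
        return tuple(tail)

    def sequence(self) -> TokenSequence:
        pairs = dict(self.ring_pairs)
        for idx in self._open_rings:  # still-open marks stay known-open
            pairs[idx] = OPEN_PARTNER
        return TokenSequence(list(self.tokens), pairs)


def classify_context(prefix: TokenSequence | Sequence[str]) -> ContextCondition:
    """Stratum of a prefix: (any unmatched '(' ?, open ring marks clamped to 9)."""
    seq = prefix if isinstance(prefix, TokenSequence) else TokenSequence(list(prefix))
    return PrefixTracker(seq).condition()


def substring_select(prefix: TokenSequence | Sequence[str], n: int) -> list[str]:
    """Substring selector: contract closed branches, return the last n-1 tokens.

    Every outermost *closed* parenthesis group ``( t1 ... tq )`` is reduced to
    ``( t1 )`` (nested closed groups collapse with it); unclosed groups are
    left intact.  The last ``n-1`` tokens of the contracted prefix are
    returned (fewer if the contracted prefix is shorter).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = prefix if isinstance(prefix, TokenSequence) else TokenSequence(list(prefix))
    tracker = PrefixTracker(seq)
    if n == 1:
        return []
    return tracker.contracted[-(n - 1) :]


def sanitize_partial(seq: TokenSequence) -> str:
    """Repair a possibly-partial sequence into a parseable SMILES string.

    Unmatched ``(`` marks, stray ``)`` marks and unpaired ring marks are
    removed before decoding.  Raises :class:`SanitizeError` when the repaired
    string still fails the grammar check (callers typically assign such
    structures zero likelihood).
    """
    drop: set[int] = set()
    paren_stack: list[int] = []
    for i, tok in enumerate(seq.tokens):
        if tok == "(":
            paren_stack.append(i)
        elif tok == ")":
            if paren_stack:
                paren_stack.pop()
            else:
                drop.add(i)
    drop.update(paren_stack)

    pairs = _complete_ring_pairs(seq)
    for i, tok in enumerate(seq.tokens):
        if _is_ring_token(tok) and i not in pairs:
            drop.add(i)

    keep = [i for i in range(len(seq.tokens)) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    new_pairs = {
        remap[i]: remap[j]
        for i, j in seq.ring_pairs.items()
        if i in remap and j in remap
    }
    repaired = TokenSequence([seq.tokens[i] for i in keep], new_pairs)
    try:
        smi = to_smiles(repaired)
    except PartialStringError as exc:  # pragma: no cover - defensive
        raise SanitizeError(str(exc)) from exc
    if not smi or not grammar_check(smi):
        raise SanitizeError(f"sanitized string {smi!r} is not a valid structure")
    return smi


def reorder(smiles: str, rng) -> str:
    """Rewrite a valid SMILES rooted at a uniformly chosen atom.

    The output is a (generally non-canonical) string of the same molecule;
    it is deterministic given the random stream.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot reorder invalid SMILES {smiles!r}")
    root = int(rng.integers(mol.GetNumAtoms()))
    return Chem.MolToSmiles(mol, canonical=False, rootedAtAtom=root, isomericSmiles=False)


def grammar_check(smiles: str) -> bool:
    """True iff the string parses and survives kekulization/valence checks."""
    if not smiles or not isinstance(smiles, str):
        return False
    try:
        return Chem.MolFromSmiles(smiles) is not None
    except Exception:  # pragma: no cover - RDKit raises only on exotic input
        return False


def canonical(smiles: str) -> str | None:
    """Canonical form of a SMILES string, or None if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def read_smiles_file(path) -> list[str]:
    """Read one SMILES per line; an optional tab-separated id is ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(line.split("\t")[0].split()[0])
    return out


def write_smiles_file(path, smiles_list) -> None:
    with open(path, "w") as fh:
        for s in smiles_list:
            fh.write(s + "\n")
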