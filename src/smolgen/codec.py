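"""SELFIES-style molecular string codec with bracket-level tokenization.

SELFIES (Self-Referencing Embedded Strings) is a molecular string grammar in
which *every* token sequence derives a valid molecule: bond orders are capped
by the remaining valence of the atoms involved, branch and ring symbols read
their length/target from the following index tokens, and derivation simply
stops when the attachment point is saturated.  That totality is what lets a
token-level language model guarantee 100% chemical validity of its samples,
and is the property the downstream RL stage relies on (a policy can drift
arbitrarily in token space without ever producing an unparseable string).

This module implements the grammar over the neutral organic subset
(C, N, O, S, P, F, Cl, Br, I; no formal charges, isotopes or radicals;
stereochemistry is stripped on encoding), which is the universe of the
synthetic drug-like corpora used throughout the toolkit.  Encoding walks the
kekulized molecular graph depth-first, emitting one bracketed token per atom,
``[BranchK]`` headers for side chains and ``[RingK]`` back-references for ring
closures; decoding replays the derivation with RDKit bookkeeping.

Round trip: ``decode(encode(smiles))`` reproduces the RDKit-canonical SMILES
of the (stereo-stripped) input molecule.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ConversionError",
    "TokenizationError",
    "VocabularyError",
    "PAD", "SOS", "EOS",
    "split_tokens",
    "smiles_to_selfies",
    "selfies_to_smiles",
    "tokens_to_smiles",
    "smiles_to_tokens",
    "token_category",
    "Vocabulary",
    "build_vocabulary",
    "TokenizedMolecule",
    "encode",
    "decode",
    "decode_ids",
]


class ConversionError(ValueError):
    """SMILES cannot be parsed or lies outside the supported chemical subset."""


class TokenizationError(ValueError):
    """Malformed bracket structure; carries the byte offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class VocabularyError(ValueError):
    """Vocabulary construction or lookup failure."""


PAD = "[PAD]"
SOS = "[SOS]"
EOS = "[EOS]"
SPECIAL_TOKENS = (PAD, SOS, EOS)

# Default valences of the supported neutral elements.
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
            "F": 1, "Cl": 1, "Br": 1, "I": 1}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}

# Index alphabet: tokens double as base-16 digits after Ring/Branch symbols.
INDEX_ALPHABET = (
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]",
)
_INDEX_OF = {t: i for i, t in enumerate(INDEX_ALPHABET)}

_ATOM_RE = re.compile(r"\[([=#]?)(C|N|O|S|P|F|Cl|Br|I)\]$")
_BRANCH_RE = re.compile(r"\[([=#]?)Branch([12])\]$")
_RING_RE = re.compile(r"\[([=#]?)Ring([12])\]$")


# ---------------------------------------------------------------------------
# Tokenization


def split_tokens(selfies: str) -> list[str]:
    """Split a SELFIES string at each closing bracket.

    Every token of the result starts with ``[`` and ends with ``]`` and their
    concatenation equals the input.
    """
    tokens: list[str] = []
    i = 0
    n = len(selfies)
    while i < n:
        if selfies[i] != "[":
            raise TokenizationError("expected '['", i)
        j = selfies.find("]", i)
        if j < 0:
            raise TokenizationError("unclosed bracket", i)
        tokens.append(selfies[i:j + 1])
        i = j + 1
    return tokens


def token_category(token: str) -> str:
    """Assign a token its vocabulary category (control vs. chemistry classes)."""
    if token in SPECIAL_TOKENS:
        return "Special"
    body = token[1:-1] if token.startswith("[") and token.endswith("]") else token
    if "Branch" in body:
        return "Branch (ramifications)"
    if "Ring" in body:
        return "Ring (ring closures)"
    if "@" in body:
        return "Stereochemistry (chiral centers)"
    if body.startswith("/") or body.startswith("\\"):
        return "Directed bond"
    if "+" in body or "-" in body or re.search(r"[A-Za-z]H\d*$", body):
        return "Formal charge/explicit H"
    return "Pure atoms"


def _index_value(tokens: Sequence[str]) -> int:
    value = 0
    for t in tokens:
        value = value * 16 + _INDEX_OF.get(t, 0)
    return value


def _index_tokens(value: int, width: int) -> list[str]:
    digits = []
    for _ in range(width):
        digits.append(INDEX_ALPHABET[value % 16])
        value //= 16
    return digits[::-1]


# ---------------------------------------------------------------------------
# Decoding (total: never fails on any token sequence)


class _Builder:
    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.free: list[int] = []

    def add_atom(self, element: str) -> int:
        idx = self.mol.AddAtom(Chem.Atom(element))
        self.free.append(_VALENCE[element])
        return idx

    def add_bond(self, a: int, b: int, order: int) -> None:
        bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE}[order]
        self.mol.AddBond(a, b, bt)
        self.free[a] -= order
        self.free[b] -= order


def _derive(toks: Sequence[str], builder: _Builder, attach: int | None) -> None:
    prev = attach
    i = 0
    while i < len(toks):
        tok = toks[i]
        i += 1
        m = _ATOM_RE.match(tok)
        if m:
            order = _PREFIX_BOND[m.group(1)]
            element = m.group(2)
            if prev is None:
                prev = builder.add_atom(element)
                continue
            if builder.free[prev] <= 0:
                return  # attachment saturated: derivation of this chain ends
            order = min(order, builder.free[prev], _VALENCE[element])
            new = builder.add_atom(element)
            builder.add_bond(prev, new, order)
            prev = new
            continue
        m = _BRANCH_RE.match(tok)
        if m:
            width = int(m.group(2))
            idx_toks = toks[i:i + width]
            i += width
            if len(idx_toks) < width:
                return
            length = _index_value(idx_toks) + 1
            sub = toks[i:i + length]
            i += length
            if prev is not None and builder.free[prev] > 0:
                _derive(sub, builder, attach=prev)
            continue
        m = _RING_RE.match(tok)
        if m:
            order = _PREFIX_BOND[m.group(1)]
            width = int(m.group(2))
            idx_toks = toks[i:i + width]
            i += width
            if len(idx_toks) < width:
                return
            if prev is None:
                continue
            target = prev - (_index_value(idx_toks) + 1)
            if target < 0:
                target = 0
            if target == prev or builder.mol.GetBondBetweenAtoms(prev, target):
                continue
            order = min(order, builder.free[prev], builder.free[target])
            if order > 0:
                builder.add_bond(prev, target, order)
            continue
        # Unknown symbol (e.g. a control token leaked into the stream): skip.
    return


def tokens_to_smiles(tokens: Sequence[str]) -> str:
    """Derive a molecule from any chemical-token sequence; returns canonical SMILES.

    Total by construction: bond orders are capped by remaining valence,
    saturated attachments end the derivation, truncated branch/ring operands
    are discarded.  A sequence deriving zero atoms yields the empty string.
    """
    builder = _Builder()
    _derive(list(tokens), builder, attach=None)
    if builder.mol.GetNumAtoms() == 0:
        return ""
    mol = builder.mol.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def selfies_to_smiles(selfies: str) -> str:
    """Decode a SELFIES string to canonical SMILES."""
    if not selfies:
        raise ConversionError("empty SELFIES string")
    return tokens_to_smiles(split_tokens(selfies))


# ---------------------------------------------------------------------------
# Encoding


def _check_supported(mol: Chem.Mol) -> None:
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ConversionError("multi-fragment (dot-disconnected) molecules are unsupported")
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _VALENCE:
            raise ConversionError(f"unsupported element {sym!r}")
        if atom.GetFormalCharge() != 0:
            raise ConversionError(f"formal charge on atom {atom.GetIdx()} unsupported")
        if atom.GetIsotope() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise ConversionError("isotopes/radicals unsupported")


def smiles_to_tokens(smiles: str) -> list[str]:
    """Encode a SMILES string as a chemical-token list (no control tokens).

    The molecule is canonicalized, stereochemistry stripped and the Kekulé
    graph walked depth-first from the first atom of the canonical ordering,
    so a given canonical SMILES always yields the same token sequence.
    """
    if not smiles:
        raise ConversionError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConversionError(f"unparseable SMILES: {smiles!r}")
    # Re-parse the canonical form so atom order is canonical-string order.
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    Chem.RemoveStereochemistry(mol)
    _check_supported(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if used > _VALENCE[atom.GetSymbol()]:
            raise ConversionError(
                f"atom {atom.GetIdx()} ({atom.GetSymbol()}) exceeds supported valence")

    pos: dict[int, int] = {}
    visited: set[int] = set()
    closed: set[int] = set()
    counter = [0]

    def bond_order(a: int, b: int) -> int:
        return int(mol.GetBondBetweenAtoms(a, b).GetBondTypeAsDouble())

    def ring_tokens(span: int, order: int) -> list[str]:
        prefix = _BOND_PREFIX[order]
        if span < 16:
            return [f"[{prefix}Ring1]"] + _index_tokens(span, 1)
        if span < 256:
            return [f"[{prefix}Ring2]"] + _index_tokens(span, 2)
        raise ConversionError("ring span exceeds 256 atoms")

    def branch_wrap(sub: list[str]) -> list[str]:
        length = len(sub)
        if length <= 16:
            return ["[Branch1]"] + _index_tokens(length - 1, 1) + sub
        if length <= 256:
            return ["[Branch2]"] + _index_tokens(length - 1, 2) + sub
        raise ConversionError("branch exceeds 256 tokens")

    def walk(a: int, parent: int | None, order_from_parent: int) -> list[str]:
        visited.add(a)
        pos[a] = counter[0]
        counter[0] += 1
        prefix = _BOND_PREFIX[order_from_parent]
        toks = [f"[{prefix}{mol.GetAtomWithIdx(a).GetSymbol()}]"]
        neighbors = sorted(nb.GetIdx() for nb in mol.GetAtomWithIdx(a).GetNeighbors())
        for nb in neighbors:
            if nb == parent or nb not in visited:
                continue
            bidx = mol.GetBondBetweenAtoms(a, nb).GetIdx()
            if bidx in closed:
                continue
            closed.add(bidx)
            toks += ring_tokens(pos[a] - pos[nb] - 1, bond_order(a, nb))
        subtrees = []
        for nb in neighbors:
            if nb not in visited:
                subtrees.append(walk(nb, a, bond_order(a, nb)))
        for sub in subtrees[:-1]:
            toks += branch_wrap(sub)
        if subtrees:
            toks += subtrees[-1]
        return toks

    return walk(0, None, 1)


def smiles_to_selfies(smiles: str) -> str:
    """Convert SMILES to a SELFIES string (bracketed tokens, concatenated)."""
    return "".join(smiles_to_tokens(smiles))


# ---------------------------------------------------------------------------
# Vocabulary


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with control tokens and a padded logit space.

    ``padded_size`` is the model's output-layer width (default 512); ids at or
    beyond ``len(tokens)`` are unused logit slots that never appear in
    encodings.
    """

    tokens: tuple[str, ...]
    padded_size: int = 512
    token_to_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tokens[:3] != SPECIAL_TOKENS:
            raise VocabularyError("tokens must start with [PAD], [SOS], [EOS]")
        if len(set(self.tokens)) != len(self.tokens):
            raise VocabularyError("duplicate tokens")
        if len(self.tokens) > self.padded_size:
            raise VocabularyError(
                f"{len(self.tokens)} tokens exceed padded_size {self.padded_size}; "
                "increase padded_size")
        object.__setattr__(self, "token_to_id",
                           {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def sos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    @property
    def chemical_ids(self) -> np.ndarray:
        """Ids of non-control tokens (the sampler's admissible chemistry)."""
        return np.arange(3, len(self.tokens))

    def category_of(self, token: str) -> str:
        if token not in self.token_to_id:
            raise VocabularyError(f"token {token!r} not in vocabulary")
        return token_category(token)

    def is_atom_token(self, token_id: int) -> bool:
        return _ATOM_RE.match(self.tokens[token_id]) is not None

    @property
    def sha256(self) -> str:
        payload = "\n".join(self.tokens) + f"\n#padded_size={self.padded_size}"
        return hashlib.sha256(payload.encode()).hexdigest()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# smolgen vocabulary v1\n")
            fh.write(f"# padded_size={self.padded_size}\n")
            for t in self.tokens:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        padded_size = 512
        tokens: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    m = re.search(r"padded_size=(\d+)", line)
                    if m:
                        padded_size = int(m.group(1))
                    continue
                if line:
                    tokens.append(line)
        return cls(tokens=tuple(tokens), padded_size=padded_size)


def build_vocabulary(corpus: Iterable, padded_size: int = 512) -> Vocabulary:
    """Collect all tokens observed in a corpus into a deterministic vocabulary.

    Control tokens occupy ids 0-2; observed chemical tokens follow in
    lexicographic order, so the result is independent of corpus order.
    Accepts MoleculeEntry objects or plain SMILES strings.
    """
    observed: set[str] = set()
    empty = True
    for entry in corpus:
        empty = False
        smiles = getattr(entry, "smiles", entry)
        observed.update(smiles_to_tokens(smiles))
    if empty:
        raise VocabularyError("empty corpus")
    tokens = SPECIAL_TOKENS + tuple(sorted(observed))
    if len(tokens) > padded_size:
        raise VocabularyError(
            f"{len(tokens)} tokens exceed padded_size {padded_size}; "
            "increase padded_size")
    return Vocabulary(tokens=tokens, padded_size=padded_size)


# ---------------------------------------------------------------------------
# Sequence encoding


@dataclass(frozen=True)
class TokenizedMolecule:
    """A molecule as ``[SOS] chemistry... [EOS]`` ids, right-padded to max_len."""

    ids: np.ndarray
    length: int

    def __post_init__(self) -> None:
        if self.length < 2 or self.length > len(self.ids):
            raise ValueError("invalid length")


def encode(entry, vocab: Vocabulary, max_len: int = 82) -> TokenizedMolecule:
    """Encode a molecule as [SOS] + chemical tokens + [EOS], padded to max_len."""
    smiles = getattr(entry, "smiles", entry)
    toks = smiles_to_tokens(smiles)
    if len(toks) + 2 > max_len:
        raise ConversionError(
            f"molecule needs {len(toks) + 2} tokens, exceeding max_len {max_len}")
    ids = np.full(max_len, vocab.pad_id, dtype=np.int32)
    ids[0] = vocab.sos_id
    for i, t in enumerate(toks, start=1):
        if t not in vocab.token_to_id:
            raise VocabularyError(f"out-of-vocabulary token {t!r}")
        ids[i] = vocab.token_to_id[t]
    ids[len(toks) + 1] = vocab.eos_id
    return TokenizedMolecule(ids=ids, length=len(toks) + 2)


def decode(tm: TokenizedMolecule, vocab: Vocabulary) -> str:
    """Decode a TokenizedMolecule back to canonical SMILES."""
    return decode_ids(tm.ids, vocab)


def decode_ids(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Decode an id sequence: skip [SOS]/[PAD], stop at the first [EOS]."""
    toks: list[str] = []
    for i in ids:
        i = int(i)
        if i == vocab.eos_id:
            break
        if i in (vocab.sos_id, vocab.pad_id):
            continue
        if i >= len(vocab.tokens):
            continue  # unused logit slot: ignore defensively
        toks.append(vocab.tokens[i])
    return tokens_to_smiles(toks)
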