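"""Drug-like molecule corpora: synthetic generation, filtering and .smi I/O.

The synthetic generator stands in for a large screening-library subset
(molecular weight 250-500 Da, LogP 1-4.5, encoded length at most 82 tokens —
a Lipinski-style window for orally available drug candidates).  It samples
random SELFIES token sequences, which always derive valid molecules, decodes
them and rejection-filters on the descriptor window, so every downstream
stage (vocabulary, pretraining, RL, evaluation) can run without any external
database.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from . import codec

__all__ = [
    "MoleculeEntry",
    "CorpusFilter",
    "CorpusGenerationError",
    "generate_synthetic_corpus",
    "apply_corpus_filter",
    "read_smiles_file",
    "write_smiles_file",
    "write_corpus_csv",
]

logger = logging.getLogger(__name__)


class CorpusGenerationError(RuntimeError):
    """Raised when the rejection sampler exhausts its attempt budget."""


@dataclass(frozen=True)
class MoleculeEntry:
    """One corpus record: canonical SMILES plus the two filter descriptors."""

    smiles: str
    mol_weight: float
    logp: float

    def __post_init__(self) -> None:
        if self.mol_weight <= 0:
            raise ValueError("mol_weight must be positive")


@dataclass(frozen=True)
class CorpusFilter:
    """Descriptor window for drug-like corpora (daltons, LogP, token count)."""

    mw_min: float = 250.0
    mw_max: float = 500.0
    logp_min: float = 1.0
    logp_max: float = 4.5
    max_tokens: int = 82

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if not self.logp_min < self.logp_max:
            raise ValueError("logp_min must be < logp_max")
        if self.max_tokens < 3:
            raise ValueError("max_tokens must be >= 3 ([SOS], one token, [EOS])")

    def admits_descriptors(self, mw: float, logp: float) -> bool:
        return (self.mw_min <= mw <= self.mw_max
                and self.logp_min <= logp <= self.logp_max)


def entry_from_smiles(smiles: str) -> MoleculeEntry:
    """Canonicalize a SMILES string and compute its filter descriptors."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise codec.ConversionError(f"unparseable SMILES: {smiles!r}")
    return MoleculeEntry(
        smiles=Chem.MolToSmiles(mol),
        mol_weight=Descriptors.MolWt(mol),
        logp=Descriptors.MolLogP(mol),
    )


# Weighted chemical-token alphabet for the rejection sampler.  Carbon-rich
# with enough N/O to keep LogP inside the window, and branch/ring symbols at
# roughly the frequency drug-like frameworks exhibit.
_ALPHABET: tuple[tuple[str, float], ...] = (
    ("[C]", 30.0), ("[=C]", 12.0), ("[N]", 8.0), ("[=N]", 3.0),
    ("[O]", 8.0), ("[=O]", 5.0), ("[S]", 1.5), ("[F]", 2.0),
    ("[Cl]", 1.5), ("[Branch1]", 9.0), ("[Ring1]", 8.0),
    ("[#C]", 1.0), ("[P]", 0.3), ("[Br]", 0.5),
)
_TOKENS = tuple(t for t, _ in _ALPHABET)
_WEIGHTS = np.array([w for _, w in _ALPHABET])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

# Chemical tokens per raw draw: uniform over [8, 60], mimicking the long-tail
# length distribution of screening libraries at desk scale.
_MIN_DRAW_TOKENS = 8
_MAX_DRAW_TOKENS = 60


def generate_synthetic_corpus(
    n: int,
    seed: int,
    filter: CorpusFilter | None = None,
    max_attempts: int | None = None,
) -> list[MoleculeEntry]:
    """Rejection-sample ``n`` molecules satisfying ``filter``, reproducibly.

    Random SELFIES token sequences (8-60 chemical tokens, weighted alphabet)
    are decoded — every sequence yields a valid, single-fragment molecule —
    and kept iff molecular weight, LogP and encoded token length all lie
    inside the window.  Identical ``(n, seed, filter)`` reproduce the
    identical list.

    Raises
    ------
    CorpusGenerationError
        If the attempt budget (default ``1000 + 200*n``) is exhausted; the
        message names the filter dimension that rejected most candidates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    filt = filter or CorpusFilter()
    budget = max_attempts if max_attempts is not None else 1000 + 200 * n
    rng = np.random.default_rng(seed)
    out: list[MoleculeEntry] = []
    rejected = {"molecular weight": 0, "LogP": 0, "token length": 0, "empty": 0}
    attempts = 0
    while len(out) < n:
        if attempts >= budget:
            limiting = max(rejected, key=rejected.get)
            raise CorpusGenerationError(
                f"attempt budget {budget} exhausted after accepting "
                f"{len(out)}/{n}; limiting filter: {limiting} "
                f"(rejections: {rejected})")
        attempts += 1
        k = int(rng.integers(_MIN_DRAW_TOKENS, _MAX_DRAW_TOKENS + 1))
        seq = [_TOKENS[i] for i in rng.choice(len(_TOKENS), size=k, p=_WEIGHTS)]
        smiles = codec.tokens_to_smiles(seq)
        if not smiles:
            rejected["empty"] += 1
            continue
        entry = entry_from_smiles(smiles)
        if not (filt.mw_min <= entry.mol_weight <= filt.mw_max):
            rejected["molecular weight"] += 1
            continue
        if not (filt.logp_min <= entry.logp <= filt.logp_max):
            rejected["LogP"] += 1
            continue
        if len(codec.smiles_to_tokens(entry.smiles)) + 2 > filt.max_tokens:
            rejected["token length"] += 1
            continue
        out.append(entry)
    return out


def apply_corpus_filter(
    entries: list[MoleculeEntry],
    filter: CorpusFilter | None = None,
) -> list[MoleculeEntry]:
    """Keep entries inside the descriptor window with encoded length in bounds.

    Order is preserved; unparseable/unencodable entries are dropped with a
    logged reason rather than raising.
    """
    filt = filter or CorpusFilter()
    kept: list[MoleculeEntry] = []
    for entry in entries:
        if not filt.admits_descriptors(entry.mol_weight, entry.logp):
            continue
        try:
            n_tokens = len(codec.smiles_to_tokens(entry.smiles)) + 2
        except codec.ConversionError as exc:
            logger.warning("dropping unencodable entry %r: %s", entry.smiles, exc)
            continue
        if n_tokens > filt.max_tokens:
            continue
        kept.append(entry)
    return kept


def read_smiles_file(path) -> list[MoleculeEntry]:
    """Read a .smi file (``SMILES[<TAB>id]`` per line), computing descriptors.

    Malformed lines are skipped with a warning carrying the line number; an
    empty file yields an empty list.
    """
    entries: list[MoleculeEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            smiles = line.split("\t")[0].split()[0]
            try:
                entries.append(entry_from_smiles(smiles))
            except (codec.ConversionError, ValueError) as exc:
                warnings.warn(f"{path}:{lineno}: skipping malformed line: {exc}")
    return entries


def write_smiles_file(entries: list[MoleculeEntry], path) -> None:
    """Write one canonical SMILES per line."""
    with open(path, "w") as fh:
        for entry in entries:
            fh.write(entry.smiles + "\n")


def write_corpus_csv(entries: list[MoleculeEntry], path) -> None:
    """CSV export with columns smiles, mol_weight, logp."""
    pd.DataFrame(
        [(e.smiles, e.mol_weight, e.logp) for e in entries],
        columns=["smiles", "mol_weight", "logp"],
    ).to_csv(path, index=False)
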