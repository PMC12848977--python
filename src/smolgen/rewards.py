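"""Docking-score reward algebra for RL fine-tuning.

Docking scores (kcal/mol; more negative = stronger predicted binding) are
mapped to rewards in (0, 1) by an affine rescale followed by a logistic
squash:

    rescale:  the empirical docking range [-12, -6] kcal/mol maps linearly
              onto [-6, 6]  (with defaults, f(x) = 2x + 18);
    squash:   s(x) = 1 / (1 + exp(-x));
    reward:   R(x) = 1 - s(f(x)),  so better (more negative) docking gives
              higher reward, R(-9) = 0.5, and R(-12) + R(-6) = 1 by logistic
              symmetry.

The two-pocket variant is the convex combination
R2(x1, x2) = alpha*[1 - s(f(x1))] + beta*[1 - s(f(x2))] with alpha+beta = 1,
used for dual-target design (equal preference: alpha = beta = 0.5).  A
scaffold gate zeroes the reward of molecules that do not contain a required
substructure.

Real docking engines plug in through the :class:`DockingAdapter` contract;
:func:`surrogate_docking_adapter` provides a deterministic, desk-scale
stand-in whose pseudo-scores vary smoothly with structural descriptors, so
reward landscapes are non-trivial and fully reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

__all__ = [
    "RewardSpec",
    "DockingAdapter",
    "ScaffoldConstraint",
    "rescale_score",
    "single_pocket_reward",
    "two_pocket_reward",
    "scaffold_gated_reward",
    "surrogate_docking_adapter",
    "SurrogateDockingAdapter",
    "CsvDockingAdapter",
    "adapter_reward_fn",
]


@dataclass(frozen=True)
class RewardSpec:
    """Rescale window and pocket weights for the logistic docking reward."""

    dock_lo: float = -12.0
    dock_hi: float = -6.0
    map_lo: float = -6.0
    map_hi: float = 6.0
    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not self.dock_lo < self.dock_hi:
            raise ValueError("dock_lo must be < dock_hi")
        if not self.map_lo < self.map_hi:
            raise ValueError("map_lo must be < map_hi")
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("pocket weights must satisfy alpha + beta = 1, both >= 0")


@runtime_checkable
class DockingAdapter(Protocol):
    """Contract for docking engines: SMILES batch + pocket id -> kcal/mol scores."""

    deterministic: bool
    provenance: str

    def score_batch(self, smiles: Sequence[str], pocket: str) -> list[float]:
        ...


@dataclass(frozen=True)
class ScaffoldConstraint:
    """A required substructure, optionally with SELFIES tokens to prime generation."""

    scaffold: str
    prefix_tokens: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self._query() is None:
            raise ValueError(f"unparseable scaffold pattern {self.scaffold!r}")

    def _query(self) -> Chem.Mol | None:
        mol = Chem.MolFromSmiles(self.scaffold)
        if mol is None:
            mol = Chem.MolFromSmarts(self.scaffold)
        return mol

    def matches(self, smiles: str) -> bool:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return False
        return mol.HasSubstructMatch(self._query())


def rescale_score(x: float, spec: RewardSpec | None = None) -> float:
    """Affine map sending [dock_lo, dock_hi] onto [map_lo, map_hi].

    Out-of-range scores extrapolate linearly; the logistic downstream
    saturates them smoothly.
    """
    spec = spec or RewardSpec()
    slope = (spec.map_hi - spec.map_lo) / (spec.dock_hi - spec.dock_lo)
    return spec.map_lo + slope * (x - spec.dock_lo)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def single_pocket_reward(x: float, spec: RewardSpec | None = None) -> float:
    """R(x) = 1 - logistic(rescale(x)); strictly decreasing in x, range (0, 1).

    Evaluated as logistic(-rescale(x)) — the same function, but accurate near
    0 where the 1 - sigma form would round away.
    """
    spec = spec or RewardSpec()
    return float(_logistic(-rescale_score(x, spec)))


def two_pocket_reward(x1: float, x2: float,
                      spec: RewardSpec | None = None) -> float:
    """Convex combination of the two single-pocket rewards (weights alpha, beta)."""
    spec = spec or RewardSpec()
    return float(spec.alpha * single_pocket_reward(x1, spec)
                 + spec.beta * single_pocket_reward(x2, spec))


def scaffold_gated_reward(smiles: str, base_reward: float,
                          constraint: ScaffoldConstraint) -> float:
    """Pass ``base_reward`` through iff the molecule contains the scaffold, else 0."""
    return base_reward if constraint.matches(smiles) else 0.0


class SurrogateDockingAdapter:
    """Deterministic pseudo-docking engine for desk-scale experiments.

    Maps each molecule to a smooth score in roughly [-12, -6] kcal/mol via a
    seeded random linear form over standardized structural descriptors (heavy
    atoms, rings, aromatic atoms, heteroatom fraction, rotatable bonds, LogP):
    score = -9 + 3*tanh(w . z).  Different pocket identifiers hash to
    different weight vectors, so single- and two-pocket landscapes differ.
    Unparseable molecules receive the worst-case score ``dock_hi`` instead of
    aborting the batch.
    """

    deterministic = True
    provenance = "surrogate"

    # Standardization constants for descriptor z-scores, set to the location
    # and spread of the synthetic drug-like corpus so that typical molecules
    # score near the centre of the docking range (non-trivial landscape).
    _MEANS = np.array([21.0, 0.6, 0.1, 0.35, 11.0, 2.4])
    _SCALES = np.array([4.0, 0.8, 0.5, 0.10, 4.5, 0.9])

    def __init__(self, seed: int = 0, dock_hi: float = -6.0):
        self.seed = seed
        self.dock_hi = dock_hi

    def _weights(self, pocket: str) -> np.ndarray:
        digest = hashlib.sha256(pocket.encode()).digest()
        mix = (self.seed ^ int.from_bytes(digest[:4], "little")) % (2 ** 31)
        rng = np.random.default_rng(mix)
        w = rng.normal(0, 1, size=len(self._MEANS))
        return w / np.linalg.norm(w)

    def _descriptors(self, mol: Chem.Mol) -> np.ndarray:
        n_heavy = mol.GetNumHeavyAtoms()
        return np.array([
            n_heavy,
            rdMolDescriptors.CalcNumRings(mol),
            sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
            sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
            / max(n_heavy, 1),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            Descriptors.MolLogP(mol),
        ])

    def score_batch(self, smiles: Sequence[str], pocket: str = "default") -> list[float]:
        w = self._weights(pocket)
        out: list[float] = []
        for s in smiles:
            mol = Chem.MolFromSmiles(s) if s else None
            if mol is None or mol.GetNumHeavyAtoms() == 0:
                out.append(self.dock_hi)
                continue
            z = (self._descriptors(mol) - self._MEANS) / self._SCALES
            out.append(float(-9.0 + 3.0 * np.tanh(w @ z)))
        return out


def surrogate_docking_adapter(seed: int = 0) -> SurrogateDockingAdapter:
    """Build the deterministic desk-scale surrogate docking adapter."""
    return SurrogateDockingAdapter(seed=seed)


class CsvDockingAdapter:
    """Replay precomputed docking scores from a CSV (smiles, pocket, score).

    Lookup is by toolkit-canonical SMILES; molecules absent from the table
    receive the worst-case score ``dock_hi``.
    """

    deterministic = True
    provenance = "csv"

    def __init__(self, path, dock_hi: float = -6.0):
        frame = pd.read_csv(path)
        required = {"smiles", "pocket", "score"}
        if not required.issubset(frame.columns):
            raise ValueError(f"CSV must have columns {sorted(required)}")
        self.dock_hi = dock_hi
        self._table: dict[tuple[str, str], float] = {}
        for _, row in frame.iterrows():
            mol = Chem.MolFromSmiles(str(row["smiles"]))
            if mol is None:
                continue
            key = (Chem.MolToSmiles(mol), str(row["pocket"]))
            self._table[key] = float(row["score"])

    def score_batch(self, smiles: Sequence[str], pocket: str) -> list[float]:
        out = []
        for s in smiles:
            mol = Chem.MolFromSmiles(s) if s else None
            if mol is None:
                out.append(self.dock_hi)
                continue
            out.append(self._table.get((Chem.MolToSmiles(mol), pocket),
                                       self.dock_hi))
        return out


def adapter_reward_fn(adapter: DockingAdapter, pocket: str,
                      spec: RewardSpec | None = None,
                      pocket2: str | None = None,
                      constraint: ScaffoldConstraint | None = None,
                      ) -> Callable[[Sequence[str]], np.ndarray]:
    """Compose adapter scoring, reward squashing and optional scaffold gating.

    Returns a batch function SMILES list -> rewards in [0, 1].  With
    ``pocket2`` set, uses the two-pocket convex combination.  The latest raw
    scores are kept on the returned function (``last_scores`` attribute) for
    diagnostics.
    """
    spec = spec or RewardSpec()
    slope = (spec.map_hi - spec.map_lo) / (spec.dock_hi - spec.dock_lo)

    def pocket_reward(x: np.ndarray) -> np.ndarray:
        return _logistic(-(spec.map_lo + slope * (x - spec.dock_lo)))

    def fn(smiles: Sequence[str]) -> np.ndarray:
        x1 = np.asarray(adapter.score_batch(smiles, pocket), dtype=float)
        if pocket2 is not None:
            x2 = np.asarray(adapter.score_batch(smiles, pocket2), dtype=float)
            r = spec.alpha * pocket_reward(x1) + spec.beta * pocket_reward(x2)
            fn.last_scores = 0.5 * (x1 + x2)
        else:
            r = pocket_reward(x1)
            fn.last_scores = x1
        if constraint is not None:
            gate = np.array([constraint.matches(s) for s in smiles])
            r = np.where(gate, r, 0.0)
        return r

    fn.last_scores = np.empty(0)
    return fn
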