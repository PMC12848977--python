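"""Generation-quality evaluation: the nine-criterion panel, novelty analysis
and property-distribution comparison.

The panel evaluates one generation batch on: mean docking score (through a
docking adapter), QED, percentage of molecules with LogP in [0, 5], synthetic
accessibility (SAS, 1 easy - 10 hard), internal diversity (1 minus mean
pairwise Tanimoto similarity of 2048-bit radius-2 Morgan/ECFP4 fingerprints),
toxicity-flagged percentage (a molecule is flagged if any of 12 endpoint
probabilities reaches 0.5), and validity / uniqueness / novelty in the
GuacaMol sense — uniqueness computed over valid molecules and novelty over
unique ones, with canonical SMILES as the identity key throughout.

Novelty is refined by a 2x2 molecule/scaffold confusion: a molecule is novel
iff its maximum fingerprint Tanimoto similarity against the reference falls
below a threshold (default 0.4), and its scaffold is novel iff its
Bemis-Murcko framework is absent from the reference scaffold set.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Descriptors, QED
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.DataStructs import BulkTanimotoSimilarity

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsError",
    "MetricsReport",
    "NoveltyConfusion",
    "ToxicityPredictor",
    "StructuralAlertToxicityPredictor",
    "diversity",
    "validity_uniqueness_novelty",
    "drug_likeness_panel",
    "toxicity_pass_rate",
    "novelty_scaffold_confusion",
    "property_distribution_report",
    "evaluate_batch",
]

_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class MetricsError(ValueError):
    """A metric was requested on an input where it is undefined."""


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    return Chem.MolToSmiles(mol) if mol is not None and mol.GetNumAtoms() else None


def _fingerprints(smiles: Sequence[str]):
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    return [_FPGEN.GetFingerprint(m) for m in mols if m is not None]


# ---------------------------------------------------------------------------
# Diversity


def diversity(molecules: Sequence[str]) -> float:
    """1 - mean pairwise Tanimoto similarity (2048-bit ECFP4) over all pairs."""
    fps = _fingerprints(molecules)
    if len(fps) < 2:
        raise MetricsError("diversity is undefined for fewer than 2 molecules")
    sims = []
    for i in range(1, len(fps)):
        sims.extend(BulkTanimotoSimilarity(fps[i], fps[:i]))
    return float(1.0 - np.mean(sims))


# ---------------------------------------------------------------------------
# Validity / uniqueness / novelty


def validity_uniqueness_novelty(
    generated: Sequence[str],
    reference: set[str] | Sequence[str],
) -> tuple[float, float, float]:
    """Percentages in dependency order: valid of all, unique of valid, novel of unique.

    ``reference`` must hold toolkit-canonical SMILES; generated strings are
    canonicalized before comparison so dialect aliases collapse.
    """
    if not generated:
        raise MetricsError("empty generation batch")
    reference = set(reference)
    canon = [_canonical(s) for s in generated]
    valid = [c for c in canon if c is not None]
    validity = 100.0 * len(valid) / len(generated)
    unique: list[str] = []
    seen: set[str] = set()
    for c in valid:
        if c not in seen:
            seen.add(c)
            unique.append(c)
    uniqueness = 100.0 * len(unique) / len(valid) if valid else 0.0
    novel = [c for c in unique if c not in reference]
    novelty = 100.0 * len(novel) / len(unique) if unique else 0.0
    return validity, uniqueness, novelty


# ---------------------------------------------------------------------------
# Drug-likeness panel


def drug_likeness_panel(molecules: Sequence[str]) -> dict:
    """QED mean±sd, percentage with LogP in [0, 5], SAS mean±sd.

    Molecules the property provider rejects are excluded and counted.
    """
    qed_vals, logp_vals, sas_vals = [], [], []
    failures = 0
    for s in molecules:
        mol = Chem.MolFromSmiles(s) if s else None
        if mol is None or mol.GetNumAtoms() == 0:
            failures += 1
            continue
        try:
            qed_vals.append(QED.qed(mol))
            logp_vals.append(Descriptors.MolLogP(mol))
            sas_vals.append(sascorer.calculateScore(mol))
        except Exception as exc:  # pragma: no cover - provider edge cases
            failures += 1
            logger.warning("property provider failed on %r: %s", s, exc)
    if failures:
        logger.warning("drug_likeness_panel excluded %d molecules", failures)
    logp_arr = np.asarray(logp_vals)
    return {
        "qed_mean": float(np.mean(qed_vals)),
        "qed_sd": float(np.std(qed_vals)),
        "logp_in_range_pct": float(100.0 * np.mean((logp_arr >= 0) & (logp_arr <= 5))),
        "sas_mean": float(np.mean(sas_vals)),
        "sas_sd": float(np.std(sas_vals)),
        "excluded": failures,
    }


# ---------------------------------------------------------------------------
# Toxicity


@runtime_checkable
class ToxicityPredictor(Protocol):
    """Contract: one molecule -> 12 endpoint probabilities in [0, 1]."""

    def predict(self, smiles: str) -> Sequence[float]:
        ...


class StructuralAlertToxicityPredictor:
    """Deterministic 12-endpoint stub driven by structural alerts.

    Each endpoint is tied to a SMARTS alert (nitro groups, Michael acceptors,
    aldehydes, ...); a match yields probability 0.9, otherwise 0.05.  This is
    a test harness standing in for a trained multi-endpoint assay predictor,
    not a validated toxicity model.
    """

    _ALERTS = (
        "[N+](=O)[O-]", "C=CC=O", "[CX3H1]=O", "C1OC1", "N=[N+]=[N-]",
        "C(=O)Cl", "NN", "[SH]", "S(=O)(=O)F", "C(=O)OC(=O)", "[Br,I]CC=C",
        "N=C=O",
    )

    def __init__(self) -> None:
        self._queries = [Chem.MolFromSmarts(s) for s in self._ALERTS]

    def predict(self, smiles: str) -> list[float]:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            return [0.9] * 12
        return [0.9 if mol.HasSubstructMatch(q) else 0.05 for q in self._queries]


def toxicity_pass_rate(molecules: Sequence[str],
                       predictor: ToxicityPredictor) -> float:
    """Percentage of molecules flagged toxic (any endpoint probability >= 0.5)."""
    flagged = 0
    for s in molecules:
        probs = list(predictor.predict(s))
        if len(probs) != 12:
            raise MetricsError(
                f"toxicity predictor returned {len(probs)} endpoints, expected 12")
        if any(p >= 0.5 for p in probs):
            flagged += 1
    return 100.0 * flagged / len(molecules)


# ---------------------------------------------------------------------------
# Molecule/scaffold novelty confusion


@dataclass(frozen=True)
class NoveltyConfusion:
    """2x2 counts over (molecule novel?, scaffold novel?)."""

    novel_scaffold_novel: int
    novel_scaffold_known: int
    known_scaffold_novel: int
    known_scaffold_known: int
    threshold: float = 0.4

    @property
    def total(self) -> int:
        return (self.novel_scaffold_novel + self.novel_scaffold_known
                + self.known_scaffold_novel + self.known_scaffold_known)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.novel_scaffold_novel, self.novel_scaffold_known],
             [self.known_scaffold_novel, self.known_scaffold_known]],
            index=["Novel molecule", "Not novel molecule"],
            columns=["scaffold novel", "scaffold not novel"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _scaffold(smiles: str) -> str:
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


def novelty_scaffold_confusion(generated: Sequence[str],
                               reference: Sequence[str],
                               threshold: float = 0.4) -> NoveltyConfusion:
    """Cross molecule novelty (max Tanimoto < threshold) with scaffold novelty.

    Scaffold novelty: the generated molecule's Bemis-Murcko framework is
    absent from the reference's framework set (canonical-SMILES comparison).
    """
    if not generated or not reference:
        raise MetricsError("both molecule sets must be non-empty")
    ref_fps = _fingerprints(reference)
    ref_scaffolds = {_scaffold(s) for s in reference
                     if Chem.MolFromSmiles(s) is not None}
    counts = np.zeros((2, 2), dtype=int)
    for s in generated:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        max_sim = max(BulkTanimotoSimilarity(_FPGEN.GetFingerprint(mol), ref_fps))
        mol_novel = max_sim < threshold
        scaf_novel = _scaffold(s) not in ref_scaffolds
        counts[0 if mol_novel else 1, 0 if scaf_novel else 1] += 1
    return NoveltyConfusion(
        novel_scaffold_novel=int(counts[0, 0]),
        novel_scaffold_known=int(counts[0, 1]),
        known_scaffold_novel=int(counts[1, 0]),
        known_scaffold_known=int(counts[1, 1]),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Batch report and distribution comparison


@dataclass(frozen=True)
class MetricsReport:
    """The nine-criterion panel for one generation batch."""

    docking_mean: float
    docking_sd: float
    qed_mean: float
    qed_sd: float
    logp_in_range_pct: float
    sas_mean: float
    sas_sd: float
    diversity: float
    toxicity_flagged_pct: float
    validity_pct: float
    uniqueness_pct: float
    novelty_pct: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped export: criterion, value (two-decimal mean ± sd)."""
        rows = [
            ("Docking Score (kcal/mol, ↓)", f"{self.docking_mean:.2f} ± {self.docking_sd:.2f}"),
            ("QED (↑)", f"{self.qed_mean:.2f} ± {self.qed_sd:.2f}"),
            ("LogP (%, 0–5, ↑)", f"{self.logp_in_range_pct:.2f}"),
            ("SAS (↓)", f"{self.sas_mean:.2f} ± {self.sas_sd:.2f}"),
            ("Diversity (↑)", f"{self.diversity:.2f}"),
            ("Toxicity (%, ↓)", f"{self.toxicity_flagged_pct:.2f}"),
            ("Validity (%, ↑)", f"{self.validity_pct:.2f}"),
            ("Uniqueness (%, ↑)", f"{self.uniqueness_pct:.2f}"),
            ("Novelty (%, ↑)", f"{self.novelty_pct:.2f}"),
        ]
        return pd.DataFrame(rows, columns=["criterion", "value"])


def evaluate_batch(generated: Sequence[str], reference: Sequence[str],
                   adapter, pocket: str = "default",
                   predictor: ToxicityPredictor | None = None) -> MetricsReport:
    """Compute the full nine-criterion report for one generation batch."""
    predictor = predictor or StructuralAlertToxicityPredictor()
    ref_canon = {c for c in (_canonical(s) for s in reference) if c}
    validity, uniqueness, novelty = validity_uniqueness_novelty(generated, ref_canon)
    parseable = [s for s in generated if _canonical(s)]
    scores = np.asarray(adapter.score_batch(parseable, pocket))
    panel = drug_likeness_panel(parseable)
    return MetricsReport(
        docking_mean=float(scores.mean()),
        docking_sd=float(scores.std()),
        qed_mean=panel["qed_mean"], qed_sd=panel["qed_sd"],
        logp_in_range_pct=panel["logp_in_range_pct"],
        sas_mean=panel["sas_mean"], sas_sd=panel["sas_sd"],
        diversity=diversity(parseable),
        toxicity_flagged_pct=toxicity_pass_rate(parseable, predictor),
        validity_pct=validity, uniqueness_pct=uniqueness, novelty_pct=novelty,
    )


def property_distribution_report(set_a: Sequence, set_b: Sequence,
                                 labels: tuple[str, str] = ("set_a", "set_b"),
                                 predictor: ToxicityPredictor | None = None,
                                 ) -> pd.DataFrame:
    """Side-by-side property distributions of two corpora (means ± sd rows).

    Accepts MoleculeEntry objects or SMILES strings.  Rows: QED, LogP-in-range
    percentage, SAS, molecular weight, toxicity-flagged percentage.
    """
    if not len(set_a) or not len(set_b):
        raise MetricsError("both sets must be non-empty")
    predictor = predictor or StructuralAlertToxicityPredictor()

    def column(entries) -> dict:
        smiles = [getattr(e, "smiles", e) for e in entries]
        panel = drug_likeness_panel(smiles)
        mws = [Descriptors.MolWt(Chem.MolFromSmiles(s)) for s in smiles
               if Chem.MolFromSmiles(s) is not None]
        return {
            "QED (↑)": f"{panel['qed_mean']:.2f} ± {panel['qed_sd']:.2f}",
            "LogP (%, 0–5, ↑)": f"{panel['logp_in_range_pct']:.2f}",
            "SAS (↓)": f"{panel['sas_mean']:.2f} ± {panel['sas_sd']:.2f}",
            "MW (↓)": f"{np.mean(mws):.2f} ± {np.std(mws):.2f}",
            "Toxicity (%, ↓)": f"{toxicity_pass_rate(smiles, predictor):.2f}",
        }

    return pd.DataFrame({labels[0]: column(set_a), labels[1]: column(set_b)})
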