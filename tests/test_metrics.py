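"""Evaluation metrics: diversity, validity/uniqueness/novelty, panels, confusion."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.DataStructs import TanimotoSimilarity

from smolgen import metrics
from smolgen.metrics import (
    MetricsError, StructuralAlertToxicityPredictor, diversity,
    novelty_scaffold_confusion, toxicity_pass_rate, validity_uniqueness_novelty,
)


# ---------------------------------------------------------------------------
# diversity


def test_identical_copies_have_zero_diversity():
    assert diversity(["c1ccccc1"] * 5) == pytest.approx(0.0)


def test_disjoint_fingerprints_have_unit_diversity():
    assert diversity(["C", "N"]) == pytest.approx(1.0)


def test_diversity_matches_exhaustive_pair_oracle(small_corpus):
    smiles = [e.smiles for e in small_corpus[:12]]
    fps = [metrics._FPGEN.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
    sims = [TanimotoSimilarity(fps[i], fps[j])
            for i in range(len(fps)) for j in range(i + 1, len(fps))]
    assert diversity(smiles) == pytest.approx(1.0 - np.mean(sims), abs=1e-9)


def test_diversity_permutation_invariant_and_bounded(small_corpus):
    smiles = [e.smiles for e in small_corpus[:10]]
    d = diversity(smiles)
    assert 0.0 <= d <= 1.0
    assert diversity(list(reversed(smiles))) == pytest.approx(d)


def test_diversity_undefined_below_two_molecules():
    with pytest.raises(MetricsError):
        diversity(["CCO"])


# ---------------------------------------------------------------------------
# validity / uniqueness / novelty


def test_duplicates_reduce_uniqueness():
    v, u, n = validity_uniqueness_novelty(["CCO", "CCO", "CCN"], set())
    assert v == pytest.approx(100.0)
    assert u == pytest.approx(200 / 3)
    assert n == pytest.approx(100.0)


def test_novelty_is_set_difference_over_unique():
    ref = {Chem.MolToSmiles(Chem.MolFromSmiles("CCN"))}
    _, _, n = validity_uniqueness_novelty(["CCO", "CCN"], ref)
    assert n == pytest.approx(50.0)


def test_invalid_strings_lower_validity_only():
    v, u, n = validity_uniqueness_novelty(["CCO", "xxx((", "CCN", "C1CC"], set())
    assert v == pytest.approx(50.0)
    assert u == pytest.approx(100.0)


def test_dialect_aliases_collapse():
    v, u, _ = validity_uniqueness_novelty(["OCC", "CCO", "C(C)O"], set())
    assert v == pytest.approx(100.0)
    assert u == pytest.approx(100 / 3)


# ---------------------------------------------------------------------------
# drug-likeness panel


def test_panel_ranges_on_synthetic_corpus(small_corpus):
    smiles = [e.smiles for e in small_corpus[:60]]
    panel = metrics.drug_likeness_panel(smiles)
    # corpus guarantees LogP in [1, 4.5], a subset of the [0, 5] window
    assert panel["logp_in_range_pct"] == pytest.approx(100.0)
    assert 0.0 <= panel["qed_mean"] <= 1.0
    assert 1.0 <= panel["sas_mean"] <= 10.0


# ---------------------------------------------------------------------------
# toxicity


class _StubPredictor:
    def __init__(self, probs_by_smiles):
        self.probs = probs_by_smiles

    def predict(self, smiles):
        return self.probs[smiles]


def test_all_clear_predictor_flags_nothing():
    stub = _StubPredictor({"CCO": [0.0] * 12, "CCN": [0.0] * 12})
    assert toxicity_pass_rate(["CCO", "CCN"], stub) == 0.0


def test_half_flagged():
    stub = _StubPredictor({"CCO": [0.05] * 11 + [0.6], "CCN": [0.05] * 12})
    assert toxicity_pass_rate(["CCO", "CCN"], stub) == 50.0


def test_wrong_endpoint_count_is_contract_error():
    stub = _StubPredictor({"CCO": [0.1] * 11})
    with pytest.raises(MetricsError, match="12"):
        toxicity_pass_rate(["CCO"], stub)


def test_structural_alert_stub_is_deterministic_and_12_wide():
    predictor = StructuralAlertToxicityPredictor()
    probs = predictor.predict("O=[N+]([O-])c1ccccc1")  # nitrobenzene
    assert len(probs) == 12
    assert max(probs) >= 0.5  # nitro alert fires
    assert predictor.predict("CCO") == [0.05] * 12


# ---------------------------------------------------------------------------
# novelty/scaffold confusion


def test_self_comparison_is_all_known():
    smiles = ["Cc1ccccc1", "CCc1ccccc1", "CCO"]
    table = novelty_scaffold_confusion(smiles, smiles)
    assert table.novel_scaffold_novel == 0
    assert table.known_scaffold_known == len(smiles)
    assert table.total == len(smiles)


def test_disjoint_sets_are_all_novel():
    generated = ["c1ccncc1CCF", "C1CCOC1CCl"]
    reference = ["CC(C)CC(C)(C)C"]
    table = novelty_scaffold_confusion(generated, reference)
    assert table.novel_scaffold_novel == len(generated)
    assert table.total == len(generated)


def test_confusion_counts_match_exhaustive_oracle(small_corpus):
    """Counts agree with an explicit per-molecule similarity/scaffold check."""
    generated = [e.smiles for e in small_corpus[:25]]
    reference = [e.smiles for e in small_corpus[20:45]]
    table = novelty_scaffold_confusion(generated, reference, threshold=0.4)

    from rdkit.Chem.Scaffolds import MurckoScaffold
    ref_fps = [metrics._FPGEN.GetFingerprint(Chem.MolFromSmiles(s))
               for s in reference]
    ref_scaffolds = {MurckoScaffold.MurckoScaffoldSmiles(smiles=s)
                     for s in reference}
    expected = np.zeros((2, 2), dtype=int)
    for s in generated:
        fp = metrics._FPGEN.GetFingerprint(Chem.MolFromSmiles(s))
        novel = max(TanimotoSimilarity(fp, r) for r in ref_fps) < 0.4
        scaf_novel = MurckoScaffold.MurckoScaffoldSmiles(smiles=s) \
            not in ref_scaffolds
        expected[0 if novel else 1, 0 if scaf_novel else 1] += 1
    assert table.to_frame().to_numpy().tolist() == expected.tolist()
    assert table.total == len(generated)


def test_raising_threshold_never_decreases_novel_count(small_corpus):
    generated = [e.smiles for e in small_corpus[:20]]
    reference = [e.smiles for e in small_corpus[10:30]]
    novel_counts = []
    for threshold in (0.2, 0.4, 0.6, 0.8):
        t = novelty_scaffold_confusion(generated, reference, threshold=threshold)
        novel_counts.append(t.novel_scaffold_novel + t.novel_scaffold_known)
    assert novel_counts == sorted(novel_counts)


def test_confusion_requires_non_empty_sets():
    with pytest.raises(MetricsError):
        novelty_scaffold_confusion([], ["CCO"])


# ---------------------------------------------------------------------------
# distribution report


def test_identical_sets_give_identical_columns(small_corpus):
    frame = metrics.property_distribution_report(
        small_corpus[:15], small_corpus[:15], labels=("a", "b"))
    assert (frame["a"] == frame["b"]).all()


def test_synthetic_set_mean_mw_inside_window(small_corpus):
    frame = metrics.property_distribution_report(
        small_corpus[:30], small_corpus[30:60])
    mw_mean = float(frame.loc["MW (↓)", "set_a"].split(" ± ")[0])
    assert 250 <= mw_mean <= 500


def test_report_serializes_with_stated_row_order(small_corpus, tmp_path):
    frame = metrics.property_distribution_report(small_corpus[:5], small_corpus[5:10])
    assert list(frame.index) == ["QED (↑)", "LogP (%, 0–5, ↑)", "SAS (↓)",
                                 "MW (↓)", "Toxicity (%, ↓)"]
    frame.to_csv(tmp_path / "report.csv")
    assert (tmp_path / "report.csv").exists()
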