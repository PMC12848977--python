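"""Reward algebra: rescale, logistic squash, two-pocket mix, gating, surrogate."""

import numpy as np
import pytest

from smolgen import rewards
from smolgen.rewards import (
    RewardSpec, ScaffoldConstraint, rescale_score, scaffold_gated_reward,
    single_pocket_reward, surrogate_docking_adapter, two_pocket_reward,
)


# ---------------------------------------------------------------------------
# rescale_score


@pytest.mark.parametrize("x,expected", [
    (-12.0, -6.0),   # lower endpoint
    (-6.0, 6.0),     # upper endpoint
    (-9.0, 0.0),     # midpoint
    (-7.5, 3.0),     # 2*(-7.5) + 18
])
def test_rescale_endpoints_and_interior(x, expected):
    assert rescale_score(x) == pytest.approx(expected)


def test_rescale_extrapolates_linearly():
    assert rescale_score(-15.0) == pytest.approx(-12.0)
    assert rescale_score(0.0) == pytest.approx(18.0)


# ---------------------------------------------------------------------------
# single-pocket reward


def test_midpoint_reward_is_half():
    assert single_pocket_reward(-9.0) == pytest.approx(0.5)


def test_reward_at_range_ends():
    assert single_pocket_reward(-12.0) == pytest.approx(1 - 1 / (1 + np.exp(6)))
    assert single_pocket_reward(-6.0) == pytest.approx(1 / (1 + np.exp(6)))


def test_logistic_symmetry_sums_to_one():
    assert single_pocket_reward(-12.0) + single_pocket_reward(-6.0) \
        == pytest.approx(1.0, abs=1e-12)


def test_strict_monotonicity_on_random_pairs():
    rng = np.random.default_rng(0)
    xs = rng.uniform(-20, 0, size=(1000, 2))
    for x1, x2 in xs:
        lo, hi = sorted((x1, x2))
        if lo == hi:
            continue
        assert single_pocket_reward(lo) > single_pocket_reward(hi)


def test_reward_range_is_open_unit_interval():
    # strict bounds hold throughout the extrapolated docking range; far
    # outside it the logistic saturates to the closed endpoints in float64
    for x in (-20.0, -12.0, -9.0, -6.0, 10.0):
        assert 0.0 < single_pocket_reward(x) < 1.0
    assert 0.0 <= single_pocket_reward(-50.0) <= 1.0


# ---------------------------------------------------------------------------
# two-pocket reward


def test_equal_midpoint_inputs():
    assert two_pocket_reward(-9.0, -9.0) == pytest.approx(0.5)


def test_degenerate_weighting_reduces_to_single_pocket():
    spec = RewardSpec(alpha=1.0, beta=0.0)
    for x1, x2 in [(-11.0, -6.5), (-8.0, -12.0)]:
        assert two_pocket_reward(x1, x2, spec) \
            == pytest.approx(single_pocket_reward(x1, spec))


def test_symmetric_extremes_average_to_half():
    assert two_pocket_reward(-12.0, -6.0) == pytest.approx(0.5)


def test_two_pocket_bounded_by_single_rewards():
    rng = np.random.default_rng(1)
    for x1, x2 in rng.uniform(-14, -5, size=(200, 2)):
        r = two_pocket_reward(x1, x2)
        singles = sorted((single_pocket_reward(x1), single_pocket_reward(x2)))
        assert singles[0] - 1e-12 <= r <= singles[1] + 1e-12


def test_equal_arguments_collapse_for_any_weights():
    for alpha in (0.0, 0.25, 0.7, 1.0):
        spec = RewardSpec(alpha=alpha, beta=1 - alpha)
        assert two_pocket_reward(-10.3, -10.3, spec) \
            == pytest.approx(single_pocket_reward(-10.3, spec))


def test_invalid_weights_rejected_at_construction():
    with pytest.raises(ValueError):
        RewardSpec(alpha=0.7, beta=0.7)
    with pytest.raises(ValueError):
        RewardSpec(alpha=-0.2, beta=1.2)


# ---------------------------------------------------------------------------
# scaffold gating


def test_gate_open_and_closed():
    constraint = ScaffoldConstraint("c1ccccc1")
    assert scaffold_gated_reward("Cc1ccccc1", 0.8, constraint) == 0.8
    assert scaffold_gated_reward("CCCCCC", 0.8, constraint) == 0.0


def test_gate_uses_substructure_semantics():
    constraint = ScaffoldConstraint("c1ccccc1")
    assert constraint.matches("Cc1ccccc1")  # toluene contains benzene


def test_gate_never_increases_and_is_idempotent():
    constraint = ScaffoldConstraint("c1ccncc1")
    for smiles in ("c1ccncc1CC", "CCCC"):
        once = scaffold_gated_reward(smiles, 0.6, constraint)
        assert once <= 0.6
        assert scaffold_gated_reward(smiles, once, constraint) == once


def test_unmatchable_scaffold_pattern_rejected():
    with pytest.raises(ValueError):
        ScaffoldConstraint("c1ccc")  # unclosed aromatic ring


# ---------------------------------------------------------------------------
# surrogate docking adapter


def test_surrogate_is_deterministic(small_corpus):
    smiles = [e.smiles for e in small_corpus[:50]]
    a = surrogate_docking_adapter(seed=5).score_batch(smiles, "pocketA")
    b = surrogate_docking_adapter(seed=5).score_batch(smiles, "pocketA")
    assert a == b
    assert surrogate_docking_adapter(seed=5).deterministic


def test_surrogate_scores_lie_in_docking_range():
    from smolgen import corpus as corpus_mod
    smiles = [e.smiles for e in corpus_mod.generate_synthetic_corpus(1000, seed=23)]
    scores = np.array(surrogate_docking_adapter(seed=5).score_batch(smiles, "p"))
    assert np.isfinite(scores).all()
    assert np.mean((scores >= -13) & (scores <= -5)) >= 0.99


def test_surrogate_provenance_label():
    assert surrogate_docking_adapter(seed=0).provenance == "surrogate"


def test_surrogate_pockets_differ(small_corpus):
    smiles = [e.smiles for e in small_corpus[:30]]
    adapter = surrogate_docking_adapter(seed=5)
    assert adapter.score_batch(smiles, "pocketA") \
        != adapter.score_batch(smiles, "pocketB")


def test_unparseable_molecule_gets_worst_case_score():
    adapter = surrogate_docking_adapter(seed=5)
    assert adapter.score_batch(["not_a_smiles((("], "p") == [-6.0]


# ---------------------------------------------------------------------------
# CSV adapter + composed reward


def test_csv_adapter_replays_scores(tmp_path):
    path = tmp_path / "scores.csv"
    path.write_text("smiles,pocket,score\nCCO,p1,-10.5\nCCO,p2,-7.0\n")
    adapter = rewards.CsvDockingAdapter(path)
    assert adapter.score_batch(["OCC"], "p1") == [-10.5]  # canonical lookup
    assert adapter.score_batch(["CCO"], "p2") == [-7.0]
    assert adapter.score_batch(["CCN"], "p1") == [-6.0]   # absent -> worst case


def test_adapter_reward_fn_range_and_scores(small_corpus):
    fn = rewards.adapter_reward_fn(surrogate_docking_adapter(seed=5), "pocketA")
    smiles = [e.smiles for e in small_corpus[:40]]
    r = fn(smiles)
    assert ((r > 0) & (r < 1)).all()
    assert fn.last_scores.shape == (40,)


def test_two_pocket_reward_fn_is_convex_combination(small_corpus):
    adapter = surrogate_docking_adapter(seed=5)
    smiles = [e.smiles for e in small_corpus[:20]]
    both = rewards.adapter_reward_fn(adapter, "pocketA", pocket2="pocketB")(smiles)
    x1 = adapter.score_batch(smiles, "pocketA")
    x2 = adapter.score_batch(smiles, "pocketB")
    expected = [two_pocket_reward(a, b) for a, b in zip(x1, x2)]
    assert np.allclose(both, expected)
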