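"""Shared fixtures.

The expensive artefacts (synthetic corpus, pretrained tiny model, the PPO
study runs) are session-scoped: they are built once and shared between the
unit tests that inspect them and the acceptance tests that assert on them.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest
from rdkit import Chem

from smolgen import codec, corpus, model as model_mod, ppo, pretrain, rewards

STUDY_CORPUS_N = 2000
STUDY_CORPUS_SEED = 42
STUDY_PRETRAIN = pretrain.TrainConfig(max_iters=300, seed=1)
STUDY_PPO_SEEDS = (13, 14, 15)


@pytest.fixture(scope="session")
def small_corpus() -> list[corpus.MoleculeEntry]:
    return corpus.generate_synthetic_corpus(300, seed=7)


@pytest.fixture(scope="session")
def vocab(small_corpus) -> codec.Vocabulary:
    return codec.build_vocabulary(small_corpus)


@pytest.fixture(scope="session")
def tiny_lm(vocab) -> model_mod.CausalLM:
    return model_mod.CausalLM(model_mod.ModelConfig.from_preset("tiny"),
                              vocab, seed=3)


@pytest.fixture(scope="session")
def study_corpus() -> list[corpus.MoleculeEntry]:
    return corpus.generate_synthetic_corpus(STUDY_CORPUS_N, seed=STUDY_CORPUS_SEED)


@pytest.fixture(scope="session")
def study_vocab(study_corpus) -> codec.Vocabulary:
    return codec.build_vocabulary(study_corpus)


@pytest.fixture(scope="session")
def study_train_config() -> pretrain.TrainConfig:
    return STUDY_PRETRAIN


@pytest.fixture(scope="session")
def pretrained(study_corpus, study_vocab):
    """Tiny model pretrained on the 2000-molecule synthetic corpus."""
    tokenized = [codec.encode(e, study_vocab) for e in study_corpus]
    model = model_mod.CausalLM(model_mod.ModelConfig.from_preset("tiny"),
                               study_vocab, seed=0)
    model, history = pretrain.pretrain(model, tokenized, STUDY_PRETRAIN)
    return model, history


@pytest.fixture(scope="session")
def surrogate_adapter() -> rewards.SurrogateDockingAdapter:
    return rewards.surrogate_docking_adapter(seed=5)


@pytest.fixture(scope="session")
def ppo_uplift_runs(pretrained, surrogate_adapter):
    """Three seeded PPO runs against the single-pocket surrogate reward."""
    model, _ = pretrained
    histories = []
    for seed in STUDY_PPO_SEEDS:
        fn = rewards.adapter_reward_fn(surrogate_adapter, "pocketA")
        m = copy.deepcopy(model)
        _, history = ppo.finetune(m, fn, ppo.PPOConfig(total_epochs=10, seed=seed))
        histories.append(history)
    return histories


@pytest.fixture(scope="session")
def scaffold_run(pretrained, surrogate_adapter):
    """Scaffold-constrained PPO run (prefix priming + reward gating)."""
    model, _ = pretrained
    scaffold = "c1ccncc1"
    constraint = rewards.ScaffoldConstraint(
        scaffold, prefix_tokens=tuple(codec.smiles_to_tokens(scaffold)))
    fn = rewards.adapter_reward_fn(surrogate_adapter, "pocketA")
    m = copy.deepcopy(model)
    _, history = ppo.finetune(m, fn, ppo.PPOConfig(total_epochs=10, seed=13),
                              constraint=constraint)
    return constraint, history


@pytest.fixture(scope="session")
def ring_reward_run(pretrained):
    """PPO run under a reward that favors ring-containing molecules."""
    model, _ = pretrained

    def ring_reward(smiles):
        out = []
        for s in smiles:
            mol = Chem.MolFromSmiles(s) if s else None
            out.append(0.0 if mol is None
                       else min(mol.GetRingInfo().NumRings(), 4) / 4.0)
        return np.array(out)

    m = copy.deepcopy(model)
    _, history = ppo.finetune(m, ring_reward, ppo.PPOConfig(total_epochs=10, seed=13))
    return history
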