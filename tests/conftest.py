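"""Shared fixtures: small synthetic PCM datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import RDLogger

from pcmlearn import (
    MorganCountFeaturizer,
    assemble_pcm_matrix,
    generate_bioactivities,
    generate_compounds,
    generate_targets,
    zscale_descriptors,
)

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def planted_dataset():
    """A mid-size synthetic PCM dataset with three planted ±1 effects.

    Noise SD 0.3 keeps the planted signal dominant so attribution and
    model-recovery tests have a known answer.
    """
    seed = 5
    smiles = generate_compounds(250, seed=seed)
    target_set = generate_targets(6, n_positions=20, divergence=0.5, seed=seed)
    table, truth = generate_bioactivities(
        smiles,
        target_set,
        seed=seed,
        n_effects=3,
        effect_size=1.0,
        noise_sd=0.3,
        interaction_sd=0.1,
        completeness=0.6,
    )
    featurizer = MorganCountFeaturizer().fit(smiles)
    counts = featurizer.transform(smiles)
    counts.index = [f"CPD{i:04d}" for i in range(len(smiles))]
    target_block = zscale_descriptors(target_set.alignment, target_set.selected_columns)
    design, response = assemble_pcm_matrix(counts, target_block, table)
    return {
        "smiles": smiles,
        "target_set": target_set,
        "table": table,
        "truth": truth,
        "counts": counts,
        "target_block": target_block,
        "design": design,
        "response": response,
        "vocabulary": featurizer.vocabulary_,
    }


@pytest.fixture(scope="session")
def toy_member_predictions():
    """Small member-prediction matrix with a known good/bad member mix."""
    rng = np.random.default_rng(42)
    y = rng.uniform(4, 10, 60)
    members = np.column_stack(
        [
            y + rng.normal(0, 0.3, 60),
            y + rng.normal(0, 0.6, 60),
            y + rng.normal(0, 1.2, 60),
            rng.uniform(4, 10, 60),  # pure-noise member
        ]
    )
    return members, y
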