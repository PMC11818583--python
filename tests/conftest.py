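"""Shared fixtures: hand-built miniature feature tables and a session-scoped
study-condition simulation run through the preprocessing chain."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amoplspy import FeatureTable, SimConfig, preprocess, simulate_dataset


def build_table(
    bio: np.ndarray,
    feature_names,
    origins,
    resistances,
    qc: np.ndarray | None = None,
    blank: np.ndarray | None = None,
) -> FeatureTable:
    """Assemble a FeatureTable from raw blocks (blank rows first, then QC,
    then biological, mirroring an injection sequence)."""
    blocks, roles, ids = [], [], []
    if blank is not None:
        blocks.append(blank)
        roles += ["blank"] * blank.shape[0]
        ids += [f"blank_{i+1}" for i in range(blank.shape[0])]
    if qc is not None:
        blocks.append(qc)
        roles += ["qc"] * qc.shape[0]
        ids += [f"QC_{i+1}" for i in range(qc.shape[0])]
    blocks.append(bio)
    roles += ["biological"] * bio.shape[0]
    ids += [f"S_{i+1}" for i in range(bio.shape[0])]
    n_extra = len(ids) - bio.shape[0]
    intensities = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(ids, name="sample_id"), columns=list(feature_names)
    )
    factors = pd.DataFrame(
        {
            "origin": [None] * n_extra + list(origins),
            "resistance": [None] * n_extra + list(resistances),
        },
        index=intensities.index,
    )
    factors = factors.where(factors.notna())  # normalize None -> NaN
    return FeatureTable(intensities, pd.Series(roles, index=intensities.index), factors)


def balanced_factors(n_reps: int, origins=("A", "B", "C", "D"), resistances=("naive", "resistant")):
    """Origin/resistance label vectors for a balanced factorial design."""
    orig = np.repeat(origins, len(resistances) * n_reps)
    res = np.tile(np.repeat(resistances, n_reps), len(origins))
    return list(orig), list(res)


def preprocess_chain(table: FeatureTable):
    """filter -> PQN -> impute -> UV scale; returns (scaled, factors)."""
    filtered, _ = preprocess.filter_features(table)
    norm = preprocess.pqn_normalize(filtered)
    imputed = preprocess.impute_missing(norm.corrected)
    scaled, _, _ = preprocess.uv_scale(imputed.matrix("biological"))
    return scaled, imputed.biological_factors()


@pytest.fixture(scope="session")
def study_sim():
    """Default study-condition simulation (seed fixed for the suite)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_prepped(study_sim):
    table, truth = study_sim
    scaled, factors = preprocess_chain(table)
    return scaled, factors, truth


@pytest.fixture()
def tiny_sim():
    """Small, fast dataset for model-level tests."""
    cfg = SimConfig(n_features=60, replicates_per_cell=3, seed=7, n_blank_fail=0)
    return simulate_dataset(cfg)
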