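"""Multiblock kernel-OPLS: dummy response, kernels, fit invariants, oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from amoplspy import (
    InputError,
    back_project_loadings,
    block_kernels,
    build_dummy_response,
    decompose,
    fit_amopls,
)

from conftest import balanced_factors


def _factors(reps):
    o, r = balanced_factors(reps)
    return pd.DataFrame({"origin": o, "resistance": r})


# --------------------------------------------------------------------------
# dummy response
# --------------------------------------------------------------------------


def test_dummy_response_rank_and_centering():
    Y8 = build_dummy_response(_factors(1))
    assert Y8.Y.shape == (8, 14)
    assert Y8.rank == 7
    Y48 = build_dummy_response(_factors(6))
    np.testing.assert_allclose(Y48.Y.sum(axis=0), 0.0, atol=1e-10)


def test_dummy_response_rows_sum_to_one_per_block_before_centering():
    f = _factors(2)
    origin = f["origin"].to_numpy()
    # uncentered block structure: each sample indicates exactly one level
    for levels, col in [(set(origin), "origin"), ({"naive", "resistant"}, "resistance")]:
        onehots = np.column_stack([(f[col] == lev).astype(float) for lev in levels])
        np.testing.assert_allclose(onehots.sum(axis=1), 1.0)


def test_degenerate_single_cell_design_rejected():
    f = pd.DataFrame({"origin": ["A"] * 4, "resistance": ["naive"] * 4})
    with pytest.raises(InputError, match="degenerate"):
        build_dummy_response(f)


# --------------------------------------------------------------------------
# block kernels
# --------------------------------------------------------------------------


def test_kernels_unit_frobenius_norm_and_gram_oracle():
    rng = np.random.default_rng(0)
    f = _factors(1)
    X = rng.standard_normal((8, 5))
    d = decompose(X, f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero residual block in saturated design
        bk = block_kernels(d)
    for name, K in bk.kernels.items():
        if name == "residual":
            np.testing.assert_allclose(K, 0.0, atol=1e-15)
            continue
        assert np.linalg.norm(K, "fro") == pytest.approx(1.0, abs=1e-12)
        # explicit-loop Gram oracle
        Xb = d.blocks()[name]
        G = np.array(
            [[sum(Xb[i, j] * Xb[k, j] for j in range(5)) for k in range(8)] for i in range(8)]
        )
        np.testing.assert_allclose(K, G / np.linalg.norm(G, "fro"), atol=1e-10)


def test_zero_residual_block_warns():
    f = _factors(1)
    X = np.random.default_rng(1).standard_normal((8, 4))
    with pytest.warns(UserWarning, match="residual"):
        block_kernels(decompose(X, f))


# --------------------------------------------------------------------------
# fit: perfect-signal limit, oracle equivalence, invariants
# --------------------------------------------------------------------------


def _noise_free_single_factor():
    """X equals its origin-level means exactly; the only varying factor is
    origin and the level-mean matrix has full rank 3 after centering."""
    origin = np.repeat(["A", "B", "C", "D"], 4)
    resist = ["naive"] * 16
    offsets = {
        "A": [1.0, 0.0, 0.3],
        "B": [-1.0, 0.5, 0.1],
        "C": [0.0, -1.0, 0.8],
        "D": [0.0, 0.5, -1.2],
    }
    X = np.array([offsets[o] for o in origin])
    return X, pd.DataFrame({"origin": origin, "resistance": resist})


def test_perfect_signal_limit_r2y_one_and_lambda_one():
    X, f = _noise_free_single_factor()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = decompose(X, f)
        model = fit_amopls(d, n_pred=3, n_orth=0)
    assert model.r2y == pytest.approx(1.0, abs=1e-6)
    for c in model.predictive_ids:
        assert model.lambda_.loc[c, "origin"] == pytest.approx(1.0, abs=1e-9)
        assert model.attribution[c] == "origin"


@pytest.mark.parametrize("reps,p,seed", [(1, 8, 0), (2, 10, 1), (2, 6, 2)])
def test_predictive_subspace_matches_eigendecomposition_oracle(reps, p, seed):
    """Power-iteration scores span the top eigenspace of the Y-projected
    consensus kernel K P_Y K (principal angles <= 1e-6)."""
    rng = np.random.default_rng(seed)
    f = _factors(reps)
    X = rng.standard_normal((len(f), p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = decompose(X, f)
        model = fit_amopls(d, n_orth=0)
        bk = block_kernels(d)
    Yv = build_dummy_response(f).Y
    P = Yv @ np.linalg.pinv(Yv.T @ Yv) @ Yv.T
    M = bk.consensus @ P @ bk.consensus
    evals, evecs = scipy.linalg.eigh(M)
    k = model.n_pred
    oracle = evecs[:, np.argsort(evals)[::-1][:k]]
    T = model.scores[model.predictive_ids].to_numpy()
    angles = scipy.linalg.subspace_angles(T, oracle)
    assert np.max(angles) <= 1e-6


def test_fit_invariants_scores_lambda_compvar(tiny_sim):
    from conftest import preprocess_chain

    table, _ = tiny_sim
    X, f = preprocess_chain(table)
    model = fit_amopls(decompose(X, f), n_orth=2)
    S = model.scores.to_numpy()
    G = S.T @ S - np.eye(S.shape[1])
    assert np.abs(G).max() <= 1e-8  # unit-norm, pairwise orthogonal scores
    np.testing.assert_allclose(model.lambda_.sum(axis=1), 1.0, atol=1e-9)
    assert (model.lambda_.to_numpy() >= -1e-12).all()
    assert (model.comp_var.to_numpy() >= 0).all()
    assert model.comp_var.sum() <= 1 + 1e-9
    # orthogonal scores uncorrelated with every dummy column
    for c in model.orthogonal_ids:
        assert np.abs(model.scores[c].to_numpy() @ model.y.Y).max() <= 1e-8
    # sign convention: the largest-|loading| entry is positive
    for c in model.scores.columns:
        load = model.loadings[c].to_numpy()
        assert load[np.argmax(np.abs(load))] > 0


def test_model_invariant_to_feature_order(tiny_sim):
    from conftest import preprocess_chain

    table, _ = tiny_sim
    X, f = preprocess_chain(table)
    rng = np.random.default_rng(5)
    perm = rng.permutation(X.shape[1])
    m0 = fit_amopls(decompose(X, f), n_orth=1)
    m1 = fit_amopls(decompose(X.iloc[:, perm], f), n_orth=1)
    pd.testing.assert_frame_equal(m0.scores, m1.scores, atol=1e-8, rtol=0)
    pd.testing.assert_frame_equal(
        m0.loadings.iloc[perm].reset_index(drop=True),
        m1.loadings.reset_index(drop=True),
        atol=1e-8,
        rtol=0,
    )


def test_single_block_reduces_to_kernel_pls():
    """With one informative block, zero residual and a univariate response,
    the first predictive score matches a PLS oracle up to sign/scale."""
    from sklearn.cross_decomposition import PLSRegression

    origin = np.repeat(["A", "B"], 4)
    resist = np.tile(["naive"], 8)
    rng = np.random.default_rng(3)
    base = {"A": rng.standard_normal(5), "B": rng.standard_normal(5)}
    X = np.array([base[o] for o in origin])  # exactly the level means
    f = pd.DataFrame({"origin": origin, "resistance": resist})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_amopls(decompose(X, f), n_pred=1, n_orth=0)
    y = (origin == "A").astype(float) - 0.5
    pls = PLSRegression(n_components=1, scale=False).fit(X - X.mean(axis=0), y)
    t_ours = model.scores["tp1"].to_numpy()
    t_pls = pls.x_scores_[:, 0]
    corr = abs(np.corrcoef(t_ours, t_pls)[0, 1])
    assert corr == pytest.approx(1.0, abs=1e-8)


def test_back_projection_reconstruction_improves_with_components(tiny_sim):
    from conftest import preprocess_chain

    table, _ = tiny_sim
    X, f = preprocess_chain(table)
    d = decompose(X, f)
    model = fit_amopls(d, n_orth=0)
    Xc = d.centered()
    loads = back_project_loadings(model, pd.DataFrame(Xc, columns=X.columns))
    errs = []
    recon = np.zeros_like(Xc)
    for c in model.predictive_ids:
        t = model.scores[c].to_numpy()
        recon += np.outer(t, loads[c].to_numpy())
        errs.append(np.linalg.norm(Xc - recon))
    assert all(e2 < e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


def test_loadings_rank_effect_carrying_features_highest():
    """In a simulation where only a subset of features carries the origin
    effect, those features dominate the origin component loadings."""
    from amoplspy import SimConfig, simulate_dataset
    from conftest import preprocess_chain

    cfg = SimConfig(
        n_features=60,
        replicates_per_cell=3,
        seed=11,
        effect_fractions={"origin": 0.3, "resistance": 0.0, "interaction": 0.0, "residual": 0.7},
        effect_feature_fraction=0.4,
        orthogonal_fraction=0.0,
        n_blank_fail=0,
        missing_rate=0.0,
    )
    table, truth = simulate_dataset(cfg)
    X, f = preprocess_chain(table)
    model = fit_amopls(decompose(X, f), n_orth=0)
    comps = model.components_for("origin")
    energy = (model.loadings[comps] ** 2).sum(axis=1).sort_values(ascending=False)
    top = set(energy.index[: len(truth.effect_features)])
    carriers = set(truth.effect_features)
    overlap = len(top & carriers) / len(carriers)
    assert overlap >= 0.9


def test_back_projection_dimension_mismatch_and_npred_bounds(tiny_sim):
    from conftest import preprocess_chain

    table, _ = tiny_sim
    X, f = preprocess_chain(table)
    d = decompose(X, f)
    model = fit_amopls(d, n_orth=0)
    with pytest.raises(InputError, match="rows"):
        back_project_loadings(model, X.iloc[:-1])
    with pytest.raises(InputError, match="n_pred"):
        fit_amopls(d, n_pred=8)
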