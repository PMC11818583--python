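"""Multiblock kernel-OPLS on ANOVA effect blocks (AMOPLS).

The ANOVA effect matrices {X_origin, X_resistance, X_interaction} and the
residual E each form one block. Block kernels K_b = X_b X_b' are normalized
by their Frobenius norm so no block dominates by scale, and the consensus
kernel is their unweighted mean. With Y the column-centered concatenation of
level indicators for the included effects (4 + 2 + 8 columns, rank 7 for the
full 4x2 design):

* predictive components are the dominant eigenvectors of the Y-projected
  consensus kernel K P_Y K (P_Y = orthogonal projector onto col(Y)),
  extracted by deterministic power iteration with deflation — they span the
  part of kernel space correlated with the design;
* each orthogonal component is the dominant eigenvector of (I-P_Y) K (I-P_Y),
  i.e. the largest Y-uncorrelated structured variation, and is deflated from
  the kernel before the predictive components are (re-)estimated;
* the block contribution of component c is
  lambda_{b,c} = t_c' K_b t_c / sum_b t_c' K_b t_c, identifying which effect
  a component summarizes;
* comp_var_c is the share of the total (centered, scaled) data variance the
  component explains, and R2Y the share of Y variance explained by the
  predictive score subspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import EFFECTS, EffectDecomposition
from .errors import InputError, NumericalError

BLOCKS = (*EFFECTS, "residual")


# --------------------------------------------------------------------------
# Dummy response
# --------------------------------------------------------------------------


@dataclass
class DummyResponse:
    """Column-centered indicator matrix for origin (4), resistance (2) and
    interaction (8) levels; rank 7 for the full balanced 4x2 design."""

    Y: np.ndarray
    columns: list
    rank: int


def build_dummy_response(factors: pd.DataFrame) -> DummyResponse:
    if factors[["origin", "resistance"]].isna().any().any():
        raise InputError("factors contain missing levels")
    origin = factors["origin"].to_numpy()
    resist = factors["resistance"].to_numpy()
    o_levels = list(pd.unique(origin))
    r_levels = list(pd.unique(resist))

    cols, names = [], []
    for o in o_levels:
        cols.append((origin == o).astype(float))
        names.append(f"origin:{o}")
    for r in r_levels:
        cols.append((resist == r).astype(float))
        names.append(f"resistance:{r}")
    for o in o_levels:
        for r in r_levels:
            cols.append(((origin == o) & (resist == r)).astype(float))
            names.append(f"interaction:{o}*{r}")
    Y = np.column_stack(cols)
    Y = Y - Y.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Y))
    if rank == 0:
        raise InputError("degenerate design: all samples share one design cell")
    return DummyResponse(Y=Y, columns=names, rank=rank)


# --------------------------------------------------------------------------
# Block kernels
# --------------------------------------------------------------------------


@dataclass
class BlockKernels:
    kernels: dict  # block name -> normalized (n, n) Gram matrix
    consensus: np.ndarray


def block_kernels(decomp: EffectDecomposition) -> BlockKernels:
    """Frobenius-normalized Gram matrix per block plus their unweighted mean.

    An all-zero block yields a zero kernel (with a warning); its lambda will
    be 0 on every component.
    """
    kernels = {}
    for name, X_b in decomp.blocks().items():
        K = X_b @ X_b.T
        norm = np.linalg.norm(K, "fro")
        if norm <= 0:
            warnings.warn(f"block {name!r} is all zero; its kernel is the zero matrix")
            kernels[name] = np.zeros_like(K)
        else:
            kernels[name] = K / norm
    consensus = sum(kernels.values()) / len(kernels)
    return BlockKernels(kernels=kernels, consensus=consensus)


# --------------------------------------------------------------------------
# Power iteration
# --------------------------------------------------------------------------


def _dominant_eigvec(
    M: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    prev: list | None = None,
):
    """Dominant eigenpair of a symmetric PSD matrix by power iteration with
    deterministic initialization (first kernel column; largest-norm column if
    that one is numerically zero).

    ``prev`` holds already-extracted eigenvectors: each iterate is explicitly
    re-orthogonalized against them, which keeps successive components
    orthogonal to machine precision. Convergence is declared when either the
    iterate stabilizes or the Rayleigh quotient does — the latter handles
    (near-)degenerate eigenvalues, where any vector of the dominant eigenspace
    is a valid component but the iterate itself may keep rotating within it.
    """
    prev = prev or []
    col_norms = np.linalg.norm(M, axis=0)
    if col_norms.max() <= 1e-300:
        return None, 0.0
    v = M[:, 0] if col_norms[0] > 1e-12 * col_norms.max() else M[:, int(col_norms.argmax())]
    for u in prev:
        v = v - u * (u @ v)
    nv = np.linalg.norm(v)
    if nv <= 1e-300:
        return None, 0.0
    v = v / nv
    ev = float(v @ M @ v)
    for _ in range(max_iter):
        w = M @ v
        for u in prev:  # twice for numerical stability
            w = w - u * (u @ w)
        for u in prev:
            w = w - u * (u @ w)
        nw = np.linalg.norm(w)
        if nw <= 1e-300:
            return None, 0.0
        v_new = w / nw
        ev_new = float(v_new @ M @ v_new)
        if (
            np.linalg.norm(v_new - v) < tol
            or abs(ev_new - ev) <= tol * max(abs(ev_new), 1e-300)
        ):
            return v_new, ev_new
        v, ev = v_new, ev_new
    # almost-degenerate leading eigenvalues can stall power iteration; fall
    # back to a dense symmetric eigensolver (deterministic) in that case
    import scipy.linalg

    evals, evecs = scipy.linalg.eigh(M)
    v = evecs[:, int(np.argmax(evals))]
    for u in prev:
        v = v - u * (u @ v)
    nv = np.linalg.norm(v)
    if nv <= 1e-300:
        return None, 0.0
    v = v / nv
    return v, float(v @ M @ v)


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------


@dataclass
class AmoplsModel:
    """Fitted AMOPLS model: predictive ('tp1'..) and orthogonal ('tpo1'..)
    unit-norm score vectors, feature-space loadings, block contributions
    lambda (rows sum to 1), per-component explained data variance, and R2Y."""

    scores: pd.DataFrame  # samples x components (tp*, tpo*)
    loadings: pd.DataFrame  # features x components
    lambda_: pd.DataFrame  # components x blocks
    comp_var: pd.Series  # component -> share of total data variance
    eigvals: pd.Series  # component -> kernel eigenvalue at extraction
    r2y: float
    attribution: dict  # predictive component -> block with largest lambda
    n_pred: int
    n_orth: int
    y: DummyResponse

    @property
    def predictive_ids(self) -> list:
        return [c for c in self.scores.columns if not c.startswith("tpo")]

    @property
    def orthogonal_ids(self) -> list:
        return [c for c in self.scores.columns if c.startswith("tpo")]

    def components_for(self, effect: str) -> list:
        return [c for c in self.predictive_ids if self.attribution[c] == effect]


def fit_amopls(
    decomp: EffectDecomposition,
    Y: DummyResponse | None = None,
    n_pred: int | None = None,
    n_orth: int = 1,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> AmoplsModel:
    """Fit the multiblock kernel-OPLS model on an effect decomposition."""
    if Y is None:
        Y = build_dummy_response(decomp.factors)
    if n_pred is None:
        n_pred = Y.rank
    if n_pred < 1 or n_pred > Y.rank:
        raise InputError(f"n_pred must lie in [1, rank(Y)={Y.rank}] (got {n_pred})")
    if n_orth < 0:
        raise InputError("n_orth must be >= 0")

    bk = block_kernels(decomp)
    K = bk.consensus
    n = K.shape[0]
    if Y.Y.shape[0] != n:
        raise InputError("dummy response row count does not match kernel size")

    P_Y = Y.Y @ np.linalg.pinv(Y.Y.T @ Y.Y) @ Y.Y.T
    Q = np.eye(n) - P_Y

    Kw = K.copy()
    T_orth, orth_eig = [], []
    for _ in range(n_orth):
        M = Q @ Kw @ Q
        M = 0.5 * (M + M.T)
        t, ev = _dominant_eigvec(M, tol=tol, max_iter=max_iter, prev=T_orth)
        if t is None or ev <= 1e-12 * max(np.trace(K), 1e-300):
            warnings.warn("no further orthogonal structure; stopping extraction")
            break
        T_orth.append(t)
        orth_eig.append(ev)
        D = np.eye(n) - np.outer(t, t)
        Kw = D @ Kw @ D

    # predictive components from the Y-projected (deflated) consensus kernel
    Mp = Kw @ P_Y @ Kw
    Mp = 0.5 * (Mp + Mp.T)
    T_pred, pred_eig = [], []
    for _ in range(n_pred):
        t, ev = _dominant_eigvec(Mp, tol=tol, max_iter=max_iter, prev=T_pred)
        if t is None or ev <= 0:
            break
        T_pred.append(t)
        pred_eig.append(ev)
    if not T_pred:
        raise NumericalError("no predictive component could be extracted")

    Xc = decomp.centered()
    total_ss = float(np.sum(Xc**2))

    # label predictive components tp1.. in order of explained data variance
    # (the convention used when reading effects off the score plots);
    # orthogonal components keep extraction order
    pred_var = [float(np.sum((Xc.T @ t) ** 2)) / total_ss for t in T_pred]
    order = sorted(range(len(T_pred)), key=lambda i: -pred_var[i])
    T_pred = [T_pred[i] for i in order]
    pred_eig = [pred_eig[i] for i in order]

    ids = [f"tp{i + 1}" for i in range(len(T_pred))] + [
        f"tpo{i + 1}" for i in range(len(T_orth))
    ]
    all_scores = T_pred + T_orth
    eigvals = pred_eig + orth_eig

    # sign convention: the largest-|loading| feature loads positively
    # (ties broken by lowest feature index via argmax)
    loadings = []
    for k, t in enumerate(all_scores):
        load = Xc.T @ t  # t is unit norm
        imax = int(np.argmax(np.abs(load)))
        if load[imax] < 0:
            t = -t
            load = -load
            all_scores[k] = t
        loadings.append(load)

    lam = np.zeros((len(all_scores), len(BLOCKS)))
    for k, t in enumerate(all_scores):
        contribs = np.array([float(t @ bk.kernels[b] @ t) for b in BLOCKS])
        contribs = np.clip(contribs, 0.0, None)  # kernels are PSD; clip fp dust
        s = contribs.sum()
        lam[k] = contribs / s if s > 0 else 0.0

    comp_var = np.array(
        [float(np.sum((Xc.T @ t) ** 2)) / total_ss for t in all_scores]
    )

    Tp = np.column_stack(T_pred)
    r2y = float(np.sum((Tp.T @ Y.Y) ** 2) / np.sum(Y.Y**2))

    feat_idx = (
        decomp.feature_names
        if decomp.feature_names is not None
        else pd.RangeIndex(Xc.shape[1])
    )
    lam_df = pd.DataFrame(lam, index=ids, columns=list(BLOCKS))
    model = AmoplsModel(
        scores=pd.DataFrame(
            np.column_stack(all_scores), index=decomp.factors.index, columns=ids
        ),
        loadings=pd.DataFrame(np.column_stack(loadings), index=feat_idx, columns=ids),
        lambda_=lam_df,
        comp_var=pd.Series(comp_var, index=ids, name="explained_variance"),
        eigvals=pd.Series(eigvals, index=ids, name="kernel_eigenvalue"),
        r2y=r2y,
        attribution={
            c: lam_df.loc[c].idxmax() for c in ids if not c.startswith("tpo")
        },
        n_pred=len(T_pred),
        n_orth=len(T_orth),
        y=Y,
    )
    return model


def back_project_loadings(model: AmoplsModel, X_scaled) -> pd.DataFrame:
    """Feature-space loadings loading_c = X' t_c / (t_c' t_c) for each
    component, indexed by lipid name when X carries column names."""
    Xv = np.asarray(X_scaled, dtype=float)
    if Xv.shape[0] != model.scores.shape[0]:
        raise InputError(
            f"X has {Xv.shape[0]} rows but the model was fitted on "
            f"{model.scores.shape[0]} samples"
        )
    cols = X_scaled.columns if isinstance(X_scaled, pd.DataFrame) else pd.RangeIndex(Xv.shape[1])
    out = {}
    for c in model.scores.columns:
        t = model.scores[c].to_numpy()
        out[c] = Xv.T @ t / float(t @ t)
    return pd.DataFrame(out, index=cols)
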