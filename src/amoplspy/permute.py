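"""Permutation-based effect significance and orthogonal-component selection.

The test statistic for an effect is its lambda-weighted explained variance
summed over the predictive components attributed to it (attribution = largest
block contribution), matching how effects are read off the fitted model. The
null is built by refitting the full decomposition + model with the tested
effect's labels permuted:

* main effects: the factor's labels are permuted within strata of the other
  factor (restricted permutation), which preserves the tested null and keeps
  the balanced design balanced;
* interaction: the joint (origin, resistance) cell-assignment vector is
  permuted across samples, fixing all margins.

When the permutation space has no more than ``n_perm`` distinct arrangements,
all of them are enumerated exactly instead of sampled.

The number of orthogonal components is selected by a dimensionality-style
permutation test: component k is retained iff its captured data variance
exceeds the 95th percentile of the same quantity after the residual matrix's
rows have been permuted independently within each feature column — a null
that destroys structured inter-sample residual variation while leaving the
design effects untouched.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amopls import AmoplsModel, build_dummy_response, fit_amopls
from .anova import EFFECTS, decompose
from .errors import InputError

TESTABLE_EFFECTS = EFFECTS  # origin, resistance, interaction


@dataclass
class PermutationResult:
    effect: str
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    exact: bool = False


def effect_statistic(model: AmoplsModel, effect: str) -> float:
    """Sum over predictive components attributed to ``effect`` of
    lambda_{effect,c} x comp_var_c."""
    stat = 0.0
    for c in model.components_for(effect):
        stat += float(model.lambda_.loc[c, effect]) * float(model.comp_var[c])
    return stat


def _fit(X, factors, n_pred, n_orth) -> AmoplsModel:
    decomp = decompose(X, factors)
    return fit_amopls(decomp, n_pred=n_pred, n_orth=n_orth)


def _effect_rng(seed: int, effect: str) -> np.random.Generator:
    # per-effect stream: adding an effect does not perturb the others' nulls
    return np.random.default_rng([abs(int(seed)), zlib.crc32(effect.encode())])


def _permuted_factors(factors: pd.DataFrame, effect: str, rng) -> pd.DataFrame:
    out = factors.copy()
    if effect == "interaction":
        perm = rng.permutation(len(out))
        out.iloc[:, :] = out.to_numpy()[perm]
        return out
    other = "resistance" if effect == "origin" else "origin"
    labels = out[effect].to_numpy().copy()
    for lev in pd.unique(out[other]):
        idx = np.flatnonzero(out[other].to_numpy() == lev)
        labels[idx] = labels[idx[rng.permutation(len(idx))]]
    out[effect] = labels
    return out


def _multiset_permutations(items):
    """All distinct orderings of a multiset (lexicographic)."""
    items = sorted(items)
    n = len(items)
    while True:
        yield tuple(items)
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])


def _multinomial(counts) -> int:
    n = sum(counts)
    out = math.factorial(n)
    for c in counts:
        out //= math.factorial(c)
    return out


def _n_distinct_arrangements(factors: pd.DataFrame, effect: str) -> int:
    if effect == "interaction":
        pairs = list(zip(factors["origin"], factors["resistance"]))
        return _multinomial(pd.Series(pairs).value_counts().to_list())
    other = "resistance" if effect == "origin" else "origin"
    total = 1
    for lev in pd.unique(factors[other]):
        sub = factors.loc[factors[other] == lev, effect]
        total *= _multinomial(sub.value_counts().to_list())
    return total


def _enumerate_factors(factors: pd.DataFrame, effect: str):
    """Yield every distinct label arrangement (including the identity)."""
    if effect == "interaction":
        pairs = list(zip(factors["origin"], factors["resistance"]))
        for arrangement in _multiset_permutations(pairs):
            out = factors.copy()
            out["origin"] = [a[0] for a in arrangement]
            out["resistance"] = [a[1] for a in arrangement]
            yield out
        return
    other = "resistance" if effect == "origin" else "origin"
    strata = [np.flatnonzero(factors[other].to_numpy() == lev) for lev in pd.unique(factors[other])]
    per_stratum = [
        list(_multiset_permutations(factors[effect].to_numpy()[idx])) for idx in strata
    ]
    import itertools

    for combo in itertools.product(*per_stratum):
        labels = factors[effect].to_numpy().copy()
        for idx, arrangement in zip(strata, combo):
            labels[idx] = arrangement
        out = factors.copy()
        out[effect] = labels
        yield out


def effect_significance(
    X,
    factors: pd.DataFrame,
    effect: str,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    n_pred: int | None = None,
    n_orth: int = 0,
) -> PermutationResult:
    """Permutation p-value for one design effect.

    p = (1 + #{null >= observed}) / (1 + n_perm); with 10^3 permutations the
    smallest attainable p is therefore ~1e-3 (the empirical floor).
    """
    if effect not in TESTABLE_EFFECTS:
        raise InputError(f"unknown effect {effect!r}; choose from {TESTABLE_EFFECTS}")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")

    observed = effect_statistic(_fit(X, factors, n_pred, n_orth), effect)
    rng = _effect_rng(seed, effect)

    n_distinct = _n_distinct_arrangements(factors, effect)
    exact = n_distinct <= n_perm + 1
    null = []
    if exact:
        identity = tuple(zip(factors["origin"], factors["resistance"]))
        skipped_identity = False
        for perm_factors in _enumerate_factors(factors, effect):
            arr = tuple(zip(perm_factors["origin"], perm_factors["resistance"]))
            if not skipped_identity and arr == identity:
                skipped_identity = True
                continue
            null.append(effect_statistic(_fit(X, perm_factors, n_pred, n_orth), effect))
        n_perm = len(null)
    else:
        for _ in range(n_perm):
            perm_factors = _permuted_factors(factors, effect, rng)
            null.append(effect_statistic(_fit(X, perm_factors, n_pred, n_orth), effect))

    null = np.asarray(null)
    tol = 1e-12 * max(abs(observed), 1.0)
    p = (1 + int(np.sum(null >= observed - tol))) / (1 + n_perm)
    return PermutationResult(
        effect=effect,
        observed_stat=observed,
        null_stats=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        exact=exact,
    )


def significance_frame(results) -> pd.DataFrame:
    rows = [
        (r.effect, r.observed_stat, r.p_value, r.n_perm, r.seed) for r in results
    ]
    return pd.DataFrame(
        rows, columns=["effect", "observed_stat", "p_value", "n_perm", "seed"]
    ).set_index("effect")


def select_n_orthogonal(
    X,
    factors: pd.DataFrame,
    max_orth: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    n_pred: int | None = None,
) -> int:
    """Number of orthogonal components supported by the data.

    Components are added one at a time; component k is retained iff its
    captured share of the data variance exceeds the (1-alpha) quantile of the
    same quantity under the feature-wise residual permutation null.
    """
    Xv = np.asarray(X, dtype=float)
    cols = X.columns if isinstance(X, pd.DataFrame) else None
    decomp = decompose(Xv, factors)
    structured = decomp.grand_mean[None, :] + sum(decomp.effects.values())
    rng = np.random.default_rng([abs(int(seed)), zlib.crc32(b"n_orth")])

    # cell codes for re-projecting permuted residuals onto the within-cell
    # complement (so the null preserves each feature's residual SS there,
    # instead of leaking it into the effect subspaces)
    cells = pd.Series(
        list(zip(factors["origin"], factors["resistance"]))
    ).astype("category").cat.codes.to_numpy()
    n_cells = cells.max() + 1
    ss0 = np.sum(decomp.residual**2, axis=0)

    def _null_residual() -> np.ndarray:
        Ep = rng.permuted(decomp.residual, axis=0)
        for c in range(n_cells):
            rows = cells == c
            Ep[rows] -= Ep[rows].mean(axis=0)
        ssp = np.sum(Ep**2, axis=0)
        scale = np.sqrt(np.divide(ss0, ssp, out=np.ones_like(ss0), where=ssp > 0))
        return Ep * scale[None, :]

    for k in range(1, max_orth + 1):
        model = fit_amopls(decomp, n_pred=n_pred, n_orth=k)
        comp_id = f"tpo{k}"
        if model.n_orth < k:
            return k - 1
        observed = float(model.comp_var[comp_id])
        null = np.empty(n_perm)
        for b in range(n_perm):
            X_null = structured + _null_residual()
            if cols is not None:
                X_null = pd.DataFrame(X_null, index=factors.index, columns=cols)
            m = fit_amopls(decompose(X_null, factors), n_pred=n_pred, n_orth=k)
            null[b] = float(m.comp_var[comp_id]) if m.n_orth >= k else 0.0
        if observed <= np.quantile(null, 1 - alpha):
            return k - 1
    warnings.warn(f"all {max_orth} tested orthogonal components were significant")
    return max_orth
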