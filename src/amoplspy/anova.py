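"""Two-factor ANOVA decomposition of the sample x feature matrix.

For a balanced origin x resistance design the centered data matrix splits
exactly into pairwise-orthogonal pure effect matrices

    X - 1 m'  =  X_origin + X_resistance + X_interaction + E

where rows of ``X_origin`` hold (origin-level mean - grand mean), analogously
for resistance, the interaction rows hold (cell mean - origin mean -
resistance mean + grand mean), and ``E`` is the within-cell residual.
Sum-of-squares shares (Frobenius norms over the grand-mean-centered total)
then sum to exactly 1 and quantify how much of the lipidome variation each
design effect carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

EFFECTS = ("origin", "resistance", "interaction")


@dataclass
class EffectDecomposition:
    """Grand mean plus pure effect matrices and residual, with SS shares."""

    grand_mean: np.ndarray
    effects: dict  # name -> (n, p) array for origin/resistance/interaction
    residual: np.ndarray
    ss_shares: dict  # effect name (incl. 'residual') -> fraction of total SS
    factors: pd.DataFrame
    feature_names: pd.Index | None = None

    def blocks(self) -> dict:
        """Effect matrices plus residual, in canonical block order."""
        out = {name: self.effects[name] for name in EFFECTS}
        out["residual"] = self.residual
        return out

    def centered(self) -> np.ndarray:
        """The grand-mean-centered data matrix (sum of all blocks)."""
        return sum(self.blocks().values())

    def reconstruct(self) -> np.ndarray:
        return self.grand_mean[None, :] + self.centered()


def _check_design(factors: pd.DataFrame, unbalanced: str) -> pd.Series:
    counts = factors.groupby(["origin", "resistance"], observed=True).size()
    origins = factors["origin"].unique()
    resist = factors["resistance"].unique()
    if len(counts) != len(origins) * len(resist):
        raise InputError("empty design cell: every origin x resistance cell needs >=1 sample")
    if counts.nunique() != 1 and unbalanced != "weighted":
        raise InputError(
            f"unbalanced design (cell counts {dict(counts)}); "
            "pass unbalanced='weighted' to use unweighted cell-mean averaging"
        )
    return counts


def decompose(
    X,
    factors: pd.DataFrame,
    *,
    unbalanced: str = "error",
) -> EffectDecomposition:
    """Decompose a (scaled) biological-sample matrix by the two fixed factors.

    Balanced designs are required by default. The opt-in
    ``unbalanced='weighted'`` mode averages cell means with equal level
    weights (Type-III-like), an extension beyond the balanced study design.
    """
    feature_names = X.columns if isinstance(X, pd.DataFrame) else None
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim != 2:
        raise InputError("X must be 2-D (samples x features)")
    if len(factors) != Xv.shape[0]:
        raise InputError("factors length does not match number of rows")
    if factors[["origin", "resistance"]].isna().any().any():
        raise InputError("factors contain missing levels")
    if np.isnan(Xv).any():
        raise InputError("X contains missing values; impute before decomposing")
    _check_design(factors, unbalanced)

    n, p = Xv.shape
    origin = factors["origin"].to_numpy()
    resist = factors["resistance"].to_numpy()
    o_levels = pd.unique(origin)
    r_levels = pd.unique(resist)

    cell_mean = {}
    for o in o_levels:
        for r in r_levels:
            rows = (origin == o) & (resist == r)
            cell_mean[(o, r)] = Xv[rows].mean(axis=0)

    balanced = (
        factors.groupby(["origin", "resistance"], observed=True).size().nunique() == 1
    )
    if balanced:
        grand = Xv.mean(axis=0)
        o_mean = {o: Xv[origin == o].mean(axis=0) for o in o_levels}
        r_mean = {r: Xv[resist == r].mean(axis=0) for r in r_levels}
    else:
        # unweighted averaging of cell means: robust to unequal replication
        grand = np.mean(list(cell_mean.values()), axis=0)
        o_mean = {
            o: np.mean([cell_mean[(o, r)] for r in r_levels], axis=0) for o in o_levels
        }
        r_mean = {
            r: np.mean([cell_mean[(o, r)] for o in o_levels], axis=0) for r in r_levels
        }

    X_o = np.empty_like(Xv)
    X_r = np.empty_like(Xv)
    X_or = np.empty_like(Xv)
    E = np.empty_like(Xv)
    for i in range(n):
        o, r = origin[i], resist[i]
        X_o[i] = o_mean[o] - grand
        X_r[i] = r_mean[r] - grand
        X_or[i] = cell_mean[(o, r)] - o_mean[o] - r_mean[r] + grand
        E[i] = Xv[i] - cell_mean[(o, r)]

    total = float(np.sum((Xv - grand) ** 2))
    if total <= 0:
        raise InputError("zero total sum of squares; nothing to decompose")
    shares = {
        "origin": float(np.sum(X_o**2)) / total,
        "resistance": float(np.sum(X_r**2)) / total,
        "interaction": float(np.sum(X_or**2)) / total,
        "residual": float(np.sum(E**2)) / total,
    }
    return EffectDecomposition(
        grand_mean=grand,
        effects={"origin": X_o, "resistance": X_r, "interaction": X_or},
        residual=E,
        ss_shares=shares,
        factors=factors[["origin", "resistance"]].copy(),
        feature_names=feature_names,
    )


def effect_proportions_frame(decomp: EffectDecomposition) -> pd.DataFrame:
    """Two-column export table (effect, percent of total centered SS)."""
    rows = [(name, 100.0 * decomp.ss_shares[name]) for name in (*EFFECTS, "residual")]
    return pd.DataFrame(rows, columns=["effect", "percent"]).set_index("effect")
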