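"""Synthetic factorial-design lipidomics datasets with known ground truth.

The generator emulates the study conditions of a 4 (cell-line origin) x 2
(FOLFOXIRI-resistance status) balanced design measured by untargeted LC-HRMS:
log-normal feature intensities carrying additive origin / resistance /
interaction effects with controllable sum-of-squares shares, per-sample
dilution factors, pooled-QC and blank injections, missing values, and lipid
shorthand feature names drawn from the study's class vocabulary.

Effects are generated on the log-intensity scale and exponentiated (MS
intensities are multiplicative); per feature, each component (effect offsets,
structured orthogonal trend, i.i.d. noise) is scaled to its exact requested
share of the sum of squares, so the planted fractions are exact on the log
scale and remain recoverable — up to the usual finite-sample noise leakage
into estimated group means — through the exp -> PQN -> unit-variance-scaling
analysis path as long as the log-scale spread stays moderate (default 25% CV).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import FeatureTable

ORIGIN_LEVELS = ("DLD1", "HCT116", "LS174T", "SW620")
RESISTANCE_LEVELS = ("naive", "resistant")

#: orthonormal centered contrasts over the four origins; axis 1 separates
#: {LS174T, SW620} from {DLD1, HCT116}, the dominant split in the study system
_ORIGIN_CONTRASTS = np.array(
    [
        [-0.5, -0.5, 0.5, 0.5],
        [-0.5, 0.5, -0.5, 0.5],
        [-0.5, 0.5, 0.5, -0.5],
    ]
)

#: default class palette (class -> weight); sphingolipid classes get ;2O/;3O
#: suffixes, 'ether*' classes produce O- chain prefixes.
DEFAULT_CLASS_PALETTE = {
    "TG": 0.20,
    "PC": 0.16,
    "PE": 0.10,
    "PI": 0.05,
    "PS": 0.05,
    "PG": 0.02,
    "BMP": 0.02,
    "LPC": 0.04,
    "LPE": 0.03,
    "DG": 0.05,
    "CE": 0.03,
    "SM": 0.08,
    "Cer_NS": 0.05,
    "HexCer": 0.05,
    "etherTG": 0.03,
    "etherPC": 0.03,
    "etherPE": 0.01,
}

SPHINGO_PREFIXES = ("SM", "ASM", "Cer", "HexCer")


@dataclass
class PlantedShift:
    """A class-targeted resistant/naive fold change planted in one origin,
    optionally restricted to long or short acyl chains (sphingolipids)."""

    lipid_class: str
    origin: str
    log2fc: float
    chain: str | None = None  # None, 'long' or 'short'
    acyl_threshold: int = 18


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_features: int = 750
    replicates_per_cell: int = 6
    n_qc: int = 5
    n_blank: int = 3
    effect_fractions: dict = field(
        default_factory=lambda: {
            "origin": 0.584,
            "resistance": 0.078,
            "interaction": 0.181,
            "residual": 0.157,
        }
    )
    dilution_sd: float = 0.2
    missing_rate: float = 0.02
    class_palette: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PALETTE))
    seed: int = 0
    # shaping of the planted structure
    origin_axis_weights: tuple = (0.68, 0.255, 0.065)
    orthogonal_fraction: float = 0.3  # share of residual SS in a structured source
    effect_feature_fraction: float = 1.0  # fraction of features carrying effects
    n_blank_fail: int = 3  # features engineered to fail the 5x-blank rule
    # intensity scales (natural-log units)
    base_log_mean: float = np.log(5e6)
    base_log_sd: float = 1.0
    signal_log_sd: float = 0.25
    qc_cv: float = 0.05
    blank_rel_level: float = 1e-3
    planted_shifts: tuple = ()

    def validate(self) -> None:
        f = self.effect_fractions
        keys = {"origin", "resistance", "interaction", "residual"}
        if set(f) != keys:
            raise ConfigError(f"effect_fractions must have keys {sorted(keys)}")
        vals = np.array([f[k] for k in sorted(keys)], dtype=float)
        if (vals < 0).any():
            raise ConfigError("effect fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigError(f"effect_fractions must sum to 1 (got {vals.sum()!r})")
        if self.replicates_per_cell < 2:
            raise ConfigError("replicates_per_cell must be >= 2 for residual estimability")
        if f["residual"] == 0 and self.replicates_per_cell > 1:
            raise ConfigError("residual fraction 0 is infeasible with replicates > 1")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.dilution_sd < 0:
            raise ConfigError("dilution_sd must be >= 0")
        if not (0 < self.effect_feature_fraction <= 1):
            raise ConfigError("effect_feature_fraction must lie in (0, 1]")
        carried = (f["origin"] + f["resistance"] + f["interaction"]) / self.effect_feature_fraction
        if carried > 1 + 1e-9:
            raise ConfigError(
                "effect_feature_fraction too small: carrier features would need "
                f"an effect share of {carried:.3f} > 1"
            )
        if not (0 <= self.orthogonal_fraction < 1):
            raise ConfigError("orthogonal_fraction must lie in [0, 1)")
        w = np.asarray(self.origin_axis_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("origin_axis_weights must be 3 non-negative numbers summing to 1")
        if self.n_features < 12:
            raise ConfigError("n_features must be >= 12 (PQN needs >= 10 reference features)")
        if self.n_qc < 2 or self.n_blank < 1:
            raise ConfigError("need >= 2 QC and >= 1 blank injections")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset (log-scale effect matrices,
    dilution factors, realized sum-of-squares shares, planted feature sets)."""

    effect_matrices: dict  # origin/resistance/interaction -> (n_bio, p) DataFrame
    dilution_factors: pd.Series  # per sample, 1.0 on qc/blank rows
    true_fractions: dict  # realized log-scale SS shares (incl. residual)
    requested_fractions: dict
    blank_fail_features: list
    effect_features: list  # features carrying design effects
    orthogonal_scores: pd.Series | None  # planted Y-orthogonal sample trend
    planted_shift_features: dict  # PlantedShift index -> feature list


def _allocate_counts(palette: dict, n: int) -> dict:
    """Largest-remainder allocation of n features over class weights."""
    total = sum(palette.values())
    raw = {c: n * w / total for c, w in palette.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return {c: k for c, k in counts.items() if k > 0}


def _make_names(rng: np.random.Generator, palette: dict, n: int) -> list:
    """Unique shorthand names with plausible carbons/double bonds: carbons in
    [30, 60], double bonds in [0, 8]; sphingolipids get a ;2O (or ;3O) suffix,
    ether classes an O- prefix."""
    counts = _allocate_counts(palette, n)
    names = []
    for cls in sorted(counts):
        k = counts[cls]
        ether = cls.lower().startswith("ether")
        base = cls[5:] if ether else cls
        sphingo = base.split("_")[0] in SPHINGO_PREFIXES
        combos = [(c, d) for c in range(30, 61) for d in range(0, 9)]
        if k > len(combos):
            raise ConfigError(f"class {cls}: cannot draw {k} unique compositions")
        picks = rng.choice(len(combos), size=k, replace=False)
        for idx in picks:
            c, d = combos[idx]
            prefix = "O-" if ether else ""
            suffix = ""
            if sphingo:
                n_ox = 2 if rng.random() < 0.85 else 3
                suffix = f";{n_ox}O"
            names.append(f"{base} {prefix}{c}:{d}{suffix}")
    rng.shuffle(names)
    return names


def _chain_side(name: str, shift: PlantedShift) -> str | None:
    from .io import parse_lipid_name, LipidParseError

    try:
        ann = parse_lipid_name(name)
    except LipidParseError:
        return None
    acyl = ann.total_carbons - 18 if ann.sphingolipid else ann.total_carbons
    return "long" if acyl >= shift.acyl_threshold else "short"


def simulate_dataset(cfg: SimConfig) -> tuple[FeatureTable, SimTruth]:
    """Generate a balanced 4x2 feature table plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_features
    reps = cfg.replicates_per_cell
    n_bio = len(ORIGIN_LEVELS) * len(RESISTANCE_LEVELS) * reps
    frac = cfg.effect_fractions

    names = _make_names(rng, cfg.class_palette, p)

    origin = np.repeat(ORIGIN_LEVELS, len(RESISTANCE_LEVELS) * reps)
    resist = np.tile(np.repeat(RESISTANCE_LEVELS, reps), len(ORIGIN_LEVELS))
    bio_ids = [
        f"{o}_{'R' if r == 'resistant' else 'N'}_{k % reps + 1}"
        for k, (o, r) in enumerate(zip(origin, resist))
    ]
    o_idx = np.array([ORIGIN_LEVELS.index(o) for o in origin])
    r_idx = np.array([RESISTANCE_LEVELS.index(r) for r in resist])
    cell_idx = o_idx * 2 + r_idx

    # per-feature target SS on log scale
    T = n_bio * cfg.signal_log_sd**2
    rho = cfg.effect_feature_fraction
    n_carrier = max(1, int(round(rho * p)))
    carrier = np.zeros(p, dtype=bool)
    carrier[rng.choice(p, size=n_carrier, replace=False)] = True

    w_axes = np.asarray(cfg.origin_axis_weights, dtype=float)
    res_contrast = np.array([-1.0, 1.0]) / np.sqrt(2.0)

    # planted Y-orthogonal structured sample trend (lives in the residual block)
    v = rng.standard_normal(n_bio)
    for c in range(8):  # residualize against the cell-mean subspace
        rows = cell_idx == c
        v[rows] -= v[rows].mean()
    v /= np.linalg.norm(v)

    A = np.zeros((n_bio, p))
    B = np.zeros((n_bio, p))
    G = np.zeros((n_bio, p))
    R = np.zeros((n_bio, p))
    for j in range(p):
        f_o = frac["origin"] / rho if carrier[j] else 0.0
        f_b = frac["resistance"] / rho if carrier[j] else 0.0
        f_g = frac["interaction"] / rho if carrier[j] else 0.0
        f_e = 1.0 - f_o - f_b - f_g

        if f_o > 0:
            signs = rng.choice([-1.0, 1.0], size=3)
            alpha = (np.sqrt(w_axes) * signs) @ _ORIGIN_CONTRASTS  # (4,)
            a = alpha[o_idx]
            A[:, j] = a * np.sqrt(f_o * T / np.sum(a**2))
        if f_b > 0:
            b = (rng.choice([-1.0, 1.0]) * res_contrast)[r_idx]
            B[:, j] = b * np.sqrt(f_b * T / np.sum(b**2))
        if f_g > 0:
            g0 = rng.standard_normal((4, 2))
            g0 = g0 - g0.mean(axis=1, keepdims=True) - g0.mean(axis=0, keepdims=True) + g0.mean()
            g = g0[o_idx, r_idx]
            ss = np.sum(g**2)
            if ss > 1e-24:
                G[:, j] = g * np.sqrt(f_g * T / ss)
        if f_e > 0:
            # i.i.d. noise with full variance on every sample-space direction
            # (only the planted structured source is projected out, keeping
            # its share exact); the noise therefore leaks O(1/n) into the
            # estimated effect matrices, the usual finite-sample bias
            e = rng.standard_normal(n_bio)
            of = cfg.orthogonal_fraction
            if of > 0:
                # keep the structured source's share exact; without a source
                # the noise must stay fully isotropic (no shared zero-variance
                # direction), or row exchangeability would be broken
                e -= v * (v @ e)
                e *= np.sqrt((1.0 - of) * f_e * T / np.sum(e**2))
                R[:, j] = e + v * (rng.choice([-1.0, 1.0]) * np.sqrt(of * f_e * T))
            else:
                R[:, j] = e * np.sqrt(f_e * T / np.sum(e**2))

    mu = cfg.base_log_mean + cfg.base_log_sd * rng.standard_normal(p)
    L = mu[None, :] + A + B + G + R

    # class/chain-targeted resistant-vs-naive shifts (report-stage truth)
    factors_bio = pd.DataFrame({"origin": origin, "resistance": resist}, index=bio_ids)
    shift_features: dict = {}
    for si, shift in enumerate(cfg.planted_shifts):
        hit = []
        for j, name in enumerate(names):
            cls = name.split(" ")[0]
            target = shift.lipid_class[5:] if shift.lipid_class.lower().startswith("ether") else shift.lipid_class
            if cls != target:
                continue
            if shift.chain is not None and _chain_side(name, shift) != shift.chain:
                continue
            hit.append(name)
            rows = (origin == shift.origin) & (resist == "resistant")
            L[rows, j] += shift.log2fc * np.log(2.0)
        shift_features[si] = hit

    comp_ss = {
        "origin": float(np.sum(A**2)),
        "resistance": float(np.sum(B**2)),
        "interaction": float(np.sum(G**2)),
        "residual": float(np.sum(R**2)),
    }
    total_ss = sum(comp_ss.values())
    realized = {k: v_ / total_ss for k, v_ in comp_ss.items()}

    dil = np.exp(cfg.dilution_sd * rng.standard_normal(n_bio)) if cfg.dilution_sd > 0 else np.ones(n_bio)
    base = np.exp(L)
    bio = base * dil[:, None]

    if cfg.missing_rate > 0:
        # left-censoring: a cell goes missing when it falls below the
        # feature's detection limit (its missing_rate quantile), emulating
        # non-detection of low signals. The limit is applied to the
        # dilution-free intensity so that missingness does not itself inject
        # dilution-correlated structure: the generator's planted effect and
        # orthogonal-trend ground truth must stay the only structure present.
        limits = np.quantile(base, cfg.missing_rate, axis=0)
        bio[base < limits[None, :]] = np.nan

    qc = np.exp(mu[None, :] + cfg.qc_cv * rng.standard_normal((cfg.n_qc, p)))
    blank_scale = np.full(p, cfg.blank_rel_level)
    blank_fail = []
    if cfg.n_blank_fail > 0:
        idx = rng.choice(p, size=min(cfg.n_blank_fail, p), replace=False)
        blank_scale[idx] = 2.0  # blank at 2x signal level -> 5x-blank rule fires
        blank_fail = [names[j] for j in sorted(idx)]
    blank = np.exp(mu[None, :]) * blank_scale[None, :] * np.exp(
        0.2 * rng.standard_normal((cfg.n_blank, p))
    )

    blank_ids = [f"blank_{k + 1}" for k in range(cfg.n_blank)]
    qc_ids = [f"QC_{k + 1}" for k in range(cfg.n_qc)]
    all_ids = blank_ids + qc_ids + bio_ids
    intensities = pd.DataFrame(
        np.vstack([blank, qc, bio]), index=pd.Index(all_ids, name="sample_id"), columns=names
    )
    roles = pd.Series(
        ["blank"] * cfg.n_blank + ["qc"] * cfg.n_qc + ["biological"] * n_bio,
        index=intensities.index,
        name="role",
    )
    factors = pd.DataFrame(
        {
            "origin": [None] * (cfg.n_blank + cfg.n_qc) + list(origin),
            "resistance": [None] * (cfg.n_blank + cfg.n_qc) + list(resist),
        },
        index=intensities.index,
    )
    factors = factors.where(factors.notna())  # normalize None -> NaN
    table = FeatureTable(intensities, roles, factors)

    truth = SimTruth(
        effect_matrices={
            "origin": pd.DataFrame(A, index=bio_ids, columns=names),
            "resistance": pd.DataFrame(B, index=bio_ids, columns=names),
            "interaction": pd.DataFrame(G, index=bio_ids, columns=names),
        },
        dilution_factors=pd.Series(
            np.concatenate([np.ones(cfg.n_blank + cfg.n_qc), dil]),
            index=intensities.index,
            name="dilution",
        ),
        true_fractions=realized,
        requested_fractions=dict(frac),
        blank_fail_features=blank_fail,
        effect_features=[names[j] for j in range(p) if carrier[j]],
        orthogonal_scores=(
            pd.Series(v, index=bio_ids, name="orthogonal_trend")
            if cfg.orthogonal_fraction > 0
            else None
        ),
        planted_shift_features=shift_features,
    )
    return table, truth


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML-loaded) mapping."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    kwargs = dict(d)
    if "planted_shifts" in kwargs:
        kwargs["planted_shifts"] = tuple(
            PlantedShift(**s) if isinstance(s, dict) else s for s in kwargs["planted_shifts"]
        )
    if "origin_axis_weights" in kwargs:
        kwargs["origin_axis_weights"] = tuple(kwargs["origin_axis_weights"])
    return SimConfig(**kwargs)
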