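"""Feature-quality filtering, PQN normalization, imputation and UV scaling.

The filtering rules mirror standard pooled-QC-based quality control of an
untargeted lipidomics feature table; defaults are the study values:

(a) missingness: a biological cell counts as missing when it is absent or
    <= 5x the feature's mean blank signal; features missing in > 75% of
    biological samples are dropped (features with no blank signal fall back
    to absolute missingness);
(b) mean pooled-QC intensity < 1e5;
(c) pooled-QC coefficient of variation (sd/mean, n-1 denominator, on raw QC
    intensities) > 40%;
(d) zero interquartile range across biological samples
    (linear-interpolation quartiles).

Removal is by union of the rules; the report attributes each removed feature
to its first failing rule in (a)(b)(c)(d) order. Missingness is computed
across biological samples only (QCs are pooled copies, blanks are solvent) —
this choice is recorded in the report.

Probabilistic quotient normalization (PQN) estimates one dilution factor per
injection as the median ratio of its features to a reference spectrum (the
per-feature median over pooled-QC injections) and divides the row by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import FeatureTable

FILTER_RULES = ("missingness", "qc_intensity", "qc_cv", "iqr")

_MISSINGNESS_NOTE = (
    "missingness computed across biological samples only (QC/blank excluded); "
    "a cell counts as missing when absent or <= blank_mult x mean blank signal"
)


@dataclass
class FilterReport:
    n_input: int
    removed_by_missingness: list
    removed_by_qc_intensity: list
    removed_by_qc_cv: list
    removed_by_iqr: list
    first_fail: dict  # feature -> first failing rule
    n_retained: int
    note: str = _MISSINGNESS_NOTE

    @property
    def removed(self) -> set:
        return (
            set(self.removed_by_missingness)
            | set(self.removed_by_qc_intensity)
            | set(self.removed_by_qc_cv)
            | set(self.removed_by_iqr)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, rule) for f, rule in self.first_fail.items()]
        df = pd.DataFrame(rows, columns=["feature", "first_failing_rule"])
        return df.set_index("feature")


def filter_features(
    table: FeatureTable,
    missing_frac: float = 0.75,
    blank_mult: float = 5.0,
    qc_min_mean: float = 1e5,
    qc_max_cv: float = 0.40,
    *,
    require_blank: bool = True,
) -> tuple[FeatureTable, FilterReport]:
    """Apply the four quality rules; retained features keep original order.

    Requires >= 1 QC row; requires >= 1 blank row unless ``require_blank``
    is False, in which case the blank-threshold part of rule (a) is disabled.
    """
    qc = table.matrix("qc").to_numpy()
    if qc.shape[0] == 0:
        raise InputError("no QC rows: QC-dependent filter rules are unevaluable")
    blank = table.matrix("blank").to_numpy()
    if blank.shape[0] == 0:
        if require_blank:
            raise InputError(
                "no blank rows: pass require_blank=False to disable the blank rule"
            )
        blank_mean = np.zeros(table.n_features)
    else:
        blank_mean = np.where(np.isnan(blank), 0.0, blank).mean(axis=0)
    bio = table.matrix("biological").to_numpy()
    if bio.shape[0] == 0:
        raise InputError("no biological rows")

    names = table.feature_names

    # (a) missingness vs 5x blank
    thresh = blank_mult * blank_mean
    counts_as_missing = np.isnan(bio) | (
        (thresh[None, :] > 0) & (np.where(np.isnan(bio), np.inf, bio) <= thresh[None, :])
    )
    # absent cells always count; the <= comparison uses +inf placeholders so
    # NaN never leaks through the comparison
    counts_as_missing |= np.isnan(bio)
    fail_a = counts_as_missing.mean(axis=0) > missing_frac

    # (b)/(c) pooled-QC intensity and repeatability; non-detected QC cells = 0
    qc0 = np.where(np.isnan(qc), 0.0, qc)
    qc_mean = qc0.mean(axis=0)
    fail_b = qc_mean < qc_min_mean
    if qc0.shape[0] > 1:
        qc_sd = qc0.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            qc_cv = np.where(qc_mean > 0, qc_sd / qc_mean, np.inf)
    else:
        qc_cv = np.zeros(table.n_features)  # CV unevaluable with one QC row
    fail_c = qc_cv > qc_max_cv

    # (d) zero IQR across biological samples
    with np.errstate(invalid="ignore"):
        q75 = np.nanpercentile(bio, 75, axis=0)
        q25 = np.nanpercentile(bio, 25, axis=0)
    iqr = q75 - q25
    fail_d = ~(iqr > 0)  # NaN (all-missing feature) also fails

    fails = {"missingness": fail_a, "qc_intensity": fail_b, "qc_cv": fail_c, "iqr": fail_d}
    first_fail = {}
    for j, name in enumerate(names):
        for rule in FILTER_RULES:
            if fails[rule][j]:
                first_fail[name] = rule
                break
    removed_any = fail_a | fail_b | fail_c | fail_d
    keep = [names[j] for j in range(len(names)) if not removed_any[j]]

    report = FilterReport(
        n_input=table.n_features,
        removed_by_missingness=[n for j, n in enumerate(names) if fail_a[j]],
        removed_by_qc_intensity=[n for j, n in enumerate(names) if fail_b[j]],
        removed_by_qc_cv=[n for j, n in enumerate(names) if fail_c[j]],
        removed_by_iqr=[n for j, n in enumerate(names) if fail_d[j]],
        first_fail=first_fail,
        n_retained=len(keep),
    )
    filtered = table.with_intensities(table.intensities[keep])
    return filtered, report


@dataclass
class NormalizationResult:
    corrected: FeatureTable
    dilution_factors: pd.Series
    reference_spectrum: pd.Series


def pqn_normalize(table: FeatureTable, *, min_quotients: int = 10) -> NormalizationResult:
    """Probabilistic quotient normalization against the median QC spectrum.

    Every row (biological, QC and blank alike) is divided by the median of
    its quotients against the reference; features with a missing value or a
    non-positive reference are excluded from the quotient set. A row with
    fewer than ``min_quotients`` evaluable quotients is an error.
    """
    qc = table.matrix("qc")
    if qc.shape[0] == 0:
        raise InputError("PQN needs >= 1 QC row to build the reference spectrum")
    ref = np.nanmedian(qc.to_numpy(), axis=0)
    ref_ok = np.isfinite(ref) & (ref > 0)
    if ref_ok.sum() < min_quotients:
        raise InputError(
            f"only {int(ref_ok.sum())} strictly positive reference features; "
            f"need >= {min_quotients}"
        )

    X = table.intensities.to_numpy()
    factors = np.empty(X.shape[0])
    for i, sid in enumerate(table.sample_ids):
        mask = ref_ok & np.isfinite(X[i])
        if mask.sum() < min_quotients:
            raise InputError(
                f"sample {sid!r} has {int(mask.sum())} evaluable quotients; "
                f"need >= {min_quotients}"
            )
        factors[i] = np.median(X[i, mask] / ref[mask])
    corrected = table.intensities.div(factors, axis=0)

    return NormalizationResult(
        corrected=table.with_intensities(corrected),
        dilution_factors=pd.Series(factors, index=table.sample_ids, name="dilution_factor"),
        reference_spectrum=pd.Series(ref, index=table.feature_names, name="reference"),
    )


def impute_missing(table: FeatureTable, method: str = "half_min") -> FeatureTable:
    """Replace missing cells; ``half_min`` uses half the feature's minimum
    observed biological intensity, ``none`` errors if any cell is missing."""
    X = table.intensities
    if method == "none":
        if X.isna().any().any():
            n = int(X.isna().to_numpy().sum())
            raise InputError(f"{n} missing cells remain and method='none'")
        return table.copy()
    if method != "half_min":
        raise InputError(f"unknown imputation method {method!r}")
    bio = table.matrix("biological")
    mins = bio.min(axis=0, skipna=True)
    dead = mins.index[~np.isfinite(mins.to_numpy())]
    if len(dead):
        raise InputError(
            f"features with no observed biological value (should have been "
            f"filtered): {list(dead)}"
        )
    filled = X.fillna(mins * 0.5)
    return table.with_intensities(filled)


def uv_scale(X) -> tuple:
    """Unit-variance scale a biological-sample matrix: center each column and
    divide by its sd (n-1 denominator). Returns (scaled, means, sds) so that
    loadings can be back-transformed."""
    is_frame = isinstance(X, pd.DataFrame)
    Xv = np.asarray(X, dtype=float)
    if np.isnan(Xv).any():
        raise InputError("matrix contains missing values; impute before scaling")
    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        names = list(X.columns[zero]) if is_frame else list(zero)
        raise InputError(f"zero-variance features cannot be scaled: {names}")
    scaled = (Xv - mean) / sd
    if is_frame:
        scaled = pd.DataFrame(scaled, index=X.index, columns=X.columns)
        mean = pd.Series(mean, index=X.columns, name="mean")
        sd = pd.Series(sd, index=X.columns, name="sd")
    return scaled, mean, sd


def uv_unscale(scaled, mean, sd):
    """Inverse of :func:`uv_scale`."""
    return scaled * sd + mean
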