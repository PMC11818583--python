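"""Descriptive lipid-signature outputs.

Normalized class compositions per design group, resistant/naive log2 fold
changes per origin (species- or class-level), and chain-length shift tables
for classes whose species behave differently by acyl length (sphingolipids:
acyl carbons = total carbons - 18, a d18 sphingoid backbone being assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import FeatureTable, LipidAnnotation

OTHER_CLASS = "other"


def _group_means(table: FeatureTable) -> pd.DataFrame:
    """Per-(origin, resistance) group mean intensity per feature (NaN-aware),
    indexed by the group pair."""
    bio = table.matrix("biological")
    factors = table.biological_factors()
    groups = bio.groupby(
        [factors["origin"], factors["resistance"]], observed=True
    ).mean()
    if groups.isna().all(axis=1).any():
        raise InputError("a design group has no observed intensities")
    return groups


def _class_of(name: str, annotations: dict) -> str:
    ann = annotations.get(name)
    if isinstance(ann, LipidAnnotation):
        # ether species grouped under an 'ether<class>' label, as in the
        # study's sub-class vocabulary
        return ("ether" + ann.lipid_class) if ann.ether else ann.lipid_class
    return OTHER_CLASS


@dataclass
class ClassComposition:
    """Fraction of summed intensity per lipid class in one design group."""

    group: tuple  # (origin, resistance)
    shares: dict  # lipid_class -> fraction, summing to 1


def class_composition(table: FeatureTable, annotations: dict) -> list:
    """Per design group: mean feature intensity over replicates, summed
    within class, divided by the group's grand total."""
    means = _group_means(table)
    classes = pd.Series(
        {name: _class_of(name, annotations) for name in table.feature_names}
    )
    out = []
    for group, row in means.iterrows():
        totals = row.groupby(classes).sum()
        grand = float(totals.sum())
        if grand <= 0:
            raise InputError(f"group {group} has zero total intensity")
        out.append(ClassComposition(group=tuple(group), shares=dict(totals / grand)))
    return out


def composition_frame(compositions: list) -> pd.DataFrame:
    """Wide export table: rows = groups, columns = classes."""
    rows = {
        f"{origin}:{resistance}": comp.shares
        for comp, (origin, resistance) in ((c, c.group) for c in compositions)
    }
    return pd.DataFrame(rows).T.fillna(0.0).rename_axis("group")


@dataclass
class FoldChangeTable:
    """log2(mean resistant / mean naive) per origin; antisymmetric under
    swapping the group roles. Non-computable cells are NaN with a reason."""

    values: pd.DataFrame  # rows = features or classes, columns = origins
    reasons: pd.DataFrame  # same shape; '' where computable


def log2_fold_change(
    table: FeatureTable,
    level_by: str = "species",
    annotations: dict | None = None,
) -> FoldChangeTable:
    """Resistant/naive log2 fold changes on PQN-corrected intensities,
    per origin, at species or class level."""
    if level_by not in ("species", "class"):
        raise InputError("level_by must be 'species' or 'class'")
    if level_by == "class" and annotations is None:
        raise InputError("class-level fold changes need annotations")
    means = _group_means(table)
    origins = means.index.get_level_values(0).unique()
    res_levels = set(means.index.get_level_values(1))
    if not {"naive", "resistant"} <= res_levels:
        raise InputError(
            f"both resistance levels required; found {sorted(res_levels)}"
        )

    if level_by == "class":
        classes = pd.Series(
            {name: _class_of(name, annotations) for name in table.feature_names}
        )
        means = means.T.groupby(classes).sum(min_count=1).T

    vals = {}
    reasons = {}
    for o in origins:
        num = means.loc[(o, "resistant")]
        den = means.loc[(o, "naive")]
        ok = (num > 0) & (den > 0) & num.notna() & den.notna()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(ok, np.log2(num / den), np.nan)
        vals[o] = pd.Series(fc, index=means.columns)
        reasons[o] = pd.Series(
            np.where(ok, "", "non-positive or missing group mean"),
            index=means.columns,
        )
    return FoldChangeTable(values=pd.DataFrame(vals), reasons=pd.DataFrame(reasons))


def chain_length_shift(
    table: FeatureTable,
    annotations: dict,
    class_filter: str,
    acyl_threshold: int = 18,
    *,
    sphingoid_carbons: int = 18,
) -> pd.DataFrame:
    """Per-origin chain-length-resolved fold-change directions for one class.

    For sphingolipid classes the acyl chain length is total carbons minus the
    sphingoid backbone (default d18); other classes use total carbons, with
    the caller choosing a suitable threshold. Species with
    acyl >= ``acyl_threshold`` are labeled 'long', the rest 'short';
    direction is the sign of the per-origin log2 fold change.
    """
    target_ether = class_filter.lower().startswith("ether")
    target = class_filter[5:] if target_ether else class_filter
    members = []
    for name in table.feature_names:
        ann = annotations.get(name)
        if not isinstance(ann, LipidAnnotation):
            continue
        if ann.lipid_class == target and ann.ether == target_ether:
            members.append((name, ann))
    if not members:
        warnings.warn(f"no features of class {class_filter!r}; empty table")
        return pd.DataFrame(
            columns=["origin", "species", "acyl_carbons", "chain", "log2fc", "direction"]
        )

    sub = table.with_intensities(table.intensities[[n for n, _ in members]])
    fc = log2_fold_change(sub, level_by="species")
    rows = []
    for name, ann in members:
        acyl = ann.total_carbons - sphingoid_carbons if ann.sphingolipid else ann.total_carbons
        side = "long" if acyl >= acyl_threshold else "short"
        for origin in fc.values.columns:
            val = fc.values.loc[name, origin]
            rows.append(
                {
                    "origin": origin,
                    "species": name,
                    "acyl_carbons": acyl,
                    "chain": side,
                    "log2fc": val,
                    "direction": float(np.sign(val)) if np.isfinite(val) else np.nan,
                }
            )
    return pd.DataFrame(rows)
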