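"""Feature-table I/O and lipid shorthand parsing.

The feature table is the samples x lipid-features intensity matrix exported by
an alignment tool (MS-DIAL style): rows are injections, columns are lipid
features, and a companion metadata table assigns each injection a role
(``biological``, ``qc`` for pooled quality controls, ``blank``) and, for
biological injections, the two design factors (cell-line origin and
FOLFOXIRI-resistance status).

Missing measurements are held as NaN, never as zero: MS-DIAL writes 0 for
non-detected peaks, so by default literal zeros are converted to missing on
read (``zero_is_missing``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, LipidParseError

ROLES = ("biological", "qc", "blank")
FACTOR_COLUMNS = ("origin", "resistance")

# --------------------------------------------------------------------------
# Lipid shorthand
# --------------------------------------------------------------------------

#: classes whose names imply a sphingoid backbone (d18 assumed downstream)
SPHINGOLIPID_CLASSES = ("SM", "ASM", "Cer", "HexCer")

#: the study's class vocabulary; parsing is total on these tokens and keeps
#: any unknown token verbatim as the class.
KNOWN_CLASSES = (
    "TG", "DG", "MGDG", "PC", "LPC", "PE", "LPE", "PI", "PS", "PG", "BMP",
    "SM", "ASM", "CE",
    "Cer", "Cer_NS", "Cer_HS", "Cer_HDS", "Cer_HD",
    "HexCer", "HexCer_HS",
)

_CHAIN_RE = re.compile(
    r"^(?P<eth>[OP]-)?(?P<c>\d+):(?P<d>\d+)"
    r"(?:;(?:(?P<n1>\d*)O|O(?P<n2>\d*)))?$"
)


@dataclass(frozen=True)
class LipidAnnotation:
    """Parsed lipid shorthand: 'SM 36:1;2O' -> class SM, 36 carbons, 1 double
    bond, 2 oxygens; an 'O-' (or plasmenyl 'P-') chain prefix or an 'ether'
    class alias marks an ether linkage."""

    lipid_class: str
    ether: bool
    total_carbons: int
    double_bonds: int
    oxygens: int
    raw_name: str

    @property
    def sphingolipid(self) -> bool:
        base = self.lipid_class.split("_")[0]
        return base in SPHINGOLIPID_CLASSES

    def canonical(self) -> str:
        """Canonical single-composition form of the name."""
        prefix = "O-" if self.ether else ""
        s = f"{self.lipid_class} {prefix}{self.total_carbons}:{self.double_bonds}"
        if self.oxygens == 1:
            s += ";O"
        elif self.oxygens > 1:
            s += f";{self.oxygens}O"
        return s


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse MS-DIAL-style lipid shorthand.

    Chain-level annotations ('PC 16:0/18:2' or 'PC 16:0_18:2') are summed to
    total composition. Subclass suffixes after an underscore in the class
    token ('Cer_NS') are kept as part of the class. Raises
    :class:`LipidParseError` when no carbons:double-bonds field is present.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    s = name.strip()
    parts = s.split(None, 1)
    if len(parts) == 1:
        raise LipidParseError(f"no composition field in {name!r}")
    cls, rest = parts
    ether = False
    if cls.lower().startswith("ether") and len(cls) > 5:
        cls = cls[5:]
        ether = True
    carbons = dbs = oxys = 0
    for chain in re.split(r"[/_]", rest):
        m = _CHAIN_RE.match(chain.strip())
        if m is None:
            raise LipidParseError(f"unparsable chain {chain!r} in {name!r}")
        if m.group("eth"):
            ether = True
        carbons += int(m.group("c"))
        dbs += int(m.group("d"))
        n = m.group("n1") if m.group("n1") is not None else m.group("n2")
        if n is not None:
            oxys += int(n) if n != "" else 1
    if dbs > carbons:
        raise LipidParseError(f"double bonds exceed carbons in {name!r}")
    return LipidAnnotation(cls, ether, carbons, dbs, oxys, raw_name=name)


def annotate_features(names) -> dict:
    """Parse a collection of names; unparsable names map to None."""
    out = {}
    for name in names:
        try:
            out[name] = parse_lipid_name(name)
        except LipidParseError:
            out[name] = None
    return out


# --------------------------------------------------------------------------
# Feature table
# --------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Intensity matrix (rows = injections, columns = lipid features) plus
    per-injection role and design-factor metadata.

    ``intensities`` holds floats with NaN for missing cells; ``factors`` has
    columns ``origin`` and ``resistance``, NaN on qc/blank rows.
    """

    intensities: pd.DataFrame
    roles: pd.Series
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        idx = self.intensities.index
        if not (self.roles.index.equals(idx) and self.factors.index.equals(idx)):
            raise InputError("roles/factors index does not match intensity rows")
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise InputError(f"duplicate sample ids: {dups}")
        cols = self.intensities.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise InputError(f"duplicate feature names: {dups}")
        bad_roles = set(self.roles) - set(ROLES)
        if bad_roles:
            raise InputError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        for col in FACTOR_COLUMNS:
            if col not in self.factors.columns:
                raise InputError(f"factors table lacks column {col!r}")
        bio = self.roles == "biological"
        if self.factors.loc[bio, list(FACTOR_COLUMNS)].isna().any().any():
            missing = self.factors.loc[bio].index[
                self.factors.loc[bio, list(FACTOR_COLUMNS)].isna().any(axis=1)
            ]
            raise InputError(f"biological samples without factor levels: {list(missing)}")
        if self.factors.loc[~bio, list(FACTOR_COLUMNS)].notna().any().any():
            raise InputError("qc/blank rows must not carry factor levels")
        vals = self.intensities.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise InputError("negative intensities are not allowed")

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_names(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def mask(self, role: str) -> pd.Series:
        return self.roles == role

    def matrix(self, role: str) -> pd.DataFrame:
        """Intensity sub-matrix for one role, row order preserved."""
        return self.intensities.loc[self.mask(role)]

    def biological_factors(self) -> pd.DataFrame:
        return self.factors.loc[self.mask("biological"), list(FACTOR_COLUMNS)]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.roles.copy(), self.factors.copy()
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureTable":
        """New table sharing metadata, with a replaced intensity matrix
        (feature subset allowed, sample set must match)."""
        if not intensities.index.equals(self.intensities.index):
            raise InputError("replacement intensities must keep the sample index")
        return FeatureTable(intensities, self.roles.copy(), self.factors.copy())


def _read_delimited(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    return pd.read_csv(path, sep=None, engine="python", **kw)


def read_feature_table(
    features_path,
    metadata_path,
    *,
    zero_is_missing: bool = True,
    sample_id_col: str = "sample_id",
    role_col: str = "role",
    origin_col: str = "origin",
    resistance_col: str = "resistance",
) -> FeatureTable:
    """Read a feature table + metadata table (comma or tab, sniffed).

    The features file must have sample ids in its first column; the metadata
    column layout is configurable since alignment exports vary. A features
    file whose *header* matches the metadata sample ids is rejected as
    transposed rather than silently fixed.
    """
    for path in (features_path, metadata_path):
        if not Path(path).exists():
            raise InputError(f"file not found: {path}")

    # duplicate feature names must be caught on the raw header (pandas would
    # silently mangle them to 'name.1')
    import csv

    with open(features_path) as fh:
        first_line = fh.readline()
    try:
        sep = csv.Sniffer().sniff(first_line, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    header = next(csv.reader([first_line], delimiter=sep))[1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise InputError(f"duplicate feature names: {dups}")

    feats = _read_delimited(features_path, index_col=0)
    meta = _read_delimited(metadata_path)
    for col in (sample_id_col, role_col, origin_col, resistance_col):
        if col not in meta.columns:
            raise InputError(f"metadata lacks column {col!r}")
    meta = meta.set_index(sample_id_col)
    if meta.index.has_duplicates:
        dups = sorted(meta.index[meta.index.duplicated()].unique())
        raise InputError(f"duplicate sample ids in metadata: {dups}")

    feat_ids = set(map(str, feats.index))
    meta_ids = set(map(str, meta.index))
    if feat_ids != meta_ids:
        if meta_ids <= set(map(str, feats.columns)):
            raise InputError(
                "features file appears transposed (sample ids found in its "
                "header); expected rows = injections, columns = features"
            )
        missing = sorted(meta_ids - feat_ids) + sorted(feat_ids - meta_ids)
        raise InputError(f"sample ids mismatch between files: {missing}")
    meta = meta.loc[feats.index]

    intensities = feats.apply(pd.to_numeric, errors="coerce").astype(float)
    if zero_is_missing:
        intensities = intensities.where(intensities != 0.0)

    roles = meta[role_col].astype(str).str.strip().str.lower()
    roles.name = "role"
    factors = pd.DataFrame(
        {
            "origin": meta[origin_col].where(meta[origin_col].notna()),
            "resistance": meta[resistance_col].where(meta[resistance_col].notna()),
        },
        index=meta.index,
    )
    # empty strings in qc/blank factor cells count as absent
    for col in FACTOR_COLUMNS:
        factors[col] = factors[col].replace("", np.nan)
    return FeatureTable(intensities, roles, factors)


def write_feature_table(table: FeatureTable, features_path, metadata_path) -> None:
    """Write a feature table as a (features.csv, metadata.csv) pair that
    round-trips exactly through :func:`read_feature_table`: present values are
    written with round-trip float precision, missing cells as empty."""
    df = table.intensities.copy()
    df.index.name = "sample_id"
    df.to_csv(features_path, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "role": table.roles.to_numpy(),
            "origin": table.factors["origin"].to_numpy(),
            "resistance": table.factors["resistance"].to_numpy(),
        }
    )
    meta.to_csv(metadata_path, index=False)


# --------------------------------------------------------------------------
# Result export
# --------------------------------------------------------------------------

#: bundle key -> exported file name; keys absent or empty are skipped.
RESULT_FILES = {
    "filter_report": "filter_report.csv",
    "effect_proportions": "effect_proportions.csv",
    "scores": "scores.csv",
    "loadings": "loadings.csv",
    "block_contributions": "block_contributions.csv",
    "permutation_pvalues": "permutation_pvalues.csv",
    "class_composition": "class_composition.csv",
    "fold_changes": "fold_changes.csv",
}


def write_results(results: dict, out_dir) -> list:
    """Write the result bundle as comma-delimited tables (full float
    precision, one header row); returns the list of written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for key, fname in RESULT_FILES.items():
        obj = results.get(key)
        if obj is None:
            continue
        if isinstance(obj, pd.DataFrame) and obj.empty:
            continue
        path = out_dir / fname
        obj.to_csv(path, float_format="%.17g")
        manifest.append(path)
    return manifest
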