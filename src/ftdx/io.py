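"""CSV readers/writers for feature tables and metadata.

Dialect: UTF-8 CSV with header. Feature columns are named
``<prefix>_<atlas label>`` with prefixes ``thk_`` (cortical thickness),
``cvol_`` (cortical volume) and ``svol_`` (subcortical volume); the
features file and the metadata file are joined on ``subject_id``.
Missing values are rejected, never imputed.
"""

from __future__ import annotations

import os

import pandas as pd

from .atlas import AtlasSchema, default_atlas_schema
from .tables import METADATA_COLUMNS, FeatureTable, JoinError, SchemaError


def load_feature_table(
    features_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    schema: AtlasSchema | None = None,
    harmonized: bool = False,
) -> FeatureTable:
    """Load and validate a feature table from a features CSV + metadata CSV.

    Rows of the features file are matched to metadata rows by
    ``subject_id``; the returned table follows the metadata row order.

    Raises
    ------
    SchemaError
        If feature columns are missing/extra relative to the schema.
    JoinError
        If any subject_id fails to match across the two files.
    ValueError
        If a feature cell is non-numeric or missing.
    """
    schema = schema or default_atlas_schema()
    sep_f = "\t" if str(features_path).endswith((".tsv", ".txt")) else ","
    sep_m = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
    feats = pd.read_csv(features_path, sep=sep_f)
    meta = pd.read_csv(metadata_path, sep=sep_m)

    missing_meta = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_meta:
        raise SchemaError(f"metadata missing columns: {sorted(missing_meta)}")
    if "subject_id" not in feats.columns:
        raise SchemaError("features file has no subject_id column")

    expected = schema.feature_names
    got = [c for c in feats.columns if c != "subject_id"]
    missing = sorted(set(expected) - set(got))
    extra = sorted(set(got) - set(expected))
    if missing or extra:
        raise SchemaError(
            f"feature columns do not match schema: {len(missing)} missing "
            f"(e.g. {missing[:5]}), {len(extra)} unexpected (e.g. {extra[:5]})"
        )

    unmatched = set(meta["subject_id"]) ^ set(feats["subject_id"])
    if unmatched:
        raise JoinError(
            f"subject_id mismatch between features and metadata: "
            f"{sorted(map(str, unmatched))[:10]}"
        )

    feats = feats.set_index("subject_id").loc[meta["subject_id"]]
    block = feats[expected]
    non_numeric = block.select_dtypes(exclude="number").columns
    if len(non_numeric):
        col = non_numeric[0]
        bad = block[pd.to_numeric(block[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(
            f"non-numeric feature value at column {col!r}, subject {row!r}"
        )
    if block.isna().any().any():
        col = block.columns[block.isna().any().to_numpy()][0]
        raise ValueError(f"missing feature values in column {col!r}")

    return FeatureTable(
        metadata=meta.reset_index(drop=True),
        features=block.reset_index(drop=True).astype(float),
        schema=schema,
        harmonized=harmonized,
    )


def write_feature_table(
    table: FeatureTable,
    features_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    float_format: str = "%.10g",
) -> None:
    """Write the features and metadata CSVs (round-trips with the loader)."""
    out = table.features.copy()
    out.insert(0, "subject_id", table.metadata["subject_id"].to_numpy())
    out.to_csv(features_path, index=False, float_format=float_format)
    table.metadata.to_csv(metadata_path, index=False, float_format=float_format)
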