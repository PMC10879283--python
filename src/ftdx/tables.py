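"""Subject-by-feature morphometry table: the pipeline's exchange object.

A :class:`FeatureTable` pairs a metadata frame (diagnosis, age, sex,
education, TIV, cohort, scanner) with a 735-column feature matrix whose
column order is bound to an :class:`~ftdx.atlas.AtlasSchema`. Raw tables
hold physical units (mm for thickness, mm^3 for volumes); harmonized
tables hold unitless w-scores and carry ``harmonized=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import N_CORTICAL, N_SUBCORTICAL, AtlasSchema, default_atlas_schema

DIAGNOSES = ("bvFTD", "nfvPPA", "svPPA")

#: metadata columns every table must provide
METADATA_COLUMNS = (
    "subject_id",
    "diagnosis",
    "age",
    "sex",
    "education",
    "tiv",
    "cohort",
    "scanner_id",
)


class SchemaError(ValueError):
    """Feature columns do not match the atlas schema."""


class JoinError(ValueError):
    """Feature and metadata tables cannot be joined on subject_id."""


@dataclass
class FeatureTable:
    """Validated subjects x 735 morphometry table plus per-subject metadata.

    Attributes
    ----------
    metadata
        One row per subject; columns as in :data:`METADATA_COLUMNS`.
    features
        Numeric frame, columns = ``schema.feature_names`` in canonical
        order (thickness block, cortical-volume block, subcortical block).
    schema
        The atlas label registry the columns are bound to.
    harmonized
        True once values are w-scores rather than raw measurements.
    """

    metadata: pd.DataFrame
    features: pd.DataFrame
    schema: AtlasSchema = field(default_factory=default_atlas_schema)
    harmonized: bool = False

    def __post_init__(self) -> None:
        expected = self.schema.feature_names
        got = list(self.features.columns)
        if got != expected:
            missing = sorted(set(expected) - set(got))
            extra = sorted(set(got) - set(expected))
            if missing or extra:
                raise SchemaError(
                    f"feature columns do not match schema: "
                    f"{len(missing)} missing (e.g. {missing[:3]}), "
                    f"{len(extra)} unexpected (e.g. {extra[:3]})"
                )
            # same set, wrong order: reorder silently
            self.features = self.features[expected]
        if len(self.metadata) != len(self.features):
            raise JoinError(
                f"metadata has {len(self.metadata)} rows, "
                f"features has {len(self.features)}"
            )

    # ---- block views -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.metadata)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.metadata["subject_id"].to_numpy()

    @property
    def diagnosis(self) -> np.ndarray:
        return self.metadata["diagnosis"].to_numpy()

    @property
    def X(self) -> np.ndarray:
        """Full (n, 735) float matrix in canonical block order."""
        return self.features.to_numpy(dtype=float)

    @property
    def thickness(self) -> np.ndarray:
        return self.X[:, :N_CORTICAL]

    @property
    def cortical_volume(self) -> np.ndarray:
        return self.X[:, N_CORTICAL : 2 * N_CORTICAL]

    @property
    def subcortical_volume(self) -> np.ndarray:
        return self.X[:, 2 * N_CORTICAL :]

    def subset(self, indices) -> "FeatureTable":
        """Row subset (positional), preserving order of `indices`."""
        idx = np.asarray(indices)
        return FeatureTable(
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            features=self.features.iloc[idx].reset_index(drop=True),
            schema=self.schema,
            harmonized=self.harmonized,
        )

    def with_features(self, values: np.ndarray, harmonized: bool) -> "FeatureTable":
        """Same subjects/schema with a replaced feature matrix."""
        if values.shape != (self.n_subjects, self.schema.n_features):
            raise ValueError(f"feature matrix shape {values.shape} invalid")
        return FeatureTable(
            metadata=self.metadata.copy(),
            features=pd.DataFrame(values, columns=self.schema.feature_names),
            schema=self.schema,
            harmonized=harmonized,
        )


def validate_table(table: FeatureTable) -> list[str]:
    """Return a list of invariant violations (empty iff the table is valid).

    Checks: duplicate subject ids, unknown diagnosis labels, nonpositive
    age/TIV, missing values, and (raw tables only) nonpositive thickness.
    """
    report: list[str] = []
    md = table.metadata
    dup = md["subject_id"][md["subject_id"].duplicated()].unique()
    for sid in dup:
        report.append(f"duplicate subject_id: {sid}")
    bad_dx = md.loc[~md["diagnosis"].isin(DIAGNOSES), "subject_id"]
    for sid in bad_dx:
        report.append(f"unknown diagnosis for subject {sid}")
    for col, name in (("age", "age"), ("tiv", "TIV")):
        bad = md.loc[md[col] <= 0, "subject_id"]
        for sid in bad:
            report.append(f"nonpositive {name} for subject {sid}")
    if table.features.isna().any().any():
        rows, cols = np.nonzero(table.features.isna().to_numpy())
        for r, c in zip(rows[:20], cols[:20]):
            report.append(
                f"missing value at subject {md['subject_id'].iloc[r]}, "
                f"feature {table.features.columns[c]}"
            )
    if not table.harmonized:
        thk = table.thickness
        rows, cols = np.nonzero(thk <= 0)
        for r, c in zip(rows, cols):
            report.append(
                f"nonpositive thickness for subject "
                f"{md['subject_id'].iloc[r]}, feature "
                f"{table.features.columns[c]}"
            )
    return report
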