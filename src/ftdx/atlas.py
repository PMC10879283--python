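"""Atlas label registry for the 735-feature morphometric schema.

The feature space is 360 cortical patches (HCP-MMP1-style parcellation,
180 per hemisphere) carrying both a mean-thickness and a mean-volume
feature, plus 15 FreeSurfer-style subcortical gray-matter volumes
(7 bilateral structure pairs and the brainstem), for a total of
360 + 360 + 15 = 735 features per subject.

Real HCP-MMP1 label strings can be supplied by the user; by default the
schema carries systematic placeholder labels so the pipeline runs without
any atlas geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

N_CORTICAL = 360
N_SUBCORTICAL = 15
N_FEATURES = 2 * N_CORTICAL + N_SUBCORTICAL  # 735

#: column-name prefixes for the three feature blocks
PREFIX_THICKNESS = "thk"
PREFIX_CORTICAL_VOLUME = "cvol"
PREFIX_SUBCORTICAL_VOLUME = "svol"

_SUBCORTICAL_STRUCTURES = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
)


def _default_cortical_labels() -> list[str]:
    left = [f"L_ROI_{i:03d}" for i in range(1, N_CORTICAL // 2 + 1)]
    right = [f"R_ROI_{i:03d}" for i in range(1, N_CORTICAL // 2 + 1)]
    return left + right


def _default_subcortical_labels() -> list[str]:
    labels = [f"Left-{s}" for s in _SUBCORTICAL_STRUCTURES]
    labels += [f"Right-{s}" for s in _SUBCORTICAL_STRUCTURES]
    labels.append("Brainstem")
    return labels


@dataclass(frozen=True)
class AtlasSchema:
    """Ordered label registry binding feature-matrix columns to brain regions.

    Parameters
    ----------
    cortical_labels
        360 patch identifiers, left-hemisphere block first. Labels must be
        hemisphere-prefixed ("L_" / "R_").
    subcortical_labels
        15 structure names: 7 bilateral pairs plus the brainstem.
    """

    cortical_labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(_default_cortical_labels())
    )
    subcortical_labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(_default_subcortical_labels())
    )

    def __post_init__(self) -> None:
        if len(self.cortical_labels) != N_CORTICAL:
            raise ValueError(
                f"expected {N_CORTICAL} cortical labels, "
                f"got {len(self.cortical_labels)}"
            )
        if len(self.subcortical_labels) != N_SUBCORTICAL:
            raise ValueError(
                f"expected {N_SUBCORTICAL} subcortical labels, "
                f"got {len(self.subcortical_labels)}"
            )
        all_labels = self.cortical_labels + self.subcortical_labels
        if len(set(all_labels)) != len(all_labels):
            raise ValueError("atlas labels must be unique")

    @property
    def n_features(self) -> int:
        return 2 * len(self.cortical_labels) + len(self.subcortical_labels)

    def hemisphere(self, cortical_index: int) -> str:
        """'L' or 'R' for a cortical patch index in [0, 360)."""
        return self.cortical_labels[cortical_index][0]

    @property
    def feature_names(self) -> list[str]:
        """All 735 prefixed column names in canonical block order."""
        return (
            [f"{PREFIX_THICKNESS}_{r}" for r in self.cortical_labels]
            + [f"{PREFIX_CORTICAL_VOLUME}_{r}" for r in self.cortical_labels]
            + [f"{PREFIX_SUBCORTICAL_VOLUME}_{s}" for s in self.subcortical_labels]
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "cortical_labels": list(self.cortical_labels),
                    "subcortical_labels": list(self.subcortical_labels),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "AtlasSchema":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            cortical_labels=tuple(d["cortical_labels"]),
            subcortical_labels=tuple(d["subcortical_labels"]),
        )


def default_atlas_schema() -> AtlasSchema:
    """The default 360 + 15 label registry with placeholder patch names.

    Deterministic: the left-hemisphere block (L_ROI_001..L_ROI_180) precedes
    the right; subcortical structures are ordered left pairs, right pairs,
    brainstem last.
    """
    return AtlasSchema()
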