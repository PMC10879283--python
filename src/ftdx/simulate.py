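"""Synthetic multi-site morphometry cohorts with known ground truth.

Emulates the statistical structure of a pooled two-consortium FTD sample:
per-subject demographics drawn from the reference demographics of the
modeled cohorts (age ~ N(63.7, 7.7) truncated to [40, 90], 54.5% male,
class sizes 173/63/41 for bvFTD/nfvPPA/svPPA, cohort split ~47/53%),
linear covariate effects (age slopes; TIV scaling of volume features
only), additive cohort- and scanner-level batch offsets (larger for
volume than for thickness features, in noise units), subtype-specific
atrophy planted as a negative shift on a fixed set of patches, and
i.i.d. Gaussian measurement noise.

The generator returns both the feature table and a
:class:`SyntheticGroundTruth` so that downstream recovery tests (batch
removal, classification, attribution, statistical mapping) can be scored
against the planted truth.

Not emulated: spatial correlation between neighboring patches, scanner
upgrade drift, longitudinal structure, non-Gaussian measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import N_CORTICAL, AtlasSchema, default_atlas_schema
from .tables import DIAGNOSES, FeatureTable

FEATURE_TYPES = ("thickness", "cortical_volume", "subcortical_volume")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def feature_type_of(index: int) -> str:
    """Feature type of a flat feature index in [0, 735)."""
    if index < N_CORTICAL:
        return "thickness"
    if index < 2 * N_CORTICAL:
        return "cortical_volume"
    return "subcortical_volume"


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Feature-type keyed dicts use the keys ``thickness``,
    ``cortical_volume``, ``subcortical_volume``. Units: thickness mm,
    volumes mm^3, age/education years, TIV mm^3. ``atrophy_effect_size``
    is a Cohen's d against the feature type's ``noise_sd``.
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"bvFTD": 173, "nfvPPA": 63, "svPPA": 41}
    )
    n_cohorts: int = 2
    cohort_probs: tuple[float, ...] = (0.473, 0.527)
    n_scanners_per_cohort: int = 3
    age_mean: float = 63.7
    age_sd: float = 7.7
    age_range: tuple[float, float] = (40.0, 90.0)
    male_fraction: float = 0.545
    education_mean: float = 16.0
    education_sd: float = 3.0
    education_min: float = 8.0
    tiv_mean: float = 1.45e6
    tiv_sd: float = 1.3e5
    # per-feature-type generative parameters
    baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": 2.5,
            "cortical_volume": 3000.0,
            "subcortical_volume": 4000.0,
        }
    )
    baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": 0.25,
            "cortical_volume": 600.0,
            "subcortical_volume": 800.0,
        }
    )
    age_slope: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": -0.005,
            "cortical_volume": -10.0,
            "subcortical_volume": -5.0,
        }
    )
    sex_offset: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": 0.0,
            "cortical_volume": 50.0,
            "subcortical_volume": 30.0,
        }
    )
    tiv_slope: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": 0.0,
            "cortical_volume": 0.002,
            "subcortical_volume": 0.002,
        }
    )
    # cohort offsets ~ N(0, batch_effect_sd) per feature; scanner offsets at
    # scanner_effect_scale of that. Relative to noise_sd the volume batch
    # effect (1.0x noise) is 3x the thickness batch effect (0.33x noise),
    # reproducing the volume-dominant cohort bias of multi-site data.
    batch_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": 0.05,
            "cortical_volume": 300.0,
            "subcortical_volume": 200.0,
        }
    )
    scanner_effect_scale: float = 0.5
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "thickness": 0.15,
            "cortical_volume": 300.0,
            "subcortical_volume": 200.0,
        }
    )
    atrophy_effect_size: float = 2.0
    topography: Mapping[str, tuple[int, ...]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_per_class) != set(DIAGNOSES):
            raise ConfigError(f"n_per_class must have keys {DIAGNOSES}")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ConfigError("all class counts must be >= 1")
        if self.n_cohorts < 1 or self.n_scanners_per_cohort < 1:
            raise ConfigError("cohort/scanner counts must be >= 1")
        if len(self.cohort_probs) != self.n_cohorts:
            raise ConfigError("cohort_probs length must equal n_cohorts")
        if not np.isclose(sum(self.cohort_probs), 1.0):
            raise ConfigError("cohort_probs must sum to 1")
        for t in FEATURE_TYPES:
            if self.noise_sd[t] <= 0:
                raise ConfigError(f"noise_sd[{t!r}] must be > 0")
            if self.batch_effect_sd[t] < 0:
                raise ConfigError(f"batch_effect_sd[{t!r}] must be >= 0")
        if self.atrophy_effect_size < 0:
            raise ConfigError("atrophy_effect_size must be >= 0")


@dataclass
class SyntheticGroundTruth:
    """Planted structure of one simulated cohort.

    ``planted_patches`` maps subtype -> list of (feature index, signed
    Cohen's d); the applied shift is ``d * noise_sd[type]`` with the sign
    as stored (negative = atrophy). Offsets are additive constants per
    feature: ``cohort_offsets[c, f]`` and ``scanner_offsets[c, s, f]``.
    """

    planted_patches: dict[str, list[tuple[int, float]]]
    cohort_offsets: np.ndarray
    scanner_offsets: np.ndarray
    covariate_coefficients: dict[str, dict[str, float]]
    baselines: np.ndarray

    def planted_indices(self, subtype: str) -> np.ndarray:
        return np.array([i for i, _ in self.planted_patches[subtype]], dtype=int)

    def planted_cortical_patches(self, subtype: str) -> np.ndarray:
        """Cortical patch ids (0..359) planted in the thickness block."""
        idx = self.planted_indices(subtype)
        return idx[idx < N_CORTICAL]

    def nonnull_contrast_indices(
        self, subtype: str, n_per_class: Mapping[str, int], n_features: int = 735
    ) -> np.ndarray:
        """Features with a true one-vs-rest mean difference for ``subtype``.

        A patch planted in another subtype also shifts the pooled "rest"
        mean, so the true contrast is the subtype's shift minus the
        sample-size-weighted mean shift of the other classes; features
        where that difference is nonzero are genuine signal for the
        contrast (everything else is a true null for FDR accounting).
        """
        shifts = {dx: np.zeros(n_features) for dx in self.planted_patches}
        for dx, entries in self.planted_patches.items():
            for i, d in entries:
                shifts[dx][i] = d
        others = [dx for dx in shifts if dx != subtype]
        n_rest = sum(n_per_class[dx] for dx in others)
        rest = sum(n_per_class[dx] * shifts[dx] for dx in others) / n_rest
        return np.nonzero(np.abs(shifts[subtype] - rest) > 1e-12)[0]


def default_atrophy_topography(
    schema: AtlasSchema | None = None,
) -> dict[str, tuple[int, ...]]:
    """Subtype -> planted feature indices for the canonical atrophy patterns.

    Encodes the qualitative topography of the three syndromes on the
    placeholder parcellation: bvFTD gets bilateral frontal/insular
    patches, nfvPPA a strongly left-lateralized inferior-frontal/insular
    set, svPPA a left-dominant anterior-temporal set plus left medial
    temporal subcortical structures. Each subtype's cortical patches are
    planted in both the thickness and the cortical-volume block; subtype
    pairs share a few patches to mimic overlapping early atrophy.
    Left-hemisphere patches are indices 0..179, right 180..359.
    """
    # cortical patch ids per subtype (20 each, partially overlapping)
    bvftd = list(range(0, 12)) + list(range(180, 188))           # 12 L + 8 R
    nfvppa = list(range(8, 12)) + list(range(20, 34)) + [200, 201]  # shares 8-11
    svppa = [10, 11] + list(range(40, 54)) + list(range(220, 224))  # shares 10-11
    topo: dict[str, tuple[int, ...]] = {}
    for name, patches in (("bvFTD", bvftd), ("nfvPPA", nfvppa), ("svPPA", svppa)):
        feats = [p for p in patches] + [N_CORTICAL + p for p in patches]
        topo[name] = tuple(feats)
    # svPPA: left hippocampus (724) and amygdala (725) volumes
    topo["svPPA"] = topo["svPPA"] + (2 * N_CORTICAL + 4, 2 * N_CORTICAL + 5)
    return topo


def complementary_atrophy_topography(
    schema: AtlasSchema | None = None,
) -> dict[str, tuple[int, ...]]:
    """Topography in which the two feature types carry complementary signal.

    bvFTD separates from the rest only through thickness patches, nfvPPA
    only through cortical-volume patches, and svPPA through half of each
    — so neither single feature type suffices for three-way diagnosis and
    fusion of the two types is required.
    """
    bvftd = tuple(range(0, 20))                                  # thickness only
    nfvppa = tuple(N_CORTICAL + p for p in range(40, 60))        # volume only
    svppa = tuple(range(80, 90)) + tuple(N_CORTICAL + p for p in range(100, 110))
    return {"bvFTD": bvftd, "nfvPPA": nfvppa, "svPPA": svppa}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    config: SimulationConfig | None = None,
    schema: AtlasSchema | None = None,
) -> tuple[FeatureTable, SyntheticGroundTruth]:
    """Simulate one multi-site cohort.

    Each feature value is::

        baseline_f + (age - age_mean) * beta_age
                   + male * beta_sex
                   + (tiv - tiv_mean) * beta_tiv      (volume features)
                   + cohort_offset_f + scanner_offset_f
                   - d * noise_sd                     (planted patches)
                   + N(0, noise_sd)

    Age and TIV enter centered so baselines are the expected value at
    reference demographics. Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    config.validate()
    schema = schema or default_atlas_schema()
    rng = np.random.default_rng(config.seed)
    p = schema.n_features
    ftype = np.array([feature_type_of(i) for i in range(p)])

    # --- per-feature structural parameters (drawn once per simulation)
    baselines = np.empty(p)
    noise = np.empty(p)
    b_age = np.empty(p)
    b_sex = np.empty(p)
    b_tiv = np.empty(p)
    batch_sd = np.empty(p)
    for t in FEATURE_TYPES:
        m = ftype == t
        lo = 1.5 if t == "thickness" else 500.0
        baselines[m] = _truncated_normal(
            rng, config.baseline_mean[t], config.baseline_sd[t], lo, np.inf, m.sum()
        )
        noise[m] = config.noise_sd[t]
        b_age[m] = config.age_slope[t]
        b_sex[m] = config.sex_offset[t]
        b_tiv[m] = config.tiv_slope[t]
        batch_sd[m] = config.batch_effect_sd[t]

    cohort_offsets = rng.normal(0.0, 1.0, (config.n_cohorts, p)) * batch_sd
    scanner_offsets = (
        rng.normal(0.0, 1.0, (config.n_cohorts, config.n_scanners_per_cohort, p))
        * batch_sd
        * config.scanner_effect_scale
    )

    topo = config.topography if config.topography is not None else (
        default_atrophy_topography(schema)
    )
    planted = {
        dx: [(int(i), -config.atrophy_effect_size) for i in topo.get(dx, ())]
        for dx in DIAGNOSES
    }

    # --- subjects
    rows = []
    feats = []
    sid = 0
    for dx in DIAGNOSES:
        n = config.n_per_class[dx]
        age = _truncated_normal(
            rng, config.age_mean, config.age_sd, *config.age_range, n
        )
        male = rng.random(n) < config.male_fraction
        edu = _truncated_normal(
            rng, config.education_mean, config.education_sd,
            config.education_min, np.inf, n,
        )
        tiv = _truncated_normal(
            rng, config.tiv_mean, config.tiv_sd, 1e5, np.inf, n
        )
        cohort = rng.choice(config.n_cohorts, size=n, p=list(config.cohort_probs))
        scanner = rng.integers(0, config.n_scanners_per_cohort, size=n)

        shift = np.zeros(p)
        for i, d in planted[dx]:
            shift[i] = d * noise[i]

        x = (
            baselines[None, :]
            + (age[:, None] - config.age_mean) * b_age[None, :]
            + male[:, None] * b_sex[None, :]
            + (tiv[:, None] - config.tiv_mean) * b_tiv[None, :]
            + cohort_offsets[cohort]
            + scanner_offsets[cohort, scanner]
            + shift[None, :]
            + rng.normal(0.0, 1.0, (n, p)) * noise[None, :]
        )
        feats.append(x)
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"SYN{sid:05d}",
                    "diagnosis": dx,
                    "age": age[k],
                    "sex": "M" if male[k] else "F",
                    "education": edu[k],
                    "tiv": tiv[k],
                    "cohort": f"COHORT{cohort[k]}",
                    "scanner_id": f"COHORT{cohort[k]}_SC{scanner[k]}",
                }
            )
            sid += 1

    table = FeatureTable(
        metadata=pd.DataFrame(rows),
        features=pd.DataFrame(np.vstack(feats), columns=schema.feature_names),
        schema=schema,
    )
    truth = SyntheticGroundTruth(
        planted_patches=planted,
        cohort_offsets=cohort_offsets,
        scanner_offsets=scanner_offsets,
        covariate_coefficients={
            t: {
                "age": config.age_slope[t],
                "sex": config.sex_offset[t],
                "tiv": config.tiv_slope[t],
            }
            for t in FEATURE_TYPES
        },
        baselines=baselines,
    )
    return table, truth


def scaled_config(base: SimulationConfig, factor: float) -> SimulationConfig:
    """Config with class counts scaled by `factor` (min 1 per class)."""
    return replace(
        base,
        n_per_class={k: max(1, round(v * factor)) for k, v in base.n_per_class.items()},
    )
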