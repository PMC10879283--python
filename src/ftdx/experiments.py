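"""Canned validation experiments on synthetic cohorts.

Each function generates its own data, runs the corresponding pipeline
stage end to end, and returns summary numbers. They define the fixed
study conditions under which the package's behavior is verified (batch
removal, leakage safety, classification recovery, architecture
comparison, attribution recovery, statistical-map recovery) and are
shared by the test suite and the reproduction script so both measure
the same thing.

Problem sizes are chosen to finish on a single CPU core in minutes; the
methods note records each experiment's scale.
"""

from __future__ import annotations

import numpy as np

from .attribution import population_importance_map
from .crossval import fit_outer_fold, make_nested_splits, run_ablation, run_nested_cv
from .harmonize import WScoreHarmonizer, cohort_coefficients
from .pipeline import audit_leakage
from .simulate import (
    SimulationConfig,
    complementary_atrophy_topography,
    generate_cohort,
)
from .statmap import patchwise_group_contrast, planted_recovery
from .tables import DIAGNOSES, FeatureTable


def _seed(base: int, offset: int) -> int:
    return (base * 9973 + offset) % (2**31)


def permute_diagnoses(table: FeatureTable, seed: int) -> FeatureTable:
    """Label-permuted negative control (breaks all feature-label links)."""
    rng = np.random.default_rng(seed)
    out = table.subset(np.arange(table.n_subjects))
    out.metadata["diagnosis"] = rng.permutation(
        out.metadata["diagnosis"].to_numpy()
    )
    return out


# ---------------------------------------------------------------------
def harmonization_check(seed: int = 0, n_total: int = 500) -> dict:
    """Batch-effect removal at n=500 (class proportions preserved).

    Fits the w-score harmonizer on the cohort and reports (a) the exact
    standardization of reference-group training w-scores (per-feature
    mean and SD), (b) the fraction of features whose cohort coefficient
    on the reference training rows is below 0.05 in absolute value
    (OLS orthogonality makes these exactly zero), and (c) how much the
    cohort effect on volume features shrinks over *all* subjects, on a
    standardized scale, relative to the raw data.
    """
    frac = n_total / 277
    config = SimulationConfig(
        n_per_class={
            "bvFTD": round(173 * frac),
            "nfvPPA": round(63 * frac),
            "svPPA": round(41 * frac),
        },
        seed=_seed(seed, 1),
    )
    table, _ = generate_cohort(config)
    model = WScoreHarmonizer().fit(table)
    w = model.transform(table)

    ref_idx = np.nonzero(table.diagnosis == "bvFTD")[0]
    ref_w = w.X[ref_idx]
    ref_mean_abs = float(np.abs(ref_w.mean(axis=0)).max())
    ref_sd = ref_w.std(axis=0, ddof=1)

    ref_coef = cohort_coefficients(w.subset(ref_idx))
    frac_small = float((np.abs(ref_coef).max(axis=0) < 0.05).mean())

    vol = slice(360, 735)
    raw_coef = cohort_coefficients(table)[:, vol]
    raw_sd = table.X[:, vol].std(axis=0, ddof=1)
    raw_std_effect = float(np.median(np.abs(raw_coef) / raw_sd))
    post_effect = float(
        np.median(np.abs(cohort_coefficients(w)[:, vol]))
    )
    return {
        "n": table.n_subjects,
        "reference_mean_abs_max": ref_mean_abs,
        "reference_sd_min": float(ref_sd.min()),
        "reference_sd_max": float(ref_sd.max()),
        "fraction_cohort_coef_below_0.05": frac_small,
        "raw_volume_cohort_effect_standardized": raw_std_effect,
        "post_volume_cohort_effect": post_effect,
        "shrink_factor": raw_std_effect / max(post_effect, 1e-12),
    }


# ---------------------------------------------------------------------
def leakage_check(seed: int = 0, max_epochs: int = 4) -> dict:
    """Leakage audit on a reduced cohort, plus its negative control."""
    config = SimulationConfig(
        n_per_class={"bvFTD": 44, "nfvPPA": 16, "svPPA": 12},
        seed=_seed(seed, 2),
    )
    table, _ = generate_cohort(config)
    honest = audit_leakage(table, seed=seed, k=4, max_epochs=max_epochs)
    leaky = audit_leakage(
        table, seed=seed, k=4, max_epochs=max_epochs,
        leaky_harmonization=True,
    )
    return {
        "n": table.n_subjects,
        "audit_passed": honest["passed"],
        "negative_control_failed": not leaky["passed"],
    }


# ---------------------------------------------------------------------
def classification_recovery(
    seed: int = 0, max_epochs: int = 200, permuted_epochs: int = 100
) -> dict:
    """Nested-CV recovery at the full study conditions (173/63/41, d=2)
    plus the label-permuted chance-level control."""
    table, _ = generate_cohort(SimulationConfig(seed=_seed(seed, 3)))
    result = run_nested_cv(
        table, seed=seed, k=10, max_epochs=max_epochs, patience=30
    )
    permuted = permute_diagnoses(table, _seed(seed, 4))
    null = run_nested_cv(
        permuted, seed=seed, k=10, max_epochs=permuted_epochs, patience=30
    )
    return {
        "n": table.n_subjects,
        "overall_balanced_accuracy": result.report["overall_balanced_accuracy"],
        "per_class": result.report["per_class_balanced_accuracy"],
        "permuted_overall_balanced_accuracy": null.report[
            "overall_balanced_accuracy"
        ],
        "per_fold": result.per_fold_overall_ba,
    }


# ---------------------------------------------------------------------
#: conditions of the architecture comparison: the study's cohort
#: composition and optimizer regime, complementary-signal topography at
#: a moderate effect size so neither model sits at floor or ceiling
ABLATION_CONDITIONS = dict(
    n_per_class={"bvFTD": 173, "nfvPPA": 63, "svPPA": 41},
    atrophy_effect_size=1.5,
    k=3,
    max_epochs=120,
    batch_size=32,
)


def ablation_comparison(seeds=range(10), conditions: dict | None = None) -> dict:
    """Parallel fusion vs naive concatenation on complementary signal.

    For each seed, a fresh cohort in which thickness and volume carry
    complementary class information; both architectures share identical
    splits and training budget. Reports per-seed overall balanced
    accuracies and how often fusion >= concatenation.
    """
    cond = dict(ABLATION_CONDITIONS)
    if conditions:
        cond.update(conditions)
    topo = complementary_atrophy_topography()
    pairs = []
    for s in seeds:
        cfg = SimulationConfig(
            n_per_class=cond["n_per_class"],
            atrophy_effect_size=cond["atrophy_effect_size"],
            topography=topo,
            seed=_seed(s, 5),
        )
        table, _ = generate_cohort(cfg)
        res = run_ablation(
            table, seed=s, k=cond["k"],
            experiments=("concat", "parallel"),
            max_epochs=cond["max_epochs"], patience=30,
            batch_size=cond["batch_size"],
        )
        pairs.append(
            (
                res["concat"].report["overall_balanced_accuracy"],
                res["parallel"].report["overall_balanced_accuracy"],
            )
        )
    wins = sum(1 for c, p in pairs if p >= c)
    return {
        "n": len(pairs),
        "pairs": pairs,
        "parallel_wins": wins,
        "mean_concat": float(np.mean([c for c, _ in pairs])),
        "mean_parallel": float(np.mean([p for _, p in pairs])),
    }


# ---------------------------------------------------------------------
def ig_recovery(
    seeds=range(5),
    n_per_class: int = 150,
    max_epochs: int = 150,
    steps: int = 64,
    top_k: int = 20,
) -> dict:
    """Attribution recovery: do the top-|IG| thickness patches of each
    subtype coincide with its planted atrophy patches?

    Trains one outer fold's nine-member ensemble per seed at d=2 and
    scores the top-``top_k`` thickness patches of the population map
    against the planted truth.
    """
    overlaps = []
    for s in seeds:
        cfg = SimulationConfig(
            n_per_class={dx: n_per_class for dx in DIAGNOSES},
            seed=_seed(s, 6),
        )
        table, truth = generate_cohort(cfg)
        splits = make_nested_splits(table.diagnosis, k=10, seed=s)
        ensemble, _ = fit_outer_fold(
            table, splits.folds[0], 0, s, max_epochs=max_epochs, patience=30
        )
        wtable = ensemble.harmonizer.transform(table)
        for dx in DIAGNOSES:
            m = population_importance_map(ensemble, wtable, dx, steps=steps)
            top = np.argsort(np.abs(m["thickness"]))[::-1][:top_k]
            planted = set(truth.planted_cortical_patches(dx).tolist())
            overlaps.append(len(planted & set(top.tolist())) / top_k)
    return {
        "n": len(overlaps),
        "overlaps": overlaps,
        "mean_top20_overlap": float(np.mean(overlaps)),
    }


# ---------------------------------------------------------------------
def statmap_recovery(
    seed: int = 0, n_sims: int = 20, n_per_class: int = 150
) -> dict:
    """Mass-univariate recovery over repeated simulations at d=2.

    Per simulation and subtype: sensitivity of BH-significant thickness
    patches against planted truth, and false-discovery proportion
    against true-null features; plus the raw type-I rate under permuted
    labels.
    """
    sens, fdp, null_rates = [], [], []
    counts = {dx: n_per_class for dx in DIAGNOSES}
    for i in range(n_sims):
        cfg = SimulationConfig(n_per_class=counts, seed=_seed(seed, 100 + i))
        table, truth = generate_cohort(cfg)
        w = WScoreHarmonizer().fit(table).transform(table)
        for dx in DIAGNOSES:
            res = patchwise_group_contrast(w, dx)
            rec = planted_recovery(
                res,
                truth.planted_indices(dx),
                "thickness",
                truth.nonnull_contrast_indices(dx, counts),
            )
            sens.append(rec["sensitivity"])
            fdp.append(rec["false_discovery_proportion"])
        if i < 5:
            null = permute_diagnoses(w, _seed(seed, 200 + i))
            res0 = patchwise_group_contrast(null, "svPPA")
            null_rates.append(float((res0.p_value < 0.05).mean()))
    return {
        "n": n_sims,
        "mean_sensitivity": float(np.mean(sens)),
        "empirical_fdr": float(np.mean(fdp)),
        "null_raw_rejection_rate": float(np.mean(null_rates)),
    }
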