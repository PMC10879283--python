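"""Integrated-Gradient feature attribution for the subtype classifier.

For a class score :math:`F_c` (the pre-softmax logit by default), input
``x`` and baseline ``x'``, the attribution of feature ``i`` is

.. math::

    IG_i(x) = (x_i - x'_i) \\int_0^1
        \\frac{\\partial F_c(x' + \\alpha (x - x'))}{\\partial x_i}
        \\, d\\alpha

approximated with a midpoint Riemann sum. Population maps default to a
grand-mean w-score baseline (the cohort's "average patient"), so
attributions read as the contribution of each regional deviation from
the average presentation to the subtype call; an all-zero w-score
baseline (the harmonization reference norm) is available but is itself
the reference-class prototype and mutes attributions toward that class.
Completeness holds in the limit: the attributions sum to
:math:`F_c(x) - F_c(x')`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import N_CORTICAL, AtlasSchema
from .crossval import TrainedEnsemble, N_INNER
from .tables import DIAGNOSES, FeatureTable

DEFAULT_STEPS = 128


def integrated_gradients(
    grad_fn,
    x: np.ndarray,
    baseline: np.ndarray,
    steps: int = DEFAULT_STEPS,
) -> np.ndarray:
    """Midpoint-rule Integrated Gradients along the straight path.

    Parameters
    ----------
    grad_fn : callable
        Maps a (m, d) batch of inputs to the (m, d) gradients of the
        target class score with respect to the inputs.
    x, baseline : ndarray of shape (d,)
        Input and reference point.
    steps : int
        Number of midpoint evaluations (>= 1).
    """
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if x.shape != baseline.shape:
        raise ValueError("input and baseline must have the same shape")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    alphas = (np.arange(steps) + 0.5) / steps
    path = baseline[None, :] + alphas[:, None] * (x - baseline)[None, :]
    grads = grad_fn(path)
    if not np.isfinite(grads).all():
        raise FloatingPointError("non-finite gradients along the IG path")
    return (x - baseline) * grads.mean(axis=0)


def _logit_grad_fn(net, target_class: int):
    return lambda batch: net.input_gradients(batch, target_class)


def subject_attributions(
    ensemble: TrainedEnsemble,
    X: np.ndarray,
    target_class: int,
    baseline: np.ndarray | None = None,
    steps: int = DEFAULT_STEPS,
) -> np.ndarray:
    """Per-subject IG toward ``target_class``, averaged over the 9 members.

    ``X``: (n, 735) w-score rows. Returns (n, 735) signed attributions.
    """
    n, d = X.shape
    if baseline is None:
        baseline = np.zeros(d)
    diff = X - baseline[None, :]
    alphas = (np.arange(steps) + 0.5) / steps
    out = np.zeros_like(X, dtype=float)
    # batch subjects x steps through one forward/backward per member
    chunk = max(1, int(2**22 // (steps * d)) or 1)
    for member in ensemble.members:
        net = member.net_
        for s in range(0, n, chunk):
            block = slice(s, min(s + chunk, n))
            m = block.stop - block.start
            paths = (
                baseline[None, None, :]
                + alphas[None, :, None] * diff[block, None, :]
            ).reshape(m * steps, d)
            grads = net.input_gradients(paths, target_class)
            out[block] += diff[block] * grads.reshape(m, steps, d).mean(axis=1)
    return out / N_INNER


def population_importance_map(
    ensemble: TrainedEnsemble,
    table: FeatureTable,
    subtype: str,
    steps: int = DEFAULT_STEPS,
    baseline: np.ndarray | None = None,
    correct_only: bool = False,
) -> dict[str, np.ndarray]:
    """Population-mean IG importance map of one subtype.

    Averages attributions toward the subtype's own logit over all
    subjects of that diagnosis (optionally only correctly classified
    ones) and over the nine ensemble members. ``table`` must hold
    w-scores produced by the ensemble's harmonizer.

    The default baseline is the grand-mean w-score vector over the
    table (an "average patient"). The all-zero w-score vector is *not*
    a neutral point here: it is exactly the covariate-adjusted profile
    of the harmonization reference group, and taking a class prototype
    as the IG baseline suppresses attributions toward that class.

    Returns dict with the full 735-vector plus the thickness /
    cortical-volume / subcortical-volume block views.
    """
    if not table.harmonized:
        raise ValueError("population_importance_map expects a harmonized table")
    target = DIAGNOSES.index(subtype)
    mask = table.diagnosis == subtype
    if not mask.any():
        raise ValueError(f"no subjects with diagnosis {subtype!r}")
    if baseline is None:
        baseline = table.X.mean(axis=0)
    X = table.X[mask]
    if correct_only:
        from .crossval import ensemble_predict

        _, pred = ensemble_predict(ensemble, X)
        X = X[pred == subtype]
        if len(X) == 0:
            raise ValueError(f"no correctly classified {subtype!r} subjects")
    attr = subject_attributions(ensemble, X, target, baseline, steps).mean(axis=0)
    return {
        "all": attr,
        "thickness": attr[:N_CORTICAL],
        "cortical_volume": attr[N_CORTICAL : 2 * N_CORTICAL],
        "subcortical_volume": attr[2 * N_CORTICAL :],
        "subtype": subtype,
        "steps": steps,
        "n_subjects": int(len(X)),
    }


def completeness_residual(
    net, x: np.ndarray, baseline: np.ndarray, target_class: int, steps: int
) -> float:
    """|sum(IG) - (F_c(x) - F_c(baseline))| for one subject and member."""
    attr = integrated_gradients(
        _logit_grad_fn(net, target_class), x, baseline, steps
    )
    fx = net.predict_logits(x[None, :])[0, target_class]
    fb = net.predict_logits(baseline[None, :])[0, target_class]
    return float(abs(attr.sum() - (fx - fb)))


#: display range used for flat-heatmap rendering of importance maps
DEFAULT_COLOR_RANGE = 0.06


def export_importance_tables(
    maps: dict[str, dict], schema: AtlasSchema, path
) -> pd.DataFrame:
    """Write per-patch mean attributions as a CSV keyed by atlas labels.

    ``maps``: subtype -> output of :func:`population_importance_map`.
    One row per atlas label per feature type (360 + 360 + 15 rows per
    subtype column), suitable for external cortical-surface rendering.
    """
    rows = []
    for c, label in enumerate(schema.cortical_labels):
        rows.append({"feature_type": "thickness", "label": label, "index": c})
    for c, label in enumerate(schema.cortical_labels):
        rows.append(
            {"feature_type": "cortical_volume", "label": label,
             "index": N_CORTICAL + c}
        )
    for s, label in enumerate(schema.subcortical_labels):
        rows.append(
            {"feature_type": "subcortical_volume", "label": label,
             "index": 2 * N_CORTICAL + s}
        )
    df = pd.DataFrame(rows)
    for subtype, m in maps.items():
        df[f"attribution_{subtype}"] = m["all"][df["index"].to_numpy()]
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def plot_importance_heatmap(maps: dict[str, dict], path, vmax: float | None = None):
    """Flat subtype x feature heatmap of mean attributions (diagnostic).

    Color scale is symmetric; defaults to the max |attribution| across
    maps. Not a cortical-surface rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = np.vstack([m["all"] for m in maps.values()])
    vmax = vmax or float(np.abs(M).max())
    fig, ax = plt.subplots(figsize=(10, 2.5))
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(maps)), list(maps.keys()))
    ax.set_xlabel("feature index (thickness | cortical vol | subcortical vol)")
    fig.colorbar(im, ax=ax, label="mean IG attribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
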