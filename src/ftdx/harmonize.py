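"""GLM-based w-score feature harmonization.

Each feature is regressed on demographic and acquisition covariates
using only the *reference diagnostic group* (default bvFTD, the largest
class), and every subject's value is re-expressed as the standardized
residual of that fit::

    w_if = (x_if - design_i . beta_f) / sigma_f

where ``sigma_f`` is the reference-group residual standard deviation
(denominator ``n_ref - p``). The w-score is a covariate-adjusted
deviation from the reference norm, in reference-SD units; it removes
additive cohort/scanner batch effects and covariate trends while
preserving disease contrast between groups.

Strict fit/transform separation: the model is fit on training rows of a
cross-validation fold only and applied unchanged to held-out rows, so no
information leaks from test subjects into the harmonization.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import FeatureTable

DEFAULT_COVARIATES = ("age", "sex", "tiv", "site")
_CONTINUOUS = {"age", "tiv", "education"}


class DegenerateFeatureError(ValueError):
    """A feature has zero residual variance in the reference group."""


class SampleSizeError(ValueError):
    """Too few reference-group subjects for the requested design."""


def _site_levels(metadata) -> np.ndarray:
    """Combined cohort x scanner factor (scanner nested within cohort)."""
    return (
        metadata["cohort"].astype(str) + "|" + metadata["scanner_id"].astype(str)
    ).to_numpy()


class WScoreHarmonizer(TransformerMixin, BaseEstimator):
    """Per-feature reference-group GLM harmonizer (w-score transform).

    Parameters
    ----------
    reference_group : str
        Diagnosis label whose subjects define the normative fit.
    covariates : tuple of str
        Ordered covariate names. Continuous: ``age``, ``tiv``,
        ``education``. Categorical (dummy-coded against the
        lexicographically smallest training level): ``sex``, ``cohort``,
        ``site`` (= combined cohort x scanner factor).

    Attributes
    ----------
    coef_ : ndarray of shape (p_design, n_features)
        OLS coefficients per feature.
    sigma_ : ndarray of shape (n_features,)
        Reference-group residual SD per feature (dof = n_ref - p).
    design_columns_ : list of str
        Names of the design-matrix columns, intercept first.
    levels_ : dict
        Training category levels per categorical covariate (reference
        level first).
    """

    def __init__(
        self,
        reference_group: str = "bvFTD",
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ):
        self.reference_group = reference_group
        self.covariates = covariates

    # ---- design matrix ----------------------------------------------
    def _raw_column(self, metadata, name) -> np.ndarray:
        if name == "site":
            return _site_levels(metadata)
        if name not in metadata.columns and name == "scanner":
            return metadata["scanner_id"].astype(str).to_numpy()
        return metadata[name].to_numpy()

    def _build_design(self, metadata, fit: bool) -> np.ndarray:
        n = len(metadata)
        cols = [np.ones(n)]
        names = ["intercept"]
        if fit:
            self.levels_ = {}
        for cov in self.covariates:
            raw = self._raw_column(metadata, cov)
            if cov in _CONTINUOUS:
                cols.append(np.asarray(raw, dtype=float))
                names.append(cov)
                continue
            raw = np.asarray(raw, dtype=str)
            if fit:
                self.levels_[cov] = sorted(set(raw))
            levels = self.levels_[cov]
            known = np.isin(raw, levels)
            if not known.all():
                unseen = sorted(set(raw[~known]))
                warnings.warn(
                    f"unseen {cov} level(s) {unseen} mapped to reference "
                    f"level {levels[0]!r}",
                    stacklevel=3,
                )
                raw = raw.copy()
                raw[~known] = levels[0]
            for lev in levels[1:]:  # first level is the reference
                cols.append((raw == lev).astype(float))
                names.append(f"{cov}[{lev}]")
        if fit:
            self.design_columns_ = names
        return np.column_stack(cols)

    # ---- estimator API ----------------------------------------------
    def fit(self, table: FeatureTable, y=None) -> "WScoreHarmonizer":
        """Fit per-feature OLS on reference-group rows of ``table``."""
        ref_mask = table.diagnosis == self.reference_group
        if ref_mask.sum() == 0:
            raise SampleSizeError(
                f"no subjects with reference diagnosis {self.reference_group!r}"
            )
        ref_meta = table.metadata.loc[ref_mask].reset_index(drop=True)
        D = self._build_design(ref_meta, fit=True)
        n_ref, p = D.shape
        if n_ref < p + 2:
            raise SampleSizeError(
                f"need >= {p + 2} reference subjects for a {p}-column design, "
                f"got {n_ref}"
            )
        rank = np.linalg.matrix_rank(D)
        if rank < p:
            # name the columns whose removal restores full rank
            bad = []
            for j in range(1, p):
                keep = [k for k in range(p) if k != j and k not in bad]
                if np.linalg.matrix_rank(D[:, keep]) == rank:
                    bad.append(j)
            raise ValueError(
                "rank-deficient harmonization design; collinear columns: "
                f"{[self.design_columns_[j] for j in bad]}"
            )
        Y = table.X[ref_mask]
        beta, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
        resid = Y - D @ beta
        ssr = (resid**2).sum(axis=0)
        sigma = np.sqrt(ssr / (n_ref - p))
        if (sigma <= 0).any() or (~np.isfinite(sigma)).any():
            bad_feats = [
                table.schema.feature_names[i]
                for i in np.nonzero(~(sigma > 0))[0][:5]
            ]
            raise DegenerateFeatureError(
                f"zero reference residual variance for feature(s) {bad_feats}"
            )
        self.coef_ = beta
        self.sigma_ = sigma
        self.n_reference_ = int(n_ref)
        self.feature_names_ = list(table.schema.feature_names)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        """Map every subject (all diagnoses) to w-scores."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("harmonizer is not fitted")
        D = self._build_design(table.metadata, fit=False)
        W = (table.X - D @ self.coef_) / self.sigma_[None, :]
        return table.with_features(W, harmonized=True)

    # ---- serialization ----------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "reference_group": self.reference_group,
            "covariates": list(self.covariates),
            "design_columns": self.design_columns_,
            "levels": self.levels_,
            "coef": self.coef_.tolist(),
            "sigma": self.sigma_.tolist(),
            "n_reference": self.n_reference_,
            "feature_names": self.feature_names_,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "WScoreHarmonizer":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        est = cls(
            reference_group=d["reference_group"],
            covariates=tuple(d["covariates"]),
        )
        est.design_columns_ = d["design_columns"]
        est.levels_ = d["levels"]
        est.coef_ = np.asarray(d["coef"], dtype=float)
        est.sigma_ = np.asarray(d["sigma"], dtype=float)
        est.n_reference_ = d["n_reference"]
        est.feature_names_ = d["feature_names"]
        return est


def fit_harmonization(
    train_table: FeatureTable,
    reference_group: str = "bvFTD",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> WScoreHarmonizer:
    """Functional wrapper: fit a :class:`WScoreHarmonizer` on a table."""
    return WScoreHarmonizer(reference_group, covariates).fit(train_table)


def transform_to_wscores(
    model: WScoreHarmonizer, table: FeatureTable
) -> FeatureTable:
    """Functional wrapper over :meth:`WScoreHarmonizer.transform`."""
    return model.transform(table)


def cohort_coefficients(table: FeatureTable) -> np.ndarray:
    """Per-feature OLS coefficient of features on a cohort indicator.

    Diagnostic mirroring the before/after batch-bias panorama: regress
    each feature on intercept + dummy-coded cohort and return the
    coefficient matrix of shape (n_cohort_levels - 1, n_features). On
    w-scores these should be near zero.
    """
    cohorts = table.metadata["cohort"].astype(str).to_numpy()
    levels = sorted(set(cohorts))
    D = np.column_stack(
        [np.ones(table.n_subjects)] + [(cohorts == l).astype(float) for l in levels[1:]]
    )
    beta, _, _, _ = np.linalg.lstsq(D, table.X, rcond=None)
    return beta[1:, :]
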