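"""Training-time confounder adjustment by multiple linear regression.

Each ECG feature is regressed on LV mass index, age and sex (coded 0/1) by
ordinary least squares.  During training the feature is replaced by its
residual re-centered at the training mean, so the adjusted value stays on the
feature's physical scale while carrying no linear confounder signal.  At
inference the adjustment is an exact identity: predictions are made on raw
feature values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COVARIATES = ("lvmi", "age", "sex")


@dataclass(frozen=True)
class AdjustmentModel:
    """Per-feature OLS coefficients against (1, lvmi, age, sex)."""

    feature_names: tuple[str, ...]
    coef: np.ndarray          # (n_features, 4): intercept, b_lvmi, b_age, b_sex
    train_mean: np.ndarray    # (n_features,)
    r_squared: np.ndarray     # (n_features,)
    n_used: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coef, index=list(self.feature_names),
            columns=["intercept", *(f"beta_{c}" for c in COVARIATES)],
        )
        df["train_mean"] = self.train_mean
        df["r_squared"] = self.r_squared
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AdjustmentModel":
        cols = ["intercept", *(f"beta_{c}" for c in COVARIATES)]
        return cls(
            feature_names=tuple(df.index),
            coef=df[cols].to_numpy(float),
            train_mean=df["train_mean"].to_numpy(float),
            r_squared=df["r_squared"].to_numpy(float),
            n_used=len(df),
            n_dropped=0,
        )


def _design(covariates: pd.DataFrame) -> np.ndarray:
    missing = [c for c in COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate columns missing: {missing}")
    C = covariates[list(COVARIATES)].to_numpy(float)
    return np.column_stack([np.ones(len(C)), C])


def fit_adjusters(features: pd.DataFrame, covariates: pd.DataFrame) -> AdjustmentModel:
    """Fit one OLS model per feature column.

    Rows with any missing covariate are dropped (and counted); a
    rank-deficient design (e.g. a constant covariate) falls back to the
    pseudoinverse solution with a warning.
    """
    if len(features) != len(covariates):
        raise ValueError("features and covariates must have the same number of rows")
    keep = ~covariates[list(COVARIATES)].isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    Y = features.to_numpy(float)[keep]
    D = _design(covariates)[keep]
    if len(Y) < 10:
        raise ValueError("need at least 10 complete rows to fit the adjustment")

    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        warnings.warn(
            "rank-deficient covariate design; using pseudoinverse", stacklevel=2
        )
        B = np.linalg.pinv(D) @ Y
    else:
        B, *_ = np.linalg.lstsq(D, Y, rcond=None)

    resid = Y - D @ B
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)

    return AdjustmentModel(
        feature_names=tuple(features.columns),
        coef=B.T,
        train_mean=Y.mean(axis=0),
        r_squared=r2,
        n_used=int(keep.sum()),
        n_dropped=n_dropped,
    )


def apply_adjustment(
    model: AdjustmentModel,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    mode: str = "train",
) -> pd.DataFrame:
    """Apply the adjustment in ``train`` mode, or pass through in ``inference``.

    train:      adjusted = raw - (intercept + B @ covariates) + training mean
    inference:  adjusted = raw (identity; the deployed model sees raw features)
    """
    if mode not in ("train", "inference"):
        raise ValueError("mode must be 'train' or 'inference'")
    if tuple(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the fitted adjustment model")
    if mode == "inference":
        return features.copy()
    if covariates is None:
        raise ValueError("train mode requires covariates")
    D = _design(covariates)
    predicted = D @ model.coef.T
    out = features.to_numpy(float) - predicted + model.train_mean
    return pd.DataFrame(out, index=features.index, columns=features.columns)
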