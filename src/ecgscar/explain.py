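"""Shapley-value explanations of scar predictions.

Kernel SHAP estimates per-feature Shapley values by a weighted least-squares
fit over feature coalitions: a coalition keeps the explained ECG's value on
its member features and averages the model output over background
substitutions for the rest.  Coalitions are weighted by the Shapley kernel
``(d-1) / (C(d,k) k (d-k))``; when full enumeration is affordable (small d)
all 2^d - 2 proper coalitions are used and the solution equals exact Shapley
values, otherwise coalition sizes are sampled from the kernel distribution.
The additivity constraint (base value + sum of attributions = model output)
is enforced exactly by variable elimination.

Two cohort-level views aggregate single-prediction explanations: the mean
absolute Shapley value per (ECG component, lead), and the fraction of
predictions in which a feature ranks in the top 20% by Shapley magnitude.
Welch's unequal-variance t-test compares raw feature values between the Scar
and NoScar groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import COMPONENT_OF, VECTOR_COLUMNS, column_feature, column_lead

__all__ = [
    "Explanation",
    "kernel_shap",
    "summarize_components",
    "top_feature_frequency",
    "welch_compare",
]


@dataclass(frozen=True)
class Explanation:
    """Per-feature Shapley attributions for one prediction."""

    phi: np.ndarray          # (d,) attribution per feature, model-output units
    base_value: float        # expected model output over the background
    output_value: float      # model output at the explained point
    feature_names: tuple[str, ...] | None = None
    region: str | None = None
    group_id: int | None = None

    def local_accuracy_gap(self) -> float:
        return float(abs(self.base_value + self.phi.sum() - self.output_value))


def _kernel_weight(d: int, k: int) -> float:
    return (d - 1) / (math.comb(d, k) * k * (d - k))


def _coalition_matrix(
    d: int, n_coalitions: int, rng: np.random.Generator, force_sampling: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Coalition masks and their regression weights.

    Enumerates all proper coalitions when they fit in the budget (the WLS
    solution is then exact); otherwise samples sizes from the Shapley-kernel
    distribution (unit regression weights, importance sampling), always
    including every coalition of size 1 and d-1.
    """
    n_all = 2**d - 2 if d <= 30 else n_coalitions + 1
    if n_all <= n_coalitions and not force_sampling:
        masks = ((np.arange(1, 2**d - 1)[:, None] >> np.arange(d)) & 1).astype(float)
        weights = np.array([_kernel_weight(d, int(m.sum())) for m in masks])
        return masks, weights

    # importance sampling: coalition sizes drawn from the kernel distribution,
    # members uniform at random; unit regression weights keep it unbiased
    sizes = np.arange(1, d)
    probs = np.array([_kernel_weight(d, int(k)) * math.comb(d, int(k)) for k in sizes])
    probs = probs / probs.sum()
    drawn = rng.choice(sizes, size=n_coalitions, p=probs)
    M = np.zeros((n_coalitions, d))
    for i, k in enumerate(drawn):
        M[i, rng.choice(d, size=int(k), replace=False)] = 1.0
    return M, np.ones(n_coalitions)


def kernel_shap(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    x: np.ndarray,
    n_coalitions: int = 2048,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    chunk_rows: int = 200_000,
    force_sampling: bool = False,
) -> Explanation:
    """Kernel SHAP attribution of ``model_fn`` at ``x``.

    ``model_fn`` maps an (n, d) matrix to n scalar outputs; masked-out
    features are imputed by averaging the model output over background
    substitutions.  Local accuracy (base + sum phi = f(x)) holds exactly by
    construction; on toy problems small enough to enumerate, the result
    equals exact Shapley values.
    """
    background = np.atleast_2d(np.asarray(background, float))
    x = np.asarray(x, float).ravel()
    d = x.size
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    if background.shape[1] != d:
        raise ValueError("background dimension mismatch")
    if n_coalitions < d + 2:
        raise ValueError(f"n_coalitions must be at least d + 2 = {d + 2}")

    rng = np.random.default_rng(seed)
    base = float(np.mean(model_fn(background)))
    fx = float(np.asarray(model_fn(x[None, :])).ravel()[0])

    M, w = _coalition_matrix(d, n_coalitions, rng, force_sampling=force_sampling)
    m = M.shape[0]
    nb = background.shape[0]

    # v(S): mean model output with S features from x, rest from background
    v = np.empty(m)
    rows_per_chunk = max(1, chunk_rows // nb)
    for start in range(0, m, rows_per_chunk):
        Mc = M[start : start + rows_per_chunk]
        blend = (
            Mc[:, None, :] * x[None, None, :]
            + (1.0 - Mc[:, None, :]) * background[None, :, :]
        ).reshape(-1, d)
        out = np.asarray(model_fn(blend)).reshape(Mc.shape[0], nb)
        v[start : start + rows_per_chunk] = out.mean(axis=1)

    # weighted least squares with the additivity constraint folded in by
    # eliminating the last feature: phi_last = (fx - base) - sum(others)
    y = v - base - M[:, -1] * (fx - base)
    A = M[:, :-1] - M[:, [-1]]
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    phi = np.empty(d)
    phi[:-1] = coef
    phi[-1] = (fx - base) - coef.sum()

    names = tuple(feature_names) if feature_names is not None else None
    return Explanation(phi=phi, base_value=base, output_value=fx, feature_names=names)


def _names_of(explanations: Sequence[Explanation]) -> tuple[str, ...]:
    if not explanations:
        raise ValueError("need at least one explanation")
    first = explanations[0].feature_names or tuple(VECTOR_COLUMNS[: explanations[0].phi.size])
    for e in explanations:
        names = e.feature_names or tuple(VECTOR_COLUMNS[: e.phi.size])
        if names != first:
            raise ValueError("explanations use different feature registries")
    return first


def summarize_components(
    explanations: Sequence[Explanation], signed: bool = False
) -> pd.DataFrame:
    """Mean Shapley importance per (ECG component, lead), ranked.

    By default importance is the mean absolute Shapley value; ``signed=True``
    averages signed values instead (direction of push toward Scar/NoScar).
    """
    names = _names_of(explanations)
    phis = np.stack([e.phi for e in explanations])
    vals = phis if signed else np.abs(phis)
    per_feature = vals.mean(axis=0)
    rows = {}
    for name, v in zip(names, per_feature):
        key = (COMPONENT_OF[column_feature(name)], column_lead(name))
        rows.setdefault(key, []).append(v)
    df = pd.DataFrame(
        [
            {"component": comp, "lead": lead, "mean_shap": float(np.mean(vs))}
            for (comp, lead), vs in rows.items()
        ]
    )
    return df.sort_values("mean_shap", ascending=False, ignore_index=True)


def top_feature_frequency(
    explanations: Sequence[Explanation], quantile: float = 0.2
) -> pd.Series:
    """Fraction of predictions where each feature ranks in the top quantile.

    Per prediction, features are ranked by Shapley magnitude (ties broken by
    registry index) and the top ``ceil(quantile * d)`` are marked; for the
    276-feature registry and quantile 0.2 that is 56 features per prediction.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    names = _names_of(explanations)
    phis = np.stack([e.phi for e in explanations])
    d = phis.shape[1]
    k = math.ceil(quantile * d)
    counts = np.zeros(d)
    for phi in phis:
        order = np.lexsort((np.arange(d), -np.abs(phi)))  # magnitude desc, index asc
        counts[order[:k]] += 1
    return pd.Series(counts / phis.shape[0], index=list(names), name="frequency")


def welch_compare(features: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Welch's unequal-variance t-test per feature, Scar vs NoScar.

    Returns per-feature group means and SDs, the t statistic and the
    two-sided p-value.  A class with fewer than two observations yields NaN
    statistics for every feature.
    """
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    a = features.loc[y == 1]
    b = features.loc[y == 0]
    out = pd.DataFrame(index=features.columns)
    out["scar_mean"] = a.mean()
    out["scar_sd"] = a.std(ddof=1)
    out["noscar_mean"] = b.mean()
    out["noscar_sd"] = b.std(ddof=1)
    if len(a) < 2 or len(b) < 2:
        out["t"] = np.nan
        out["p"] = np.nan
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=False)
    out["t"] = t
    out["p"] = p
    return out
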