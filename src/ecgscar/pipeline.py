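"""End-to-end orchestration: adjust -> partition -> train -> predict -> explain.

The training entry point consumes a feature table (one row per ECG, 276
lead-major feature columns plus covariates and regional labels), applies the
training-time confounder adjustment, partitions patients per region, trains
the per-group classifiers, and evaluates on held-out patients.  Prediction
always runs on raw (unadjusted) features.
"""

from __future__ import annotations

import dataclasses
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import adjust as _adjust
from .explain import Explanation, kernel_shap
from .metrics import ConfusionMetrics, confusion
from .partition import PartitionConfig, PartitionModel, recursive_partition
from .registry import VECTOR_COLUMNS
from .scarf import (
    RegionalScarModels,
    ScarfConfig,
    predict as _predict_rows,
    train_regional_models,
)
from .synthetic import REGIONS, CohortConfig

LABEL_COLUMNS = tuple(f"label_{r}" for r in REGIONS)
COVARIATE_COLUMNS = ("lvmi", "age", "sex")


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.2
    adjust_at_inference: bool = False   # the prescribed asymmetry: raw at inference
    seed: int = 0


@dataclass(frozen=True)
class ExplainConfig:
    n_coalitions: int = 600
    max_background: int = 30
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    scarf: ScarfConfig = field(default_factory=ScarfConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed into every stage."""
        s = int(seed) % (2**31 - 1)
        return PipelineConfig(
            cohort=dataclasses.replace(self.cohort, seed=s),
            partition=dataclasses.replace(self.partition, seed=s + 1),
            scarf=dataclasses.replace(self.scarf, seed=s + 2),
            train=dataclasses.replace(self.train, seed=s + 3),
            explain=dataclasses.replace(self.explain, seed=s + 4),
        )


def _from_dict(cls, data: dict):
    """Build a (frozen) dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(val, dict):
            val = _from_dict(f.type, val)
        kwargs[f.name] = val
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    """Validate and build a :class:`PipelineConfig` from a nested dict (YAML)."""
    sections = {"cohort": CohortConfig, "partition": PartitionConfig,
                "scarf": ScarfConfig, "train": TrainConfig, "explain": ExplainConfig}
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for key, cls in sections.items():
        if key in data:
            sub = dict(data[key])
            if key == "cohort" and "scar_effect_map" in sub:
                from .synthetic import ScarEffect

                sub["scar_effect_map"] = tuple(
                    ScarEffect(**e) if isinstance(e, dict) else ScarEffect(*e)
                    for e in sub["scar_effect_map"]
                )
            kwargs[key] = _from_dict(cls, sub)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# fitted pipeline
# ---------------------------------------------------------------------------


@dataclass
class ScarPipeline:
    """A fully fitted model bundle."""

    adjustment: _adjust.AdjustmentModel
    partitions: dict[str, PartitionModel]
    models: RegionalScarModels
    config: PipelineConfig
    backgrounds: dict[str, dict[int, np.ndarray]]  # SHAP background per group

    def predict(self, features: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        X = _feature_matrix(features)
        if X.shape[0] == 0:
            cols = [f"p_{r}" for r in REGIONS] + [f"pred_{r}" for r in REGIONS]
            return pd.DataFrame(columns=cols + ["pred_global"])
        return _predict_rows(self.models, X)

    def explain(
        self,
        x: np.ndarray,
        region: str,
        n_coalitions: int | None = None,
        seed: int | None = None,
    ) -> Explanation:
        """Shapley attribution of one ECG's prediction for one region."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        x = np.asarray(x, float).ravel()
        part = self.partitions[region]
        gid = part.assign_group(x)
        model = self.models.models[region][gid]
        cfg = self.config.explain
        exp = kernel_shap(
            model.predict_proba,
            self.backgrounds[region][gid],
            x,
            n_coalitions=n_coalitions or cfg.n_coalitions,
            seed=cfg.seed if seed is None else seed,
            feature_names=VECTOR_COLUMNS,
        )
        return dataclasses.replace(exp, region=region, group_id=gid)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ScarPipeline":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _feature_matrix(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[list(VECTOR_COLUMNS)].to_numpy(float)
    X = np.atleast_2d(np.asarray(features, float))
    if X.size == 0:
        return X.reshape(0, len(VECTOR_COLUMNS))
    return X


def split_patients(
    table: pd.DataFrame, test_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level train/test split (all ECGs of a patient stay together)."""
    rng = np.random.default_rng(seed)
    patients = table["patient_id"].unique()
    n_test = int(round(test_fraction * patients.size))
    test_pat = set(rng.choice(patients, size=n_test, replace=False))
    mask = table["patient_id"].isin(test_pat)
    return table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)


def fit_pipeline(table: pd.DataFrame, config: PipelineConfig) -> ScarPipeline:
    """Fit the full pipeline on a training feature table."""
    features = table[list(VECTOR_COLUMNS)]
    covariates = table[list(COVARIATE_COLUMNS)]

    adj = _adjust.fit_adjusters(features, covariates)
    X_adj = _adjust.apply_adjustment(adj, features, covariates, mode="train")

    # patient-level aggregation for partitioning
    pat_ids = table["patient_id"].to_numpy()
    uniq, pat_pos = np.unique(pat_ids, return_inverse=True)
    X_rows = X_adj.to_numpy(float)
    X_pat = np.zeros((uniq.size, X_rows.shape[1]))
    np.add.at(X_pat, pat_pos, X_rows)
    X_pat /= np.bincount(pat_pos)[:, None]

    partitions: dict[str, PartitionModel] = {}
    labels_rows: dict[str, np.ndarray] = {}
    for region in REGIONS:
        y_rows = table[f"label_{region}"].to_numpy(int)
        labels_rows[region] = y_rows
        y_pat = np.zeros(uniq.size, dtype=int)
        y_pat[pat_pos] = y_rows  # labels are constant within patient
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            partitions[region] = recursive_partition(X_pat, y_pat, config.partition)

    models = train_regional_models(
        partitions, X_pat, X_rows, pat_pos, labels_rows, config.scarf
    )

    # background matrices for Kernel SHAP (training rows of each group)
    rng = np.random.default_rng(config.explain.seed)
    backgrounds: dict[str, dict[int, np.ndarray]] = {}
    for region in REGIONS:
        part = partitions[region]
        patient_group = np.empty(uniq.size, dtype=int)
        for gid, grp in enumerate(part.groups):
            patient_group[grp.members] = gid
        row_group = patient_group[pat_pos]
        backgrounds[region] = {}
        for gid in range(part.n_groups):
            rows = np.flatnonzero(row_group == gid)
            if rows.size > config.explain.max_background:
                rows = rng.choice(rows, size=config.explain.max_background, replace=False)
            backgrounds[region][gid] = X_rows[rows]

    return ScarPipeline(
        adjustment=adj,
        partitions=partitions,
        models=models,
        config=config,
        backgrounds=backgrounds,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion-derived metrics per region and for the global OR rule."""

    per_region: dict[str, ConfusionMetrics]
    global_scar: ConfusionMetrics

    def to_frame(self) -> pd.DataFrame:
        rows = {r: m.as_dict() for r, m in self.per_region.items()}
        rows["global"] = self.global_scar.as_dict()
        return pd.DataFrame(rows).T


def evaluate_pipeline(pipe: ScarPipeline, test_table: pd.DataFrame) -> EvaluationReport:
    """Patient-level evaluation: mean probability over a patient's ECGs,
    thresholded, then the OR rule for global scar."""
    probs = pipe.predict(test_table)
    probs = probs.set_index(test_table.index)
    grouped = probs.groupby(test_table["patient_id"].to_numpy())
    per_region = {}
    preds = {}
    truths = {}
    for region in REGIONS:
        p_pat = grouped[f"p_{region}"].mean()
        y_pat = test_table.groupby("patient_id")[f"label_{region}"].first()
        pred = (p_pat >= pipe.models.threshold).to_numpy()
        per_region[region] = confusion(y_pat.to_numpy(), pred)
        preds[region] = pred
        truths[region] = y_pat.to_numpy().astype(bool)
    global_pred = preds["basal"] | preds["mid"] | preds["apical"]
    global_true = truths["basal"] | truths["mid"] | truths["apical"]
    return EvaluationReport(per_region=per_region, global_scar=confusion(global_true, global_pred))


def run_train(
    table: pd.DataFrame, config: PipelineConfig
) -> tuple[ScarPipeline, EvaluationReport]:
    """Train on a patient-level split and report held-out performance."""
    train_df, test_df = split_patients(
        table, config.train.test_fraction, config.train.seed
    )
    pipe = fit_pipeline(train_df, config)
    report = evaluate_pipeline(pipe, test_df)
    return pipe, report


def cross_validate(
    table: pd.DataFrame, config: PipelineConfig, n_runs: int = 2, n_folds: int = 5
) -> pd.DataFrame:
    """Repeated k-fold cross-validation at the patient level.

    Returns one row per (run, fold, region/global) with the confusion-derived
    metrics; summarize with ``df.groupby('region').agg(['mean', 'std'])``.
    """
    records = []
    patients = table["patient_id"].unique()
    for run in range(n_runs):
        rng = np.random.default_rng(config.train.seed + 7 * run)
        order = rng.permutation(patients)
        folds = np.array_split(order, n_folds)
        for fold_i, fold_pat in enumerate(folds):
            mask = table["patient_id"].isin(set(fold_pat))
            pipe = fit_pipeline(table[~mask].reset_index(drop=True), config)
            rep = evaluate_pipeline(pipe, table[mask].reset_index(drop=True))
            for region, m in {**rep.per_region, "global": rep.global_scar}.items():
                records.append({"run": run, "fold": fold_i, "region": region, **m.as_dict()})
    return pd.DataFrame(records)


def explain_batch(
    pipe: ScarPipeline,
    features: pd.DataFrame | np.ndarray,
    region: str,
    max_ecgs: int | None = None,
    seed: int = 0,
) -> list[Explanation]:
    """Explanations for (a subsample of) a batch of ECGs, one region."""
    X = _feature_matrix(features)
    idx = np.arange(X.shape[0])
    if max_ecgs is not None and idx.size > max_ecgs:
        idx = np.random.default_rng(seed).choice(idx, size=max_ecgs, replace=False)
    return [pipe.explain(X[i], region, seed=seed + int(i)) for i in idx]
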