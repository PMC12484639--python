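"""Self-supervised contrastive pretraining + supervised scar heads.

Per merged patient group and per LV region, an encoder is pretrained with
random-feature-corruption contrastive learning: 60% of the feature
coordinates of each ECG vector are resampled from the empirical training
marginals, and an InfoNCE objective pulls each ECG's embedding toward its own
corrupted view and away from the corrupted views of the other ECGs in the
batch.  A fully connected head is then attached and encoder + head are
jointly fine-tuned on weighted cross-entropy.  Regional probabilities are
combined into a global scar call by OR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .nn import MLP, Adam, normalize_rows, normalize_rows_backward
from .partition import PartitionModel
from .synthetic import REGIONS

__all__ = [
    "ScarfConfig",
    "ScarPrediction",
    "GroupScarModel",
    "ConstantModel",
    "RegionalScarModels",
    "corrupt",
    "corrupt_batch",
    "info_nce_loss",
    "train_regional_models",
    "predict",
]


@dataclass(frozen=True)
class ScarfConfig:
    corruption_rate: float = 0.6
    temperature: float = 1.0
    embedding_dim: int = 32
    encoder_hidden: tuple[int, ...] = (128, 128)
    head_hidden: tuple[int, ...] = (32,)
    batch_size: int = 128
    pretrain_epochs: int = 20
    finetune_epochs: int = 15
    pretrain_lr: float = 1e-3
    finetune_lr: float = 1e-3
    threshold: float = 0.5
    corruption_mode: str = "empirical"   # or 'interval': uniform over [min, max]
    freeze_encoder: bool = False
    no_self_supervised: bool = False     # ablation: skip contrastive pretraining
    labeled_fraction: float = 1.0        # fraction of rows whose labels fine-tuning sees
    cv_grid: dict | None = None          # e.g. {"finetune_lr": [...], "embedding_dim": [...]}
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in (0, 1]")
        if self.corruption_mode not in ("empirical", "interval"):
            raise ValueError("corruption_mode must be 'empirical' or 'interval'")


@dataclass(frozen=True)
class ScarPrediction:
    """One ECG's regional probabilities, regional calls and the global OR."""

    p_basal: float
    p_mid: float
    p_apical: float
    basal: bool
    mid: bool
    apical: bool

    @property
    def global_scar(self) -> bool:
        return self.basal or self.mid or self.apical


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------


def corrupt_batch(
    X: np.ndarray,
    train_matrix: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mode: str = "empirical",
) -> np.ndarray:
    """Corrupted views of the rows of ``X``.

    For each row, ``k = round(rate * d)`` distinct coordinates are chosen
    uniformly without replacement and replaced by draws from that feature's
    empirical training column (or, in ``interval`` mode, uniformly from the
    column's [min, max] range).  A constant training column can only be
    replaced by its constant value.
    """
    if train_matrix.shape[0] == 0:
        raise ValueError("train matrix must be nonempty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    k = int(round(rate * d))
    if k == 0:
        return X.copy()
    out = X.copy()
    # per-row random subset of k columns: argpartition of random keys
    keys = rng.random((n, d))
    cols = np.argpartition(keys, k - 1, axis=1)[:, :k]
    row_idx = np.repeat(np.arange(n), k)
    col_idx = cols.ravel()
    if mode == "empirical":
        src = rng.integers(0, train_matrix.shape[0], size=row_idx.size)
        out[row_idx, col_idx] = train_matrix[src, col_idx]
    elif mode == "interval":
        lo = train_matrix.min(axis=0)[col_idx]
        hi = train_matrix.max(axis=0)[col_idx]
        out[row_idx, col_idx] = rng.uniform(lo, hi)
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return out


def corrupt(
    x: np.ndarray,
    train_matrix: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mode: str = "empirical",
) -> np.ndarray:
    """Corrupted view of a single feature vector (see :func:`corrupt_batch`)."""
    return corrupt_batch(x[None, :], train_matrix, rate, rng, mode)[0]


# ---------------------------------------------------------------------------
# contrastive objective
# ---------------------------------------------------------------------------


def info_nce_loss(sim: np.ndarray) -> float:
    """InfoNCE loss of a similarity matrix already divided by temperature.

    ``sim[i, j]`` is the similarity of anchor i with corrupted view j; the
    positives sit on the diagonal.  With all similarities equal the loss is
    exactly ``ln(N)``.
    """
    sim = np.asarray(sim, dtype=float)
    mx = sim.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(sim - mx).sum(axis=1))
    return float(np.mean(lse - np.diag(sim)))


def _info_nce_grad(sim: np.ndarray) -> np.ndarray:
    """dL/dsim for :func:`info_nce_loss` (softmax rows minus identity, / N)."""
    mx = sim.max(axis=1, keepdims=True)
    e = np.exp(sim - mx)
    P = e / e.sum(axis=1, keepdims=True)
    n = sim.shape[0]
    return (P - np.eye(n)) / n


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class ConstantModel:
    """Fallback for merged groups whose training labels are single-class."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], self.p)


class GroupScarModel:
    """Encoder + head for one merged group and one LV region."""

    def __init__(self, config: ScarfConfig, n_features: int, seed: int):
        config.validate()
        self.config = config
        self.n_features = n_features
        self.seed = int(seed) % (2**31 - 1)
        rng = np.random.default_rng(self.seed)
        self.encoder = MLP(
            [n_features, *config.encoder_hidden, config.embedding_dim], rng
        )
        self.head = MLP([config.embedding_dim, *config.head_hidden, 1], rng)
        self._rng = rng
        self.scale_mean = np.zeros(n_features)
        self.scale_sd = np.ones(n_features)
        self.pretrain_losses: list[float] = []
        self.finetune_losses: list[float] = []

    # -- helpers ------------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, float)) - self.scale_mean) / self.scale_sd

    def _fit_scaler(self, X: np.ndarray) -> None:
        self.scale_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_sd = np.where(sd > 0, sd, 1.0)

    # -- self-supervised pretraining ----------------------------------------

    def pretrain(self, X: np.ndarray) -> list[float]:
        """Contrastive pretraining of the encoder on unlabeled rows."""
        cfg = self.config
        Xz = self._standardize(X)
        n = Xz.shape[0]
        if n < 4:
            warnings.warn("too few rows to pretrain; skipping", stacklevel=2)
            return []
        opt = Adam(self.encoder.params(), lr=cfg.pretrain_lr)
        rng = self._rng
        losses = []
        for _ in range(cfg.pretrain_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if idx.size < 2:
                    continue
                xa = Xz[idx]
                xb = corrupt_batch(xa, Xz, cfg.corruption_rate, rng, cfg.corruption_mode)
                ua, cache_a = self.encoder.forward(xa)
                ub, cache_b = self.encoder.forward(xb)
                za, na = normalize_rows(ua)
                zb, nb = normalize_rows(ub)
                sim = (za @ zb.T) / cfg.temperature
                loss = info_nce_loss(sim)
                if not math.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite contrastive loss (batch size {idx.size}); "
                        "check input scaling and learning rate"
                    )
                epoch_losses.append(loss)
                dS = _info_nce_grad(sim) / cfg.temperature
                dza = dS @ zb
                dzb = dS.T @ za
                dua = normalize_rows_backward(ua, za, na, dza)
                dub = normalize_rows_backward(ub, zb, nb, dzb)
                dWa, dba, _ = self.encoder.backward(cache_a, dua)
                dWb, dbb, _ = self.encoder.backward(cache_b, dub)
                grads = [ga + gb for ga, gb in zip(dWa + dba, dWb + dbb)]
                opt.step(grads)
            losses.append(float(np.mean(epoch_losses)))
        self.pretrain_losses = losses
        return losses

    # -- supervised fine-tuning ----------------------------------------------

    def finetune(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Joint cross-entropy training of head (and encoder unless frozen)."""
        cfg = self.config
        Xz = self._standardize(X)
        y = np.asarray(y, dtype=float).ravel()
        n = Xz.shape[0]
        # inverse-frequency class weights
        pos = y.sum()
        neg = n - pos
        w_pos = n / (2.0 * pos) if pos > 0 else 0.0
        w_neg = n / (2.0 * neg) if neg > 0 else 0.0
        params = self.head.params() if cfg.freeze_encoder else (
            self.encoder.params() + self.head.params()
        )
        opt = Adam(params, lr=cfg.finetune_lr)
        rng = self._rng
        losses = []
        for _ in range(cfg.finetune_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xz[idx], y[idx]
                emb, cache_e = self.encoder.forward(xb)
                logit, cache_h = self.head.forward(emb)
                logit = logit[:, 0]
                p = 1.0 / (1.0 + np.exp(-logit))
                w = np.where(yb > 0, w_pos, w_neg)
                eps = 1e-12
                loss = float(
                    -np.mean(w * (yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
                )
                if not math.isfinite(loss):
                    raise RuntimeError("non-finite classification loss")
                epoch_losses.append(loss)
                dlogit = (w * (p - yb) / idx.size)[:, None]
                dWh, dbh, demb = self.head.backward(cache_h, dlogit)
                if cfg.freeze_encoder:
                    opt.step(dWh + dbh)
                else:
                    dWe, dbe, _ = self.encoder.backward(cache_e, demb)
                    opt.step(dWe + dbe + dWh + dbh)
            losses.append(float(np.mean(epoch_losses)))
        self.finetune_losses = losses
        return losses

    def fit(self, X: np.ndarray, y: np.ndarray, labeled_mask: np.ndarray | None = None):
        """Pretrain on all rows, fine-tune on the labeled subset."""
        X = np.atleast_2d(np.asarray(X, float))
        self._fit_scaler(X)
        if not self.config.no_self_supervised:
            self.pretrain(X)
        if labeled_mask is None:
            labeled_mask = np.ones(X.shape[0], dtype=bool)
        self.finetune(X[labeled_mask], np.asarray(y)[labeled_mask])
        return self

    def embed(self, X: np.ndarray) -> np.ndarray:
        return self.encoder(self._standardize(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logit = self.head(self.encoder(self._standardize(X)))[:, 0]
        return 1.0 / (1.0 + np.exp(-logit))


# ---------------------------------------------------------------------------
# regional training and prediction
# ---------------------------------------------------------------------------


@dataclass
class RegionalScarModels:
    """Per-region partition + per-group classifier bundle."""

    partitions: dict[str, PartitionModel]
    models: dict[str, dict[int, GroupScarModel | ConstantModel]]
    config: ScarfConfig
    threshold: float = 0.5


def _cv_score(model_cfg: ScarfConfig, X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Mean F1 over stratified k-fold CV for one hyperparameter combo."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=model_cfg.cv_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        m = GroupScarModel(replace(model_cfg, cv_grid=None), X.shape[1], seed)
        m.fit(X[tr], y[tr])
        pred = m.predict_proba(X[te]) >= model_cfg.threshold
        tp = np.sum(pred & (y[te] > 0))
        fp = np.sum(pred & (y[te] == 0))
        fn = np.sum(~pred & (y[te] > 0))
        scores.append(tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn > 0 else 1.0)
    return float(np.mean(scores))


def _select_config(config: ScarfConfig, X: np.ndarray, y: np.ndarray, seed: int) -> ScarfConfig:
    if not config.cv_grid:
        return config
    import itertools

    keys = sorted(config.cv_grid)
    best_cfg, best_score = config, -1.0
    for combo in itertools.product(*(config.cv_grid[k] for k in keys)):
        cand = replace(config, **dict(zip(keys, combo)))
        score = _cv_score(cand, X, y, seed)
        if score > best_score:
            best_cfg, best_score = cand, score
    return replace(best_cfg, cv_grid=None)


def train_regional_models(
    partitions: Mapping[str, PartitionModel],
    X_patients: np.ndarray,
    X_rows: np.ndarray,
    patient_of_row: np.ndarray,
    labels_rows: Mapping[str, np.ndarray],
    config: ScarfConfig,
) -> RegionalScarModels:
    """Train one encoder+head per (region, merged group).

    ``X_patients`` is the patient-level matrix the partitions were fitted on;
    ECG rows are routed to groups through their patient's membership.  Groups
    whose training labels are single-class get a constant-probability
    fallback.  ``labeled_fraction < 1`` hides a per-patient subset of labels
    from fine-tuning while pretraining still sees every row.
    """
    config.validate()
    models: dict[str, dict[int, GroupScarModel | ConstantModel]] = {}
    rng = np.random.default_rng(config.seed)
    for r_idx, region in enumerate(REGIONS):
        if region not in partitions:
            raise ValueError(f"no partition fitted for region {region!r}")
        part = partitions[region]
        y = np.asarray(labels_rows[region]).astype(int)
        patient_group = np.empty(X_patients.shape[0], dtype=int)
        for gid, grp in enumerate(part.groups):
            patient_group[grp.members] = gid
        row_group = patient_group[patient_of_row]
        models[region] = {}
        for gid in range(part.n_groups):
            rows = np.flatnonzero(row_group == gid)
            Xg, yg = X_rows[rows], y[rows]
            seed = (config.seed * 1009 + r_idx * 101 + gid) % (2**31 - 1)
            if len(np.unique(yg)) < 2:
                p = float(yg.mean()) if yg.size else 0.0
                warnings.warn(
                    f"group {gid} for region {region} is single-class; "
                    "constant-probability fallback",
                    stacklevel=2,
                )
                models[region][gid] = ConstantModel(p)
                continue
            labeled_mask = np.ones(rows.size, dtype=bool)
            if config.labeled_fraction < 1.0:
                # hide labels per patient so replicates don't leak
                pats = np.unique(patient_of_row[rows])
                n_keep = max(2, int(round(config.labeled_fraction * pats.size)))
                keep = rng.choice(pats, size=n_keep, replace=False)
                labeled_mask = np.isin(patient_of_row[rows], keep)
                if len(np.unique(yg[labeled_mask])) < 2:
                    # ensure both classes are represented among labeled rows
                    for cls in (0, 1):
                        if not np.any(yg[labeled_mask] == cls) and np.any(yg == cls):
                            labeled_mask[np.flatnonzero(yg == cls)[0]] = True
            cfg = _select_config(config, Xg[labeled_mask], yg[labeled_mask], seed)
            model = GroupScarModel(cfg, X_rows.shape[1], seed)
            model.fit(Xg, yg, labeled_mask=labeled_mask)
            models[region][gid] = model
    return RegionalScarModels(
        partitions=dict(partitions), models=models, config=config,
        threshold=config.threshold,
    )


def predict_proba_regional(
    bundle: RegionalScarModels, X: np.ndarray
) -> pd.DataFrame:
    """Regional scar probabilities for each ECG row.

    Each ECG is routed to its merged group per region by centroid similarity,
    and scored by that group's model.
    """
    X = np.atleast_2d(np.asarray(X, float))
    out = {}
    for region in REGIONS:
        if region not in bundle.models:
            raise ValueError(f"region {region!r} has no fitted models")
        part = bundle.partitions[region]
        gids = part.assign_groups(X)
        p = np.empty(X.shape[0])
        for gid in np.unique(gids):
            rows = np.flatnonzero(gids == gid)
            p[rows] = bundle.models[region][int(gid)].predict_proba(X[rows])
        out[f"p_{region}"] = p
    return pd.DataFrame(out)


def predict(bundle: RegionalScarModels, X: np.ndarray) -> pd.DataFrame:
    """Regional probabilities, regional calls and the global OR rule.

    A probability exactly at the threshold classifies as positive.
    """
    probs = predict_proba_regional(bundle, X)
    for region in REGIONS:
        probs[f"pred_{region}"] = probs[f"p_{region}"] >= bundle.threshold
    probs["pred_global"] = (
        probs["pred_basal"] | probs["pred_mid"] | probs["pred_apical"]
    )
    return probs


def predict_one(bundle: RegionalScarModels, x: np.ndarray) -> ScarPrediction:
    row = predict(bundle, np.atleast_2d(x)).iloc[0]
    return ScarPrediction(
        p_basal=float(row["p_basal"]),
        p_mid=float(row["p_mid"]),
        p_apical=float(row["p_apical"]),
        basal=bool(row["pred_basal"]),
        mid=bool(row["pred_mid"]),
        apical=bool(row["pred_apical"]),
    )
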