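"""Two-stage hierarchical classifier and its evaluation protocols.

Stage 1 separates NS from SC over all samples; samples predicted NS are
routed to stage 2, which separates AD from SQ and is trained only on NS
rows.  Each stage owns its full preprocessing chain (min-max normalization,
information-gain selection, dimensionality reduction, neural classifier).
The overall accuracy combines the stages by the class-fraction-weighted
product rule:

    overall = sc_frac * stage1_acc + ns_frac * stage1_acc * stage2_acc

Because t-SNE has no native out-of-sample transform, evaluation supports a
transductive policy (train and test rows embedded jointly, test labels
hidden) and a knn_map policy (test points placed at the distance-weighted
mean of their nearest training embeddings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .config import PipelineConfig, StageConfig
from .core_io import DescriptorMatrix, LabeledDataset, SubLabel, TopLabel
from .errors import ValidationError
from .feature_select import InfoGainScore, rank_and_select
from .nnet import MLPConfig, TrainedMLP, mlp_init, mlp_predict, mlp_train
from .dimred import pca_fit, pca_transform, tsne_embed
from .preprocess import (
    NormalizationState,
    apply_normalization,
    discretize,
    fit_normalization,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StagePipeline",
    "TwoStageModel",
    "EvaluationReport",
    "fit_two_stage",
    "predict_two_stage",
    "overall_accuracy",
    "cross_validate",
    "evaluate_independent",
    "fit_naive_multiclass",
    "cross_validate_naive",
    "stratified_fold_indices",
]


# --- single-stage pipeline -------------------------------------------------

@dataclass
class StagePipeline:
    """Fitted preprocessing + dimred + classifier for one binary stage."""

    classes: list[str]
    norm_state: NormalizationState
    selected_features: list[str]
    scores: list[InfoGainScore]
    stage_config: StageConfig
    classifier: TrainedMLP
    pca_model: object | None = None
    train_features: np.ndarray | None = None  # selected-feature space, for knn_map
    embed_cache: dict[str, np.ndarray] = field(default_factory=dict)
    final_kl: float = 0.0

    def transform(self, matrix: DescriptorMatrix) -> np.ndarray:
        """Map raw-descriptor rows into the stage's reduced space."""
        if list(matrix.col_ids) != list(self.norm_state.col_ids):
            raise ValidationError("matrix columns incompatible with stage pipeline")
        normed = apply_normalization(matrix, self.norm_state)
        feats = normed.select_columns(self.selected_features)
        if self.stage_config.dimred == "pca":
            return pca_transform(self.pca_model, feats.values).coords
        coords = np.empty((feats.values.shape[0], self._out_dim()))
        for i, name in enumerate(feats.row_ids):
            cached = self.embed_cache.get(name)
            coords[i] = cached if cached is not None else self._knn_map(feats.values[i])
        return coords

    def predict(self, matrix: DescriptorMatrix) -> tuple[list[str], np.ndarray]:
        coords = self.transform(matrix)
        idx, probs = mlp_predict(self.classifier, coords)
        return [self.classes[i] for i in idx], probs

    def _out_dim(self) -> int:
        return self.stage_config.tsne.out_dim

    def _knn_map(self, x: np.ndarray) -> np.ndarray:
        if self.train_features is None or not self.embed_cache:
            raise ValidationError("no fitted embedding available for knn mapping")
        train_coords = np.array(
            [self.embed_cache[n] for n in self._train_names], dtype=float
        )
        d = np.linalg.norm(self.train_features - x, axis=1)
        k = min(self.stage_config.knn_k, d.shape[0])
        nn = np.argsort(d, kind="stable")[:k]
        w = 1.0 / (d[nn] + 1e-8)
        return (w[:, None] * train_coords[nn]).sum(axis=0) / w.sum()

    _train_names: list[str] = field(default_factory=list)


def _fit_stage(
    X: DescriptorMatrix,
    labels: list[str],
    classes: list[str],
    config: PipelineConfig,
    stage_config: StageConfig,
    seed: int,
    oos: DescriptorMatrix | None = None,
) -> StagePipeline:
    """Fit normalize -> select -> dimred -> classify on one stage's rows.

    ``oos`` rows (labels unknown) participate only where a policy requires
    them: pooled normalization or transductive t-SNE embedding.
    """
    for cls in classes:
        if labels.count(cls) < 2:
            raise ValidationError(f"class {cls!r} needs >= 2 training samples")

    if config.normalize_scope == "pooled" and oos is not None:
        pooled = DescriptorMatrix(
            list(X.row_ids) + list(oos.row_ids),
            list(X.col_ids),
            np.vstack([X.values, oos.values]),
        )
        norm_state = fit_normalization(pooled)
    else:
        norm_state = fit_normalization(X)
    normed = apply_normalization(X, norm_state)

    n_cols = len(normed.col_ids)
    k = config.select_k
    if k > n_cols:
        if not config.clamp_k:
            raise ValidationError(f"select.k={k} exceeds {n_cols} columns")
        logger.info("clamping select.k from %d to %d columns", k, n_cols)
        k = n_cols
    disc = discretize(normed, config.discretize)
    selected, scores = rank_and_select(disc, normed, labels, k, config.select_log_base)
    logger.info(
        "stage %s: features %d -> %d by information gain", "/".join(classes), n_cols, k
    )

    pipeline = StagePipeline(
        classes=list(classes),
        norm_state=norm_state,
        selected_features=list(selected.col_ids),
        scores=scores,
        stage_config=stage_config,
        classifier=None,  # type: ignore[arg-type]  # set below
    )
    pipeline._train_names = list(selected.row_ids)
    pipeline.train_features = selected.values

    if stage_config.dimred == "pca":
        n_comp = min(stage_config.pca_components, selected.values.shape[0], k)
        pipeline.pca_model = pca_fit(selected.values, n_comp)
        train_coords = pca_transform(pipeline.pca_model, selected.values).coords
    else:
        tsne_cfg = replace(stage_config.tsne, seed=stage_config.tsne.seed + seed)
        if oos is not None and stage_config.oos == "transductive":
            oos_feats = apply_normalization(oos, norm_state).select_columns(
                pipeline.selected_features
            )
            joint = np.vstack([selected.values, oos_feats.values])
            emb = tsne_embed(joint, tsne_cfg)
            names = list(selected.row_ids) + list(oos_feats.row_ids)
        else:
            emb = tsne_embed(selected.values, tsne_cfg)
            names = list(selected.row_ids)
        pipeline.final_kl = emb.final_kl
        pipeline.embed_cache = {n: emb.coords[i] for i, n in enumerate(names)}
        train_coords = emb.coords[: len(selected.row_ids)]

    y = np.array([classes.index(l) for l in labels])
    mlp_cfg = replace(config.mlp, seed=config.mlp.seed + seed)
    net = mlp_init(train_coords.shape[1], len(classes), mlp_cfg)
    pipeline.classifier = mlp_train(net, train_coords, y, mlp_cfg)
    return pipeline


# --- two-stage model -------------------------------------------------------

@dataclass
class TwoStageModel:
    stage1: StagePipeline  # classes NS, SC
    stage2: StagePipeline  # classes AD, SQ


@dataclass
class EvaluationReport:
    stage1_acc: float
    stage1_sd: float
    stage2_acc: float
    stage2_sd: float
    ns_frac: float
    sc_frac: float
    overall_acc: float
    protocol: str  # 'cv5' | 'independent'
    baseline_multiclass_acc: float | None = None
    fold_stage1: list[float] = field(default_factory=list)
    fold_stage2: list[float] = field(default_factory=list)
    confusion: dict | None = None

    def __post_init__(self) -> None:
        expected = overall_accuracy(self.stage1_acc, self.stage2_acc, self.ns_frac, self.sc_frac)
        if abs(expected - self.overall_acc) > 1e-9:
            raise ValidationError(
                f"overall_acc {self.overall_acc} inconsistent with stages (expected {expected})"
            )

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "stage1_acc": self.stage1_acc,
            "stage1_sd": self.stage1_sd,
            "stage2_acc": self.stage2_acc,
            "stage2_sd": self.stage2_sd,
            "ns_frac": self.ns_frac,
            "sc_frac": self.sc_frac,
            "overall_acc": self.overall_acc,
            "baseline_multiclass_acc": self.baseline_multiclass_acc,
            "fold_stage1": self.fold_stage1,
            "fold_stage2": self.fold_stage2,
            "confusion": self.confusion,
        }


def overall_accuracy(stage1_acc: float, stage2_acc: float, ns_frac: float, sc_frac: float) -> float:
    """Fraction-weighted product rule combining the two stage accuracies."""
    for name, v in (
        ("stage1_acc", stage1_acc),
        ("stage2_acc", stage2_acc),
        ("ns_frac", ns_frac),
        ("sc_frac", sc_frac),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if abs(ns_frac + sc_frac - 1.0) > 1e-9:
        raise ValidationError(f"ns_frac + sc_frac must equal 1, got {ns_frac + sc_frac}")
    return sc_frac * stage1_acc + ns_frac * stage1_acc * stage2_acc


def fit_two_stage(
    train: LabeledDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    oos: DescriptorMatrix | None = None,
) -> TwoStageModel:
    """Fit stage 1 on all rows (NS vs SC) and stage 2 on the NS rows (AD vs SQ).

    ``oos`` optionally passes unlabeled rows for transductive embedding /
    pooled normalization; their labels are never consulted.
    """
    config = config or PipelineConfig()
    top = [t.value for t in train.top_labels]
    for cls in ("NS", "SC"):
        if top.count(cls) < 2:
            raise ValidationError(f"class {cls!r} needs >= 2 training samples")
    ns_idx = [
        i
        for i, (t, s) in enumerate(zip(train.top_labels, train.sub_labels))
        if t == TopLabel.NS and s != SubLabel.NONE
    ]
    subs = [train.sub_labels[i].value for i in ns_idx]
    for cls in ("AD", "SQ"):
        if subs.count(cls) < 2:
            raise ValidationError(f"class {cls!r} needs >= 2 training samples")

    stage1 = _fit_stage(
        train.descriptors, top, ["NS", "SC"], config, config.stage1, seed * 2 + 1, oos
    )
    ns_data = train.subset(ns_idx)
    stage2 = _fit_stage(
        ns_data.descriptors, subs, ["AD", "SQ"], config, config.stage2, seed * 2 + 2, oos
    )
    return TwoStageModel(stage1=stage1, stage2=stage2)


def predict_two_stage(
    model: TwoStageModel, X: DescriptorMatrix
) -> tuple[list[str], list[dict]]:
    """Route each sample: SC terminates at stage 1, NS continues to stage 2.

    Returns final leaf labels in {SC, AD, SQ} and a per-sample routing trace.
    """
    s1_labels, s1_probs = model.stage1.predict(X)
    ns_rows = [i for i, l in enumerate(s1_labels) if l == "NS"]
    traces: list[dict] = []
    final = list(s1_labels)
    if ns_rows:
        mask = np.zeros(len(s1_labels), dtype=bool)
        mask[ns_rows] = True
        s2_labels, s2_probs = model.stage2.predict(X.select_rows(mask))
        for j, i in enumerate(ns_rows):
            final[i] = s2_labels[j]
    for i, name in enumerate(X.row_ids):
        trace = {"name": name, "stage1": s1_labels[i], "stage1_probs": s1_probs[i].tolist()}
        if s1_labels[i] == "NS":
            trace["stage2"] = final[i]
        trace["final"] = final[i]
        traces.append(trace)
    return final, traces


# --- evaluation protocols --------------------------------------------------

def stratified_fold_indices(
    labels: list[str], k: int, seed: int, stratified: bool = True
) -> list[np.ndarray]:
    """Seeded disjoint exhaustive folds, stratified by label when requested."""
    n = len(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified:
        for cls in sorted(set(labels)):
            idx = np.array([i for i, l in enumerate(labels) if l == cls])
            if len(idx) < k:
                raise ValidationError(
                    f"class {cls!r} has {len(idx)} < {k} members; use a smaller k "
                    "or unstratified folds"
                )
            rng.shuffle(idx)
            offset = int(rng.integers(k))  # rotate so small classes spread evenly
            for pos, i in enumerate(idx):
                folds[(pos + offset) % k].append(int(i))
    else:
        idx = rng.permutation(n)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _class_fractions(
    data: LabeledDataset, config: PipelineConfig
) -> tuple[float, float]:
    ns = sum(t == TopLabel.NS for t in data.top_labels)
    ns_frac = ns / len(data)
    sc_frac = 1.0 - ns_frac
    if config.eval.ns_frac_override is not None:
        ns_frac = config.eval.ns_frac_override
        sc_frac = (
            config.eval.sc_frac_override
            if config.eval.sc_frac_override is not None
            else 1.0 - ns_frac
        )
    return ns_frac, sc_frac


def _confusion(true: list[str], pred: list[str]) -> dict:
    classes = sorted(set(true) | set(pred))
    table = {t: {p: 0 for p in classes} for t in classes}
    for t, p in zip(true, pred):
        table[t][p] += 1
    return table


def cross_validate(
    data: LabeledDataset,
    config: PipelineConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """k-fold evaluation of the two-stage model.

    Per fold, stage-1 accuracy is measured on every test row and stage-2
    accuracy on test rows whose true top label is NS (conditional accuracy,
    matching the product-rule combiner).  Class fractions come from the full
    dataset unless overridden in the config.
    """
    config = config or PipelineConfig()
    k = k if k is not None else config.eval.k_folds
    seed = seed if seed is not None else config.eval.seed
    folds = stratified_fold_indices(data.leaf_labels(), k, seed, config.eval.stratified)

    s1_accs: list[float] = []
    s2_accs: list[float] = []
    all_true: list[str] = []
    all_pred: list[str] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
        train, test = data.subset(train_idx), data.subset(test_idx)
        model = fit_two_stage(train, config, seed=seed * 100 + fi, oos=test.descriptors)

        s1_pred, _ = model.stage1.predict(test.descriptors)
        s1_true = [t.value for t in test.top_labels]
        s1_accs.append(float(np.mean([p == t for p, t in zip(s1_pred, s1_true)])))

        ns_rows = [
            i
            for i, (t, s) in enumerate(zip(test.top_labels, test.sub_labels))
            if t == TopLabel.NS and s != SubLabel.NONE
        ]
        if ns_rows:
            mask = np.zeros(len(test), dtype=bool)
            mask[ns_rows] = True
            s2_pred, _ = model.stage2.predict(test.descriptors.select_rows(mask))
            s2_true = [test.sub_labels[i].value for i in ns_rows]
            s2_accs.append(float(np.mean([p == t for p, t in zip(s2_pred, s2_true)])))

        pred, _ = predict_two_stage(model, test.descriptors)
        all_true.extend(test.leaf_labels())
        all_pred.extend(pred)

    s1_mean, s1_sd = float(np.mean(s1_accs)), float(np.std(s1_accs, ddof=1))
    s2_mean = float(np.mean(s2_accs)) if s2_accs else 0.0
    s2_sd = float(np.std(s2_accs, ddof=1)) if len(s2_accs) > 1 else 0.0
    ns_frac, sc_frac = _class_fractions(data, config)
    overall = overall_accuracy(s1_mean, s2_mean, ns_frac, sc_frac)
    logger.info(
        "CV%d: stage1 %.3f±%.3f, stage2 %.3f±%.3f, NS%%=%.3f SC%%=%.3f, overall %.3f",
        k, s1_mean, s1_sd, s2_mean, s2_sd, ns_frac, sc_frac, overall,
    )
    return EvaluationReport(
        stage1_acc=s1_mean,
        stage1_sd=s1_sd,
        stage2_acc=s2_mean,
        stage2_sd=s2_sd,
        ns_frac=ns_frac,
        sc_frac=sc_frac,
        overall_acc=overall,
        protocol=f"cv{k}",
        fold_stage1=s1_accs,
        fold_stage2=s2_accs,
        confusion=_confusion(all_true, all_pred),
    )


def evaluate_independent(
    config: PipelineConfig | None,
    train: LabeledDataset,
    test: LabeledDataset,
    seed: int | None = None,
) -> EvaluationReport:
    """Fit on all of ``train``, evaluate stage accuracies on ``test``."""
    config = config or PipelineConfig()
    seed = seed if seed is not None else config.eval.seed
    model = fit_two_stage(train, config, seed=seed, oos=test.descriptors)

    s1_pred, _ = model.stage1.predict(test.descriptors)
    s1_true = [t.value for t in test.top_labels]
    s1_acc = float(np.mean([p == t for p, t in zip(s1_pred, s1_true)]))

    ns_rows = [
        i
        for i, (t, s) in enumerate(zip(test.top_labels, test.sub_labels))
        if t == TopLabel.NS and s != SubLabel.NONE
    ]
    if ns_rows:
        mask = np.zeros(len(test), dtype=bool)
        mask[ns_rows] = True
        s2_pred, _ = model.stage2.predict(test.descriptors.select_rows(mask))
        s2_true = [test.sub_labels[i].value for i in ns_rows]
        s2_acc = float(np.mean([p == t for p, t in zip(s2_pred, s2_true)]))
    else:
        s2_acc = 0.0

    ns_frac, sc_frac = _class_fractions(test, config)
    pred, _ = predict_two_stage(model, test.descriptors)
    return EvaluationReport(
        stage1_acc=s1_acc,
        stage1_sd=0.0,
        stage2_acc=s2_acc,
        stage2_sd=0.0,
        ns_frac=ns_frac,
        sc_frac=sc_frac,
        overall_acc=overall_accuracy(s1_acc, s2_acc, ns_frac, sc_frac),
        protocol="independent",
        fold_stage1=[s1_acc],
        fold_stage2=[s2_acc] if ns_rows else [],
        confusion=_confusion(test.leaf_labels(), pred),
    )


# --- naive multiclass baseline --------------------------------------------

def fit_naive_multiclass(
    train: LabeledDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    oos: DescriptorMatrix | None = None,
) -> StagePipeline:
    """One flat classifier over the leaf classes, same preprocessing chain."""
    config = config or PipelineConfig()
    labels = train.leaf_labels()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("naive baseline needs >= 2 leaf classes")
    return _fit_stage(
        train.descriptors, labels, classes, config, config.stage1, seed, oos
    )


def cross_validate_naive(
    data: LabeledDataset,
    config: PipelineConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> tuple[float, float, list[float]]:
    """k-fold leaf-class accuracy of the flat baseline, using the same
    seeded splitter as :func:`cross_validate` for head-to-head comparison."""
    config = config or PipelineConfig()
    k = k if k is not None else config.eval.k_folds
    seed = seed if seed is not None else config.eval.seed
    folds = stratified_fold_indices(data.leaf_labels(), k, seed, config.eval.stratified)
    accs: list[float] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
        train, test = data.subset(train_idx), data.subset(test_idx)
        model = fit_naive_multiclass(
            train, config, seed=seed * 100 + fi, oos=test.descriptors
        )
        pred, _ = model.predict(test.descriptors)
        true = test.leaf_labels()
        accs.append(float(np.mean([p == t for p, t in zip(pred, true)])))
    return float(np.mean(accs)), float(np.std(accs, ddof=1)), accs
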