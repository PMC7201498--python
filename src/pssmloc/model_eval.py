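"""RBF-SVM with grid search, jackknife evaluation, and the six metrics.

The classifier is an RBF-kernel SVM whose cost c and kernel width gamma
are chosen by exhaustive grid search (stratified cross-validated
accuracy inside the training data). Evaluation is leave-one-out over
the original samples; synthetic rows created by resampling are training
material only, never test points. Per class (one-vs-rest) the report
carries Sn, Sp, F-measure, Mcc, and G-mean; the aggregate is the
overall accuracy plus unweighted macro averages, with zero-denominator
metrics flagged undefined and excluded from macros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from pssmloc.errors import ParameterError, UsageError
from pssmloc.features import bid_cc, encode_collection, im_psepssm
from pssmloc.imbalance import (
    LabeledFeatureSet,
    Method,
    Placement,
    ResamplingPlan,
    Strategy,
    resample,
)
from pssmloc.pssm_io import PssmMatrix

#: Conventional libsvm-style grids (powers of two).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))

METRIC_NAMES = ("Sn", "Sp", "F-m", "Mcc", "G-mean")


@dataclass(frozen=True)
class SvmConfig:
    """Grid-searched RBF-SVM configuration."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_cv: int = 5  # stratified folds for the selection rule
    grid_mode: str = "per_fold"  # "per_fold" | "global"
    decision_shape: str = "ovo"  # canonical multiclass decomposition
    standardize: bool = False  # optional z-scoring fitted on training data

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ParameterError("c and gamma grids must be non-empty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ParameterError("grid values must be strictly positive")
        if self.grid_mode not in ("per_fold", "global"):
            raise ParameterError("grid_mode must be 'per_fold' or 'global'")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts per class; TP+FP+TN+FN = n for each."""

    counts: Mapping[object, tuple[int, int, int, int]]  # (TP, FP, TN, FN)
    n: int

    def __getitem__(self, label: object) -> tuple[int, int, int, int]:
        return self.counts[label]

    @property
    def labels(self) -> list[object]:
        return list(self.counts)


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Per-class one-vs-rest confusion counts over the union of labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise UsageError(
            f"y_true has {len(y_true)} entries but y_pred has {len(y_pred)}"
        )
    if len(y_true) == 0:
        raise UsageError("confusion requires at least one sample")
    labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()), key=str)
    n = len(y_true)
    out = {}
    for lab in labels:
        t = y_true == lab
        p = y_pred == lab
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        tn = n - tp - fp - fn
        out[lab] = (tp, fp, tn, fn)
    return ConfusionCounts(counts=out, n=n)


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den != 0 else None


def per_class_metrics(counts: ConfusionCounts) -> dict[object, dict[str, float | None]]:
    """Sn, Sp, F-m, Mcc, G-mean per class; None marks a zero denominator."""
    out: dict[object, dict[str, float | None]] = {}
    for lab in counts.labels:
        tp, fp, tn, fn = counts[lab]
        sn = _safe_div(tp, tp + fn)
        sp = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        if prec is None or sn is None or prec + sn == 0:
            fm = None
        else:
            fm = 2 * prec * sn / (prec + sn)
        mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den != 0 else None
        gmean = np.sqrt(sn * sp) if sn is not None and sp is not None else None
        out[lab] = {
            "Sn": sn,
            "Sp": sp,
            "F-m": fm,
            "Mcc": None if mcc is None else float(mcc),
            "G-mean": None if gmean is None else float(gmean),
        }
    return out


@dataclass
class EvaluationReport:
    """Per-class and aggregate metrics from one evaluation run."""

    per_class: dict[object, dict[str, float | None]]
    macro: dict[str, float | None]
    oa: float
    n: int
    undefined_counts: dict[str, int]
    y_true: tuple = ()
    y_pred: tuple = ()
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "OA": self.oa,
            "n": self.n,
            "undefined_counts": self.undefined_counts,
            "y_true": [str(v) for v in self.y_true],
            "y_pred": [str(v) for v in self.y_pred],
            "metadata": self.metadata,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_table(self) -> str:
        """Human-readable table: one row per class plus the macro row."""
        cols = list(METRIC_NAMES)
        lines = ["class\t" + "\t".join(cols)]
        fmt = lambda v: "undef" if v is None else f"{v:.4f}"  # noqa: E731
        for lab, m in self.per_class.items():
            lines.append(str(lab) + "\t" + "\t".join(fmt(m[c]) for c in cols))
        lines.append("macro\t" + "\t".join(fmt(self.macro[c]) for c in cols))
        lines.append(f"OA\t{self.oa:.4f}")
        return "\n".join(lines)


def metrics(
    counts: ConfusionCounts,
    y_true: Sequence | None = None,
    y_pred: Sequence | None = None,
    metadata: dict | None = None,
) -> EvaluationReport:
    """Assemble the six-metric report from confusion counts.

    OA is the fraction of correctly labelled samples (sum of per-class TP
    over n, since every correct sample is the TP of exactly one class).
    Macro averages are unweighted over classes with defined values.
    """
    per_class = per_class_metrics(counts)
    oa = sum(counts[lab][0] for lab in counts.labels) / counts.n
    macro: dict[str, float | None] = {}
    undefined: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = [m[name] for m in per_class.values() if m[name] is not None]
        undefined[name] = sum(1 for m in per_class.values() if m[name] is None)
        macro[name] = float(np.mean(vals)) if vals else None
    return EvaluationReport(
        per_class=per_class,
        macro=macro,
        oa=float(oa),
        n=counts.n,
        undefined_counts=undefined,
        y_true=tuple(y_true) if y_true is not None else (),
        y_pred=tuple(y_pred) if y_pred is not None else (),
        metadata=metadata or {},
    )


def _fit_svm(X: np.ndarray, y: np.ndarray, c: float, gamma: float, cfg: SvmConfig) -> SVC:
    model = SVC(
        C=c,
        gamma=gamma,
        kernel="rbf",
        decision_function_shape=cfg.decision_shape,
        random_state=0,
    )
    model.fit(X, y)
    return model


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def grid_search_svm(
    train: LabeledFeatureSet, cfg: SvmConfig
) -> tuple[SVC, tuple[float, float]]:
    """Exhaustive (c, gamma) search; returns the refit model and the pair.

    Selection: mean accuracy over stratified ``inner_cv`` folds (capped at
    the smallest class count; if that leaves fewer than 2 folds, training
    accuracy is used instead). Ties break toward the earliest grid cell,
    c varying slowest — deterministic given data and grids.
    """
    X, y = train.X, train.y
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("grid search needs at least two classes in the training set")
    if cfg.standardize:
        mu, sd = _standardizer(X)
        X = (X - mu) / sd
    n_splits = min(cfg.inner_cv, int(class_counts.min()))
    best_score, best_pair = -np.inf, None
    for c in cfg.c_grid:
        for g in cfg.gamma_grid:
            if n_splits >= 2:
                skf = StratifiedKFold(n_splits=n_splits, shuffle=False)
                accs = []
                for tr, va in skf.split(X, y):
                    model = _fit_svm(X[tr], y[tr], c, g, cfg)
                    accs.append(float(np.mean(model.predict(X[va]) == y[va])))
                score = float(np.mean(accs))
            else:
                model = _fit_svm(X, y, c, g, cfg)
                score = float(np.mean(model.predict(X) == y))
            if score > best_score:
                best_score, best_pair = score, (c, g)
    assert best_pair is not None
    model = _fit_svm(X, y, best_pair[0], best_pair[1], cfg)
    if cfg.standardize:
        model._pssmloc_scale = (mu, sd)  # reused by jackknife's predict path
    return model, best_pair


def _predict(model: SVC, X: np.ndarray) -> np.ndarray:
    scale = getattr(model, "_pssmloc_scale", None)
    if scale is not None:
        X = (X - scale[0]) / scale[1]
    return model.predict(X)


def jackknife(
    data: LabeledFeatureSet,
    cfg: SvmConfig,
    plan: ResamplingPlan | None = None,
    block_slices: Sequence[slice] | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation over the original samples.

    With ``plan.placement == BEFORE_CV`` the whole set is resampled once
    and each original row is then held out in turn (its synthetic
    descendants stay in training — the paper-faithful mode). With
    ``TRAIN_FOLD_ONLY`` each fold's n-1 originals are resampled afresh
    with a fold-specific seed, so no held-out sample ever contributes to
    its own training fold, directly or as a SMOTE parent.

    Deterministic given data, config, and plan seed: n samples, n models.
    """
    plan = plan or ResamplingPlan()
    n = data.n
    n_classes = len(set(data.y.tolist()))
    if n < n_classes + 1:
        raise ParameterError("jackknife needs at least one more sample than classes")

    global_pair = None
    if cfg.grid_mode == "global":
        _, global_pair = grid_search_svm(data, cfg)

    preds = np.empty(n, dtype=object)
    fold_params: list[tuple[float, float]] = []

    if plan.placement is Placement.BEFORE_CV and plan.method is not Method.NONE:
        pool = resample(data, plan, block_slices=block_slices)
        orig_pos = {id_: i for i, id_ in enumerate(pool.ids.tolist())}
        for i in range(n):
            mask = np.ones(pool.n, dtype=bool)
            j = orig_pos.get(data.ids[i])
            if j is not None:  # ENN may have deleted the held-out original
                mask[j] = False
            train = pool.subset(np.flatnonzero(mask))
            preds[i], pair = _fit_predict_one(train, data.X[i : i + 1], cfg, global_pair)
            fold_params.append(pair)
    else:
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            train = data.subset(np.flatnonzero(mask))
            if plan.method is not Method.NONE:
                fold_seed = int(
                    np.random.SeedSequence([plan.seed, i]).generate_state(1)[0]
                )
                train = resample(train, plan, seed=fold_seed, block_slices=block_slices)
            preds[i], pair = _fit_predict_one(train, data.X[i : i + 1], cfg, global_pair)
            fold_params.append(pair)

    report = metrics(
        confusion(data.y, preds),
        y_true=data.y.tolist(),
        y_pred=preds.tolist(),
        metadata={
            "n_models": n,
            "plan": {
                "method": plan.method.value,
                "k_neighbors": plan.k_neighbors,
                "N": plan.N,
                "enn_neighbors": plan.enn_neighbors,
                "seed": plan.seed,
                "placement": plan.placement.value,
                "strategy": plan.strategy.value,
            },
            "svm": {
                "c_grid": list(cfg.c_grid),
                "gamma_grid": list(cfg.gamma_grid),
                "grid_mode": cfg.grid_mode,
            },
            "fold_params": fold_params,
            "singleton_classes": sorted(
                str(lab) for lab, c in data.class_counts().items() if c == 1
            ),
        },
    )
    return report


def _fit_predict_one(
    train: LabeledFeatureSet,
    x: np.ndarray,
    cfg: SvmConfig,
    global_pair: tuple[float, float] | None,
) -> tuple[object, tuple[float, float]]:
    if global_pair is not None:
        X, y = train.X, train.y
        if cfg.standardize:
            mu, sd = _standardizer(X)
            X = (X - mu) / sd
        model = _fit_svm(X, y, global_pair[0], global_pair[1], cfg)
        if cfg.standardize:
            model._pssmloc_scale = (mu, sd)
        pair = global_pair
    else:
        model, pair = grid_search_svm(train, cfg)
    return _predict(model, x)[0], pair


def run_strategy(
    matrices: Sequence[PssmMatrix],
    labels: Sequence,
    xi: int,
    S: int,
    plan: ResamplingPlan,
    cfg: SvmConfig,
    norm: str = "per_lag",
) -> EvaluationReport:
    """Encode, fuse, resample per the plan's strategy, and jackknife.

    RESAMPLE_THEN_FUSE oversamples the column-lag block and the
    cross-correlation block separately (shared seed and draw schedule so
    synthetic rows align index-wise) before concatenation;
    FUSE_THEN_RESAMPLE concatenates first. With ``plan.method == NONE``
    the two strategies coincide.
    """
    if len(matrices) != len(labels):
        raise UsageError("labels length must match the number of matrices")
    block_a = encode_collection(matrices, "IM_PSEPSSM", xi=xi, norm=norm)
    block_b = encode_collection(matrices, "BIDCC", S=S)
    widths = (block_a.shape[1], block_b.shape[1])
    X = np.hstack([block_a.to_numpy(), block_b.to_numpy()])
    data = LabeledFeatureSet(X=X, y=np.asarray(labels), ids=block_a.index.to_numpy())
    slices = None
    if plan.strategy is Strategy.RESAMPLE_THEN_FUSE:
        slices = (slice(0, widths[0]), slice(widths[0], widths[0] + widths[1]))
    report = jackknife(data, cfg, plan, block_slices=slices)
    report.metadata["feature_widths"] = {
        "im_psepssm": widths[0],
        "bid_cc": widths[1],
        "fused": int(sum(widths)),
    }
    report.metadata["params"] = {"xi": xi, "S": S, "norm": norm}
    return report
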