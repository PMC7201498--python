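"""SMOTE oversampling, ENN editing, and their composite.

SMOTE synthesises minority-class points by convex interpolation between
a minority sample and one of its k same-class Euclidean nearest
neighbours: x_new = x + u * (y - x) with u ~ Uniform[0, 1). ENN then
deletes any sample whose three nearest neighbours (in the pre-deletion
set) majority-vote for a different class. The composite applies SMOTE
first, then ENN.

Originals are never modified by SMOTE; every synthetic row carries a
provenance entry naming its parent, the chosen neighbour, and the
interpolation weight, so the geometry is fully auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from pssmloc.errors import ParameterError, ValidationError


class Method(str, Enum):
    NONE = "NONE"
    SMOTE = "SMOTE"
    ENN = "ENN"
    SMOTEENN = "SMOTEENN"


class Placement(str, Enum):
    BEFORE_CV = "BEFORE_CV"
    TRAIN_FOLD_ONLY = "TRAIN_FOLD_ONLY"


class Strategy(str, Enum):
    RESAMPLE_THEN_FUSE = "RESAMPLE_THEN_FUSE"
    FUSE_THEN_RESAMPLE = "FUSE_THEN_RESAMPLE"


@dataclass(frozen=True)
class SynthRecord:
    """Provenance of one synthetic sample."""

    label: object
    parent_index: int  # row index into the input set
    neighbor_index: int  # row index into the input set
    u: float


@dataclass
class LabeledFeatureSet:
    """Feature matrix with class labels and per-row provenance.

    ``provenance[i]`` is ``"original"`` or ``"synthetic:<parent_id>"``.
    """

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    provenance: np.ndarray | None = None
    synth_log: tuple[SynthRecord, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValidationError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if n < 1:
            raise ValidationError("feature set must contain at least one sample")
        if len(self.y) != n:
            raise ValidationError("y length does not match X rows")
        if not np.isfinite(self.X).all():
            raise ValidationError("X contains non-finite entries")
        if self.ids is None:
            self.ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if len(self.ids) != n:
                raise ValidationError("ids length does not match X rows")
        if self.provenance is None:
            self.provenance = np.array(["original"] * n, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if len(self.provenance) != n:
                raise ValidationError("provenance length does not match X rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict[object, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, index: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            X=self.X[index],
            y=self.y[index],
            ids=self.ids[index],
            provenance=self.provenance[index],
        )


@dataclass(frozen=True)
class ResamplingPlan:
    """Which resampler runs, with what neighbour counts, and where."""

    method: Method = Method.NONE
    k_neighbors: int = 5
    N: int | str = "auto"  # per-class magnification, or "auto" to equalise
    enn_neighbors: int = 3
    seed: int = 0
    placement: Placement = Placement.TRAIN_FOLD_ONLY
    strategy: Strategy = Strategy.FUSE_THEN_RESAMPLE

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")
        if self.enn_neighbors < 1:
            raise ParameterError("enn_neighbors must be >= 1")
        if isinstance(self.N, str):
            if self.N.lower() != "auto":
                raise ParameterError("N must be a positive integer or 'auto'")
        elif self.N < 1:
            raise ParameterError("N must be a positive integer or 'auto'")


def _class_neighbors(Xc: np.ndarray, k: int) -> np.ndarray:
    """Indices (within the class) of each point's k nearest same-class
    neighbours, excluding itself."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
    idx = nn.kneighbors(Xc, return_distance=False)
    # Drop self-matches; with exact duplicates self may not be first, so
    # filter by index rather than position.
    out = np.empty((Xc.shape[0], k), dtype=int)
    for i, row in enumerate(idx):
        others = row[row != i][:k]
        if len(others) < k:  # duplicates swallowed the self entry
            others = np.concatenate([others, row[row == i][1:]])[:k]
        out[i] = others
    return out


def smote(
    data: LabeledFeatureSet,
    plan: ResamplingPlan,
    rng: np.random.Generator | None = None,
) -> LabeledFeatureSet:
    """Oversample minority classes by neighbourhood interpolation.

    With ``N='auto'`` every class is topped up to the majority count;
    with integer N each minority sample spawns N * k synthetics. Original
    rows are preserved verbatim and synthetics appended after them.
    """
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    counts = data.class_counts()
    majority = max(counts.values())
    k = plan.k_neighbors

    new_rows: list[np.ndarray] = []
    new_y: list[object] = []
    new_ids: list[str] = []
    new_prov: list[str] = []
    log: list[SynthRecord] = []

    for label in sorted(counts, key=str):
        count = counts[label]
        if count >= majority:
            continue
        if isinstance(plan.N, str):
            needed = majority - count
        else:
            needed = plan.N * k * count
        if needed == 0:
            continue
        if count < k + 1:
            raise ParameterError(
                f"class {label!r} has {count} samples; SMOTE with "
                f"k_neighbors={k} needs at least {k + 1}"
            )
        class_idx = np.flatnonzero(data.y == label)
        Xc = data.X[class_idx]
        neighbors = _class_neighbors(Xc, k)
        # Draw schedule is data-independent given (counts, needed, k):
        # parent position, neighbour slot, interpolation weight.
        parents = rng.integers(0, count, size=needed)
        slots = rng.integers(0, k, size=needed)
        us = rng.random(size=needed)
        for j in range(needed):
            p = parents[j]
            q = neighbors[p, slots[j]]
            u = us[j]
            x_new = Xc[p] + u * (Xc[q] - Xc[p])
            pi = int(class_idx[p])
            qi = int(class_idx[q])
            new_rows.append(x_new)
            new_y.append(label)
            new_ids.append(f"synth:{data.ids[pi]}:{len(log)}")
            new_prov.append(f"synthetic:{data.ids[pi]}")
            log.append(SynthRecord(label=label, parent_index=pi, neighbor_index=qi, u=float(u)))

    if not new_rows:
        return replace(data, synth_log=())
    return LabeledFeatureSet(
        X=np.vstack([data.X, np.array(new_rows)]),
        y=np.concatenate([data.y, np.array(new_y, dtype=data.y.dtype)]),
        ids=np.concatenate([data.ids, np.array(new_ids, dtype=object)]),
        provenance=np.concatenate([data.provenance, np.array(new_prov, dtype=object)]),
        synth_log=tuple(log),
    )


def enn(data: LabeledFeatureSet, n_neighbors: int = 3) -> LabeledFeatureSet:
    """Edited-nearest-neighbour cleaning, single simultaneous pass.

    Each sample's ``n_neighbors`` nearest neighbours are found in the
    original (pre-deletion) set; samples whose neighbours majority-vote
    for another class are all removed at once, preserving order.
    """
    if data.n < n_neighbors + 1:
        raise ParameterError(
            f"ENN with {n_neighbors} neighbours needs at least "
            f"{n_neighbors + 1} samples, got {data.n}"
        )
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(data.X)
    idx = nn.kneighbors(data.X, return_distance=False)
    keep = np.ones(data.n, dtype=bool)
    threshold = (n_neighbors // 2) + 1  # majority of the neighbours
    for i, row in enumerate(idx):
        others = row[row != i][:n_neighbors]
        if len(others) < n_neighbors:
            others = np.concatenate([others, row[row == i][1:]])[:n_neighbors]
        disagree = int(np.sum(data.y[others] != data.y[i]))
        if disagree >= threshold:
            keep[i] = False
    before = set(np.unique(data.y).tolist())
    out = data.subset(np.flatnonzero(keep))
    after = set(np.unique(out.y).tolist())
    lost = before - after
    if lost:
        warnings.warn(f"ENN removed every sample of class(es) {sorted(map(str, lost))}")
    return out


def smoteenn(
    data: LabeledFeatureSet,
    plan: ResamplingPlan,
    rng: np.random.Generator | None = None,
) -> LabeledFeatureSet:
    """Oversample with SMOTE, then edit the union with ENN."""
    over = smote(data, plan, rng=rng)
    return enn(over, n_neighbors=plan.enn_neighbors)


def resample(
    data: LabeledFeatureSet,
    plan: ResamplingPlan,
    seed: int | None = None,
    block_slices: Sequence[slice] | None = None,
) -> LabeledFeatureSet:
    """Dispatch on ``plan.method`` and ``plan.strategy``.

    With ``block_slices`` and strategy RESAMPLE_THEN_FUSE, SMOTE runs on
    each feature block separately but with identical draw schedules
    (same seed, same parent/neighbour-slot/weight draws), so synthetic
    rows align index-wise before concatenation; ENN then edits the fused
    matrix. Without blocks (or strategy FUSE_THEN_RESAMPLE) the whole
    matrix is resampled at once.
    """
    if plan.method is Method.NONE:
        return data
    use_seed = plan.seed if seed is None else seed
    if plan.method is Method.ENN:
        return enn(data, n_neighbors=plan.enn_neighbors)

    if block_slices is not None and plan.strategy is Strategy.RESAMPLE_THEN_FUSE:
        blocks = []
        base = None
        for sl in block_slices:
            sub = LabeledFeatureSet(
                X=data.X[:, sl], y=data.y, ids=data.ids, provenance=data.provenance
            )
            over = smote(sub, plan, rng=np.random.default_rng(use_seed))
            if base is None:
                base = over
            elif over.n != base.n:
                raise RuntimeError(
                    "internal error: block row counts diverged under shared-seed SMOTE"
                )
            blocks.append(over.X)
        assert base is not None
        fused = LabeledFeatureSet(
            X=np.hstack(blocks),
            y=base.y,
            ids=base.ids,
            provenance=base.provenance,
            synth_log=base.synth_log,
        )
        if plan.method is Method.SMOTEENN:
            return enn(fused, n_neighbors=plan.enn_neighbors)
        return fused

    rng = np.random.default_rng(use_seed)
    if plan.method is Method.SMOTE:
        return smote(data, plan, rng=rng)
    return smoteenn(data, plan, rng=rng)
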