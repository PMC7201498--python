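"""Synthetic labeled PSSM collections and feature blobs for testing.

Raw synthetic scores are drawn on the integer log-odds scale (rounded
Gaussians clipped to [-10, 12]) so the matrices exercise the same
numeric range as real PSI-BLAST output before sigmoid scaling. Class
structure comes from per-class length-20 mean profiles; optional
``lag_signal`` injects covariance between adjacent columns so the
column-lag encoders carry class signal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from pssmloc.errors import ValidationError
from pssmloc.imbalance import LabeledFeatureSet
from pssmloc.pssm_io import PSIBLAST_COLUMN_ORDER, PssmMatrix

SCORE_MIN, SCORE_MAX = -10, 12


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a labeled synthetic collection."""

    n_per_class: tuple[int, ...]
    length_range: tuple[int, int] = (50, 120)
    class_profiles: np.ndarray | None = None  # (n_classes, 20) mean scores
    noise_sd: float = 2.0
    lag_signal: float | None = None
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.n_per_class or any(n < 1 for n in self.n_per_class):
            raise ValidationError("n_per_class must be positive integers")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValidationError("length_range must satisfy 2 <= L_min <= L_max")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.class_profiles is not None:
            profiles = np.asarray(self.class_profiles, dtype=float)
            if profiles.shape != (len(self.n_per_class), 20):
                raise ValidationError(
                    f"class_profiles must be ({len(self.n_per_class)}, 20), "
                    f"got {profiles.shape}"
                )
            object.__setattr__(self, "class_profiles", profiles)
        if self.class_names is not None and len(self.class_names) != len(self.n_per_class):
            raise ValidationError("class_names length must match n_per_class")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        return tuple(f"class{i}" for i in range(len(self.n_per_class)))


def separated_profiles(
    n_classes: int, separation: float, seed: int = 0, dim: int = 20
) -> np.ndarray:
    """Random class-mean profiles with pairwise scale set by ``separation``."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, separation, size=(n_classes, dim))


def generate_pssms(spec: SyntheticSpec) -> list[tuple[PssmMatrix, str]]:
    """Draw one raw (unscaled) PSSM per protein with class-dependent means.

    Row counts are uniform over ``length_range``; scores are
    profile + Gaussian noise, rounded to integers and clipped to the
    PSI-BLAST log-odds range. Deterministic per spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = spec.class_profiles
    if profiles is None:
        profiles = separated_profiles(len(spec.n_per_class), 4.0, seed=spec.seed)
        profiles = np.clip(profiles, SCORE_MIN + 2, SCORE_MAX - 2)
    out: list[tuple[PssmMatrix, str]] = []
    counter = 0
    for ci, (label, count) in enumerate(zip(spec.labels, spec.n_per_class)):
        for _ in range(count):
            counter += 1
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            base = profiles[ci] + rng.normal(0.0, spec.noise_sd, size=(L, 20))
            raw = base.copy()
            if spec.lag_signal:
                raw[:, 1:] += spec.lag_signal * base[:, :-1]
            raw = np.clip(np.rint(raw), SCORE_MIN, SCORE_MAX)
            out.append(
                (PssmMatrix(id=f"P{counter:04d}", scores=raw, scaled=False), label)
            )
    return out


def generate_feature_blobs(
    spec: SyntheticSpec, dim: int = 20, separation: float | None = None
) -> LabeledFeatureSet:
    """Gaussian blobs directly in feature space, for isolated unit tests.

    Class centres come from ``spec.class_profiles`` when given (dim must
    then be 20) or from :func:`separated_profiles` with the requested
    separation. Deterministic per spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.class_profiles is not None:
        centers = spec.class_profiles
        dim = centers.shape[1]
    else:
        centers = separated_profiles(
            len(spec.n_per_class), separation if separation is not None else 4.0,
            seed=spec.seed, dim=dim,
        )
    rows, labels = [], []
    for ci, (label, count) in enumerate(zip(spec.labels, spec.n_per_class)):
        rows.append(centers[ci] + rng.normal(0.0, spec.noise_sd, size=(count, dim)))
        labels.extend([label] * count)
    X = np.vstack(rows)
    ids = np.array([f"b{i:04d}" for i in range(X.shape[0])], dtype=object)
    return LabeledFeatureSet(X=X, y=np.array(labels, dtype=object), ids=ids)


def write_ascii_pssm(m: PssmMatrix, path: str | Path) -> None:
    """Write a matrix in the ASCII-PSSM dialect the parser reads.

    Residue letters are the per-row argmax column (arbitrary but stable);
    the weighted-percentage block is zero-filled.
    """
    path = Path(path)
    letters = list(PSIBLAST_COLUMN_ORDER)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write("            " + "   ".join(letters) + "   " + "   ".join(letters) + "\n")
        for i, row in enumerate(m.scores, start=1):
            res = letters[int(np.argmax(row))]
            scores = " ".join(f"{int(v):4d}" for v in row)
            pcts = " ".join("   0" for _ in range(20))
            fh.write(f"{i:5d} {res}  {scores}  {pcts}\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")


def write_collection(
    collection: Sequence[tuple[PssmMatrix, str]], outdir: str | Path
) -> Path:
    """Write each PSSM as ``<id>.pssm`` plus a ``labels.csv`` mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "labels.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        for m, label in collection:
            write_ascii_pssm(m, outdir / f"{m.id}.pssm")
            writer.writerow([m.id, label])
    return outdir / "labels.csv"


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Read an ``id,label`` CSV into a mapping."""
    out: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = row["label"]
    return out
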