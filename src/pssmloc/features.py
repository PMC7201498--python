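"""Fixed-length feature encodings of variable-length PSSM matrices.

Encoders
--------
``psepssm``
    Classic pseudo-PSSM: 20 column means plus, for each lag d = 1..xi
    along the sequence (row) axis, the 20 per-column mean squared
    differences between rows i and i+d. Dimension 20 + 20*xi.
``im_psepssm``
    Column-axis variant: the lagged factors pair DIFFERENT amino-acid
    columns n and n+d, one factor per (d, n) with n = 1..20-d, summed
    over all rows. Dimension (20 + 20*xi) - xi*(xi+1)/2.
``t1_im_pssm`` / ``t2_im_pssm`` / ``t3_im_pssm``
    Same layout as ``im_psepssm`` with alternative per-pair factors:
    raw cross-products (T1), products centred by the mean of row sums
    (T2), or by the mean of column sums (T3).
``bid_cc``
    For a residue distance S, the full 20 x 20 table of cross-products
    sum_i M[i, a] * M[i+S, b], flattened row-major: 400 features per S.

All encoders map proteins of any length L to the same width for fixed
parameters, so collections with heterogeneous L yield rectangular
feature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pssmloc.errors import ParameterError, UsageError
from pssmloc.pssm_io import PssmMatrix


class Encoder(str, Enum):
    PSEPSSM = "PSEPSSM"
    IM_PSEPSSM = "IM_PSEPSSM"
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    BIDCC = "BIDCC"
    BIM_PSSM = "BIM_PSSM"


#: How the per-lag factor is normalised. "per_lag" divides by L - d,
#: "max_lag" by L - xi (the printed prefactor, fixed at the largest lag),
#: "length" by L. Dimensions are identical under all three.
NormRule = str
_NORM_RULES = ("per_lag", "max_lag", "length")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length encoding of one protein with provenance."""

    id: str
    values: np.ndarray
    encoder: Encoder
    params: Mapping[str, object] = field(default_factory=dict)
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ParameterError("feature values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ParameterError(f"feature vector for {self.id!r} has non-finite entries")
        if self.names is not None and len(self.names) != len(self.values):
            raise ParameterError("feature names do not match vector length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MarginalSums:
    """Row/column sums of a PSSM and their scalar means.

    ``sum(row_sums) == sum(col_sums)`` equals the grand total.
    """

    row_sums: np.ndarray
    col_sums: np.ndarray
    row_mean: float
    col_mean: float

    @classmethod
    def of(cls, m: PssmMatrix) -> "MarginalSums":
        rows = m.scores.sum(axis=1)
        cols = m.scores.sum(axis=0)
        return cls(
            row_sums=rows,
            col_sums=cols,
            row_mean=float(rows.mean()),
            col_mean=float(cols.mean()),
        )


def pse_dim(xi: int) -> int:
    """Closed-form width of the classic pseudo-PSSM encoding."""
    return 20 + 20 * xi


def im_dim(xi: int) -> int:
    """Closed-form width of the column-lag encodings: (20+20*xi) - xi*(xi+1)/2."""
    return (20 + 20 * xi) - xi * (xi + 1) // 2


def column_means(m: PssmMatrix) -> np.ndarray:
    """Per-amino-acid average score: entry j = mean over rows of M[:, j]."""
    return m.scores.mean(axis=0)


def _check_norm(norm: NormRule) -> None:
    if norm not in _NORM_RULES:
        raise ParameterError(f"norm must be one of {_NORM_RULES}, got {norm!r}")


def _norm_factor(L: int, d: int, xi: int, norm: NormRule) -> float:
    if norm == "per_lag":
        return 1.0 / (L - d) if L > d else 1.0 / L
    if norm == "max_lag":
        return 1.0 / (L - xi) if L > xi else 1.0 / L
    return 1.0 / L


def psepssm(m: PssmMatrix, xi: int) -> FeatureVector:
    """Classic pseudo-PSSM with row-axis lags; dimension 20 + 20*xi."""
    L = m.length
    if not 0 <= xi < L:
        raise ParameterError(f"psepssm requires 0 <= xi < L; got xi={xi}, L={L}")
    M = m.scores
    parts = [column_means(m)]
    names = [f"mean_{aa}" for aa in m.column_order]
    for d in range(1, xi + 1):
        diff = M[:-d, :] - M[d:, :]
        parts.append((diff**2).mean(axis=0))
        names.extend(f"pse_d{d}_{aa}" for aa in m.column_order)
    return FeatureVector(
        id=m.id,
        values=np.concatenate(parts),
        encoder=Encoder.PSEPSSM,
        params={"xi": xi},
        names=tuple(names),
    )


def _column_lag_encode(
    m: PssmMatrix,
    xi: int,
    factor: Callable[[np.ndarray, np.ndarray], np.ndarray],
    encoder: Encoder,
    tag: str,
    norm: NormRule,
) -> FeatureVector:
    """Shared layout for the column-lag family: means, then (d, n) factors.

    Lags d ascend; within a lag, columns n ascend (n = 1..20-d). The
    per-pair factor is norm(d) * sum over rows of ``factor`` applied to
    columns n and n+d.
    """
    _check_norm(norm)
    L = m.length
    if not 0 <= xi <= 19:
        raise ParameterError(
            f"column-lag encoders require 0 <= xi <= 19 (20 columns); got xi={xi}"
        )
    M = m.scores
    parts = [column_means(m)]
    names = [f"mean_{aa}" for aa in m.column_order]
    for d in range(1, xi + 1):
        w = _norm_factor(L, d, xi, norm)
        per_pair = factor(M[:, : 20 - d], M[:, d:]).sum(axis=0) * w
        parts.append(per_pair)
        names.extend(
            f"{tag}_d{d}_{m.column_order[n]}{m.column_order[n + d]}"
            for n in range(20 - d)
        )
    return FeatureVector(
        id=m.id,
        values=np.concatenate(parts),
        encoder=encoder,
        params={"xi": xi, "norm": norm},
        names=tuple(names),
    )


def im_psepssm(m: PssmMatrix, xi: int, norm: NormRule = "per_lag") -> FeatureVector:
    """Column-lag squared-difference encoding; width (20+20*xi) - xi*(xi+1)/2."""
    return _column_lag_encode(
        m, xi, lambda a, b: (a - b) ** 2, Encoder.IM_PSEPSSM, "T", norm
    )


def t1_im_pssm(m: PssmMatrix, xi: int, norm: NormRule = "per_lag") -> FeatureVector:
    """Column-lag raw cross-product variant."""
    return _column_lag_encode(m, xi, lambda a, b: a * b, Encoder.T1, "T1", norm)


def t2_im_pssm(m: PssmMatrix, xi: int, norm: NormRule = "per_lag") -> FeatureVector:
    """Cross-products centred by the scalar mean of row sums."""
    r = MarginalSums.of(m).row_mean
    return _column_lag_encode(
        m, xi, lambda a, b: (a - r) * (b - r), Encoder.T2, "T2", norm
    )


def t3_im_pssm(m: PssmMatrix, xi: int, norm: NormRule = "per_lag") -> FeatureVector:
    """Cross-products centred by the scalar mean of column sums."""
    s = MarginalSums.of(m).col_mean
    return _column_lag_encode(
        m, xi, lambda a, b: (a - s) * (b - s), Encoder.T3, "T3", norm
    )


def bid_cc(m: PssmMatrix, S: int) -> FeatureVector:
    """Cross-column correlation table at residue distance S; 400 features.

    Entry (a, b) is sum over i = 1..L-S of M[i, a] * M[i+S, b]; the table
    is flattened row-major by (a, b), so both ordered pairs (a, b) and
    (b, a) appear for a single forward distance.
    """
    L = m.length
    if not 1 <= S < L:
        raise ParameterError(f"bid_cc requires 1 <= S < L; got S={S}, L={L}")
    M = m.scores
    table = M[:-S, :].T @ M[S:, :]  # (20, 20); row a, column b
    names = tuple(
        f"bidcc_S{S}_{a}{b}" for a in m.column_order for b in m.column_order
    )
    return FeatureVector(
        id=m.id,
        values=table.reshape(-1),
        encoder=Encoder.BIDCC,
        params={"S": S},
        names=names,
    )


def fuse(parts: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate feature vectors for one protein in the given order."""
    if not parts:
        raise UsageError("fuse requires at least one feature vector")
    ids = {p.id for p in parts}
    if len(ids) != 1:
        raise UsageError(f"fuse requires a single protein id, got {sorted(ids)}")
    names: tuple[str, ...] | None
    if all(p.names is not None for p in parts):
        names = tuple(n for p in parts for n in p.names)  # type: ignore[union-attr]
    else:
        names = None
    return FeatureVector(
        id=parts[0].id,
        values=np.concatenate([p.values for p in parts]),
        encoder=Encoder.BIM_PSSM,
        params={"parts": tuple((p.encoder.value, dict(p.params)) for p in parts)},
        names=names,
    )


_ENCODER_FNS: dict[Encoder, Callable[..., FeatureVector]] = {
    Encoder.PSEPSSM: psepssm,
    Encoder.IM_PSEPSSM: im_psepssm,
    Encoder.T1: t1_im_pssm,
    Encoder.T2: t2_im_pssm,
    Encoder.T3: t3_im_pssm,
    Encoder.BIDCC: bid_cc,
}


def encode_one(
    m: PssmMatrix,
    encoder: Encoder | str,
    xi: int | None = None,
    S: int | None = None,
    norm: NormRule = "per_lag",
) -> FeatureVector:
    """Apply a named encoder (or the BIM_PSSM fusion) to one matrix."""
    encoder = Encoder(encoder)
    if encoder is Encoder.BIM_PSSM:
        if xi is None or S is None:
            raise ParameterError("BIM_PSSM fusion needs both xi and S")
        return fuse([im_psepssm(m, xi, norm=norm), bid_cc(m, S)])
    if encoder is Encoder.BIDCC:
        if S is None:
            raise ParameterError("BIDCC needs the distance parameter S")
        return bid_cc(m, S)
    if xi is None:
        raise ParameterError(f"{encoder.value} needs the lag parameter xi")
    fn = _ENCODER_FNS[encoder]
    if encoder is Encoder.PSEPSSM:
        return fn(m, xi)
    return fn(m, xi, norm=norm)


def encode_collection(
    matrices: Iterable[PssmMatrix],
    encoder: Encoder | str,
    xi: int | None = None,
    S: int | None = None,
    norm: NormRule = "per_lag",
) -> pd.DataFrame:
    """Encode a collection into a feature matrix, one row per protein.

    Row order follows the input; the index holds protein ids. Any matrix
    violating the encoder's precondition aborts with an error naming it.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    names: tuple[str, ...] | None = None
    for m in matrices:
        try:
            fv = encode_one(m, encoder, xi=xi, S=S, norm=norm)
        except ParameterError as exc:
            raise ParameterError(f"protein {m.id!r}: {exc}") from exc
        if names is None:
            names = fv.names
        rows.append(fv.values)
        ids.append(m.id)
    if not rows:
        raise ParameterError("encode_collection received no matrices")
    cols = list(names) if names is not None else None
    return pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"), columns=cols)
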