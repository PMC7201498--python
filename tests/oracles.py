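"""Independent naive reference implementations used only by tests.

Everything here is deliberately written as plain Python loops, with no
imports from the package's computational paths, so that agreement with
the package is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_column_means(M):
    L, _ = M.shape
    return [sum(M[i][j] for i in range(L)) / L for j in range(20)]


def naive_psepssm(M, xi):
    L = M.shape[0]
    out = list(naive_column_means(M))
    for d in range(1, xi + 1):
        for j in range(20):
            s = sum((M[i][j] - M[i + d][j]) ** 2 for i in range(L - d))
            out.append(s / (L - d))
    return out


def _naive_column_lag(M, xi, pair_fn, norm="per_lag"):
    L = M.shape[0]
    out = list(naive_column_means(M))
    for d in range(1, xi + 1):
        if norm == "per_lag":
            w = 1.0 / (L - d) if L > d else 1.0 / L
        elif norm == "max_lag":
            w = 1.0 / (L - xi) if L > xi else 1.0 / L
        else:
            w = 1.0 / L
        for n in range(20 - d):
            s = sum(pair_fn(M[m][n], M[m][n + d]) for m in range(L))
            out.append(w * s)
    return out


def naive_im_psepssm(M, xi, norm="per_lag"):
    return _naive_column_lag(M, xi, lambda a, b: (a - b) ** 2, norm)


def naive_t1(M, xi, norm="per_lag"):
    return _naive_column_lag(M, xi, lambda a, b: a * b, norm)


def naive_t2(M, xi, norm="per_lag"):
    L = M.shape[0]
    row_sums = [sum(M[i][j] for j in range(20)) for i in range(L)]
    r = sum(row_sums) / L
    return _naive_column_lag(M, xi, lambda a, b: (a - r) * (b - r), norm)


def naive_t3(M, xi, norm="per_lag"):
    col_sums = [sum(M[i][j] for i in range(M.shape[0])) for j in range(20)]
    s = sum(col_sums) / 20
    return _naive_column_lag(M, xi, lambda a, b: (a - s) * (b - s), norm)


def naive_bidcc(M, S):
    L = M.shape[0]
    out = []
    for a in range(20):
        for b in range(20):
            out.append(sum(M[i][a] * M[i + S][b] for i in range(L - S)))
    return out


def naive_metrics(y_true, y_pred):
    """Per-class one-vs-rest Sn/Sp/F-m/Mcc/G-mean plus OA; None = undefined."""
    labels = sorted(set(list(y_true)) | set(list(y_pred)), key=str)
    n = len(y_true)
    per_class = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        tn = n - tp - fp - fn
        sn = tp / (tp + fn) if tp + fn else None
        sp = tn / (tn + fp) if tn + fp else None
        prec = tp / (tp + fp) if tp + fp else None
        fm = (
            2 * prec * sn / (prec + sn)
            if prec is not None and sn is not None and prec + sn
            else None
        )
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else None
        gm = math.sqrt(sn * sp) if sn is not None and sp is not None else None
        per_class[lab] = {"Sn": sn, "Sp": sp, "F-m": fm, "Mcc": mcc, "G-mean": gm}
    oa = sum(1 for t, p in zip(y_true, y_pred) if t == p) / n
    return per_class, oa


def naive_enn_keep(X, y, n_neighbors=3):
    """Boolean keep-mask from a brute-force k-NN majority vote."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    keep = []
    for i in range(n):
        d = [(float(np.sum((X[i] - X[j]) ** 2)), j) for j in range(n) if j != i]
        d.sort()
        nbrs = [j for _, j in d[:n_neighbors]]
        disagree = sum(1 for j in nbrs if y[j] != y[i])
        keep.append(disagree < (n_neighbors // 2) + 1)
    return np.array(keep)
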