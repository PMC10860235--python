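"""Dual-discretization association rules on expression data (the WLAR method).

Each gene's samples are quantile-discretized twice — into 4 bins split at
the 25/50/75% ranks and into 2 bins split at the 50% rank — and a directed
rule A -> B is scored per discretization by

    confidence(A -> B) = n(A = B  and  A > min(A)  and  B > min(B)) / n(A > min(A))
    support(A -> B)    = n(A > min(A)) + n(B > min(B))

where "A = B" compares discretized bins, min() is bin 1, and n() counts
samples.  Confidence and support are summed across the two discretizations,
and rules with summed confidence > 0.6 and summed support > 30 are
retained.  The direction points from the potential driver gene to the
potential driven gene; both directions of a pair are evaluated
independently.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

RULE_COLUMNS = [
    "lhs", "rhs", "conf2", "conf4", "conf_sum", "supp2", "supp4", "supp_sum",
]

_CUTS = {2: (0.5,), 4: (0.25, 0.5, 0.75)}


def drop_sparse_samples(X: pd.DataFrame) -> pd.DataFrame:
    """Remove samples with fewer than two strictly positive genes."""
    keep = (X > 0).sum(axis=0) >= 2
    if not keep.any():
        raise ValueError("every sample has < 2 genes with expression > 0")
    return X.loc[:, keep]


def discretize(X: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Per-gene quantile discretization into 2 or 4 bins.

    Samples are ranked ascending with average ranks on ties; the bin is one
    plus the number of quantile cuts strictly below the sample's rank
    fraction (a sample exactly at a cut stays in the lower bin).  Values
    equal to the gene minimum are always bin 1, so a constant gene is all
    bin 1.
    """
    if n_bins not in _CUTS:
        raise ValueError("n_bins must be 2 or 4")
    if X.shape[1] < n_bins:
        raise ValueError(f"need at least {n_bins} samples for {n_bins} bins")
    cuts = np.asarray(_CUTS[n_bins])
    values = X.to_numpy(dtype=float)
    n = values.shape[1]
    out = np.empty_like(values, dtype=int)
    for i in range(values.shape[0]):
        ranks = stats.rankdata(values[i], method="average")
        frac = ranks / n
        bins = 1 + (frac[:, None] > cuts[None, :]).sum(axis=1)
        bins[values[i] == values[i].min()] = 1
        out[i] = bins
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def rule_confidence(a: np.ndarray, b: np.ndarray) -> float:
    """Confidence of the discretized rule a -> b; empty denominator gives 0."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("discretized rows differ in length")
    denom = int((a > 1).sum())
    if denom == 0:
        return 0.0
    num = int(((a == b) & (a > 1) & (b > 1)).sum())
    return num / denom


def rule_support(a: np.ndarray, b: np.ndarray) -> int:
    """Support of a -> b: n(a > min) + n(b > min); symmetric in (a, b)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("discretized rows differ in length")
    return int((a > 1).sum() + (b > 1).sum())


def spearman_prefilter(
    X: pd.DataFrame, genes: Sequence[str], min_abs_rho: float
) -> list[tuple[str, str]]:
    """Ordered pairs whose |Spearman correlation| reaches the threshold."""
    sub = X.loc[list(genes)]
    rho = stats.spearmanr(sub.to_numpy(dtype=float), axis=1)[0]
    rho = np.atleast_2d(rho)
    pairs = []
    for i, j in permutations(range(len(genes)), 2):
        if abs(rho[i, j]) >= min_abs_rho:
            pairs.append((genes[i], genes[j]))
    return pairs


def compute_wlar(
    X: pd.DataFrame,
    candidate_pairs: Sequence[tuple[str, str]] | None = None,
    conf_cut: float = 0.6,
    supp_cut: float = 30.0,
) -> pd.DataFrame:
    """All retained WLAR rules over the candidate ordered gene pairs.

    Defaults to every ordered pair of genes in the matrix.  Sparse samples
    are dropped first; per pair the 2-bin and 4-bin confidence and support
    are computed and summed; rules with summed confidence strictly above
    conf_cut and summed support strictly above supp_cut are returned.
    """
    X = drop_sparse_samples(X)
    if candidate_pairs is None:
        genes = list(X.index)
        candidate_pairs = list(permutations(genes, 2))
    else:
        missing = {g for pair in candidate_pairs for g in pair} - set(X.index)
        if missing:
            raise KeyError(f"candidate genes absent from matrix: {sorted(missing)}")

    d2 = discretize(X, 2)
    d4 = discretize(X, 4)
    arr2 = {g: d2.loc[g].to_numpy() for g in d2.index}
    arr4 = {g: d4.loc[g].to_numpy() for g in d4.index}

    rows = []
    for lhs, rhs in candidate_pairs:
        c2 = rule_confidence(arr2[lhs], arr2[rhs])
        c4 = rule_confidence(arr4[lhs], arr4[rhs])
        s2 = rule_support(arr2[lhs], arr2[rhs])
        s4 = rule_support(arr4[lhs], arr4[rhs])
        conf_sum = c2 + c4
        supp_sum = s2 + s4
        if conf_sum > conf_cut and supp_sum > supp_cut:
            rows.append((lhs, rhs, c2, c4, conf_sum, s2, s4, supp_sum))
    return pd.DataFrame(rows, columns=RULE_COLUMNS)
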