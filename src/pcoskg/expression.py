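"""Expression-matrix handling: filtering, differential testing, specific-gene
calling, and dataset merging with quantile normalization.

Matrices are pandas DataFrames indexed by gene id (rows) with sample-id
columns, tpm-scale nonnegative values.  Labels are a sample -> group Series
over {NM, NA, HA} (fine) or {NM, PCOS} (coarse validation sets).

The differential test is the classic equal-variance two-sample Student's t,
two-sided, on the raw expression values; p-values are deliberately not
multiplicity-adjusted — the downstream gene calls apply the raw p < 0.05
threshold.  Fold change is the ratio of raw group means.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def validate_matrix(X: pd.DataFrame) -> None:
    if X.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if X.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    values = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or (values < 0).any():
        raise ValueError("expression values must be finite and nonnegative")


def validate_labels(X: pd.DataFrame, labels: pd.Series) -> None:
    missing = set(X.columns) - set(labels.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)}")


def filter_low_expression(X: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Drop genes whose row mean is below the tpm threshold (strict '<')."""
    if X.empty:
        raise ValueError("empty expression matrix")
    kept = X[X.mean(axis=1) >= threshold]
    if kept.empty:
        warnings.warn("low-expression filter removed every gene")
    return kept


def differential_test(
    X: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene two-sided equal-variance t-test and fold change mean(A)/mean(B).

    Zero-variance genes follow a deterministic convention: equal group means
    give p = 1; unequal means with zero pooled variance give p = 0.  A zero
    denominator mean yields an infinite fold change (treated as exceeding any
    upper cut); 0/0 is defined as 1 (equal means).
    """
    if len(X) == 0:
        raise ValueError("empty expression matrix")
    validate_labels(X, labels)
    cols_a = labels.index[labels == group_a].intersection(X.columns)
    cols_b = labels.index[labels == group_b].intersection(X.columns)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"groups {group_a!r}/{group_b!r} need >= 2 samples each "
            f"(got {len(cols_a)}, {len(cols_b)})"
        )
    a = X[cols_a].to_numpy(dtype=float)
    b = X[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        fc = mean_a / mean_b
    fc = np.where(np.isnan(fc), 1.0, fc)

    pooled_zero = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(mean_a, mean_b, rtol=0.0, atol=0.0) | (mean_a == mean_b)
    p = np.asarray(p, dtype=float)
    p[pooled_zero & equal_means] = 1.0
    p[pooled_zero & ~equal_means] = 0.0
    p[np.isnan(p)] = 1.0

    return pd.DataFrame({"p_value": p, "fold_change": fc}, index=X.index)


def call_differentiated(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    p_cut: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> set[str]:
    """Genes differentiated in either comparison.

    A gene qualifies when, in d1 or d2, p < p_cut and the fold change is
    > fc_hi or < fc_lo (all strict, matching the stated thresholds).
    """
    if set(d1.index) != set(d2.index):
        raise ValueError("differential results cover different gene sets")
    d2 = d2.reindex(d1.index)

    def hit(d):
        return (d["p_value"] < p_cut) & (
            (d["fold_change"] > fc_hi) | (d["fold_change"] < fc_lo)
        )

    mask = hit(d1) | hit(d2)
    return set(d1.index[mask])


def _comparison_hit(d: pd.DataFrame, p_cut, fc_hi, fc_lo) -> pd.Series:
    return (d["p_value"] < p_cut) & (
        (d["fold_change"] > fc_hi) | (d["fold_change"] < fc_lo)
    )


def call_specific(
    X: pd.DataFrame,
    labels: pd.Series,
    target: str,
    p_cut: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> set[str]:
    """Subtype-specific genes for ``target`` in {NA, HA}.

    A gene is specific when (a) its mean in the target group strictly exceeds
    its mean in each of the other two groups (a tie yields no winner), and
    (b) it meets the differential criteria in both the target-vs-NM and the
    target-vs-other-PCOS comparison.
    """
    if target not in ("NA", "HA"):
        raise ValueError("target must be 'NA' or 'HA'")
    other = "HA" if target == "NA" else "NA"
    validate_labels(X, labels)
    groups = set(labels.loc[list(X.columns)])
    if not {"NM", "NA", "HA"} <= groups:
        raise ValueError("all three fine groups must be present")

    means = {
        g: X[labels.index[labels == g].intersection(X.columns)].mean(axis=1)
        for g in ("NM", "NA", "HA")
    }
    highest = (means[target] > means[other]) & (means[target] > means["NM"])

    d_nm = differential_test(X, labels, target, "NM")
    d_other = differential_test(X, labels, target, other)
    both = _comparison_hit(d_nm, p_cut, fc_hi, fc_lo) & _comparison_hit(
        d_other, p_cut, fc_hi, fc_lo
    )
    return set(X.index[highest & both])


def quantile_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize each sample to the pooled reference distribution.

    The reference is the across-sample mean of sorted value vectors; ties
    within a sample receive the mean of their tied reference quantiles.
    """
    values = X.to_numpy(dtype=float)
    n = values.shape[0]
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def merge_and_normalize(
    X_list: Sequence[pd.DataFrame],
    labels_list: Sequence[pd.Series],
    prefixes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Merge datasets on their shared genes and quantile-normalize.

    Sample ids are disambiguated with a per-dataset prefix; gene sets are
    intersected; the merged matrix is normalized so every sample shares the
    pooled empirical distribution.
    """
    if not X_list:
        raise ValueError("need at least one matrix")
    if len(X_list) != len(labels_list):
        raise ValueError("matrix and label lists differ in length")
    if prefixes is None:
        prefixes = [f"ds{i + 1}" for i in range(len(X_list))]
    prefixes = list(prefixes)

    common = X_list[0].index
    for X in X_list[1:]:
        common = common.intersection(X.index)
    if len(common) == 0:
        raise ValueError("no genes shared between datasets")
    common = common.sort_values()

    parts, label_parts = [], []
    for X, lab, pre in zip(X_list, labels_list, prefixes):
        validate_labels(X, lab)
        sub = X.loc[common].copy()
        sub.columns = [f"{pre}:{c}" for c in sub.columns]
        parts.append(sub)
        lab = lab.loc[list(X.columns)].copy()
        lab.index = [f"{pre}:{c}" for c in lab.index]
        label_parts.append(lab)
    merged = pd.concat(parts, axis=1)
    labels = pd.concat(label_parts)
    labels.name = "group"
    return quantile_normalize(merged), labels
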