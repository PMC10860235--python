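"""Randomized search for rank-based classification marker sets.

Every gene is first assigned to the group (NM / NA / HA) where its mean
expression is highest.  Each search iteration draws a random set of 10–50
genes per group; a sample is predicted as the group whose gene set has the
highest mean within-sample expression rank (rank 1 = lowest expression,
average ranks on ties; a tied best group yields no call, which counts as a
misclassification).  Triples that classify every training sample correctly
are reserved, and the best triple is the one with the highest mean matching
rate on coarsely labelled validation datasets, where a prediction of NA or
HA counts as matching an actual PCOS label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import validate_labels

GROUPS = ("NM", "NA", "HA")


@dataclass(frozen=True)
class MarkerSetTriple:
    """Pairwise-disjoint NM / NA / HA marker gene sets."""

    nm: frozenset[str]
    na: frozenset[str]
    ha: frozenset[str]

    def __post_init__(self):
        if self.nm & self.na or self.nm & self.ha or self.na & self.ha:
            raise ValueError("marker sets must be pairwise disjoint")

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {"NM": self.nm, "NA": self.na, "HA": self.ha}

    def total_size(self) -> int:
        return len(self.nm) + len(self.na) + len(self.ha)

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.nm)), tuple(sorted(self.na)), tuple(sorted(self.ha)))


@dataclass
class SearchResult:
    """Reserved triples (perfect on training) and their validation rates."""

    reserved: list[MarkerSetTriple] = field(default_factory=list)
    n_iter: int = 0
    rates: list[float] = field(default_factory=list)
    best: MarkerSetTriple | None = None


def assign_gene_groups(X: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Gene -> group of highest mean expression; ties leave the gene out."""
    validate_labels(X, labels)
    means = pd.DataFrame(
        {
            g: X[labels.index[labels == g].intersection(X.columns)].mean(axis=1)
            for g in GROUPS
        }
    )
    values = means.to_numpy()
    best = values.max(axis=1, keepdims=True)
    winners = (values == best).sum(axis=1)
    assigned = means.idxmax(axis=1)[winners == 1]
    assigned.name = "group"
    return assigned


def rank_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Within-sample ascending expression ranks (average ranks on ties)."""
    ranks = np.apply_along_axis(
        lambda col: stats.rankdata(col, method="average"), 0, X.to_numpy(dtype=float)
    )
    return pd.DataFrame(ranks, index=X.index, columns=X.columns)


def predict_sample(
    sample_ranks: Mapping[str, float], triple: MarkerSetTriple
) -> str | None:
    """Group with the highest mean rank over its marker set; tie -> no call."""
    means = {}
    for group, genes in triple.as_dict().items():
        try:
            means[group] = float(np.mean([sample_ranks[g] for g in genes]))
        except KeyError as exc:
            raise KeyError(f"marker gene {exc.args[0]!r} absent from matrix") from exc
    best = max(means.values())
    winners = [g for g, m in means.items() if m == best]
    return winners[0] if len(winners) == 1 else None


def predict_all(
    ranks: pd.DataFrame, triple: MarkerSetTriple
) -> dict[str, str | None]:
    missing = (triple.nm | triple.na | triple.ha) - set(ranks.index)
    if missing:
        raise KeyError(f"marker genes absent from matrix: {sorted(missing)}")
    out = {}
    for sample in ranks.columns:
        col = ranks[sample]
        means = {
            g: float(col.loc[list(genes)].mean())
            for g, genes in triple.as_dict().items()
        }
        best = max(means.values())
        winners = [g for g, m in means.items() if m == best]
        out[sample] = winners[0] if len(winners) == 1 else None
    return out


def matching_rate(
    predictions: Mapping[str, str | None], actual: pd.Series
) -> float:
    """Fraction of samples whose prediction matches the (possibly coarse) label.

    Against a coarse label, NA or HA predictions match 'PCOS' and NM matches
    'NM'; against fine labels the match is exact.  A no-call never matches.
    """
    missing = set(actual.index) - set(predictions)
    if missing:
        raise ValueError(f"predictions missing for samples: {sorted(missing)}")
    correct = 0
    for sample, truth in actual.items():
        pred = predictions[sample]
        if pred is None:
            continue
        if truth == "PCOS":
            correct += pred in ("NA", "HA")
        else:
            correct += pred == truth
    return correct / len(actual)


def search_marker_sets(
    X: pd.DataFrame,
    labels: pd.Series,
    n_iter: int,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> SearchResult:
    """Random search over marker-set triples; reserve perfect training triples.

    Per iteration, a set size is drawn independently per group, uniform on
    the configured range (clamped to the pool when the pool is smaller), and
    genes are sampled without replacement from that group's pool.  The triple
    is reserved iff every training sample is predicted as its own fine label.
    Deterministic given the seed.
    """
    size_min, size_max = size_range
    if size_min < 1 or size_max < size_min:
        raise ValueError("invalid size range")
    assignment = assign_gene_groups(X, labels)
    pools = {g: np.asarray(assignment.index[assignment == g]) for g in GROUPS}
    for g, pool in pools.items():
        if len(pool) == 0:
            raise ValueError(f"no genes assigned to group {g}")

    ranks = rank_matrix(X).to_numpy()
    gene_pos = {g: i for i, g in enumerate(X.index)}
    pool_idx = {g: np.array([gene_pos[x] for x in pools[g]]) for g in GROUPS}
    actual = labels.loc[list(X.columns)].to_numpy()
    actual_code = np.array([GROUPS.index(a) for a in actual])

    rng = np.random.default_rng(seed)
    result = SearchResult(n_iter=n_iter)
    for _ in range(n_iter):
        idx = {}
        for g in GROUPS:
            pool = pool_idx[g]
            hi = min(size_max, len(pool))
            lo = min(size_min, hi)
            size = int(rng.integers(lo, hi + 1))
            idx[g] = rng.choice(pool, size=size, replace=False)
        group_means = np.stack([ranks[idx[g]].mean(axis=0) for g in GROUPS])
        best = group_means.max(axis=0)
        is_best = group_means == best
        unique = is_best.sum(axis=0) == 1
        pred = group_means.argmax(axis=0)
        if np.all(unique & (pred == actual_code)):
            result.reserved.append(
                MarkerSetTriple(
                    nm=frozenset(X.index[idx["NM"]]),
                    na=frozenset(X.index[idx["NA"]]),
                    ha=frozenset(X.index[idx["HA"]]),
                )
            )
    return result


def select_best(
    result: SearchResult,
    validation: Sequence[tuple[pd.DataFrame, pd.Series]],
) -> MarkerSetTriple:
    """Reserved triple with the highest mean validation matching rate.

    Ties break toward the smallest total gene count, then lexicographic gene
    lists.  Validation matrices missing some marker genes are scored on the
    shared genes only (with a warning) so public datasets with narrower gene
    coverage remain usable.
    """
    if not result.reserved:
        raise ValueError(
            "no reserved triples; increase the iteration count of the search"
        )
    cache = []
    for Xv, lab in validation:
        rk = rank_matrix(Xv).to_numpy()
        pos = {g: i for i, g in enumerate(Xv.index)}
        actual = lab.loc[list(Xv.columns)].to_numpy()
        cache.append((rk, pos, actual))

    def score(triple: MarkerSetTriple) -> float:
        rates = []
        for rk, pos, actual in cache:
            idx = {
                g: np.array([pos[x] for x in genes if x in pos], dtype=int)
                for g, genes in triple.as_dict().items()
            }
            if any(len(v) == 0 for v in idx.values()):
                warnings.warn("a marker set is entirely absent from a validation set")
                rates.append(0.0)
                continue
            n_missing = triple.total_size() - sum(len(v) for v in idx.values())
            if n_missing:
                warnings.warn(
                    f"{n_missing} marker genes absent from a validation set"
                )
            means = np.stack([rk[idx[g]].mean(axis=0) for g in GROUPS])
            best = means.max(axis=0)
            unique = (means == best).sum(axis=0) == 1
            pred = means.argmax(axis=0)
            correct = 0
            for j, truth in enumerate(actual):
                if not unique[j]:
                    continue
                name = GROUPS[pred[j]]
                if truth == "PCOS":
                    correct += name in ("NA", "HA")
                else:
                    correct += name == truth
            rates.append(correct / len(actual))
        return float(np.mean(rates)) if rates else 0.0

    scored = [(score(t), t) for t in result.reserved]
    result.rates = [s for s, _ in scored]
    best_rate = max(s for s, _ in scored)
    candidates = [t for s, t in scored if s == best_rate]
    candidates.sort(key=lambda t: (t.total_size(), t.sort_key()))
    result.best = candidates[0]
    return result.best
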