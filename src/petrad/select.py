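"""Feature selection: minimum-redundancy maximum-relevance (MRMR) ranking
to a top fraction, followed by greedy Pearson-correlation pruning.

MRMR is the greedy mutual-information-quotient variant: the first feature
is the one with the largest mutual information (MI) with the class label;
each subsequent pick maximizes relevance / redundancy, where relevance is
MI with the label and redundancy the mean MI with the already-selected
features.  MI is estimated on features discretized into quantile bins
(default 4).  Coarse quantile binning saturates: every feature whose bins
predict the label perfectly attains exactly the label entropy, so exact
relevance ties are common on well-separated data.  Ties are therefore
broken by re-estimating MI at double resolution (8 bins); remaining ties
break by feature-table column order, so the ranking is deterministic.

Pruning then walks the selected features in MRMR order and keeps a feature
iff its absolute Pearson correlation with every feature kept so far is
strictly below the threshold (default 0.30); the kept set's correlation
matrix is returned as a certificate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

__all__ = [
    "SelectionResult",
    "mrmr_rank",
    "select_top_fraction",
    "pearson_prune",
    "select_features",
    "quantile_bin",
]

MI_BINS = 4


@dataclass
class SelectionResult:
    """MRMR ranking with, after pruning, the kept subset and its
    correlation certificate."""

    ranked_features: list[str]
    scores: dict[str, float]
    k_selected: int | None = None
    kept_after_prune: list[str] = field(default_factory=list)
    correlation_matrix: pd.DataFrame | None = None
    dropped_nan_features: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        if self.k_selected is None:
            return list(self.ranked_features)
        return self.ranked_features[: self.k_selected]


def quantile_bin(x: np.ndarray, n_bins: int = MI_BINS) -> np.ndarray:
    """Discretize a feature into quantile bins for MI estimation.

    Duplicate quantile edges (heavily tied features) collapse into fewer
    bins; a constant feature maps to a single bin (MI = 0).
    """
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(x, edges)


def _drop_nan_features(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    bad = table.columns[table.isna().any(axis=0)].tolist()
    return table.drop(columns=bad), bad


def mrmr_rank(table: pd.DataFrame, labels: np.ndarray, k: int | None = None) -> SelectionResult:
    """Greedy MRMR ranking of (up to k) features.

    Features containing NaN in any subject are dropped before ranking and
    reported in ``dropped_nan_features``.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 subjects for MRMR ranking")
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("label count does not match subject count")
    table, dropped = _drop_nan_features(table)
    n_features = table.shape[1]
    if k is None:
        k = n_features
    if k > n_features:
        raise ValueError(f"k={k} exceeds {n_features} usable features")

    X = table.to_numpy(dtype=float)
    binned = [quantile_bin(X[:, j]) for j in range(n_features)]
    relevance = np.array([mutual_info_score(labels, b) for b in binned])
    # saturation tie-break: MI at double resolution, used only to order
    # features whose coarse relevance is exactly equal
    relevance_fine = np.array([
        mutual_info_score(labels, quantile_bin(X[:, j], 2 * MI_BINS))
        for j in range(n_features)
    ])

    mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(binned[a], binned[b])
        return mi_cache[key]

    remaining = list(range(n_features))
    order: list[int] = []
    scores: list[float] = []
    eps = 1e-12
    while remaining and len(order) < k:
        if not order:
            crit = relevance[remaining]
        else:
            crit = np.array([
                relevance[j] / max(np.mean([pair_mi(j, s) for s in order]), eps)
                for j in remaining
            ])
        top = crit.max()
        tied = np.flatnonzero(crit == top)
        if len(tied) > 1:  # resolve exact ties at finer resolution
            fine = relevance_fine[np.asarray(remaining)[tied]]
            tied = tied[fine == fine.max()]
        best = int(tied[0])  # remaining ties: column order
        order.append(remaining.pop(best))
        scores.append(float(top))

    names = [table.columns[j] for j in order]
    return SelectionResult(
        ranked_features=names,
        scores=dict(zip(names, scores)),
        dropped_nan_features=dropped,
    )


def select_top_fraction(result: SelectionResult, fraction: float = 0.10,
                        n_total: int | None = None) -> SelectionResult:
    """Fix k at floor(fraction x total feature count).

    ``n_total`` defaults to the number of ranked features; pass the full
    manifest size when NaN features were dropped before ranking.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    total = n_total if n_total is not None else len(result.ranked_features)
    result.k_selected = min(math.floor(fraction * total), len(result.ranked_features))
    return result


def pearson_prune(result: SelectionResult, table: pd.DataFrame,
                  r_threshold: float = 0.30) -> SelectionResult:
    """Greedy prune of the selected set: keep a feature iff max |r| with
    every already-kept feature is strictly below ``r_threshold``."""
    kept: list[str] = []
    for name in result.selected:
        x = table[name].to_numpy(dtype=float)
        ok = True
        for other in kept:
            r = np.corrcoef(x, table[other].to_numpy(dtype=float))[0, 1]
            if not np.isfinite(r) or abs(r) >= r_threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    corr = table[kept].corr(method="pearson")
    off_diag = corr.to_numpy()[~np.eye(len(kept), dtype=bool)]
    if off_diag.size and np.nanmax(np.abs(off_diag)) >= r_threshold:
        raise AssertionError("correlation certificate violated after pruning")
    result.kept_after_prune = kept
    result.correlation_matrix = corr
    return result


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    fraction: float = 0.10,
    r_threshold: float = 0.30,
) -> SelectionResult:
    """Full selection: MRMR rank, keep the top fraction of the manifest,
    prune by pairwise Pearson correlation."""
    result = mrmr_rank(table, labels)
    result = select_top_fraction(result, fraction, n_total=table.shape[1])
    return pearson_prune(result, table, r_threshold)
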