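"""Information-gain feature ranking and incremental subset construction.

Each feature is scored by the reduction in class entropy (bits) achieved by
conditioning on a discretized version of the feature. Continuous features
are discretized by recursive Fayyad-Irani minimum-description-length (MDL)
partitioning; a feature on which MDL finds no acceptable cut is irrelevant
and scores exactly 0. Features with at most two distinct values are treated
as already discrete, so a binary indicator is scored by its raw entropy
gain. For binary labels all scores lie in [0, 1], and because cuts depend
only on the ordering of values, the score is invariant under strictly
monotone transforms of a feature.

Zero-score features are pruned before ranking; on arginine-centered window
data every per-residue feature at the central position is constant and is
pruned this way. Ties in the ranking are broken by canonical feature-name
order (family-major, position-minor) via a stable sort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd


def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits of a label vector."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray) -> Tuple[float, int]:
    """Best binary cut of a sorted block: (info gain, split index).

    ``values`` must be sorted ascending. Returns the gain of the best cut
    and the index i such that the left block is ``[:i]``; (0, -1) if no cut
    exists (all values equal).
    """
    n = values.size
    base = _entropy(labels)
    best_gain, best_i = 0.0, -1
    # candidate cuts only between distinct adjacent values
    for i in range(1, n):
        if values[i] == values[i - 1]:
            continue
        gain = base - (
            i * _entropy(labels[:i]) + (n - i) * _entropy(labels[i:])
        ) / n
        if gain > best_gain:
            best_gain, best_i = gain, i
    return best_gain, best_i


def _mdl_accepts(values: np.ndarray, labels: np.ndarray, i: int, gain: float) -> bool:
    """Fayyad-Irani MDL stopping criterion for a proposed cut."""
    n = values.size
    k = np.unique(labels).size
    k1 = np.unique(labels[:i]).size
    k2 = np.unique(labels[i:]).size
    delta = np.log2(3.0**k - 2.0) - (
        k * _entropy(labels)
        - k1 * _entropy(labels[:i])
        - k2 * _entropy(labels[i:])
    )
    return gain > (np.log2(n - 1.0) + delta) / n


def _mdlp_bins(values: np.ndarray, labels: np.ndarray) -> List[np.ndarray]:
    """Recursive MDL partition; returns the list of label blocks."""
    gain, i = _best_cut(values, labels)
    if i < 0 or not _mdl_accepts(values, labels, i, gain):
        return [labels]
    return _mdlp_bins(values[:i], labels[:i]) + _mdlp_bins(values[i:], labels[i:])


def info_gain(values: Sequence[float], labels: Sequence[int]) -> float:
    """Information gain (bits) of one feature for a binary classification.

    Continuous features are MDL-discretized first; a feature MDL cannot cut
    (including any constant feature) scores exactly 0.0.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length vectors")
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")

    distinct = np.unique(v)
    if distinct.size == 1:
        return 0.0
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    if distinct.size <= 2:
        # already-discrete indicator: score by raw entropy gain
        i = int(np.searchsorted(v, distinct[1]))
        blocks = [y[:i], y[i:]]
    else:
        blocks = _mdlp_bins(v, y)
        if len(blocks) == 1:
            return 0.0
    n = y.size
    conditional = sum(b.size * _entropy(b) for b in blocks) / n
    return float(_entropy(y) - conditional)


@dataclass
class FeatureRanking:
    """Features ordered by descending information gain.

    ``entries`` excludes the zero-gain features, which are listed in
    ``pruned`` in canonical order.
    """

    entries: List[Tuple[str, float]]
    pruned: List[str]

    def names(self) -> List[str]:
        return [name for name, _ in self.entries]

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(self.entries, columns=["feature", "infogain"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        df.to_csv(path, sep="\t", index=False)


def rank_features(matrix: pd.DataFrame, labels: Sequence[int]) -> FeatureRanking:
    """Score every column of a feature matrix and rank by relevance.

    Zero-score (irrelevant) columns are pruned. The descending sort is
    stable, so equal scores keep the matrix's canonical column order.
    """
    y = np.asarray(labels)
    if len(matrix) != y.size:
        raise ValueError("matrix rows must match label length")
    scores = [(c, info_gain(matrix[c].to_numpy(), y)) for c in matrix.columns]
    pruned = [c for c, s in scores if s == 0.0]
    kept = [(c, s) for c, s in scores if s > 0.0]
    kept.sort(key=lambda e: -e[1])  # stable: ties keep column order
    return FeatureRanking(kept, pruned)


def incremental_subsets(
    ranking: FeatureRanking, step: int = 50
) -> List[List[str]]:
    """Nested prefixes of the ranking: sizes step, 2*step, ..., and the full
    retained set if it is not a multiple of ``step``."""
    if step < 1:
        raise ValueError("step must be >= 1")
    names = ranking.names()
    if not names:
        raise ValueError("empty ranking")
    sizes = list(range(step, len(names), step)) + [len(names)]
    return [names[:k] for k in sizes]


def subsets_to_json(subsets: List[List[str]], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(subsets, indent=1))
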