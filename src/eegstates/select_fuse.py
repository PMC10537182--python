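"""Minimum-redundancy feature ranking and cross-transform fusion.

Ranking is greedy mRMR in the MID (mutual-information difference) form:
the first pick maximises relevance I(f; y); every subsequent pick
maximises I(f; y) minus the mean mutual information with the already
selected features.  Mutual information is estimated on equal-frequency
discretised values (10 bins by default) and reported in bits.

Ranking operates on feature TYPES (the 27 names), aggregating over
channels: a type's relevance is the mean I(column; label) over its channel
columns, and the redundancy between two types is the mean MI between their
same-channel column pairs.  Per-column ranking of all channels x features
columns is available via ``granularity="column"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .feature_bank import FeatureMatrix

LN2 = np.log(2.0)


def discretize_equal_frequency(col: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile-based binning; a constant column collapses to one bin."""
    edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, col, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in bits between two discrete sequences."""
    return mutual_info_score(a, b) / LN2


@dataclass
class FeatureRanking:
    """Feature types ordered by non-increasing mRMR score at selection time."""

    order: list[str]
    scores: dict[str, float]
    transform: str = ""
    subband: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.order,
                "score": [self.scores[f] for f in self.order],
                "rank": np.arange(1, len(self.order) + 1),
                "transform": self.transform,
                "subband": self.subband,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_features(
    fm: FeatureMatrix,
    n_bins: int = 10,
    granularity: str = "type",
) -> FeatureRanking:
    """Greedy mRMR (MID) ranking of the feature types in ``fm``.

    Constant columns carry zero relevance and end up last.  Ties are broken
    by the printed-list feature order (the column order of ``fm``).
    """
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("ranking needs at least two classes")
    y = pd.factorize(fm.labels)[0]
    disc = np.column_stack(
        [discretize_equal_frequency(fm.values[:, j], n_bins) for j in range(fm.n_columns)]
    )

    if granularity == "column":
        groups = {f"col{j}": [j] for j in range(fm.n_columns)}
    elif granularity == "type":
        names = fm.feature_names
        groups = {
            name: list(np.flatnonzero(fm.column_meta["feature"].to_numpy() == name))
            for name in names
        }
    else:
        raise ValueError("granularity must be 'type' or 'column'")

    # constant feature types carry no information: relevance 0, forced last
    constant = [
        name
        for name, cols in groups.items()
        if all(np.ptp(fm.values[:, j]) == 0 for j in cols)
    ]
    for name in constant:
        groups.pop(name)

    relevance = {
        name: float(np.mean([mutual_information(disc[:, j], y) for j in cols]))
        for name, cols in groups.items()
    }

    red_cache: dict[tuple[str, str], float] = {}

    def redundancy(f: str, s: str) -> float:
        key = (f, s) if f < s else (s, f)
        if key not in red_cache:
            red_cache[key] = float(
                np.mean(
                    [
                        mutual_information(disc[:, jf], disc[:, js])
                        for jf, js in zip(groups[f], groups[s])
                    ]
                )
            )
        return red_cache[key]

    remaining = list(groups)
    order: list[str] = []
    scores: dict[str, float] = {}
    while remaining:
        if order:
            cand = [
                relevance[f] - np.mean([redundancy(f, s) for s in order])
                for f in remaining
            ]
        else:
            cand = [relevance[f] for f in remaining]
        best = int(np.argmax(cand))  # argmax keeps printed-list order on ties
        scores[remaining[best]] = float(cand[best])
        order.append(remaining.pop(best))

    floor = min(0.0, min(scores.values(), default=0.0))
    for name in constant:
        order.append(name)
        scores[name] = floor

    tr = fm.column_meta["transform"].iloc[0] if len(fm.column_meta) else ""
    sb = int(fm.column_meta["subband"].iloc[0]) if len(fm.column_meta) else 0
    return FeatureRanking(order, scores, transform=str(tr), subband=sb)


def select_top(fm: FeatureMatrix, ranking: FeatureRanking, k: int) -> FeatureMatrix:
    """Keep the k top-ranked feature types (all channels of each)."""
    n_types = len(ranking.order)
    if not 1 <= k <= n_types:
        raise ValueError(f"k must be in 1..{n_types}, got {k}")
    keep = ranking.order[:k]
    feat = fm.column_meta["feature"].to_numpy()
    idx = np.concatenate([np.flatnonzero(feat == name) for name in keep])
    return FeatureMatrix(
        fm.values[:, idx],
        fm.labels,
        fm.column_meta.iloc[idx].reset_index(drop=True),
    )


def fuse(
    matrices: list[tuple[FeatureMatrix, FeatureRanking]], k: int
) -> FeatureMatrix:
    """Column-wise concatenation of each transform's top-k feature types.

    All matrices must share segment order and labels; column provenance
    keeps each block traceable to its source transform and subband.
    """
    if not matrices:
        raise ValueError("nothing to fuse")
    first = matrices[0][0]
    for fm, _ in matrices[1:]:
        if fm.n_segments != first.n_segments or not np.array_equal(
            fm.labels, first.labels
        ):
            raise ValueError("segment order / labels differ between matrices")
    parts = [select_top(fm, ranking, k) for fm, ranking in matrices]
    return FeatureMatrix(
        np.hstack([p.values for p in parts]),
        first.labels,
        pd.concat([p.column_meta for p in parts], ignore_index=True),
    )
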