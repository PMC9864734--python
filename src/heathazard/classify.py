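"""Natural-breaks classification and the four-way spatiotemporal typology.

Spatial hazard (AH) and its temporal trend are each split into five ordered
classes with Fisher–Jenks natural breaks — the exact dynamic-programming
partition of sorted values minimizing the total within-class sum of squared
deviations (not the Jenks–Caspall heuristic).  Crossing the two label sets
yields four categories of interest:

1. high hazard and rapidly increasing,
2. high hazard, decreasing or unchanged,
3. low hazard and continually increasing,
4. others.

The default crossing table (overridable) places {high, medium-high} ×
{increased, slightly increased} in category 1, the remaining {high,
medium-high} rows in category 2, {middle, medium-low, low} × {increased,
slightly increased} in category 3, and everything else in category 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "SPATIAL_LABELS",
    "TEMPORAL_LABELS",
    "DEFAULT_CATEGORY_TABLE",
    "BreaksScheme",
    "jenks_breaks",
    "classify_values",
    "NaturalBreaksClassifier",
    "spatiotemporal_category",
    "classify_surfaces",
]

SPATIAL_LABELS = ("low", "medium-low", "middle", "medium-high", "high")
TEMPORAL_LABELS = ("decreased", "slightly decreased", "basically unchanged",
                   "slightly increased", "increased")

# (spatial, temporal) -> category 1..4; anything absent is category 4.
DEFAULT_CATEGORY_TABLE = {}
for _s in ("high", "medium-high"):
    for _t in ("increased", "slightly increased"):
        DEFAULT_CATEGORY_TABLE[(_s, _t)] = 1
    for _t in ("basically unchanged", "slightly decreased", "decreased"):
        DEFAULT_CATEGORY_TABLE[(_s, _t)] = 2
for _s in ("middle", "medium-low", "low"):
    for _t in ("increased", "slightly increased"):
        DEFAULT_CATEGORY_TABLE[(_s, _t)] = 3
del _s, _t


@dataclass(frozen=True)
class BreaksScheme:
    """A fitted natural-breaks scheme.

    ``cuts`` holds the k − 1 ascending class boundaries; intervals are
    right-closed (a value equal to a cut belongs to the lower class) and the
    lowest interval is unbounded below.
    """

    k: int
    cuts: tuple[float, ...]
    labels: tuple[str, ...]

    def assign(self, values) -> np.ndarray:
        """Integer class codes 0..k−1 (−1 for non-finite values)."""
        v = np.asarray(values, dtype=float)
        codes = np.searchsorted(np.asarray(self.cuts), v, side="left")
        return np.where(np.isfinite(v), codes, -1).astype(int)


def _fisher_jenks(sorted_vals: np.ndarray, k: int) -> list[int]:
    """Optimal split indices (starts of classes 2..k) for ascending data.

    Exact O(k·n²) dynamic program on prefix sums; within-class cost of
    v[i..j] is Σv² − (Σv)²/m.
    """
    n = sorted_vals.size
    s1 = np.concatenate(([0.0], np.cumsum(sorted_vals)))
    s2 = np.concatenate(([0.0], np.cumsum(sorted_vals ** 2)))

    def cost(i, j):  # inclusive endpoints, 0-based
        m = j - i + 1
        s = s1[j + 1] - s1[i]
        return s2[j + 1] - s2[i] - s * s / m

    best = np.full((k + 1, n), np.inf)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        best[1, j] = cost(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, n):
            # last class starts at i; earlier classes cover 0..i-1
            for i in range(c - 1, j + 1):
                val = best[c - 1, i - 1] + cost(i, j)
                if val < best[c, j]:
                    best[c, j] = val
                    back[c, j] = i
    splits = []
    j = n - 1
    for c in range(k, 1, -1):
        i = back[c, j]
        splits.append(i)
        j = i - 1
    return splits[::-1]


def jenks_breaks(values, k: int, labels=None) -> BreaksScheme:
    """Fisher–Jenks optimal k-class partition of a 1-D value set.

    Deterministic; requires at least k distinct finite values.  Cut points
    are the maxima of the lower classes, so classification is right-closed.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = np.sort(v[np.isfinite(v)])
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(v).size
    if n_distinct < k:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")
    if labels is not None and len(labels) != k:
        raise ValueError("need one label per class")
    if labels is None:
        labels = tuple(f"class {i + 1}" for i in range(k))
    if k == 1:
        return BreaksScheme(1, (), tuple(labels))
    splits = _fisher_jenks(v, k)
    cuts = tuple(float(v[i - 1]) for i in splits)
    return BreaksScheme(k, cuts, tuple(labels))


def classify_values(values, scheme: BreaksScheme) -> np.ndarray:
    """Class codes for ``values`` under a fitted scheme (−1 = masked)."""
    return scheme.assign(values)


class NaturalBreaksClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper: fit natural breaks, predict class codes.

    Parameters
    ----------
    k : int
        Number of classes (default 5, the spatial/temporal convention).
    labels : sequence of str, optional
        Ordered class names, low to high.

    Attributes
    ----------
    scheme_ : BreaksScheme
    breaks_ : tuple of float
        The k − 1 ascending cut points.
    """

    def __init__(self, k: int = 5, labels=None):
        self.k = k
        self.labels = labels

    def fit(self, X, y=None):
        self.scheme_ = jenks_breaks(np.asarray(X).ravel(), self.k,
                                    labels=self.labels)
        self.breaks_ = self.scheme_.cuts
        return self

    def predict(self, X):
        codes = self.scheme_.assign(np.asarray(X, dtype=float))
        return codes

    def predict_labels(self, X) -> np.ndarray:
        codes = self.predict(X)
        lab = np.asarray(self.scheme_.labels, dtype=object)
        out = np.where(codes >= 0, lab[np.clip(codes, 0, self.k - 1)], None)
        return out


def spatiotemporal_category(spatial: str, temporal: str, table=None) -> int:
    """Category 1–4 for one (spatial class, temporal class) pair."""
    if spatial not in SPATIAL_LABELS:
        raise KeyError(f"unknown spatial class {spatial!r}")
    if temporal not in TEMPORAL_LABELS:
        raise KeyError(f"unknown temporal class {temporal!r}")
    table = DEFAULT_CATEGORY_TABLE if table is None else table
    return table.get((spatial, temporal), 4)


def classify_surfaces(ah, slope, significant=None, k: int = 5, table=None):
    """Full spatiotemporal classification of hazard surfaces.

    Fits k natural-breaks classes on the AH values (spatial classes) and on
    the trend slopes (temporal classes), then crosses them into the four
    categories.  When a significance mask is given, the temporal breaks are
    fitted on significant pixels only and every non-significant pixel is
    labelled "basically unchanged".

    Returns a dict with ``spatial`` / ``temporal`` integer code arrays
    (−1 = masked), the two fitted schemes, and the ``category`` array
    (1–4, 0 where masked).
    """
    if k != 5:
        raise ValueError("the four-category table assumes 5 spatial and 5 "
                         "temporal classes")
    ah = np.asarray(ah, dtype=float)
    slope = np.asarray(slope, dtype=float)
    if ah.shape != slope.shape:
        raise ValueError("AH and slope surfaces must align")
    sp_scheme = jenks_breaks(ah[np.isfinite(ah)], k, labels=SPATIAL_LABELS)
    spatial = sp_scheme.assign(ah)

    if significant is None:
        fit_vals = slope[np.isfinite(slope)]
    else:
        significant = np.asarray(significant, dtype=bool)
        fit_vals = slope[significant & np.isfinite(slope)]
        if np.unique(fit_vals).size < k:
            # too few significant pixels to span k classes; fall back to all
            fit_vals = slope[np.isfinite(slope)]
    tm_scheme = jenks_breaks(fit_vals, k, labels=TEMPORAL_LABELS)
    temporal = tm_scheme.assign(slope)
    if significant is not None:
        unchanged = TEMPORAL_LABELS.index("basically unchanged")
        temporal = np.where(~significant & (temporal >= 0), unchanged, temporal)

    table = DEFAULT_CATEGORY_TABLE if table is None else table
    lut = np.full((k, k), 4, dtype=int)
    for (s, t), c in table.items():
        lut[SPATIAL_LABELS.index(s), TEMPORAL_LABELS.index(t)] = c
    valid = (spatial >= 0) & (temporal >= 0)
    category = np.zeros(ah.shape, dtype=int)
    category[valid] = lut[spatial[valid], temporal[valid]]
    return {"spatial": spatial, "temporal": temporal, "category": category,
            "spatial_scheme": sp_scheme, "temporal_scheme": tm_scheme}
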