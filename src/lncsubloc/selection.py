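"""Feature selection and feature-importance analysis.

mRMR (minimum-redundancy maximum-relevance) greedily ranks features by
class relevance (ANOVA F-statistic) while penalizing redundancy (mean
absolute Pearson correlation with already-selected features).  For the
selection criterion the F-statistic is mapped onto the correlation scale
(r = sqrt(F / (F + dof)), the point-biserial correlation), so the
difference criterion subtracts two commensurate [0, 1] quantities; an
exact duplicate of a selected feature (redundancy 1) therefore can never
outrank an informative independent feature.  A quotient criterion is also
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

DIFFERENCE = "difference"
QUOTIENT = "quotient"

DEFAULT_K_GRID = [10, 50, 100, 500, 1000, 1500, 2000]


@dataclass
class RankedFeatures:
    """mRMR selection order with per-feature relevance and redundancy."""

    ranking: List[Tuple[str, float, float]]  # (name, relevance F, redundancy at pick)
    k_grid: List[int] = field(default_factory=lambda: list(DEFAULT_K_GRID))

    @property
    def names(self) -> List[str]:
        return [name for name, _, _ in self.ranking]

    def top(self, k: int) -> List[str]:
        return self.names[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranking, columns=["name", "relevance", "redundancy"]
        ).assign(rank=lambda d: np.arange(1, len(d) + 1))


def _standardized(X: np.ndarray) -> np.ndarray:
    """Column-standardized copy; constant columns become all-zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0
    return Z


def mrmr_rank(
    X: pd.DataFrame,
    y: Sequence[int],
    k: int,
    criterion: str = DIFFERENCE,
) -> RankedFeatures:
    """Greedy mRMR ranking of the top *k* features.

    The first pick maximizes relevance; subsequent picks maximize the
    criterion (relevance minus, or divided by, mean |Pearson r| with the
    already-selected set).  Exact ties break lexicographically by name.
    Constant columns are kept in the pool (with a warning) but have zero
    relevance, so they rank last.
    """
    names = list(X.columns)
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} available features")
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("target must contain both classes")
    Xa = X.to_numpy(dtype=float)
    n = Xa.shape[0]
    constant = Xa.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) have zero relevance",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(Xa, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max / 4)
    dof = max(n - 2, 1)
    rel01 = np.sqrt(F / (F + dof))  # point-biserial |r|, same scale as redundancy
    Z = _standardized(Xa)

    # lexicographic tie-break: among equal scores prefer the smaller name
    name_rank = np.argsort(np.argsort(names))

    def pick(score: np.ndarray, available: np.ndarray) -> int:
        score = np.where(available, score, -np.inf)
        best = score.max()
        cand = np.flatnonzero(score == best)
        return int(cand[np.argmin(name_rank[cand])])

    available = np.ones(len(names), dtype=bool)
    redundancy_sum = np.zeros(len(names))
    ranking: List[Tuple[str, float, float]] = []
    first = pick(rel01, available)
    ranking.append((names[first], float(F[first]), 0.0))
    available[first] = False
    last = first
    eps = 1e-12
    for _ in range(1, k):
        redundancy_sum += np.abs(Z.T @ Z[:, last]) / n
        mean_red = redundancy_sum / len(ranking)
        if criterion == DIFFERENCE:
            score = rel01 - mean_red
        elif criterion == QUOTIENT:
            score = rel01 / np.maximum(mean_red, eps)
        else:
            raise ValueError(f"unknown mRMR criterion {criterion!r}")
        idx = pick(score, available)
        ranking.append((names[idx], float(F[idx]), float(mean_red[idx])))
        available[idx] = False
        last = idx
    return RankedFeatures(ranking)


def feature_label_correlation(
    X: pd.DataFrame, cnrci: Sequence[float]
) -> Tuple[pd.Series, List[str]]:
    """Pearson correlation of every descriptor with the CNRCI values.

    Returns the per-descriptor r (positive r favors cytoplasm) and the
    list of constant descriptors whose correlation was set to 0.
    """
    cnrci = np.asarray(cnrci, dtype=float)
    if len(cnrci) != len(X):
        raise ValueError("X and cnrci must have equal length")
    if len(cnrci) < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(cnrci)):
        raise ValueError("cnrci values must be finite")
    Xa = X.to_numpy(dtype=float)
    n = len(cnrci)
    Zx = _standardized(Xa)
    yc = cnrci - cnrci.mean()
    ysd = cnrci.std()
    flagged = list(X.columns[Xa.std(axis=0) == 0])
    if ysd == 0:
        r = np.zeros(Xa.shape[1])
    else:
        r = (Zx.T @ (yc / ysd)) / n
    r = np.clip(r, -1.0, 1.0)
    return pd.Series(r, index=X.columns, name="r"), flagged


def cross_cell_line_variability(
    profiles: Dict[str, pd.Series]
) -> pd.Series:
    """Range (max r - min r) of each descriptor across cell-line profiles.

    Highlights descriptors whose association with localization varies the
    most between cell lines.
    """
    if len(profiles) < 2:
        raise ValueError("need correlation profiles for at least 2 cell lines")
    frame = pd.DataFrame(profiles)
    rng = frame.max(axis=1) - frame.min(axis=1)
    return rng.sort_values(ascending=False).rename("range")
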