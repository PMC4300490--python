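"""Shape / Intensity / No-Effect classification and profile clustering.

A peptide's 6x6 surface is read as two families of time-curves: NaCl-axis
curves (one per pheromone duration) and pheromone-axis curves (one per NaCl
duration). How the *other* stimulus modulates a family decides the call:

* SHAPE — the peptide's curves fall into >= 3 distinct K-means clusters
  (K = 6 for NaCl-axis curves, 8 for pheromone-axis curves), i.e. the
  modulating stimulus changes the temporal shape;
* INTENSITY — fewer than 3 clusters but the per-curve mean levels span a
  wide range: (max - min) / mean >= 0.7;
* NONE — otherwise.

Curves are divided by their own mean before clustering by default, so the
cluster step emphasises shape and the whole classification is invariant to
a global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .core import MISSING, EffectLabel, MeanSurface

__all__ = [
    "extract_curves",
    "kmeans_curves",
    "classify_effects",
    "hier_cluster",
    "EffectCall",
]

AXES = ("nacl", "phe")


@dataclass(frozen=True)
class EffectCall:
    ppep: str
    modulating_stimulus: str  # 'NaCl' or 'Phe'
    call: EffectLabel
    n_distinct_clusters: int
    intensity_score: float


def extract_curves(surface: MeanSurface, axis: str) -> pd.DataFrame:
    """Time-curves along one stimulus axis, one per duration of the other.

    Returns a frame indexed by (ppep_id, fixed_other) whose columns are the
    axis time points. The surface must be fully imputed.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    design = surface.design
    axis_times = design.nacl_times if axis == "nacl" else design.phe_times
    other_times = design.phe_times if axis == "nacl" else design.nacl_times
    rows, index = [], []
    for ppep in surface.ppeps:
        grid = surface.grid(ppep)
        prov = surface.grid(ppep, "provenance")
        if np.any(prov == MISSING):
            raise ValueError(f"{ppep}: surface still has MISSING cells; impute first")
        for k, fixed in enumerate(other_times):
            curve = grid[:, k] if axis == "nacl" else grid[k, :]
            rows.append(curve)
            index.append((ppep, fixed))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["ppep_id", "fixed_other"]),
        columns=list(axis_times),
    )


def _scale_curves(curves: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "per_curve_mean":
        return curves.div(curves.mean(axis=1), axis=0)
    if scale == "raw":
        return curves
    raise ValueError(f"unknown scale mode {scale!r}")


def kmeans_curves(
    curves: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    scale: str = "per_curve_mean",
) -> pd.Series:
    """Cluster curves with Euclidean K-means, best of ``restarts`` seeded runs.

    Labels are 1-based. K larger than the number of curves is an error.
    """
    if k > len(curves):
        raise ValueError(f"K={k} exceeds the number of curves ({len(curves)})")
    X = _scale_curves(curves, scale).to_numpy()
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X) + 1
    return pd.Series(labels, index=curves.index, name="cluster")


def _n_distinct(sub_curves: np.ndarray, sub_labels: np.ndarray) -> int:
    """Distinct cluster labels after collapsing numerically identical curves."""
    rounded = np.round(sub_curves, 9)
    _, uniq_idx = np.unique(rounded, axis=0, return_index=True)
    return len(set(sub_labels[uniq_idx]))


def classify_effects(
    surface: MeanSurface,
    k_nacl: int = 6,
    k_phe: int = 8,
    score_threshold: float = 0.7,
    seed: int = 0,
    restarts: int = 50,
    scale: str = "per_curve_mean",
    score_mode: str = "per_curve",
) -> pd.DataFrame:
    """Per-(ppep, modulating stimulus) Shape / Intensity / No-Effect calls.

    Modulating pheromone is judged on NaCl-axis curves (K=6), modulating
    NaCl on pheromone-axis curves (K=8). ``score_mode='per_curve'`` scores
    the range of per-curve mean levels across the modulating durations;
    'axis_range' instead averages curves pointwise and takes the range
    along the axis.
    """
    results = []
    for modulating, axis, k in (("Phe", "nacl", k_nacl), ("NaCl", "phe", k_phe)):
        curves = extract_curves(surface, axis)
        labels = kmeans_curves(curves, k, seed=seed, restarts=restarts, scale=scale)
        for ppep in surface.ppeps:
            sub = curves.loc[ppep]
            sub_labels = labels.loc[ppep].to_numpy()
            n_distinct = _n_distinct(sub.to_numpy(), sub_labels)
            if n_distinct >= 3:
                results.append((ppep, modulating, EffectLabel.SHAPE, n_distinct, np.nan))
                continue
            if score_mode == "per_curve":
                v = sub.mean(axis=1).to_numpy()  # one level per modulating duration
            elif score_mode == "axis_range":
                v = sub.mean(axis=0).to_numpy()  # pointwise mean along the axis
            else:
                raise ValueError(f"unknown score_mode {score_mode!r}")
            denom = float(np.mean(v))
            if denom == 0:
                raise ValueError(f"{ppep}: zero mean intensity; data must be positive")
            score = float((np.max(v) - np.min(v)) / denom)
            call = EffectLabel.INTENSITY if score >= score_threshold else EffectLabel.NONE
            results.append((ppep, modulating, call, n_distinct, score))
    return pd.DataFrame(
        results,
        columns=["ppep", "modulating_stimulus", "call", "n_distinct_clusters", "intensity_score"],
    )


def hier_cluster(
    surface: MeanSurface,
    p: float = 2.0,
    method: str = "complete",
    k: int = 7,
) -> pd.Series:
    """Hierarchical clustering of full 36-value profiles (Minkowski distance).

    The dendrogram is cut into ``k`` flat groups; identical profiles always
    co-cluster (their distance is 0).
    """
    ppeps = surface.ppeps
    if k > len(ppeps):
        raise ValueError(f"k={k} exceeds the number of peptides ({len(ppeps)})")
    X = np.array([surface.grid(pp).ravel() for pp in ppeps])
    if np.isnan(X).any():
        raise ValueError("profiles contain MISSING cells; impute first")
    Z = scipy_linkage(pdist(X, metric="minkowski", p=p), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(ppeps, name="ppep_id"), name="cluster")
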