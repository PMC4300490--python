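"""Stimulus-specificity ratios and the pattern-match screen.

The specificity of a peptide for Stimulus_1 against a modulating Stimulus_2
is the ratio of its response to Stimulus_1 alone over its response under
co-stimulation:

    S(i, j) = (I(t1_i, 0) + eps) / (I(t1_i, t2_j) + eps)

Entries below 1 mean Stimulus_2 amplifies the Stimulus_1 response; above 1,
it inhibits it. S_NaCl takes pheromone as Stimulus_1 (the effect of NaCl on
a pheromone-induced response); S_Phe takes NaCl as Stimulus_1. Column-wise
averaging collapses a matrix to a specificity vector, one entry per
Stimulus_2 duration; the j=0 baseline entry is identically 1.

The pattern-match screen ranks candidate peptides by the Pearson
correlation of log specificity vectors within an early-response window, so
amplification and inhibition are treated symmetrically; it automates the
search for peptides that directly or inversely track a query peptide such
as doubly phosphorylated Hog1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MeanSurface

__all__ = [
    "SpecificityMatrix",
    "specificity_matrix",
    "specificity_vector",
    "default_epsilon",
    "pattern_match",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificityMatrix:
    ppep: str
    modulating_stimulus: str  # 'NaCl' or 'Phe' (Stimulus_2)
    grid: np.ndarray  # rows = Stimulus_1 time i, cols = Stimulus_2 duration j
    s1_times: tuple[int, ...]
    s2_times: tuple[int, ...]


def default_epsilon(surface: MeanSurface) -> float:
    """Pseudocount: 1% of the global median intensity."""
    return 0.01 * float(np.nanmedian(surface.df["mean"]))


def specificity_matrix(
    surface: MeanSurface,
    ppep: str,
    modulating_stimulus: str,
    eps: float | None = None,
) -> SpecificityMatrix:
    """Ratio grid quantifying how Stimulus_2 modulates the Stimulus_1 response."""
    if modulating_stimulus not in ("NaCl", "Phe"):
        raise ValueError("modulating_stimulus must be 'NaCl' or 'Phe'")
    if eps is None:
        eps = default_epsilon(surface)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    grid = surface.grid(ppep)  # rows = t_nacl, cols = t_phe
    if modulating_stimulus == "NaCl":
        # Stimulus_1 = pheromone: rows become pheromone times
        I = grid.T
        s1_times, s2_times = surface.design.phe_times, surface.design.nacl_times
    else:
        I = grid
        s1_times, s2_times = surface.design.nacl_times, surface.design.phe_times
    if np.isnan(I).any():
        raise ValueError(f"{ppep}: surface has MISSING cells; impute first")
    if eps == 0 and (I <= 0).any():
        raise ValueError(f"{ppep}: non-positive intensities; supply a positive eps")
    ratios = (I[:, [0]] + eps) / (I + eps)
    return SpecificityMatrix(ppep, modulating_stimulus, ratios, tuple(s1_times), tuple(s2_times))


def specificity_vector(matrix: SpecificityMatrix) -> pd.Series:
    """Column-wise arithmetic mean: one entry per Stimulus_2 duration."""
    return pd.Series(matrix.grid.mean(axis=0), index=list(matrix.s2_times), name=matrix.ppep)


def pattern_match(
    query: pd.Series,
    candidates: dict[str, pd.Series],
    mode: str = "SIMILAR",
    window: int = 4,
    r_min: float = 0.8,
) -> pd.DataFrame:
    """Rank candidates by log-scale correlation with a query specificity vector.

    Pearson correlation of log-transformed vectors over the first ``window``
    Stimulus_2 durations (default 4, covering 0-10 min). SIMILAR keeps
    r >= r_min, OPPOSITE keeps r <= -r_min; output is ranked by |r|.
    Zero-variance candidates within the window are skipped with a warning.
    """
    if mode not in ("SIMILAR", "OPPOSITE"):
        raise ValueError("mode must be SIMILAR or OPPOSITE")
    q = np.log(query.to_numpy()[:window])
    if np.ptp(q) == 0:
        raise ValueError("query specificity vector is constant within the window")
    rows = []
    for name, vec in candidates.items():
        v = np.log(vec.to_numpy()[:window])
        if np.ptp(v) == 0:
            log.warning("skipping %s: zero-variance specificity within the window", name)
            continue
        r = float(np.corrcoef(q, v)[0, 1])
        if (mode == "SIMILAR" and r >= r_min) or (mode == "OPPOSITE" and r <= -r_min):
            rows.append((name, r))
    out = pd.DataFrame(rows, columns=["ppep", "r"])
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
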