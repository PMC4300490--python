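"""From replicate-level intensities to the condensed per-ppep mean surface.

Order of operations mirrors standard label-free practice: TIC normalization
(run-level), feature merging, the detection filter, replicate averaging,
then cubic-spline imputation of the remaining gaps. The 1.5x mock-experiment
comparison lives here too since it operates on mean surfaces.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import IMPUTED, MISSING, OBSERVED, CoStimDataset, MeanSurface, StimulationDesign

__all__ = [
    "tic_normalize",
    "merge_features",
    "detection_filter",
    "average_replicates",
    "impute_spline",
    "mock_compare",
]

log = logging.getLogger(__name__)


def tic_normalize(dataset: CoStimDataset) -> CoStimDataset:
    """Scale every run to the mean total ion current.

    intensity' = intensity / TIC(run) * mean(all TICs). Within-run ratios
    and rank order are untouched. The returned dataset records the common
    mean TIC for every run, which makes the operation idempotent.
    """
    runs = dataset.df["run_id"].unique()
    missing = [r for r in runs if r not in dataset.tic]
    if missing:
        raise ValueError(f"no TIC recorded for run(s) {missing[:3]}")
    bad = [r for r in runs if dataset.tic[r] <= 0]
    if bad:
        raise ValueError(f"non-positive TIC for run(s) {bad[:3]}")
    mean_tic = float(np.mean([dataset.tic[r] for r in runs]))
    df = dataset.df.copy()
    df["intensity"] = df["intensity"] / df["run_id"].map(dataset.tic) * mean_tic
    return CoStimDataset(df, dataset.design, {r: mean_tic for r in runs})


def merge_features(feature_table: pd.DataFrame, design: StimulationDesign) -> CoStimDataset:
    """Merge MS1 features of the same peptide species.

    Features sharing (sequence, n_phospho) — different charge states,
    retention times, or site calls — are summed per (condition, replicate).
    Conflicting protein assignments within a merge group are an error;
    divergent site calls are recorded as ambiguous.
    """
    required = {"protein", "sites", "sequence", "n_phospho", "t_nacl", "t_phe", "replicate", "run_id", "intensity"}
    if not required <= set(feature_table.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    rows = []
    used_ids: dict[str, int] = {}
    for (seq, n_phospho), group in feature_table.groupby(["sequence", "n_phospho"]):
        proteins = sorted(group["protein"].unique())
        if len(proteins) > 1:
            raise ValueError(
                f"conflicting protein assignment for sequence {seq!r} (n_phospho={n_phospho}): {proteins}"
            )
        site_calls = sorted(group["sites"].unique())
        ambiguous = len(site_calls) > 1
        sites = site_calls[0]
        ppep_id = f"{proteins[0]}_{sites}" if sites else proteins[0]
        # same protein and site call but distinct backbone: keep both species
        if ppep_id in used_ids:
            used_ids[ppep_id] += 1
            ppep_id = f"{ppep_id}_seq{used_ids[ppep_id]}"
        else:
            used_ids[ppep_id] = 1
        summed = (
            group.groupby(["t_nacl", "t_phe", "replicate", "run_id"])["intensity"]
            .sum(min_count=1)
            .reset_index()
        )
        for rec in summed.itertuples(index=False):
            rows.append(
                (ppep_id, proteins[0], sites, seq, n_phospho, ambiguous,
                 rec.t_nacl, rec.t_phe, rec.replicate, rec.run_id, rec.intensity)
            )
    df = pd.DataFrame(
        rows,
        columns=["ppep_id", "protein", "sites", "sequence", "n_phospho", "ambiguous",
                 "t_nacl", "t_phe", "replicate", "run_id", "intensity"],
    )
    if "tic" in feature_table.columns:
        tic = feature_table.groupby("run_id")["tic"].first().to_dict()
    else:
        tic = df.groupby("run_id")["intensity"].sum(min_count=1).fillna(0.0).to_dict()
    return CoStimDataset(df.drop(columns=["ambiguous"]), design, tic)


def detection_filter(dataset: CoStimDataset, min_times: int = 4) -> set[str]:
    """Peptides detected on enough of both stimulation timelines.

    A time point counts as detected if any condition sharing that coordinate
    has at least one replicate observation; a peptide is retained when at
    least ``min_times`` NaCl time points AND ``min_times`` pheromone time
    points are detected. Monotone: extra detections never drop a peptide.
    """
    retained = set()
    detected = dataset.df.dropna(subset=["intensity"])
    for ppep, group in detected.groupby("ppep_id"):
        nacl_hit = group["t_nacl"].nunique()
        phe_hit = group["t_phe"].nunique()
        if nacl_hit >= min_times and phe_hit >= min_times:
            retained.add(ppep)
    return retained


def average_replicates(dataset: CoStimDataset) -> MeanSurface:
    """Condense replicates to per-cell mean, s.d. and detection count.

    Statistics use detected replicates only (ddof=1 s.d.; recorded as 0 when
    a single replicate was detected so downstream CVs stay computable);
    cells with no detection are MISSING.
    """
    design = dataset.design
    idx = pd.MultiIndex.from_tuples(
        [(p, tn, tp) for p in dataset.ppeps for tn, tp in design.conditions],
        names=["ppep_id", "t_nacl", "t_phe"],
    )
    grouped = dataset.df.groupby(["ppep_id", "t_nacl", "t_phe"])["intensity"]
    stats = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    stats = stats.reindex(idx)
    stats["n"] = stats["n"].fillna(0).astype(int)
    stats.loc[stats["n"] == 1, "sd"] = 0.0
    stats["provenance"] = np.where(stats["n"] > 0, OBSERVED, MISSING)
    stats.loc[stats["n"] == 0, ["mean", "sd"]] = np.nan
    return MeanSurface(stats, design)


def _spline_fill(x_obs, y_obs, x_missing):
    spline = CubicSpline(x_obs, y_obs, bc_type="natural")
    return np.clip(spline(x_missing), 0.0, None)


def impute_spline(surface: MeanSurface, min_points: int = 3) -> MeanSurface:
    """Fill MISSING cells by natural cubic splines along the NaCl axis.

    Tracks (fixed pheromone duration, NaCl time varying) with at least
    ``min_points`` observations are interpolated first; cells on tracks that
    are too sparse fall back to the pheromone axis; cells with no viable
    track stay MISSING with a logged warning. Observed cells are never
    altered; negative spline output is clipped to 0.
    """
    out = surface.copy()
    design = surface.design
    nacl = np.asarray(design.nacl_times, dtype=float)
    phe = np.asarray(design.phe_times, dtype=float)
    for ppep in surface.ppeps:
        grid = out.grid(ppep)
        prov = out.grid(ppep, "provenance")
        filled = grid.copy()
        for i, tn in enumerate(design.nacl_times):
            for j, tp in enumerate(design.phe_times):
                if prov[i, j] != MISSING:
                    continue
                col_ok = np.where(prov[:, j] == OBSERVED)[0]
                row_ok = np.where(prov[i, :] == OBSERVED)[0]
                if len(col_ok) >= min_points:
                    filled[i, j] = _spline_fill(nacl[col_ok], grid[col_ok, j], tn)
                elif len(row_ok) >= min_points:
                    filled[i, j] = _spline_fill(phe[row_ok], grid[i, row_ok], tp)
                else:
                    log.warning(
                        "cannot impute %s at (t_nacl=%s, t_phe=%s): "
                        "fewer than %d observed points on both axes",
                        ppep, tn, tp, min_points,
                    )
                    continue
                out.df.loc[(ppep, tn, tp), ["mean", "provenance"]] = [filled[i, j], IMPUTED]
    return out


def mock_compare(
    surface_real: MeanSurface,
    surface_mock: MeanSurface,
    fold: float = 1.5,
    eps: float | None = None,
) -> tuple[pd.Series, float]:
    """Mock-handling comparison with the strict 1.5x rule.

    For every cell present in both surfaces the larger/smaller ratio is
    computed (with pseudocount ``eps``, default 1% of the global median
    intensity); a peptide is 'negligible' (indistinguishable from mock) iff
    every compared cell has ratio strictly below ``fold``. Returns per-ppep
    flags and the negligible fraction.
    """
    common = surface_real.df.index.intersection(surface_mock.df.index)
    if common.empty:
        raise ValueError("surfaces share no (ppep, condition) cells")
    a = surface_real.df.loc[common, "mean"]
    b = surface_mock.df.loc[common, "mean"]
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if eps is None:
        eps = 0.01 * float(np.nanmedian(np.concatenate([a.to_numpy(), b.to_numpy()])))
    hi = np.maximum(a + eps, b + eps)
    lo = np.minimum(a + eps, b + eps)
    ratio = hi / lo
    negligible = (ratio < fold).groupby("ppep_id").all()
    return negligible, float(negligible.mean())
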