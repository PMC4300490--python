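"""Readers and writers for the three formats the pipeline touches.

* long-format intensity CSV — replicate-level co-stimulation data
  (header: ppep_id,protein,sites,sequence,n_phospho,t_nacl,t_phe,replicate,
  run_id,intensity,tic; missing intensity as empty field or "NA");
* MIDAS — normalized perturbation/time-course data for logic modeling
  (TR:NaCl / TR:Phe treatment flags, DA:<node> time and DV:<node> value
  columns; no cell-line column, single strain);
* SIF — signed interaction triples, AND gates via intermediate "and<k>"
  nodes.

Parsers reject malformed input instead of coercing; all round trips are
lossless.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    LONG_CSV_COLUMNS,
    CoStimDataset,
    LogicNetwork,
    NodeRole,
    StimulationDesign,
)

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "read_midas",
    "write_midas",
    "read_sif",
    "write_sif",
]

_SITE_SUFFIX = re.compile(r"^[A-Za-z0-9]+(_[STY]\d+)+$")
_GATE_NAME = re.compile(r"^and\d+$")


# ---------------------------------------------------------------------------
# long-format CSV


def write_long_csv(dataset: CoStimDataset, path: str | Path) -> None:
    df = dataset.df.copy()
    df["tic"] = df["run_id"].map(dataset.tic)
    df = df[LONG_CSV_COLUMNS].sort_values(["ppep_id", "t_nacl", "t_phe", "replicate"])
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_long_csv(path: str | Path) -> CoStimDataset:
    df = pd.read_csv(
        path,
        na_values=["NA", ""],
        keep_default_na=False,
        dtype={"ppep_id": str, "protein": str, "run_id": str},
        float_precision="round_trip",
    )
    unknown = set(df.columns) - set(LONG_CSV_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in long CSV: {sorted(unknown)}")
    missing = set(LONG_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long CSV lacks columns: {sorted(missing)}")
    df["sites"] = df["sites"].fillna("")
    df["sequence"] = df["sequence"].fillna("")
    if df["intensity"].dropna().lt(0).any():
        raise ValueError("negative intensity in long CSV")
    nacl_times = tuple(sorted(df["t_nacl"].unique()))
    phe_times = tuple(sorted(df["t_phe"].unique()))
    design = StimulationDesign(nacl_times, phe_times, int(df["replicate"].max()))
    tic_per_run = df.groupby("run_id")["tic"].unique()
    bad = tic_per_run[tic_per_run.apply(len) > 1]
    if not bad.empty:
        raise ValueError(f"inconsistent TIC for runs {list(bad.index)[:3]}")
    tic = {run: float(v[0]) for run, v in tic_per_run.items()}
    return CoStimDataset(df.drop(columns=["tic"]), design, tic)


# ---------------------------------------------------------------------------
# MIDAS


def write_midas(conditions: pd.DataFrame, measurements: pd.DataFrame, path: str | Path) -> None:
    """Write one row per (treatment pattern, time).

    ``conditions`` needs columns ``TR:NaCl``, ``TR:Phe`` (0/1) and ``time``
    (minutes); ``measurements`` has one column per measured node, aligned
    row-wise with ``conditions``, values in [0, 1] or NaN.
    """
    if list(conditions.columns[:2]) != ["TR:NaCl", "TR:Phe"] or "time" not in conditions:
        raise ValueError("conditions frame needs TR:NaCl, TR:Phe and time columns")
    if len(conditions) != len(measurements):
        raise ValueError("conditions and measurements must align row-wise")
    vals = measurements.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
        raise ValueError("MIDAS DV values must lie in [0, 1]")
    out = pd.DataFrame()
    out["TR:NaCl"] = conditions["TR:NaCl"].astype(int)
    out["TR:Phe"] = conditions["TR:Phe"].astype(int)
    for node in measurements.columns:
        out[f"DA:{node}"] = conditions["time"].astype(int)
    for node in measurements.columns:
        out[f"DV:{node}"] = measurements[node]
    out.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_midas(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False, float_precision="round_trip")
    for col in ("TR:NaCl", "TR:Phe"):
        if col not in df.columns:
            raise ValueError(f"MIDAS file lacks {col}")
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"{col} values must be 0/1")
    da_nodes = [c[3:] for c in df.columns if c.startswith("DA:")]
    dv_nodes = [c[3:] for c in df.columns if c.startswith("DV:")]
    orphans = set(dv_nodes) - set(da_nodes)
    if orphans:
        raise ValueError(f"DV column(s) without matching DA: {sorted(orphans)}")
    if not da_nodes:
        raise ValueError("MIDAS file has no DA: columns")
    times = df[[f"DA:{n}" for n in da_nodes]]
    if times.nunique(axis=1).gt(1).any():
        raise ValueError("per-row DA times disagree between nodes")
    measurements = df[[f"DV:{n}" for n in dv_nodes]].rename(
        columns={f"DV:{n}": n for n in dv_nodes}
    )
    vals = measurements.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("MIDAS DV values must lie in [0, 1]")
    conditions = pd.DataFrame(
        {
            "TR:NaCl": df["TR:NaCl"].astype(int),
            "TR:Phe": df["TR:Phe"].astype(int),
            "time": times.iloc[:, 0].astype(int),
        }
    )
    return conditions, measurements


# ---------------------------------------------------------------------------
# SIF


def _role_for(name: str, stimuli: tuple[str, ...]) -> tuple[NodeRole, bool]:
    if name in stimuli:
        return NodeRole.STIMULUS, False
    if _SITE_SUFFIX.match(name):
        return NodeRole.PPEP, True
    return NodeRole.PROTEIN, False


def read_sif(path: str | Path, stimuli: tuple[str, ...] = ("NaCl", "Pheromone")) -> LogicNetwork:
    triples: list[tuple[str, int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'source relation target'")
        src, rel, tgt = parts
        if rel not in ("1", "-1"):
            raise ValueError(f"{path}:{lineno}: relation must be 1 or -1, got {rel!r}")
        triples.append((src, int(rel), tgt))

    gate_names = {n for t in triples for n in (t[0], t[2]) if _GATE_NAME.match(n)}
    net = LogicNetwork()
    for src, _sign, tgt in triples:
        for name in (src, tgt):
            if name not in gate_names and name not in net.nodes:
                net.add_node(name, *_role_for(name, stimuli))
    for gate in sorted(gate_names):
        inputs = tuple((s, sg) for (s, sg, t) in triples if t == gate)
        outputs = [(s, sg, t) for (s, sg, t) in triples if s == gate]
        if len(inputs) < 2:
            raise ValueError(f"AND gate {gate} has fewer than 2 inputs")
        if len(outputs) != 1 or outputs[0][1] != 1:
            raise ValueError(f"AND gate {gate} must have exactly one activating output")
        net.add_and_gate(gate, inputs, outputs[0][2])
    for src, sign, tgt in triples:
        if src in gate_names or tgt in gate_names:
            continue
        net.add_edge(src, sign, tgt)
    return net


def write_sif(network: LogicNetwork, path: str | Path) -> None:
    lines = [f"{s} {sg} {t}" for (s, sg, t) in sorted(network.edges)]
    for gate in sorted(network.and_gates):
        inputs, target = network.and_gates[gate]
        for src, sign in inputs:
            lines.append(f"{src} {sign} {gate}")
        lines.append(f"{gate} 1 {target}")
    Path(path).write_text("\n".join(lines) + "\n")
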