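"""Core containers shared across the pipeline.

The experiment underlying everything here is a double time-course: yeast
cultures are co-stimulated with NaCl (hyper-osmotic shock, HOG pathway) and
alpha-factor pheromone (mating pathway) for every pairwise combination of
stimulation periods, and phosphopeptide (P-pep) intensities are quantified
per condition and biological replicate by label-free MS.

Conventions
-----------
* Times are minutes, stored as integers. A stimulation period of 0 means the
  stimulus was never applied (cells harvested at addition time).
* A "run" is one (condition, replicate) MS acquisition; its TIC (total ion
  current) is the sum of all intensities observed in that run.
* Missing observations are first-class (NaN in tables), never encoded as 0;
  an intensity of 0 is invalid input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TIMES",
    "StimulationDesign",
    "PpepID",
    "CoStimDataset",
    "MeanSurface",
    "NodeRole",
    "LogicNetwork",
    "EffectLabel",
    "run_id_for",
]

DEFAULT_TIMES: tuple[int, ...] = (0, 1, 5, 10, 20, 45)

LONG_CSV_COLUMNS = [
    "ppep_id",
    "protein",
    "sites",
    "sequence",
    "n_phospho",
    "t_nacl",
    "t_phe",
    "replicate",
    "run_id",
    "intensity",
    "tic",
]


def run_id_for(t_nacl: int, t_phe: int, replicate: int) -> str:
    """Canonical run identifier for a (condition, replicate) acquisition."""
    return f"n{t_nacl}_p{t_phe}_rep{replicate}"


def _validate_times(times: Sequence[int], name: str) -> tuple[int, ...]:
    times = tuple(int(t) for t in times)
    if not times or times[0] != 0:
        raise ValueError(f"{name} must start at 0, got {times!r}")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError(f"{name} must be strictly increasing, got {times!r}")
    return times


@dataclass(frozen=True)
class StimulationDesign:
    """Cross-product co-stimulation design: |nacl_times| x |phe_times| conditions."""

    nacl_times: tuple[int, ...] = DEFAULT_TIMES
    phe_times: tuple[int, ...] = DEFAULT_TIMES
    n_replicates: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "nacl_times", _validate_times(self.nacl_times, "nacl_times"))
        object.__setattr__(self, "phe_times", _validate_times(self.phe_times, "phe_times"))
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def conditions(self) -> list[tuple[int, int]]:
        """All (t_nacl, t_phe) combinations, row-major in NaCl time."""
        return [(tn, tp) for tn in self.nacl_times for tp in self.phe_times]

    @property
    def n_conditions(self) -> int:
        return len(self.nacl_times) * len(self.phe_times)


@dataclass(frozen=True)
class PpepID:
    """Identity of a phosphopeptide.

    ``sites`` are residue tokens like ``T174``; when site assignment is
    ambiguous the listed sites may be fewer than ``n_phospho`` and the
    ``ambiguous`` flag is set.
    """

    protein: str
    sites: tuple[str, ...]
    sequence: str = ""
    n_phospho: int = 1
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.n_phospho < 1:
            raise ValueError("n_phospho must be >= 1")
        if len(self.sites) > self.n_phospho:
            raise ValueError(
                f"{self.protein}: listed sites {self.sites} exceed n_phospho={self.n_phospho}"
            )

    @property
    def display_name(self) -> str:
        return "_".join((self.protein,) + self.sites) if self.sites else self.protein


class CoStimDataset:
    """Replicate-level intensities on a co-stimulation design.

    Wraps a long-format :class:`pandas.DataFrame` with one row per
    (ppep, condition, replicate); ``intensity`` is NaN when the peptide was
    not detected in that run. ``tic`` maps run_id -> total ion current.
    """

    def __init__(self, df: pd.DataFrame, design: StimulationDesign, tic: Mapping[str, float]):
        df = df.copy()
        missing_cols = [c for c in LONG_CSV_COLUMNS if c not in df.columns and c != "tic"]
        if missing_cols:
            raise ValueError(f"dataset frame lacks columns {missing_cols}")
        present = df["intensity"].dropna()
        if (present <= 0).any():
            bad = df.loc[present[present <= 0].index]
            key = bad.iloc[0][["ppep_id", "t_nacl", "t_phe", "replicate"]].tolist()
            raise ValueError(f"non-positive intensity at {key}; missing must be NaN, not 0")
        key_cols = ["ppep_id", "t_nacl", "t_phe", "replicate"]
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            raise ValueError(f"duplicate record key {df.loc[dup.idxmax(), key_cols].tolist()}")
        cond_set = set(design.conditions)
        obs_conds = set(map(tuple, df[["t_nacl", "t_phe"]].drop_duplicates().itertuples(index=False)))
        stray = obs_conds - cond_set
        if stray:
            raise ValueError(f"records at conditions outside the design: {sorted(stray)[:5]}")
        if (df["replicate"] < 1).any() or (df["replicate"] > design.n_replicates).any():
            raise ValueError("replicate index outside 1..n_replicates")
        self.df = df.reset_index(drop=True)
        self.design = design
        self.tic = dict(tic)

    @property
    def ppeps(self) -> list[str]:
        return sorted(self.df["ppep_id"].unique())

    def intensities(self, ppep_id: str) -> pd.DataFrame:
        return self.df[self.df["ppep_id"] == ppep_id]

    def with_df(self, df: pd.DataFrame) -> "CoStimDataset":
        return CoStimDataset(df, self.design, self.tic)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoStimDataset):
            return NotImplemented
        a = self.df.sort_values(["ppep_id", "t_nacl", "t_phe", "replicate"]).reset_index(drop=True)
        b = other.df.sort_values(["ppep_id", "t_nacl", "t_phe", "replicate"]).reset_index(drop=True)
        return (
            a[LONG_CSV_COLUMNS[:-1]].equals(b[LONG_CSV_COLUMNS[:-1]])
            and self.design == other.design
            and self.tic == other.tic
        )


OBSERVED = "OBSERVED"
IMPUTED = "IMPUTED"
MISSING = "MISSING"


class MeanSurface:
    """Per-ppep grid of replicate-condensed intensities.

    ``df`` is indexed by (ppep_id, t_nacl, t_phe) with columns
    ``mean``, ``sd``, ``n`` and ``provenance`` in {OBSERVED, IMPUTED, MISSING}.
    """

    def __init__(self, df: pd.DataFrame, design: StimulationDesign):
        required = {"mean", "sd", "n", "provenance"}
        if not required <= set(df.columns):
            raise ValueError(f"surface frame needs columns {sorted(required)}")
        self.df = df
        self.design = design

    @property
    def ppeps(self) -> list[str]:
        return sorted(self.df.index.get_level_values("ppep_id").unique())

    def grid(self, ppep_id: str, column: str = "mean") -> np.ndarray:
        """Values as a (|nacl_times|, |phe_times|) array; rows = NaCl time."""
        sub = self.df.loc[ppep_id]
        out = np.full((len(self.design.nacl_times), len(self.design.phe_times)), np.nan, dtype=object if column == "provenance" else float)
        for i, tn in enumerate(self.design.nacl_times):
            for j, tp in enumerate(self.design.phe_times):
                if (tn, tp) in sub.index:
                    out[i, j] = sub.loc[(tn, tp), column]
        return out

    def is_complete(self, ppep_id: str) -> bool:
        prov = self.grid(ppep_id, "provenance")
        return not np.any(prov == MISSING)

    def copy(self) -> "MeanSurface":
        return MeanSurface(self.df.copy(), self.design)


class NodeRole(enum.Enum):
    STIMULUS = "stimulus"
    PPEP = "ppep"
    PROTEIN = "protein"


@dataclass
class LogicNetwork:
    """Signed directed (hyper)graph over stimulus / P-pep / protein nodes.

    ``nodes`` maps name -> (role, measured); ``edges`` is a set of
    (source, sign, target) with sign in {+1, -1}; AND gates are stored as
    gate_id -> (inputs, target) where inputs is a tuple of (source, sign).
    """

    nodes: dict[str, tuple[NodeRole, bool]] = field(default_factory=dict)
    edges: set[tuple[str, int, str]] = field(default_factory=set)
    and_gates: dict[str, tuple[tuple[tuple[str, int], ...], str]] = field(default_factory=dict)

    def add_node(self, name: str, role: NodeRole, measured: bool = False) -> None:
        self.nodes[name] = (role, measured)

    def add_edge(self, source: str, sign: int, target: str) -> None:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +-1, got {sign}")
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise ValueError(f"edge endpoint {endpoint!r} is not a node")
        if self.nodes[target][0] is NodeRole.STIMULUS:
            raise ValueError(f"stimulus node {target!r} cannot have incoming edges")
        self.edges.add((source, sign, target))

    def add_and_gate(self, gate_id: str, inputs: Iterable[tuple[str, int]], target: str) -> None:
        inputs = tuple(inputs)
        if len(inputs) < 2:
            raise ValueError("AND gates need >= 2 inputs")
        for src, sign in inputs:
            if src not in self.nodes:
                raise ValueError(f"gate input {src!r} is not a node")
            if sign not in (1, -1):
                raise ValueError("gate input sign must be +-1")
        if target not in self.nodes:
            raise ValueError(f"gate target {target!r} is not a node")
        self.and_gates[gate_id] = (inputs, target)

    @property
    def stimulus_nodes(self) -> list[str]:
        return sorted(n for n, (r, _) in self.nodes.items() if r is NodeRole.STIMULUS)

    @property
    def n_nodes(self) -> int:
        """Number of species nodes (P-peps + proteins); stimuli are not counted."""
        return sum(1 for _, (r, _m) in self.nodes.items() if r is not NodeRole.STIMULUS)

    @property
    def n_interactions(self) -> int:
        """Plain edges plus, per AND gate, its inputs and one output."""
        return len(self.edges) + sum(len(ins) + 1 for ins, _ in self.and_gates.values())

    def incoming(self, node: str) -> list[tuple[str, int]]:
        return sorted((s, sg) for (s, sg, t) in self.edges if t == node)

    def copy(self) -> "LogicNetwork":
        return LogicNetwork(dict(self.nodes), set(self.edges), dict(self.and_gates))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.and_gates == other.and_gates
        )


class EffectLabel(str, enum.Enum):
    """Verdict for how the modulating stimulus alters a P-pep's response."""

    SHAPE = "SHAPE"
    INTENSITY = "INTENSITY"
    NONE = "NONE"
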