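"""Peptide selection for modeling and logic-network construction.

The modeling pipeline filters peptides (replicate CV < 0.25; < 25% missing
data points on the training conditions), merges redundant trajectories with
affinity propagation (the member with previously known function represents
a cluster when present, otherwise the exemplar), substitutes the surviving
peptides into a protein-level prior network with full combinatorial edge
expansion, and enumerates mechanistic variants into a model ensemble.
"""

from __future__ import annotations

import importlib.resources as resources
import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .core import CoStimDataset, LogicNetwork, MeanSurface, NodeRole

__all__ = [
    "ModelingFilterConfig",
    "VariantSpec",
    "EnsembleScheme",
    "cv_filter",
    "missingness_filter",
    "ap_merge",
    "build_pepnet",
    "apply_variant",
    "enumerate_ensemble",
    "load_prior_network",
    "load_modeling_peptides",
    "load_ensemble_scheme",
]

log = logging.getLogger(__name__)

Edge = tuple[str, int, str]


@dataclass(frozen=True)
class ModelingFilterConfig:
    cv_threshold: float = 0.25
    max_missing_fraction: float = 0.25
    ap_damping: float = 0.5
    ap_preference: str = "scaled_median"  # or "median"
    ap_preference_factor: float = 0.02
    cv_aggregation: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        if not 0 < self.cv_threshold < 1 or not 0 < self.max_missing_fraction < 1:
            raise ValueError("thresholds must lie in (0, 1)")


# ---------------------------------------------------------------------------
# fixtures


def _data_path(name: str):
    return resources.files("costim.data").joinpath(name)


def load_prior_network() -> LogicNetwork:
    from .io import read_sif

    with resources.as_file(_data_path("prior_network.sif")) as path:
        return read_sif(path)


def load_modeling_peptides() -> pd.DataFrame:
    """The shipped modeling peptide list: ppep_id, protein, known_function."""
    with resources.as_file(_data_path("modeling_peptides.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df["known_function"] = df["known_function"].astype(bool)
    return df


def load_ensemble_scheme() -> "EnsembleScheme":
    with resources.as_file(_data_path("ensemble_scheme.yaml")) as path:
        raw = yaml.safe_load(path.read_text())
    combos = [
        (bool(c["restrict_ste20_to_T511"]), bool(c["add_gpd1_hog1_loop"]))
        for c in raw["mechanism_combos"]
    ]
    groups = {
        name: tuple((s, int(sg), t) for s, sg, t in edges)
        for name, edges in raw["no_effect_groups"].items()
    }
    singles = tuple((s, int(sg), t) for s, sg, t in raw["single_removals"])
    return EnsembleScheme(combos, groups, singles)


# ---------------------------------------------------------------------------
# peptide filters


def cv_filter(
    dataset: CoStimDataset,
    threshold: float = 0.25,
    aggregation: str = "median",
) -> set[str]:
    """Peptides whose replicate coefficient of variation stays below threshold.

    Per peptide the CV (replicate s.d. / replicate mean, ddof=1) is computed
    for every condition with >= 2 detections and aggregated by the median
    (configurable to the mean); retention requires aggregate CV strictly
    below ``threshold``. Peptides with no multi-replicate condition are
    excluded with a warning.
    """
    agg = {"median": np.median, "mean": np.mean}[aggregation]
    retained = set()
    for ppep, group in dataset.df.groupby("ppep_id"):
        stats = group.groupby(["t_nacl", "t_phe"])["intensity"].agg(["mean", "std", "count"])
        multi = stats[stats["count"] >= 2]
        if multi.empty:
            log.warning("%s: no condition with >= 2 replicates; excluded from modeling", ppep)
            continue
        cv = float(agg(multi["std"] / multi["mean"]))
        if cv < threshold:
            retained.add(ppep)
    return retained


def missingness_filter(
    surface: MeanSurface,
    conditions: list[tuple[int, int]],
    max_fraction: float = 0.25,
) -> set[str]:
    """Peptides missing fewer than ``max_fraction`` of the given conditions.

    Operates on the un-imputed surface: a condition counts as missing when
    no replicate was detected. The boundary is exclusive (a peptide missing
    exactly 25% of the data points is discarded).
    """
    retained = set()
    for ppep in surface.ppeps:
        sub = surface.df.loc[ppep]
        n_missing = sum(
            1 for cond in conditions if cond not in sub.index or sub.loc[cond, "n"] == 0
        )
        if n_missing / len(conditions) < max_fraction:
            retained.add(ppep)
    return retained


# ---------------------------------------------------------------------------
# affinity-propagation merging


def _ap_cluster(X: np.ndarray, config: ModelingFilterConfig, seed: int) -> np.ndarray:
    if len(X) == 2:
        # two mutually-equal similarities make message passing degenerate;
        # near-identical pairs were already pre-merged, so keep both
        return np.arange(2)
    sims = -(
        np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    )
    off = sims[~np.eye(len(X), dtype=bool)]
    if config.ap_preference == "median":
        pref = float(np.median(off))
    elif config.ap_preference == "scaled_median":
        pref = config.ap_preference_factor * float(np.median(off))
    else:
        raise ValueError(f"unknown ap_preference rule {config.ap_preference!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(
                damping=config.ap_damping,
                preference=pref,
                random_state=seed,
                max_iter=1000,
                convergence_iter=30,
            ).fit(X)
        except ConvergenceWarning:
            log.warning("affinity propagation did not converge; using singleton clusters")
            return np.arange(len(X))
    labels = np.asarray(ap.labels_)
    if (labels < 0).any():
        log.warning("affinity propagation did not converge; using singleton clusters")
        return np.arange(len(X))
    return labels


def ap_merge(
    trajectories: dict[str, np.ndarray],
    protein_of: dict[str, str],
    known_function: set[str],
    config: ModelingFilterConfig | None = None,
    seed: int = 0,
    duplicate_tol: float = 0.05,
) -> tuple[list[str], dict[str, str]]:
    """Merge redundant same-protein trajectories; pick one representative each.

    Trajectories are max-normalized, near-identical ones (relative distance
    below ``duplicate_tol``) are pre-merged, and affinity propagation
    (negative squared Euclidean similarity) clusters the rest per protein.
    The representative of a cluster is its known-function member when one
    exists (ties broken lexicographically), else the exemplar.

    Returns (representatives, cluster_map) with cluster_map mapping every
    peptide to its representative.
    """
    config = config or ModelingFilterConfig()
    representatives: list[str] = []
    cluster_map: dict[str, str] = {}
    by_protein: dict[str, list[str]] = {}
    for ppep in sorted(trajectories):
        by_protein.setdefault(protein_of[ppep], []).append(ppep)

    for protein in sorted(by_protein):
        members = by_protein[protein]
        if len(members) == 1:
            representatives.append(members[0])
            cluster_map[members[0]] = members[0]
            continue
        X = np.array([np.asarray(trajectories[m], dtype=float) for m in members])
        X = X / np.nanmax(np.abs(X), axis=1, keepdims=True)
        # pre-merge near-identical trajectories (union-find over close pairs)
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(members)), 2):
            if np.sqrt(np.mean((X[i] - X[j]) ** 2)) < duplicate_tol:
                parent[find(j)] = find(i)
        groups: dict[int, list[int]] = {}
        for i in range(len(members)):
            groups.setdefault(find(i), []).append(i)
        reps_idx = sorted(groups)
        if len(reps_idx) == 1:
            labels = np.zeros(len(reps_idx), dtype=int)
        else:
            labels = _ap_cluster(X[reps_idx], config, seed)
        # expand labels back to all members
        label_of = {}
        for lab, ridx in zip(labels, reps_idx):
            for i in groups[ridx]:
                label_of[i] = lab
        for lab in sorted(set(label_of.values())):
            cluster_members = [members[i] for i in sorted(label_of) if label_of[i] == lab]
            known = sorted(m for m in cluster_members if m in known_function)
            rep = known[0] if known else cluster_members[0]
            representatives.append(rep)
            for m in cluster_members:
                cluster_map[m] = rep
    return sorted(representatives), cluster_map


# ---------------------------------------------------------------------------
# network construction


def build_pepnet(prior: LogicNetwork, assignment: dict[str, list[str]]) -> LogicNetwork:
    """Substitute measured peptides into a protein-level prior network.

    Every protein with >= 1 surviving peptide is replaced by those peptide
    nodes; proteins without peptides stay as unmeasured nodes; every prior
    edge A->B expands to all (a_i, b_j) pairs with the prior sign. Stimulus
    nodes are untouched.
    """
    unknown = set(assignment) - {
        n for n, (r, _) in prior.nodes.items() if r is not NodeRole.STIMULUS
    }
    if unknown:
        raise ValueError(f"assignment references absent protein(s): {sorted(unknown)}")
    expansion: dict[str, list[str]] = {}
    net = LogicNetwork()
    for name, (role, measured) in prior.nodes.items():
        peps = assignment.get(name, [])
        if role is NodeRole.STIMULUS:
            net.add_node(name, role, measured)
            expansion[name] = [name]
        elif peps:
            for pep in peps:
                net.add_node(pep, NodeRole.PPEP, True)
            expansion[name] = list(peps)
        else:
            net.add_node(name, role, False)
            expansion[name] = [name]
    for src, sign, tgt in sorted(prior.edges):
        for a in expansion[src]:
            for b in expansion[tgt]:
                net.add_edge(a, sign, b)
    for gate_id, (inputs, target) in prior.and_gates.items():
        for combo in itertools.product(
            *[[(a, sg) for a in expansion[s]] for s, sg in inputs],
            expansion[target],
        ):
            *ins, tgt_node = combo
            net.add_and_gate(f"{gate_id}_{tgt_node}", tuple(ins), tgt_node)
    return net


@dataclass(frozen=True)
class VariantSpec:
    """A mechanistic variant of the base peptide-level model."""

    restrict_ste20_to_T511: bool = False
    add_gpd1_hog1_loop: bool = False
    removed_edges: tuple[Edge, ...] = ()
    name: str = ""


def _protein_of(node: str) -> str:
    return node.split("_")[0]


def apply_variant(
    model: LogicNetwork,
    spec: VariantSpec,
    ste20_keep: str = "Ste20_T511",
    gpd1_node: str = "Gpd1_S24_S27",
    hog1_protein: str = "Hog1",
) -> LogicNetwork:
    """Apply mechanism flags and edge removals; prune stranded unmeasured nodes.

    ``restrict_ste20_to_T511`` drops every Ste20 peptide node except the
    keeper together with incident edges; ``add_gpd1_hog1_loop`` installs the
    double-negative feedback between ppGpd1 and the Hog1 phospho-forms
    (inhibitory edges both ways, expanded over all Hog1 peptide nodes).
    Unmeasured non-stimulus nodes left without a path from any stimulus are
    pruned. Idempotent for a fixed spec.
    """
    net = model.copy()
    if spec.restrict_ste20_to_T511:
        doomed = {
            n
            for n, (role, _m) in net.nodes.items()
            if role is NodeRole.PPEP and _protein_of(n) == "Ste20" and n != ste20_keep
        }
        net.edges = {e for e in net.edges if e[0] not in doomed and e[2] not in doomed}
        net.and_gates = {
            g: (ins, t)
            for g, (ins, t) in net.and_gates.items()
            if t not in doomed and all(s not in doomed for s, _ in ins)
        }
        for n in doomed:
            del net.nodes[n]
    if spec.add_gpd1_hog1_loop:
        hog1_forms = [
            n
            for n, (role, _m) in net.nodes.items()
            if role is NodeRole.PPEP and _protein_of(n) == hog1_protein
        ]
        if gpd1_node not in net.nodes or not hog1_forms:
            raise ValueError("Gpd1/Hog1 peptide nodes absent; cannot add feedback loop")
        for h in hog1_forms:
            net.add_edge(gpd1_node, -1, h)
            net.add_edge(h, -1, gpd1_node)
    for edge in spec.removed_edges:
        edge = (edge[0], int(edge[1]), edge[2])
        if edge not in net.edges:
            raise ValueError(f"cannot remove non-existent edge {edge}")
        net.edges.remove(edge)
    _prune_unreachable(net)
    return net


def _prune_unreachable(net: LogicNetwork) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((s, t) for s, _sg, t in net.edges)
    for _gate, (ins, t) in net.and_gates.items():
        for s, _sg in ins:
            g.add_edge(s, t)
    reachable: set[str] = set()
    for stim in net.stimulus_nodes:
        reachable.add(stim)
        reachable |= nx.descendants(g, stim)
    doomed = {
        n
        for n, (role, measured) in net.nodes.items()
        if role is NodeRole.PROTEIN and not measured and n not in reachable
    }
    if doomed:
        net.edges = {e for e in net.edges if e[0] not in doomed and e[2] not in doomed}
        net.and_gates = {
            g_id: (ins, t)
            for g_id, (ins, t) in net.and_gates.items()
            if t not in doomed and all(s not in doomed for s, _ in ins)
        }
        for n in doomed:
            del net.nodes[n]


@dataclass(frozen=True)
class EnsembleScheme:
    mechanism_combos: list[tuple[bool, bool]] = field(
        default_factory=lambda: [(False, False), (True, False), (False, True), (True, True)]
    )
    no_effect_groups: dict[str, tuple[Edge, ...]] = field(default_factory=dict)
    single_removals: tuple[Edge, ...] = ()


def enumerate_ensemble(
    base_model: LogicNetwork,
    scheme: EnsembleScheme | None = None,
) -> list[tuple[str, VariantSpec, LogicNetwork]]:
    """All model variants of the scheme, deduplicated by resulting network.

    Default scheme: 4 mechanism combinations + one variant per No-Effect
    interaction group + 15 single-interaction removals = 23 models.
    """
    scheme = scheme or load_ensemble_scheme()
    specs: list[VariantSpec] = []
    for restrict, loop in scheme.mechanism_combos:
        tag = {
            (False, False): "base",
            (True, False): "ste20_T511",
            (False, True): "gpd1_loop",
            (True, True): "both_mechanisms",
        }.get((restrict, loop), f"mech_{restrict}_{loop}")
        specs.append(VariantSpec(restrict, loop, (), name=tag))
    for gname, edges in scheme.no_effect_groups.items():
        specs.append(VariantSpec(False, False, tuple(edges), name=f"no_effect_{gname}"))
    for edge in scheme.single_removals:
        specs.append(
            VariantSpec(False, False, (edge,), name=f"minus_{edge[0]}__{edge[2]}")
        )
    models: list[tuple[str, VariantSpec, LogicNetwork]] = []
    seen: list[LogicNetwork] = []
    for spec in specs:
        model = apply_variant(base_model, spec)
        if any(model == m for m in seen):
            log.warning("variant %s duplicates an earlier model; collapsed", spec.name)
            continue
        seen.append(model)
        models.append((spec.name, spec, model))
    return models
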