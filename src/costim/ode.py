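"""Logic-based ODE transform, simulation, fitting, and model comparison.

Each non-stimulus node x follows

    dx/dt = tau_x * (Phi_x(inputs) - x)

where Phi_x combines incoming influences with soft Boolean logic: an
activating edge contributes the normalized Hill transfer

    f(u) = u^n * (1 + k^n) / (u^n + k^n)        (f(0)=0, f(1)=1)

an inhibiting edge contributes 1 - f(u), an AND gate the product of its
input transfers, and multiple incoming edges/gates combine as OR:
1 - prod(1 - term). Stimulus nodes are clamped to 1 from t=0 when applied
in a condition, else 0. tau is the activation time-scale (1/min); n and k
shape the Hill transfer per edge.

Data for fitting are normalized to [0, 1] with a Hill transform (default
coefficient 4) whose half-point k is the per-peptide median of all data
points, which prevents very large intensities from dominating.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import OptimizeResult, differential_evolution, least_squares

from .core import LogicNetwork, NodeRole, StimulationDesign

__all__ = [
    "OdeParams",
    "FitResult",
    "OptimizerConfig",
    "hill_normalize",
    "select_training_conditions",
    "to_logic_ode",
    "OdeSystem",
    "simulate",
    "mse",
    "aic",
    "fit",
    "compare_models",
]

log = logging.getLogger(__name__)

Edge = tuple[str, int, str]

TAU_BOUNDS = (0.01, 2.0)
HILL_N_BOUNDS = (1.0, 10.0)
HILL_K_BOUNDS = (0.01, 0.99)


@dataclass
class OdeParams:
    """tau per dynamic node; (n, k) per edge (gate input edges included)."""

    tau: dict[str, float]
    hill_n: dict[Edge, float]
    hill_k: dict[Edge, float]

    def validate(self, system: "OdeSystem") -> None:
        for node in system.dynamic_nodes:
            if self.tau.get(node, 0.0) <= 0:
                raise ValueError(f"tau for {node} must be positive")
        for edge in system.edge_list:
            n, k = self.hill_n.get(edge), self.hill_k.get(edge)
            if n is None or not (1.0 <= n <= 10.0):
                raise ValueError(f"hill_n for {edge} must lie in [1, 10]")
            if k is None or not (0.0 < k < 1.0):
                raise ValueError(f"hill_k for {edge} must lie in (0, 1)")


def hill_normalize(values, n: float = 4.0, k: float | None = None) -> np.ndarray:
    """Nonlinear normalization x -> x^n / (x^n + k^n) into [0, 1].

    ``k`` defaults to the midpoint of the empirical cumulative distribution
    (the median) of the peptide's data points.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size == 0 or (finite <= 0).any():
        raise ValueError("hill_normalize requires positive values")
    if k is None:
        if np.unique(finite).size < 2:
            raise ValueError("all values identical; Hill midpoint k is degenerate")
        k = float(np.median(finite))
    return x**n / (x**n + k**n)


def select_training_conditions(design: StimulationDesign) -> list[tuple[int, int]]:
    """First row, first column, and diagonal of the stimulation matrix.

    These share a single time origin (both stimuli, when applied, start at
    t=0), which is what makes them representable by step-clamp logic ODEs.
    """
    conds: list[tuple[int, int]] = []
    for tn in design.nacl_times:  # NaCl only
        conds.append((tn, 0))
    for tp in design.phe_times:  # pheromone only
        conds.append((0, tp))
    for t in design.nacl_times:  # simultaneous co-stimulation
        if t in design.phe_times:
            conds.append((t, t))
    seen, out = set(), []
    for c in conds:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


class OdeSystem:
    """Compiled right-hand side of the logic ODEs for one network."""

    def __init__(self, network: LogicNetwork):
        self.network = network
        self.stimuli = network.stimulus_nodes
        species = sorted(n for n, (r, _) in network.nodes.items() if r is not NodeRole.STIMULUS)
        self.species = species
        self._index = {n: i for i, n in enumerate(species)}
        # terms per node: list of lists of (source, sign, edge_key); inner list
        # length > 1 means an AND gate (product of transfers)
        self.terms: dict[str, list[list[tuple[str, int, Edge]]]] = {n: [] for n in species}
        for src, sign, tgt in sorted(network.edges):
            self.terms[tgt].append([(src, sign, (src, sign, tgt))])
        for gate_id, (inputs, tgt) in sorted(network.and_gates.items()):
            self.terms[tgt].append([(s, sg, (s, sg, f"{gate_id}->{tgt}")) for s, sg in inputs])
        self.dynamic_nodes = [n for n in species if self.terms[n]]
        self.constant_nodes = [n for n in species if not self.terms[n]]
        for n in self.constant_nodes:
            log.warning("%s has no inputs and no clamp; held constant at its initial state", n)
        self.edge_list: list[Edge] = sorted(
            {e for terms in self.terms.values() for group in [terms] for term in group for (_s, _sg, e) in term}
        )
        self._build_arrays()

    def _build_arrays(self) -> None:
        """Flatten the gate structure into reduceat-ready arrays."""
        part_src: list[str] = []       # source node or stimulus name per part
        part_sign: list[int] = []
        part_edge: list[Edge] = []
        group_starts: list[int] = []   # part index where each AND-group starts
        node_starts: list[int] = []    # group index where each node's OR starts
        dyn_idx: list[int] = []
        for node in self.dynamic_nodes:
            node_starts.append(len(group_starts))
            dyn_idx.append(self._index[node])
            for term in self.terms[node]:
                group_starts.append(len(part_src))
                for src, sign, ekey in term:
                    part_src.append(src)
                    part_sign.append(sign)
                    part_edge.append(ekey)
        self._part_src = part_src
        self._part_sign_pos = np.array([s == 1 for s in part_sign])
        self._part_edge = part_edge
        self._group_starts = np.array(group_starts, dtype=np.intp)
        self._node_starts = np.array(node_starts, dtype=np.intp)
        self._dyn_idx = np.array(dyn_idx, dtype=np.intp)
        self._part_state_idx = np.array(
            [self._index.get(s, -1) for s in part_src], dtype=np.intp
        )
        self._part_is_state = self._part_state_idx >= 0

    def default_params(self, tau: float = 0.5, n: float = 4.0, k: float = 0.5) -> OdeParams:
        return OdeParams(
            tau={node: tau for node in self.dynamic_nodes},
            hill_n={e: n for e in self.edge_list},
            hill_k={e: k for e in self.edge_list},
        )

    def _compile(self, params: OdeParams, stim_levels: dict[str, float]):
        n_species = len(self.species)
        n_arr = np.array([params.hill_n[e] for e in self._part_edge])
        k_arr = np.array([params.hill_k[e] for e in self._part_edge])
        kn = k_arr**n_arr
        one_plus_kn = 1.0 + kn
        tau = np.array([params.tau[node] for node in self.dynamic_nodes])
        const_u = np.array(
            [0.0 if is_state else stim_levels.get(src, 0.0)
             for src, is_state in zip(self._part_src, self._part_is_state)]
        )
        is_state = self._part_is_state
        state_idx = self._part_state_idx
        sign_pos = self._part_sign_pos
        g_starts, nd_starts, dyn_idx = self._group_starts, self._node_starts, self._dyn_idx

        def rhs(_t, y):
            u = np.where(is_state, y[np.maximum(state_idx, 0)], const_u)
            np.clip(u, 0.0, 1.0, out=u)
            un = u**n_arr
            f = un * one_plus_kn / (un + kn)
            sv = np.where(sign_pos, f, 1.0 - f)
            term = np.multiply.reduceat(sv, g_starts)
            phi = 1.0 - np.multiply.reduceat(1.0 - term, nd_starts)
            dy = np.zeros(n_species)
            dy[dyn_idx] = tau * (phi - y[dyn_idx])
            return dy

        return rhs

    def _compile_multi(self, params: OdeParams, level_sets: list[dict[str, float]]):
        """RHS for all conditions stacked into one state vector (fit fast path)."""
        n_cond = len(level_sets)
        n_species = len(self.species)
        P = len(self._part_edge)
        n_arr = np.tile(np.array([params.hill_n[e] for e in self._part_edge]), n_cond)
        k_arr = np.tile(np.array([params.hill_k[e] for e in self._part_edge]), n_cond)
        kn = k_arr**n_arr
        one_plus_kn = 1.0 + kn
        tau = np.tile(np.array([params.tau[n] for n in self.dynamic_nodes]), n_cond)
        const_u = np.concatenate(
            [
                [0.0 if is_state else levels.get(src, 0.0)
                 for src, is_state in zip(self._part_src, self._part_is_state)]
                for levels in level_sets
            ]
        )
        is_state = np.tile(self._part_is_state, n_cond)
        state_idx = np.concatenate(
            [np.maximum(self._part_state_idx, 0) + c * n_species for c in range(n_cond)]
        )
        sign_pos = np.tile(self._part_sign_pos, n_cond)
        g_starts = np.concatenate([self._group_starts + c * P for c in range(n_cond)])
        G = len(self._group_starts)
        nd_starts = np.concatenate([self._node_starts + c * G for c in range(n_cond)])
        dyn_idx = np.concatenate([self._dyn_idx + c * n_species for c in range(n_cond)])

        def rhs(_t, y):
            u = np.where(is_state, y[state_idx], const_u)
            np.clip(u, 0.0, 1.0, out=u)
            un = u**n_arr
            f = un * one_plus_kn / (un + kn)
            sv = np.where(sign_pos, f, 1.0 - f)
            term = np.multiply.reduceat(sv, g_starts)
            phi = 1.0 - np.multiply.reduceat(1.0 - term, nd_starts)
            dy = np.zeros(n_cond * n_species)
            dy[dyn_idx] = tau * (phi - y[dyn_idx])
            return dy

        return rhs


def to_logic_ode(network: LogicNetwork) -> OdeSystem:
    """Compile a logic network into an integrable ODE system."""
    return OdeSystem(network)


def simulate(
    system: OdeSystem,
    params: OdeParams,
    condition: dict[str, float] | tuple[int, int],
    t_grid,
    y0: dict[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> pd.DataFrame:
    """Integrate one condition; returns trajectories clipped to [0, 1].

    ``condition`` is either a stimulus->level mapping (step clamps from
    t=0) or a (t_nacl, t_phe) pair of stimulation periods, in which case
    each stimulus switches on for the final period before harvest at
    t = max(t_nacl, t_phe) (equivalent to step clamps for single-origin
    conditions).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    y_init = np.zeros(len(system.species))
    for node, v in (y0 or {}).items():
        y_init[system._index[node]] = v

    if isinstance(condition, dict):
        horizon = float(t_grid[-1]) if len(t_grid) else 0.0
        if horizon == 0.0:
            values = np.tile(y_init, (len(t_grid), 1))
        else:
            rhs = system._compile(params, {s: float(condition.get(s, 0.0)) for s in system.stimuli})
            sol = solve_ivp(
                rhs, (0.0, horizon), y_init,
                t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed for condition {condition}: {sol.message}")
            values = sol.y.T
    else:
        tn, tp = condition
        horizon = float(max(tn, tp))
        onsets = {"NaCl": horizon - tn if tn > 0 else np.inf,
                  "Phe": horizon - tp if tp > 0 else np.inf}
        stim_names = system.stimuli
        onset_by_stim = {}
        for s in stim_names:
            key = "NaCl" if "nacl" in s.lower() else "Phe"
            onset_by_stim[s] = onsets.get(key, np.inf)
        switch_times = sorted({v for v in onset_by_stim.values() if np.isfinite(v)} | {0.0, horizon})
        values = np.tile(y_init, (len(t_grid), 1))
        y = y_init.copy()
        for a, b in zip(switch_times, switch_times[1:] + [horizon]):
            if b <= a:
                continue
            levels = {s: 1.0 if onset_by_stim[s] <= a else 0.0 for s in stim_names}
            rhs = system._compile(params, levels)
            inside = (t_grid >= a) & (t_grid <= b)
            t_eval = np.unique(np.concatenate([t_grid[inside], [b]]))
            sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"integration failed for condition {condition}: {sol.message}")
            for ti, tv in enumerate(sol.t):
                hits = np.where(inside & np.isclose(t_grid, tv))[0]
                values[hits] = sol.y.T[ti]
            y = sol.y[:, -1]
    return pd.DataFrame(np.clip(values, 0.0, 1.0), index=t_grid, columns=system.species)


def mse(simulated: pd.DataFrame, data: pd.DataFrame, node_subset: list[str]) -> float:
    """Mean squared residual over observed points of the node subset.

    Both frames are indexed alike (condition/time rows); NaN data points are
    ignored.
    """
    if not node_subset:
        raise ValueError("node_subset must not be empty")
    resid = (simulated[node_subset] - data[node_subset]).to_numpy(dtype=float)
    obs = np.isfinite(data[node_subset].to_numpy(dtype=float))
    if not obs.any():
        raise ValueError("no observed data points in node subset")
    return float(np.mean(resid[obs] ** 2))


def aic(mse_value: float, n_points: int, n_params: int, formula: str = "n_ln_mse") -> float:
    """Akaike information criterion from an MSE fit summary.

    Default formula: n * ln(MSE) + 2k. An MSE of exactly 0 returns -inf
    with a warning (a perfect fit dominates any ranking).
    """
    if mse_value < 0:
        raise ValueError("mse must be >= 0")
    if mse_value == 0:
        warnings.warn("MSE is 0; AIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    if formula == "n_ln_mse":
        return n_points * math.log(mse_value) + 2 * n_params
    raise ValueError(f"unknown AIC formula {formula!r}")


@dataclass(frozen=True)
class OptimizerConfig:
    n_restarts: int = 10
    eval_budget: int = 3000  # objective-evaluation budget per restart
    seed: int = 0
    popsize: int = 12
    polish_frac: float = 0.25  # share of each restart's budget for local refinement
    tau_bounds: tuple[float, float] = TAU_BOUNDS
    n_bounds: tuple[float, float] = HILL_N_BOUNDS
    k_bounds: tuple[float, float] = HILL_K_BOUNDS
    fit_hill: bool = True


@dataclass
class FitResult:
    params: OdeParams
    mse: float
    n_points: int
    n_params: int
    aic: float
    seed: int
    evals_used: int
    best_per_restart: list[float]
    node_subset: list[str] = field(default_factory=list)
    aic_formula: str = "n_ln_mse"


def _pack_bounds(system: OdeSystem, cfg: OptimizerConfig):
    bounds = [cfg.tau_bounds] * len(system.dynamic_nodes)
    if cfg.fit_hill:
        for _ in system.edge_list:
            bounds.extend([cfg.n_bounds, cfg.k_bounds])
    return bounds


def _unpack(theta: np.ndarray, system: OdeSystem, cfg: OptimizerConfig, base: OdeParams) -> OdeParams:
    m = len(system.dynamic_nodes)
    tau = {node: float(theta[i]) for i, node in enumerate(system.dynamic_nodes)}
    if cfg.fit_hill:
        hill_n, hill_k = {}, {}
        for j, edge in enumerate(system.edge_list):
            hill_n[edge] = float(theta[m + 2 * j])
            hill_k[edge] = float(theta[m + 2 * j + 1])
    else:
        hill_n, hill_k = dict(base.hill_n), dict(base.hill_k)
    return OdeParams(tau, hill_n, hill_k)


def fit(
    system: OdeSystem,
    conditions: pd.DataFrame,
    measurements: pd.DataFrame,
    cfg: OptimizerConfig | None = None,
    node_subset: list[str] | None = None,
    y0: dict[str, float] | None = None,
    aic_formula: str = "n_ln_mse",
) -> FitResult:
    """Best-of-restarts global fit of tau and Hill parameters.

    ``conditions``/``measurements`` follow the MIDAS reader convention:
    one row per (treatment pattern, time); measured columns must be system
    species. Each restart runs a seeded differential-evolution phase
    followed by bounded least-squares refinement under a per-restart
    objective-evaluation budget (when the budget cannot afford two DE
    generations the global phase degenerates to a seeded random start).
    Deterministic for a fixed seed; restart starting points are drawn from
    one seed-derived stream, so adding restarts never worsens the best fit.
    """
    cfg = cfg or OptimizerConfig()
    node_subset = node_subset or [c for c in measurements.columns if c in system.species]
    missing = [n for n in node_subset if n not in system.species]
    if missing:
        raise ValueError(f"measured nodes absent from the model: {missing}")

    patterns = conditions[["TR:NaCl", "TR:Phe"]].drop_duplicates().itertuples(index=False)
    pattern_rows = {}
    for tr_nacl, tr_phe in patterns:
        mask = (conditions["TR:NaCl"] == tr_nacl) & (conditions["TR:Phe"] == tr_phe)
        pattern_rows[(tr_nacl, tr_phe)] = conditions.index[mask]

    stim_map = {}
    for s in system.stimuli:
        stim_map[s] = "TR:NaCl" if "nacl" in s.lower() else "TR:Phe"

    data_mat = measurements[node_subset].to_numpy(dtype=float)
    obs_mask = np.isfinite(data_mat)
    n_points = int(obs_mask.sum())
    if n_points == 0:
        raise ValueError("no observed data points to fit")
    col_idx = [node_subset.index(n) for n in node_subset]

    evals = {"n": 0}
    base_params = system.default_params()
    # precompute a stacked evaluation plan: one ODE solve covers all patterns
    level_sets, plan = [], []
    all_times = sorted(set(conditions["time"].astype(float)))
    t_union = np.array(all_times)
    time_pos = {t: i for i, t in enumerate(all_times)}
    node_pos = np.array([system._index[n] for n in node_subset])
    n_species = len(system.species)
    for c, ((tr_nacl, tr_phe), rows) in enumerate(pattern_rows.items()):
        clamp = {s: float(conditions.loc[rows[0], stim_map[s]]) for s in system.stimuli}
        level_sets.append(clamp)
        times = conditions.loc[rows, "time"].to_numpy(dtype=float)
        data = measurements.loc[rows, node_subset].to_numpy(dtype=float)
        t_idx = np.array([time_pos[t] for t in times])
        plan.append((c, t_idx, data, np.isfinite(data)))
    y_init = np.zeros(n_species)
    for node, v in (y0 or {}).items():
        y_init[system._index[node]] = v
    y0_full = np.tile(y_init, len(level_sets))

    def residuals(theta: np.ndarray) -> np.ndarray:
        evals["n"] += 1
        params = _unpack(theta, system, cfg, base_params)
        rhs = system._compile_multi(params, level_sets)
        sol = solve_ivp(
            rhs, (0.0, float(t_union[-1])), y0_full,
            t_eval=t_union, method="LSODA", rtol=1e-6, atol=1e-8,
        )
        if not sol.success:
            return np.full(n_points, 1e3)
        Y = np.clip(sol.y.T, 0.0, 1.0)  # (times, n_cond * n_species)
        out = []
        for c, t_idx, data, ok in plan:
            sim = Y[np.ix_(t_idx, c * n_species + node_pos)]
            out.append((sim - np.nan_to_num(data))[ok])
        return np.concatenate(out)

    def objective(theta: np.ndarray) -> float:
        r = residuals(theta)
        return float(np.mean(r**2))

    bounds = _pack_bounds(system, cfg)
    dim = len(bounds)
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(cfg.seed)
    per_restart = max(cfg.eval_budget, dim * 4)
    de_budget = int(per_restart * (1.0 - cfg.polish_frac))
    maxiter = max(de_budget // (cfg.popsize * dim) - 1, 1)

    best_theta, best_val = None, math.inf
    best_per_restart: list[float] = []
    for _ in range(cfg.n_restarts):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        if de_budget >= 2 * cfg.popsize * dim:
            res: OptimizeResult = differential_evolution(
                objective,
                bounds,
                seed=restart_seed,
                maxiter=maxiter,
                popsize=cfg.popsize,
                tol=0.0,
                polish=False,
                init="sobol",
            )
            theta, val = res.x, float(res.fun)
        else:
            # budget below two DE generations: seeded random start, local only
            r = np.random.default_rng(restart_seed)
            theta = lower + r.random(dim) * (upper - lower)
            val = objective(theta)
        de_ran = de_budget >= 2 * cfg.popsize * dim
        ls_budget = int(per_restart * cfg.polish_frac) if de_ran else per_restart
        if ls_budget > dim:
            local = least_squares(
                residuals,
                np.clip(theta, lower + 1e-9, upper - 1e-9),
                bounds=(lower, upper),
                max_nfev=max(ls_budget // (dim + 1), 2),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            lval = float(np.mean(local.fun**2))
            if lval < val:
                theta, val = local.x, lval
        best_per_restart.append(val)
        if val < best_val:
            best_theta, best_val = theta, val

    params = _unpack(best_theta, system, cfg, base_params)
    k = dim
    return FitResult(
        params=params,
        mse=best_val,
        n_points=n_points,
        n_params=k,
        aic=aic(best_val, n_points, k, aic_formula) if best_val > 0 else -math.inf,
        seed=cfg.seed,
        evals_used=evals["n"],
        best_per_restart=best_per_restart,
        node_subset=list(node_subset),
        aic_formula=aic_formula,
    )


def compare_models(fits: dict[str, FitResult], node_subset: list[str]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending).

    All fits must have been evaluated on the same node subset; otherwise
    their MSEs are not comparable.
    """
    rows = []
    for model_id, res in fits.items():
        if sorted(res.node_subset) != sorted(node_subset):
            raise ValueError(
                f"{model_id} was evaluated on {res.node_subset}, expected {node_subset}"
            )
        rows.append((model_id, res.mse, res.n_params, res.aic))
    table = pd.DataFrame(rows, columns=["model_id", "mse", "n_params", "aic"])
    return table.sort_values("aic", kind="stable").reset_index(drop=True)
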