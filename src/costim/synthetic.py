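"""Synthetic co-stimulation data with known ground truth.

Every downstream stage (preprocessing, effect classification, specificity,
network construction, logic-ODE fitting) is exercised on data produced here,
so the generator plants the behaviors the real experiment exhibits:

* base temporal archetypes — a transient spike (fast MAPK activation that
  peaks around 5 min and decays), a gradual sigmoid rise peaking around
  20 min, a sustained rise, and a flat non-responder;
* crosstalk modifiers driven by the *other* stimulus' duration — a dip at
  one co-stimulation period (transient down-regulation), a monotone
  intensity scaling, and a phase shift that changes curve timing;
* measurement realism — multiplicative log-normal noise, per-run total-ion-
  current scale factors, and (optionally) missing observations.

Intensities are always strictly positive; missingness is encoded as NaN.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CoStimDataset,
    EffectLabel,
    StimulationDesign,
    run_id_for,
)

__all__ = [
    "BaseShape",
    "Modifier",
    "ArchetypeSpec",
    "NoiseModel",
    "TruthSet",
    "generate_design",
    "generate_truth",
    "add_noise",
    "effect_panel",
    "modeling_panel",
]


class BaseShape(str, enum.Enum):
    SPIKE = "SPIKE"
    GRADUAL = "GRADUAL"
    SUSTAINED = "SUSTAINED"
    FLAT = "FLAT"


class Modifier(str, enum.Enum):
    NONE = "NONE"
    DIP_AT = "DIP_AT"
    SCALE_BY_T2 = "SCALE_BY_T2"
    PHASE_SHIFT_BY_T2 = "PHASE_SHIFT_BY_T2"


def generate_design(
    nacl_times=(0, 1, 5, 10, 20, 45),
    phe_times=(0, 1, 5, 10, 20, 45),
    n_replicates: int = 3,
) -> StimulationDesign:
    """Build and validate the cross-product stimulation design."""
    return StimulationDesign(tuple(nacl_times), tuple(phe_times), n_replicates)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted P-pep behavior.

    The base shape evolves along the ``driving_axis`` stimulation time; the
    crosstalk modifier is driven by the other stimulus' duration (t2).
    ``planted_labels`` gives, per modulating stimulus, the effect class the
    construction implies: a non-flat base shape means the driving stimulus
    itself modulates the overall level (INTENSITY); DIP/SCALE modifiers are
    level modulations by the other stimulus (INTENSITY); a phase shift
    changes curve timing along both axes (SHAPE).
    """

    name: str
    base_shape: BaseShape
    amplitude: float = 1e5
    driving_axis: str = "nacl"  # axis whose time the base shape follows
    modifier: Modifier = Modifier.NONE
    dip_t2: int = 1
    dip_factor: float = 0.3
    scale_max: float = 2.5
    shift_max: float = 15.0
    peak_time: float = 5.0
    half_time: float = 10.0
    basal: float = 0.1

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"{self.name}: amplitude must be positive")
        if self.driving_axis not in ("nacl", "phe"):
            raise ValueError("driving_axis must be 'nacl' or 'phe'")
        if self.base_shape is BaseShape.FLAT and self.modifier is not Modifier.NONE:
            raise ValueError("FLAT archetypes cannot carry a crosstalk modifier")

    def shape_value(self, t: float) -> float:
        """Noise-free normalized response in (0, 1] along the driving axis."""
        b = self.basal
        if self.base_shape is BaseShape.FLAT:
            return 1.0
        if self.base_shape is BaseShape.SPIKE:
            x = t / self.peak_time
            s = x * math.exp(1.0 - x)
        elif self.base_shape is BaseShape.GRADUAL:
            # logistic rise with configurable half-time, slow linear decay after 20 min
            s = 1.0 / (1.0 + math.exp(-(t - self.half_time) / 2.5))
            if t > 20.0:
                s *= max(0.0, 1.0 - 0.012 * (t - 20.0))
        elif self.base_shape is BaseShape.SUSTAINED:
            s = 1.0 / (1.0 + math.exp(-(t - self.half_time / 2.0) / 1.5))
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown base shape {self.base_shape}")
        return b + (1.0 - b) * s

    def value(self, t_nacl: int, t_phe: int, t2_max: float) -> float:
        """Noise-free intensity at one condition of the design."""
        t1, t2 = (t_nacl, t_phe) if self.driving_axis == "nacl" else (t_phe, t_nacl)
        if self.modifier is Modifier.PHASE_SHIFT_BY_T2:
            shift = self.shift_max * (t2 / t2_max) if t2_max > 0 else 0.0
            v = self.amplitude * self.shape_value(max(t1 - shift, 0.0))
        else:
            v = self.amplitude * self.shape_value(t1)
            if self.modifier is Modifier.DIP_AT and t2 == self.dip_t2:
                v *= self.dip_factor
            elif self.modifier is Modifier.SCALE_BY_T2 and t2_max > 0:
                v *= 1.0 + (self.scale_max - 1.0) * (t2 / t2_max)
        return v

    @property
    def planted_labels(self) -> dict[str, EffectLabel]:
        """Effect class per modulating stimulus ('NaCl'/'Phe') implied by construction."""
        other = "Phe" if self.driving_axis == "nacl" else "NaCl"
        driving = "NaCl" if self.driving_axis == "nacl" else "Phe"
        if self.base_shape is BaseShape.FLAT:
            return {"NaCl": EffectLabel.NONE, "Phe": EffectLabel.NONE}
        labels = {driving: EffectLabel.INTENSITY, other: EffectLabel.NONE}
        if self.modifier in (Modifier.DIP_AT, Modifier.SCALE_BY_T2):
            labels[other] = EffectLabel.INTENSITY
        elif self.modifier is Modifier.PHASE_SHIFT_BY_T2:
            # timing changes propagate to curves along both axes
            labels[other] = EffectLabel.SHAPE
            labels[driving] = EffectLabel.SHAPE
        return labels


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise and run-level artifacts.

    ``cv_multiplicative`` is the coefficient of variation of the log-normal
    peptide-level noise; ``tic_spread`` the s.d. (log scale) of per-run scale
    factors; ``missing_rate`` the MCAR dropout probability per observation.
    """

    cv_multiplicative: float = 0.05
    tic_spread: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    intensity_dependent_dropout: bool = False
    dropout_midpoint_quantile: float = 0.1
    dropout_steepness: float = 2.0
    # An MS run's total ion current is dominated by the bulk proteome, which
    # a small simulated panel does not contain; the recorded TIC therefore
    # includes a constant background of this many times the mean per-condition
    # panel signal, scaled by the run factor. 0 restores panel-only TICs.
    tic_background_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.cv_multiplicative < 0:
            raise ValueError("cv_multiplicative must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


class TruthSet:
    """Noise-free intensity surfaces plus the planted effect labels."""

    def __init__(
        self,
        design: StimulationDesign,
        values: pd.DataFrame,
        labels: dict[str, dict[str, EffectLabel]],
        archetypes: dict[str, ArchetypeSpec],
    ):
        self.design = design
        self.values = values  # index (ppep_id, t_nacl, t_phe) -> column 'value'
        self.labels = labels
        self.archetypes = archetypes

    def grid(self, ppep_id: str) -> np.ndarray:
        sub = self.values.loc[ppep_id, "value"]
        return np.array(
            [
                [sub.loc[(tn, tp)] for tp in self.design.phe_times]
                for tn in self.design.nacl_times
            ]
        )


def generate_truth(design: StimulationDesign, archetypes: list[ArchetypeSpec]) -> TruthSet:
    """Evaluate archetype closed forms on every condition of the design."""
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("archetype names must be unique")
    rows = []
    for arch in archetypes:
        t2_axis = design.phe_times if arch.driving_axis == "nacl" else design.nacl_times
        t2_max = float(max(t2_axis))
        if arch.modifier is Modifier.DIP_AT and arch.dip_t2 not in t2_axis:
            raise ValueError(f"{arch.name}: dip_t2={arch.dip_t2} not on the modulating axis")
        for tn, tp in design.conditions:
            v = arch.value(tn, tp, t2_max)
            if v <= 0:
                raise ValueError(f"{arch.name}: non-positive truth value at ({tn},{tp})")
            rows.append((arch.name, tn, tp, v))
    values = pd.DataFrame(rows, columns=["ppep_id", "t_nacl", "t_phe", "value"]).set_index(
        ["ppep_id", "t_nacl", "t_phe"]
    )
    labels = {a.name: a.planted_labels for a in archetypes}
    return TruthSet(design, values, labels, {a.name: a for a in archetypes})


def add_noise(
    truth: TruthSet,
    noise: NoiseModel,
    proteins: dict[str, str] | None = None,
    per_ppep_cv: dict[str, float] | None = None,
    forced_missing: dict[str, list[tuple[int, int]]] | None = None,
) -> CoStimDataset:
    """Observe the truth through the noise model.

    observed = truth * run_scale * exp(eps) with eps ~ N(0, sigma),
    sigma = sqrt(ln(1 + cv^2)); each observation is independently missing
    with probability ``missing_rate`` (or via an intensity-dependent
    logistic dropout if enabled). The per-run TIC is recorded as the sum of
    the intensities actually observed in that run.

    ``per_ppep_cv`` overrides the noise CV for selected peptides and
    ``forced_missing`` blanks whole conditions of a peptide across all
    replicates; both exist so panels can plant filter-relevant pathologies.
    """
    rng = np.random.default_rng(noise.seed)
    design = truth.design
    per_ppep_cv = per_ppep_cv or {}
    forced_missing = forced_missing or {}
    ppeps = sorted(truth.values.index.get_level_values("ppep_id").unique())
    run_scales = {
        run_id_for(tn, tp, rep): float(rng.lognormal(0.0, noise.tic_spread))
        for tn, tp in design.conditions
        for rep in range(1, design.n_replicates + 1)
    }
    log_values = np.log(truth.values["value"])
    lo, hi = np.quantile(log_values, [0.0, 1.0])
    mid = np.quantile(log_values, noise.dropout_midpoint_quantile)
    span = max(hi - lo, 1e-9)

    records = []
    for ppep in ppeps:
        cv = per_ppep_cv.get(ppep, noise.cv_multiplicative)
        sigma = math.sqrt(math.log1p(cv * cv))
        blanked = set(map(tuple, forced_missing.get(ppep, [])))
        for tn, tp in design.conditions:
            base = truth.values.loc[(ppep, tn, tp), "value"]
            for rep in range(1, design.n_replicates + 1):
                run = run_id_for(tn, tp, rep)
                obs = base * run_scales[run] * math.exp(rng.normal(0.0, sigma)) if sigma > 0 else base * run_scales[run]
                if (tn, tp) in blanked:
                    obs = np.nan
                elif noise.intensity_dependent_dropout:
                    z = (math.log(base) - mid) / span * noise.dropout_steepness
                    p_drop = noise.missing_rate / (1.0 + math.exp(z * 4.0))
                    if rng.random() < p_drop:
                        obs = np.nan
                elif noise.missing_rate > 0 and rng.random() < noise.missing_rate:
                    obs = np.nan
                records.append((ppep, tn, tp, rep, run, obs))
    df = pd.DataFrame(
        records, columns=["ppep_id", "t_nacl", "t_phe", "replicate", "run_id", "intensity"]
    )
    proteins = proteins or {}
    df["protein"] = [proteins.get(p, p.split("_")[0]) for p in df["ppep_id"]]
    df["sites"] = ["_".join(p.split("_")[1:]) for p in df["ppep_id"]]
    df["sequence"] = ""
    df["n_phospho"] = 1
    observed_sum = df.groupby("run_id")["intensity"].sum(min_count=1).fillna(0.0)
    background = noise.tic_background_factor * float(truth.values["value"].sum()) / design.n_conditions
    tic = {
        run: background * run_scales[run] + float(observed_sum.get(run, 0.0))
        for run in run_scales
    }
    return CoStimDataset(df, design, tic)


def effect_panel(
    n_ppeps: int = 60,
    seed: int = 0,
    design: StimulationDesign | None = None,
) -> list[ArchetypeSpec]:
    """A balanced archetype panel covering all planted effect classes.

    Composition (for the default 60): flat non-responders, single-stimulus
    responders on each axis, intensity-modulated peptides (scalings and
    transient dips), and phase-shifted peptides, with per-peptide variation
    in amplitude, peak time, and half-time.
    """
    rng = np.random.default_rng(seed)
    design = design or StimulationDesign()
    groups = [
        ("flat", BaseShape.FLAT, None, Modifier.NONE),
        ("nacl", None, "nacl", Modifier.NONE),
        ("phe", None, "phe", Modifier.NONE),
        ("scaled", None, None, Modifier.SCALE_BY_T2),
        ("shifted", None, None, Modifier.PHASE_SHIFT_BY_T2),
    ]
    per = n_ppeps // len(groups)
    extra = n_ppeps - per * len(groups)
    counts = [per + (1 if i < extra else 0) for i in range(len(groups))]
    panel: list[ArchetypeSpec] = []
    for (tag, shape, axis, modifier), count in zip(groups, counts):
        for i in range(count):
            amp = float(10 ** rng.uniform(4.0, 6.0))
            shape_options = [BaseShape.SPIKE, BaseShape.GRADUAL, BaseShape.SUSTAINED]
            # timing shifts are only expressed on transient responses: a
            # few-minute phase shift leaves a slow sigmoid essentially
            # unchanged, so shape-modified peptides use the spike form
            if modifier is Modifier.PHASE_SHIFT_BY_T2:
                shape_options = [BaseShape.SPIKE]
            base = shape or shape_options[int(rng.integers(len(shape_options)))]
            driving = axis or ("nacl" if i % 2 == 0 else "phe")
            mod = modifier
            # a third of the intensity-modulated group are transient dips
            if modifier is Modifier.SCALE_BY_T2 and i % 3 == 2:
                mod = Modifier.DIP_AT
            spec = ArchetypeSpec(
                name=f"{tag}_{i:02d}",
                base_shape=BaseShape(base),
                amplitude=amp,
                driving_axis=driving,
                modifier=mod if base is not BaseShape.FLAT else Modifier.NONE,
                dip_t2=int(rng.choice([1, 5])),
                dip_factor=0.3,
                scale_max=float(rng.uniform(2.2, 3.0)),
                shift_max=float(rng.uniform(12.0, 18.0)),
                peak_time=float(rng.uniform(4.0, 6.5)),
                half_time=float(rng.uniform(8.0, 12.0)),
            )
            panel.append(spec)
    return panel


# ---------------------------------------------------------------------------
# modeling panel

_SHAPE_RECIPES = [
    dict(base_shape=BaseShape.SPIKE, driving_axis="nacl", peak_time=5.0),
    dict(base_shape=BaseShape.GRADUAL, driving_axis="phe", half_time=10.0),
    dict(base_shape=BaseShape.SUSTAINED, driving_axis="nacl", half_time=8.0),
    dict(base_shape=BaseShape.SPIKE, driving_axis="phe", peak_time=5.0),
    dict(base_shape=BaseShape.GRADUAL, driving_axis="nacl", half_time=12.0),
    dict(base_shape=BaseShape.SPIKE, driving_axis="nacl", peak_time=20.0),
    dict(base_shape=BaseShape.SUSTAINED, driving_axis="phe", half_time=12.0),
    dict(base_shape=BaseShape.FLAT, driving_axis="nacl"),
]

_NOISY_PPEPS = {
    "Ste20_S339": "Ste20",
    "Fus3_Y182": "Fus3",
    "Dig1_S330": "Dig1",
    "Ssk1_S110": "Ssk1",
}
_SPARSE_PPEPS = {
    "Pbs2_S23": "Pbs2",
    "Hog1_S360": "Hog1",
    "Ste12_S261": "Ste12",
    "Far1_S87": "Far1",
}
_REDUNDANT_PPEPS = {
    # duplicate peptide -> (protein, peptide whose trajectory it shadows)
    "Ste20_T596": ("Ste20", "Ste20_T511"),
    "Pbs2_S115": ("Pbs2", "Pbs2_S248"),
}


def modeling_panel(seed: int = 0):
    """Replicate-level dataset emulating the modeling-input measurements.

    Contains the shipped 33-peptide modeling list with clean, mutually
    distinct trajectories (one recipe per same-protein peptide), plus
    planted pathologies the selection cascade must remove: four peptides
    with high replicate variability, four with excessive missingness on the
    training conditions, and two redundant trajectories that duplicate a
    known-function peptide of the same protein.

    Returns (dataset, info) where info carries the expected modeling set,
    the known-function set, and the peptide->protein map.
    """
    from .network import load_modeling_peptides
    from .ode import select_training_conditions

    peptides = load_modeling_peptides()
    design = StimulationDesign()
    rng = np.random.default_rng(seed)

    archetypes: list[ArchetypeSpec] = []
    protein_of: dict[str, str] = {}
    recipe_index: dict[str, int] = {}

    def add_pep(ppep: str, protein: str, recipe: dict) -> None:
        amp = float(10 ** rng.uniform(4.0, 6.0))
        archetypes.append(ArchetypeSpec(name=ppep, amplitude=amp, **recipe))
        protein_of[ppep] = protein

    for protein, group in peptides.groupby("protein", sort=False):
        for offset, ppep in enumerate(group["ppep_id"]):
            recipe = _SHAPE_RECIPES[offset % len(_SHAPE_RECIPES)]
            recipe_index[ppep] = offset % len(_SHAPE_RECIPES)
            add_pep(ppep, protein, recipe)
    for ppep, protein in _NOISY_PPEPS.items():
        add_pep(ppep, protein, _SHAPE_RECIPES[0])
    for ppep, protein in _SPARSE_PPEPS.items():
        add_pep(ppep, protein, _SHAPE_RECIPES[1])
    for ppep, (protein, source) in _REDUNDANT_PPEPS.items():
        add_pep(ppep, protein, _SHAPE_RECIPES[recipe_index[source]])

    truth = generate_truth(design, archetypes)
    training = select_training_conditions(design)
    sparse_conditions = [c for c in training if c != (0, 0)][:6]
    dataset = add_noise(
        truth,
        NoiseModel(cv_multiplicative=0.05, tic_spread=0.05, missing_rate=0.0, seed=seed),
        proteins=protein_of,
        per_ppep_cv={p: 1.0 for p in _NOISY_PPEPS},
        forced_missing={p: sparse_conditions for p in _SPARSE_PPEPS},
    )
    info = {
        "expected_modeling_set": set(peptides["ppep_id"]),
        "known_function": set(peptides.loc[peptides["known_function"], "ppep_id"]),
        "protein_of": protein_of,
        "training_conditions": training,
    }
    return dataset, info
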