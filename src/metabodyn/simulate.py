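"""Synthetic batch-culture metabolome generator with known ground truth.

Emulates a heterotrophic plant suspension culture (BY-2-like) sampled
over a 26-day batch cycle: ~360 metabolites in annotated chemical
classes, five biological replicates at ten sampling days, four planted
temporal archetypes, pathway-coupled covariation, multiplicative
log-normal replicate noise, and sporadic missing values.  A companion
medium-kinetics model produces the sugar/biomass/pH trajectory of the
culture: sucrose is taken up directly and hydrolysed extracellularly to
hexoses, hexoses feed logistic dry-biomass growth, and the medium pH
dips during early acidification before rising toward culture death.

Temporal archetypes (clusters):

1. early-high, declining over the cycle (amino acids, sterols);
2. humps at inoculation, elongation and culture death (FFAs,
   carboxylates);
3. monotone accumulation over time (sugars);
4. transient mid-culture peak around days 7-14.

All randomness flows through a single integer seed; identical
configurations produce byte-identical datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import MetaboliteTable, PathwayAnnotation, Stage, write_annotation, write_feature_table, write_gmt

__all__ = [
    "MediumParams",
    "MediumTrajectory",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_medium",
    "simulate_metabolome",
    "inject_missingness",
]

DEFAULT_DAYS = (1, 2, 3, 4, 7, 14, 18, 21, 23, 26)

DEFAULT_CLASSES = {
    "amino acids": 0.075,
    "sugars": 0.15,
    "carboxylates": 0.085,
    "FFAs": 0.035,
    "sterols": 0.030,
    "glycosides": 0.10,
    "other": 0.525,
}

DEFAULT_ARCHETYPES = {1: 0.30, 2: 0.25, 3: 0.30, 4: 0.15}

# class composition bias per archetype: early decliners are enriched for
# amino acids and sterols, the rising cluster for sugars, the multi-hump
# cluster for FFAs and carboxylates
_CLASS_BIAS = {
    1: {"amino acids": 4.0, "sterols": 4.0},
    2: {"FFAs": 4.0, "carboxylates": 4.0},
    3: {"sugars": 4.0, "glycosides": 2.0},
    4: {},
}


# ----------------------------------------------------------------------
# medium kinetics
# ----------------------------------------------------------------------

@dataclass
class MediumParams:
    """Rate constants of the discrete-step medium model.

    Units: concentrations g/L (sugars) and mg/mL (dry biomass), time in
    days.  ``hydrolysis_yield`` is the mass gain of hydrolysis (342 g
    sucrose + 18 g water -> 360 g hexose, factor 360/342 = 1.053).
    """

    sucrose_0: float = 30.0        # g/L, standard MS-medium carbon source
    hexose_0: float = 0.0
    biomass_0: float = 0.55        # mg/mL dry biomass at inoculation
    k_hydrolysis: float = 0.35     # 1/day, extracellular invertase action
    k_sucrose_uptake: float = 0.05  # L/(mg/mL)/day, direct uptake per biomass
    k_hexose_uptake: float = 0.20   # L/(mg/mL)/day
    mu: float = 0.33               # 1/day, maximal specific growth rate
    biomass_max: float = 11.0      # mg/mL, dry-biomass carrying capacity
    k_substrate: float = 1.0       # g/L, half-saturation for growth on sugars
    hydrolysis_yield: float = 1.053
    fresh_per_dry: float = 32.0    # fresh:dry mass ratio for reporting
    ph_0: float = 5.8
    ph_min: float = 5.1
    ph_t_min: float = 2.0          # day of maximal acidification
    ph_inf: float = 6.3            # plateau reached at culture death
    ph_recovery: float = 0.15      # 1/day relaxation of the initial level

    def validate(self) -> None:
        for name in (
            "sucrose_0", "hexose_0", "biomass_0", "k_hydrolysis",
            "k_sucrose_uptake", "k_hexose_uptake", "mu", "biomass_max",
            "k_substrate", "hydrolysis_yield",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")


@dataclass
class MediumTrajectory:
    """Daily medium state: sugars, biomass and pH."""

    time: np.ndarray          # days, 0..horizon
    sucrose: np.ndarray       # g/L
    hexose: np.ndarray        # g/L
    biomass_dry: np.ndarray   # mg/mL
    biomass_fresh: np.ndarray # mg/mL
    ph: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.time,
                "sucrose": self.sucrose,
                "hexose": self.hexose,
                "biomass_dry": self.biomass_dry,
                "biomass_fresh": self.biomass_fresh,
                "pH": self.ph,
            }
        )


def simulate_medium(
    params: MediumParams | None = None, horizon: int = 26, steps_per_day: int = 4
) -> MediumTrajectory:
    """Integrate the three-flux medium model with daily output.

    Fluxes: direct sucrose uptake by biomass, extracellular hydrolysis of
    sucrose to hexose (with the water-gain yield factor), and hexose
    uptake feeding logistic dry-biomass growth limited by total sugar
    availability.  pH follows a phenomenological dip-then-rise curve
    anchored at the early acidification minimum and the death-phase
    plateau.  Pools are clipped at zero (with a warning) if a step would
    overshoot.
    """
    p = params or MediumParams()
    p.validate()
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    dt = 1.0 / steps_per_day
    n = horizon * steps_per_day
    s, h, b = p.sucrose_0, p.hexose_0, p.biomass_0
    out_s = [s]
    out_h = [h]
    out_b = [b]
    clipped = False
    for i in range(n):
        hydrolysis = p.k_hydrolysis * s
        upt_s = p.k_sucrose_uptake * b * s / (p.k_substrate + s + h)
        upt_h = p.k_hexose_uptake * b * h / (p.k_substrate + s + h)
        substrate = (s + h) / (p.k_substrate + s + h)
        growth = p.mu * b * (1.0 - b / p.biomass_max) * substrate
        s = s - dt * (hydrolysis + upt_s)
        h = h + dt * (p.hydrolysis_yield * hydrolysis - upt_h)
        b = b + dt * growth
        if s < 0 or h < 0:
            clipped = True
        s, h = max(s, 0.0), max(h, 0.0)
        if (i + 1) % steps_per_day == 0:
            out_s.append(s)
            out_h.append(h)
            out_b.append(b)
    if clipped:
        warnings.warn("sugar pool clipped at zero during integration")
    time = np.arange(horizon + 1, dtype=float)
    dry = np.asarray(out_b)
    ph = _ph_curve(time, p)
    return MediumTrajectory(
        time=time,
        sucrose=np.asarray(out_s),
        hexose=np.asarray(out_h),
        biomass_dry=dry,
        biomass_fresh=dry * p.fresh_per_dry,
        ph=ph,
    )


def _ph_curve(t: np.ndarray, p: MediumParams) -> np.ndarray:
    """Dip-then-rise pH: relax from ph_0 toward ph_inf plus a gamma-shaped
    acidification dip whose depth is solved to hit ph_min at ph_t_min."""
    base = p.ph_inf + (p.ph_0 - p.ph_inf) * np.exp(-p.ph_recovery * t)
    base_at_min = p.ph_inf + (p.ph_0 - p.ph_inf) * np.exp(-p.ph_recovery * p.ph_t_min)
    depth = base_at_min - p.ph_min
    dip = depth * (t / p.ph_t_min) * np.exp(1.0 - t / p.ph_t_min)
    return base - dip


# ----------------------------------------------------------------------
# metabolome generator
# ----------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic metabolome."""

    n_metabolites: int = 360
    class_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    sampling_days: tuple[int, ...] = DEFAULT_DAYS
    n_replicates: int = 5
    archetype_assignment: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    pathway_count: int = 20
    pathway_size_range: tuple[int, int] = (5, 15)
    # draw each pathway's members from a single archetype instead of at
    # random; with coupling 1 this makes within-pathway trajectories
    # affinely identical
    pathways_follow_archetypes: bool = False
    within_pathway_coupling: float = 0.6
    noise_sd: float = 0.25          # log-scale SD of replicate noise
    missing_rate: float = 0.02
    # replicate-noise correlation shared within a pathway, per growth phase
    # (days <= phase_boundary are "early"); distinct regimes give each
    # phase its own pair-covariation fingerprint
    phase_noise_coupling: dict[str, float] = field(
        default_factory=lambda: {"early": 0.7, "late": 0.15}
    )
    phase_boundary: int = 7
    perturbation_scale: float = 0.35  # SD of shape perturbations vs archetype
    baseline_log_mean: float = 11.5   # log peak-area scale (~1e5 counts)
    baseline_log_sd: float = 1.0
    amplitude_mean: float = 0.9       # log-fold dynamic range of trajectories
    amplitude_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_composition.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        days = list(self.sampling_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if abs(sum(self.archetype_assignment.values()) - 1.0) > 1e-9:
            raise ValueError("archetype fractions must sum to 1")
        if not (0.0 <= self.within_pathway_coupling <= 1.0):
            raise ValueError("within_pathway_coupling must be in [0, 1]")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid pathway_size_range")


@dataclass
class SyntheticDataset:
    """Generated table plus the ground truth used to generate it."""

    table: MetaboliteTable
    truth_clusters: dict[str, int]
    truth_pathways: PathwayAnnotation
    medium: MediumTrajectory
    mean_profiles: pd.DataFrame  # metabolites x days, noiseless means

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(self.table, outdir / "feature_table.csv")
        write_annotation(self.table, outdir / "annotation.tsv")
        write_gmt(self.truth_pathways, outdir / "pathways.gmt.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "clusters": self.truth_clusters,
                    "pathway_archetype": {},
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        self.medium.as_frame().to_csv(outdir / "medium.csv", index=False)


def _archetype_shapes(days: np.ndarray) -> dict[int, np.ndarray]:
    """Unit-variance archetype curves evaluated at the sampling days."""
    t = days.astype(float)
    raw = {
        1: 1.0 / (1.0 + np.exp((t - 6.0) / 2.5)),
        2: (
            0.9 * np.exp(-(((t - 1.0) / 2.5) ** 2))
            + 0.8 * np.exp(-(((t - 13.0) / 2.5) ** 2))
            + 0.9 * np.exp(-(((t - 26.0) / 3.0) ** 2))
        ),
        3: 1.0 / (1.0 + np.exp(-(t - 14.0) / 3.0)),
        4: np.exp(-(((t - 10.0) / 2.5) ** 2)),
    }
    out = {}
    for k, v in raw.items():
        v = v - v.mean()
        out[k] = v / v.std()
    return out


def _largest_remainder_counts(total: int, fractions: dict[int, float]) -> dict[int, int]:
    keys = sorted(fractions)
    quotas = {k: total * fractions[k] for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    short = total - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def _smooth_curve(rng: np.random.Generator, days: np.ndarray) -> np.ndarray:
    """Random smooth zero-mean unit-SD curve: mixture of 3 Gaussian bumps."""
    t = days.astype(float)
    span = t.max() - t.min()
    centers = rng.uniform(t.min(), t.max(), size=3)
    widths = rng.uniform(span / 8.0, span / 3.0, size=3)
    coefs = rng.normal(size=3)
    curve = np.zeros_like(t)
    for c, w, a in zip(centers, widths, coefs):
        curve += a * np.exp(-(((t - c) / w) ** 2))
    curve -= curve.mean()
    sd = curve.std()
    return curve / sd if sd > 0 else curve


def simulate_metabolome(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset from a :class:`SimulationConfig`.

    Each metabolite follows its archetype's temporal shape plus smooth
    perturbations shared within its pathway at strength
    ``within_pathway_coupling`` (at coupling 1 all members of a pathway
    have affinely identical noiseless trajectories).  Replicate values
    are the mean trajectory times log-normal noise whose within-pathway
    correlation differs between early and late growth phases.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    days = np.asarray(cfg.sampling_days)
    n_days, n_rep, M = len(days), cfg.n_replicates, cfg.n_metabolites

    # archetype assignment
    counts = _largest_remainder_counts(M, cfg.archetype_assignment)
    archetype = np.concatenate(
        [np.full(c, k, dtype=int) for k, c in sorted(counts.items())]
    )
    rng.shuffle(archetype)
    shapes = _archetype_shapes(days)

    # chemical classes, biased by archetype
    class_names = list(cfg.class_composition)
    base_p = np.array([cfg.class_composition[c] for c in class_names])
    classes = np.empty(M, dtype=object)
    for i in range(M):
        bias = np.array(
            [_CLASS_BIAS[archetype[i]].get(c, 1.0) for c in class_names]
        )
        p = base_p * bias
        classes[i] = class_names[rng.choice(len(class_names), p=p / p.sum())]

    # identification level: roughly 30% identified, 25% class-annotated
    id_level = rng.choice(
        ["identified", "class-annotated", "unknown"], size=M, p=[0.30, 0.25, 0.45]
    )
    names = np.array([f"M{i:03d}" for i in range(M)], dtype=object)

    # pathways among annotated metabolites; membership independent of
    # archetype unless pathways_follow_archetypes is set
    annotated = np.flatnonzero(id_level != "unknown")
    pathway_of = np.full(M, -1, dtype=int)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    arch_ids = sorted(cfg.archetype_assignment)
    lo, hi = cfg.pathway_size_range
    for pidx in range(cfg.pathway_count):
        if cfg.pathways_follow_archetypes:
            anchor = arch_ids[pidx % len(arch_ids)]
            pool = [i for i in annotated if archetype[i] == anchor and pathway_of[i] < 0]
        else:
            pool = [i for i in annotated if pathway_of[i] < 0]
        if len(pool) < max(lo, 2):
            continue
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(pool))
        members = rng.choice(pool, size=size, replace=False)
        pathway_of[members] = pidx
        sets[f"PW{pidx:02d}"] = (
            f"synthetic pathway {pidx}",
            tuple(names[sorted(members)]),
        )
    pathways = PathwayAnnotation(sets=sets)

    # noiseless mean trajectories
    c = cfg.within_pathway_coupling
    pw_pert = {p: _smooth_curve(rng, days) for p in np.unique(pathway_of) if p >= 0}
    pw_amp = {p: rng.lognormal(np.log(cfg.amplitude_mean), cfg.amplitude_sd)
              for p in pw_pert}
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=M)
    means = np.empty((M, n_days))
    for i in range(M):
        own_pert = _smooth_curve(rng, days)
        own_amp = rng.lognormal(np.log(cfg.amplitude_mean), cfg.amplitude_sd)
        pw = pathway_of[i]
        if pw >= 0:
            pert = np.sqrt(c) * pw_pert[pw] + np.sqrt(1.0 - c) * own_pert
            amp = c * pw_amp[pw] + (1.0 - c) * own_amp
        else:
            pert, amp = own_pert, own_amp
        shape = shapes[archetype[i]] + cfg.perturbation_scale * pert
        means[i] = baseline[i] * np.exp(amp * shape)

    # replicate noise: shared pathway component with phase-dependent weight
    rho_early = float(cfg.phase_noise_coupling.get("early", 0.0))
    rho_late = float(cfg.phase_noise_coupling.get("late", 0.0))
    values = np.empty((n_days * n_rep, M))
    sample_rows = []
    row = 0
    for d_idx, day in enumerate(days):
        rho = rho_early if day <= cfg.phase_boundary else rho_late
        for rep in range(1, n_rep + 1):
            z_pw = {p: rng.normal() for p in pw_pert}
            z_own = rng.normal(size=M)
            z = np.empty(M)
            for i in range(M):
                pw = pathway_of[i]
                if pw >= 0:
                    z[i] = rho * z_pw[pw] + np.sqrt(1.0 - rho**2) * z_own[i]
                else:
                    z[i] = z_own[i]
            values[row] = means[:, d_idx] * np.exp(cfg.noise_sd * z)
            sample_rows.append((f"D{day:02d}R{rep}", int(day), rep))
            row += 1

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "day", "replicate"])
    vdf = pd.DataFrame(values, index=samples["sample_id"].to_numpy(), columns=names)
    ann = pd.DataFrame({"metabolite": names, "class": classes, "id_level": id_level})
    table = MetaboliteTable(values=vdf, samples=samples, metabolites=ann, stage=Stage.RAW)
    if cfg.missing_rate > 0:
        table = inject_missingness(table, cfg.missing_rate, seed=int(cfg.seed) + 1)

    truth = {str(names[i]): int(archetype[i]) for i in range(M)}
    medium = simulate_medium(horizon=int(days.max()))
    profiles = pd.DataFrame(means, index=names, columns=days)
    return SyntheticDataset(
        table=table,
        truth_clusters=truth,
        truth_pathways=pathways,
        medium=medium,
        mean_profiles=profiles,
    )


def inject_missingness(
    table: MetaboliteTable, rate: float, seed: int
) -> MetaboliteTable:
    """Blank cells uniformly at random, sparing one replicate per group.

    No (metabolite, day) group is ever fully blanked, so the KNN
    imputation precondition (at least one observed replicate) holds by
    construction.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    arr = values.to_numpy()
    day = table.samples["day"].to_numpy()
    drop = rng.random(arr.shape) < rate
    # restore one observed replicate in any fully-blanked (metabolite, day)
    for d in np.unique(day):
        rows = np.flatnonzero(day == d)
        sub = drop[rows]
        full = sub.all(axis=0)
        for j in np.flatnonzero(full):
            keep = rows[rng.integers(len(rows))]
            drop[keep, j] = False
    arr = np.where(drop, np.nan, arr)
    values.iloc[:, :] = arr
    return MetaboliteTable(
        values=values,
        samples=table.samples.copy(),
        metabolites=table.metabolites.copy(),
        stage=table.stage,
        flags=dict(table.flags),
    )
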