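"""Synthetic study generator with planted ground truth.

The generator emulates the structure of a grassland-revegetation soil
survey: 11 plant-species groups x 3 replicate plots = 33 samples, a few
hundred fungal ASVs, soil chemistry, wet-sieve aggregate fractions, and a
FUNGuild-style trophic-mode map.  It exists so that every downstream stage
— rarefaction, network construction, Louvain modules, Zi-Pi, module-wise
Mantel linkage, MUCA/MRC/MRCA classification and trophic comparison — can
be exercised end to end against a known answer.

Generative model
----------------
Two independent standardised soil axes drive everything:

* a **chemical axis** (a single fertility/salinity gradient) with
  group-level mean shifts; the reported chemical variables (EC, AP) are
  near-collinear noisy readouts of it;
* an **aggregate-stability axis**, also group-structured, which tilts the
  wet-sieve mass distribution toward larger size classes.  WSA/MWD/GMD are
  *computed* from the simulated sieving masses by the aggregate-indices
  code, never synthesised directly.

Each planted ASV module gets one latent factor per sample.  Modules planted
as ``none`` get i.i.d. noise; ``chemical`` modules get
``±e * chem_axis + sqrt(1-e^2) * noise``; ``chemical+aggregate`` modules
get ``±w_c * chem_axis + w_a * agg_axis + noise`` with channel weights
``w_c = e * sqrt(chem_share)`` and ``w_a = e * sqrt(1-chem_share)``.  The
chemical sign alternates within each plan class (see
:func:`generate_latents`); Mantel linkage works on distances, so the sign
is invisible downstream.  ``e`` is the module's ``latent_effect``.  Member ASV counts are negative binomial
with log-mean ``baseline + loading * latent``, then each sample is
multinomially resampled to a random library depth, mimicking amplicon
compositionality.  Background ASVs split into a small common tier (always
passing the prevalence filter) and a large rare tier (mostly filtered out,
like the rare biosphere in real surveys).

The soil table is deliberately low-dimensional — one chemical axis with two
collinear readouts, one aggregate axis behind three collinear indices — the
minimal structure that can separate "chemical-only" from
"chemical+aggregate" linkage while keeping the number of effectively
independent null Mantel tests per module small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import child_rng
from .aggregates import SievingProfile, default_size_classes, indices_table

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDesign",
    "SyntheticDataset",
    "default_design",
    "generate_soil_and_sieving",
    "generate_latents",
    "generate_asv_table",
    "generate_guild_map",
    "generate_dataset",
    "SoilData",
    "recovered_module_map",
    "planted_ari",
]

TROPHIC_MODES = ("pathotroph", "saprotroph", "symbiotroph", "unassigned")
LINKAGE_PLANS = ("none", "chemical", "chemical+aggregate")
PLAN_TO_TYPE = {"none": "MUCA", "chemical": "MRC", "chemical+aggregate": "MRCA"}

_MODE_STRING = {
    "pathotroph": "Pathotroph",
    "saprotroph": "Saprotroph",
    "symbiotroph": "Symbiotroph",
}
_MODE_GUILD = {
    "pathotroph": "Plant Pathogen",
    "saprotroph": "Undefined Saprotroph",
    "symbiotroph": "Arbuscular Mycorrhizal",
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for one synthetic dataset.

    Defaults are the desk-scale study conditions: 33 samples, 300 ASVs,
    six planted modules of 25 ASVs (2 unlinked, 2 chemical-linked, 2
    chemical+aggregate-linked) over 150 background ASVs.
    """

    n_groups: int = 11
    reps_per_group: int = 3
    n_asvs: int = 300
    module_sizes: tuple[int, ...] = (25, 25, 25, 25, 25, 25)
    linkage_plan: tuple[str, ...] = (
        "none", "none", "chemical", "chemical",
        "chemical+aggregate", "chemical+aggregate",
    )
    #: corr(latent, driving axis combination) per planted module, in [0, 1].
    latent_effect: tuple[float, ...] = (0.0, 0.0, 0.66, 0.66, 0.97, 0.97)
    #: variance share of the chemical axis within a chemical+aggregate
    #: module's driven part (the rest loads on the aggregate axis).
    chem_share: float = 0.50
    #: per planted module: categorical distribution over trophic modes.
    trophic_plan: tuple[Mapping[str, float], ...] = (
        {"pathotroph": 0.03, "saprotroph": 0.82, "symbiotroph": 0.03, "unassigned": 0.12},
        {"pathotroph": 0.03, "saprotroph": 0.82, "symbiotroph": 0.03, "unassigned": 0.12},
        {"pathotroph": 0.05, "saprotroph": 0.08, "symbiotroph": 0.80, "unassigned": 0.07},
        {"pathotroph": 0.05, "saprotroph": 0.08, "symbiotroph": 0.80, "unassigned": 0.07},
        {"pathotroph": 0.80, "saprotroph": 0.10, "symbiotroph": 0.03, "unassigned": 0.07},
        {"pathotroph": 0.80, "saprotroph": 0.10, "symbiotroph": 0.03, "unassigned": 0.07},
    )
    background_trophic: Mapping[str, float] = field(
        default_factory=lambda: {
            "pathotroph": 0.10, "saprotroph": 0.50,
            "symbiotroph": 0.08, "unassigned": 0.32,
        }
    )
    #: library depth per sample, drawn uniformly from this inclusive range.
    depth_range: tuple[int, int] = (8000, 12000)
    #: negative-binomial size parameter (larger = less overdispersed).
    dispersion: float = 25.0
    #: background ASVs are far more overdispersed than the signal-carrying
    #: planted taxa, as abundant generalists usually are in amplicon data.
    common_dispersion: float = 3.0
    #: log-scale loading of member ASVs on their module latent.
    loading: float = 0.75
    loading_sd: float = 0.1
    #: log-mean baseline abundance of planted ASVs ~ N(log(15), 0.4^2).
    planted_log_mean: float = float(np.log(15.0))
    planted_log_sd: float = 0.3
    #: background tiers: a block of moderately common ASVs and a rare tail.
    n_background_common: int = 28
    common_log_mean: float = float(np.log(100.0))
    common_log_sd: float = 0.35
    rare_log_mean: float = float(np.log(0.04))
    rare_log_sd: float = 0.7
    #: share of soil-axis variance between groups (0 disables group effects).
    group_effect: float = 0.75
    #: readout noise sd of chemical variables around the chemical axis.
    chem_noise_sd: float = 0.03
    #: wet sieving: total mass, Dirichlet concentration, stability tilt.
    total_mass_g: float = 50.0
    dirichlet_conc: float = 8000.0
    stability_beta: float = 0.25
    #: guild map: chance an assigned ASV gets a composite mode string.
    composite_prob: float = 0.08
    confidence_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Highly Probable": 0.72, "Probable": 0.24, "Possible": 0.04,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.module_sizes, default=1) < 1:
            raise ValueError("planted module sizes must be >= 1")
        if sum(self.module_sizes) > self.n_asvs:
            raise ValueError("module sizes exceed n_asvs")
        if not (len(self.module_sizes) == len(self.linkage_plan)
                == len(self.latent_effect) == len(self.trophic_plan)):
            raise ValueError("per-module fields must have equal length")
        for plan in self.linkage_plan:
            if plan not in LINKAGE_PLANS:
                raise ValueError(f"unknown linkage plan {plan!r}")
        for e in self.latent_effect:
            if not 0.0 <= e <= 1.0:
                raise ValueError("latent_effect must lie in [0, 1]")
        for tp in (*self.trophic_plan, self.background_trophic):
            if abs(sum(tp.values()) - 1.0) > 1e-9:
                raise ValueError("trophic plan probabilities must sum to 1")
            if set(tp) - set(TROPHIC_MODES):
                raise ValueError(f"unknown trophic mode in plan: {tp}")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.group_effect < 1.0:
            raise ValueError("group_effect must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.reps_per_group

    @property
    def module_labels(self) -> tuple[str, ...]:
        return tuple(f"module_{i:02d}" for i in range(len(self.module_sizes)))

    def truth_module_types(self) -> dict[str, str]:
        return {
            lab: PLAN_TO_TYPE[plan]
            for lab, plan in zip(self.module_labels, self.linkage_plan)
        }


def default_design(**overrides) -> SyntheticDesign:
    """The documented default study design, optionally with field overrides."""
    return SyntheticDesign(**overrides)


def _sample_ids(design: SyntheticDesign) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(design.n_samples)]


def _group_labels(design: SyntheticDesign) -> pd.Series:
    groups = [
        f"sp{g + 1:02d}"
        for g in range(design.n_groups)
        for _ in range(design.reps_per_group)
    ]
    return pd.Series(groups, index=_sample_ids(design), name="group")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


@dataclass(frozen=True)
class SoilData:
    """Soil chemistry + computed aggregate indices, with their hidden axes."""

    soil_table: pd.DataFrame           # samples x variables
    blocks: dict[str, str]             # variable -> {"chemical", "aggregate"}
    profiles: tuple[SievingProfile, ...]
    axes: pd.DataFrame                 # samples x {chem_axis, agg_axis}
    groups: pd.Series                  # sample -> group


def _group_axis(design: SyntheticDesign, rng: np.random.Generator) -> np.ndarray:
    """A standardised sample-level axis with a group-level variance share."""
    h = design.group_effect
    u = rng.normal(size=design.n_groups)
    eps = rng.normal(size=design.n_samples)
    g = np.repeat(u, design.reps_per_group)
    return _zscore(np.sqrt(h) * g + np.sqrt(1.0 - h) * eps)


def generate_soil_and_sieving(
    design: SyntheticDesign, seed: int | None = None
) -> SoilData:
    """Simulate the soil-property table and per-sample sieving masses.

    Aggregate variables are never drawn directly: seven fraction masses per
    sample come from a Dirichlet distribution whose expected proportions are
    tilted toward coarse classes by the aggregate axis, and WSA/MWD/GMD are
    then computed from those masses by the aggregate-indices code.
    """
    seed = design.seed if seed is None else seed
    rng = child_rng(seed, "soil")
    samples = _sample_ids(design)
    chem_axis = _group_axis(design, rng)
    agg_axis = _group_axis(design, rng)
    # In-sample orthogonalisation: with only 11 groups the two axes would
    # often correlate by chance, blurring the planted distinction between
    # chemistry-only and chemistry+aggregate linkage.  Field observation
    # matches: aggregate stability and chemistry vary independently here.
    agg_axis = _zscore(agg_axis - (agg_axis @ chem_axis) / (chem_axis @ chem_axis) * chem_axis)

    # chemical readouts: two collinear variables on one fertility axis
    ec = 18.0 + 2.5 * (chem_axis + design.chem_noise_sd * rng.normal(size=len(samples)))
    ap = 10.0 + 3.0 * (chem_axis + design.chem_noise_sd * rng.normal(size=len(samples)))

    size_classes = default_size_classes()
    base = np.array([0.16, 0.18, 0.20, 0.21, 0.10, 0.07, 0.08])
    tilt = np.linspace(1.0, -1.0, len(size_classes))
    profiles = []
    for i, sid in enumerate(samples):
        logits = np.log(base) + design.stability_beta * agg_axis[i] * tilt
        props = np.exp(logits - logits.max())
        props /= props.sum()
        props = rng.dirichlet(design.dirichlet_conc * props)
        masses = tuple(float(m) for m in props * design.total_mass_g)
        profiles.append(SievingProfile(sid, size_classes, masses))

    agg = indices_table(profiles)
    soil = pd.DataFrame({"EC": ec, "AP": ap}, index=pd.Index(samples, name="sample_id"))
    soil["WSA"] = agg["wsa"].to_numpy()
    soil["MWD"] = agg["mwd_mm"].to_numpy()
    soil["GMD"] = agg["gmd_mm"].to_numpy()
    blocks = {"EC": "chemical", "AP": "chemical",
              "WSA": "aggregate", "MWD": "aggregate", "GMD": "aggregate"}
    axes = pd.DataFrame(
        {"chem_axis": chem_axis, "agg_axis": agg_axis},
        index=soil.index,
    )
    return SoilData(
        soil_table=soil, blocks=blocks, profiles=tuple(profiles),
        axes=axes, groups=_group_labels(design),
    )


def generate_latents(
    design: SyntheticDesign, soil: SoilData, seed: int | None = None
) -> pd.DataFrame:
    """One latent factor per (sample, planted module).

    ``none`` modules get independent standard normal noise.  Linked modules
    mix the soil axes with weight ``latent_effect`` as documented in the
    module docstring.  Axis couplings alternate in sign across linked
    modules (a decreasing response is just as monotone as an increasing
    one, and Mantel distances are sign-blind): this keeps the latents of
    same-plan modules uncorrelated and cancels the axes' net imprint on
    total library composition, so compositional closure does not propagate
    a soil signal to unlinked taxa.
    """
    seed = design.seed if seed is None else seed
    rng = child_rng(seed, "latents")
    chem = _zscore(soil.axes["chem_axis"].to_numpy())
    agg = _zscore(soil.axes["agg_axis"].to_numpy())
    cols = {}

    # Noise components of *linked* modules are orthogonalised in-sample
    # against the axes and against each other: the realised correlation
    # between two planted linked modules then equals its design value
    # exactly instead of scattering by ~0.12 around it (n = 33), which
    # otherwise occasionally pushes two planted blocks close enough to be
    # detected as one.  "none" modules keep plain independent noise.
    ortho_basis: list[np.ndarray] = [chem, agg]

    def _linked_noise() -> np.ndarray:
        xi = rng.normal(size=design.n_samples)
        for b in ortho_basis:
            xi = xi - (xi @ b) / (b @ b) * b
        xi = _zscore(xi)
        ortho_basis.append(xi)
        return xi

    # Chemical-axis signs alternate within each plan class: same-plan
    # latents then correlate at -e^2 + (agg part)^2 ~ 0 instead of +e^2,
    # and the class's net chemical imprint on library totals cancels.
    # The aggregate sign stays fixed (flipping both channels would make the
    # two chemical+aggregate latents near-perfect negatives of each other).
    sign_of = {"chemical": 1.0, "chemical+aggregate": 1.0}
    for lab, plan, e in zip(design.module_labels, design.linkage_plan, design.latent_effect):
        if plan == "none" or e == 0.0:
            latent = rng.normal(size=design.n_samples)
        elif plan == "chemical":
            latent = sign_of[plan] * e * chem + np.sqrt(1.0 - e ** 2) * _linked_noise()
            sign_of[plan] = -sign_of[plan]
        else:  # chemical+aggregate
            w_c = e * np.sqrt(design.chem_share)
            w_a = e * np.sqrt(1.0 - design.chem_share)
            latent = sign_of[plan] * w_c * chem + w_a * agg
            latent = latent + np.sqrt(1.0 - e ** 2) * _linked_noise()
            sign_of[plan] = -sign_of[plan]
        cols[lab] = latent
    return pd.DataFrame(cols, index=soil.axes.index)


def generate_asv_table(
    design: SyntheticDesign,
    latents: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts with multinomial depth resampling.

    Returns the ASV x sample count table and the ground-truth partition
    (ASV -> planted module label or "background").
    """
    seed = design.seed if seed is None else seed
    rng = child_rng(seed, "asv")
    n_s = design.n_samples
    samples = list(latents.index)

    truth: list[str] = []
    log_mu_rows: list[np.ndarray] = []
    for lab, size in zip(design.module_labels, design.module_sizes):
        lat = latents[lab].to_numpy()
        base = rng.normal(design.planted_log_mean, design.planted_log_sd, size=size)
        loads = rng.normal(design.loading, design.loading_sd, size=size)
        loads = np.clip(loads, 0.0, None)
        log_mu_rows.append(base[:, None] + loads[:, None] * lat[None, :])
        truth.extend([lab] * size)

    n_bg = design.n_asvs - sum(design.module_sizes)
    n_common = min(design.n_background_common, n_bg)
    base_common = rng.normal(design.common_log_mean, design.common_log_sd, size=n_common)
    base_rare = rng.normal(design.rare_log_mean, design.rare_log_sd, size=n_bg - n_common)
    bg_base = np.concatenate([base_common, base_rare])
    log_mu_rows.append(np.repeat(bg_base[:, None], n_s, axis=1))
    truth.extend(["background"] * n_bg)

    log_mu = np.vstack(log_mu_rows) if log_mu_rows else np.empty((0, n_s))
    mu = np.exp(log_mu)
    n_planted = sum(design.module_sizes)
    theta = np.full((design.n_asvs, 1), design.common_dispersion)
    theta[:n_planted] = design.dispersion
    raw = rng.negative_binomial(theta, theta / (theta + mu))

    depths = rng.integers(design.depth_range[0], design.depth_range[1] + 1, size=n_s)
    counts = np.zeros_like(raw)
    for j in range(n_s):
        tot = raw[:, j].sum()
        if tot == 0:
            raise RuntimeError("degenerate sample with zero reads; raise baselines")
        counts[:, j] = rng.multinomial(depths[j], raw[:, j] / tot)

    asv_ids = [f"ASV{i + 1:04d}" for i in range(design.n_asvs)]
    table = pd.DataFrame(counts, index=pd.Index(asv_ids, name="asv_id"), columns=samples)
    truth_s = pd.Series(truth, index=table.index, name="planted_module")
    return table, truth_s


def generate_guild_map(
    design: SyntheticDesign, truth: pd.Series, seed: int | None = None
) -> pd.DataFrame:
    """FUNGuild-style table: trophic mode string, guild, confidence ranking.

    Modes are drawn from the planted module's trophic plan (background ASVs
    use the background plan).  An assigned ASV becomes a composite string
    such as "Pathotroph-Saprotroph" with probability ``composite_prob``;
    unassigned ASVs get "-".
    """
    seed = design.seed if seed is None else seed
    rng = child_rng(seed, "guilds")
    plan_of = dict(zip(design.module_labels, design.trophic_plan))
    conf_names = list(design.confidence_probs)
    conf_p = np.array([design.confidence_probs[c] for c in conf_names], dtype=float)
    conf_p /= conf_p.sum()

    rows = []
    canonical = ["pathotroph", "saprotroph", "symbiotroph"]
    for asv, lab in truth.items():
        plan = plan_of.get(lab, design.background_trophic)
        modes = list(plan)
        probs = np.array([plan[m] for m in modes], dtype=float)
        mode = modes[rng.choice(len(modes), p=probs / probs.sum())]
        if mode == "unassigned":
            rows.append({"asv_id": asv, "trophic_mode": "-", "guild": "-",
                         "confidence": "-"})
            continue
        if rng.random() < design.composite_prob:
            partner = [m for m in canonical if m != mode][rng.integers(0, 2)]
            both = sorted([mode, partner], key=canonical.index)
            mode_str = "-".join(_MODE_STRING[m] for m in both)
            guild = "-".join(_MODE_GUILD[m] for m in both)
        else:
            mode_str = _MODE_STRING[mode]
            guild = _MODE_GUILD[mode]
        conf = conf_names[rng.choice(len(conf_names), p=conf_p)]
        rows.append({"asv_id": asv, "trophic_mode": mode_str, "guild": guild,
                     "confidence": conf})
    return pd.DataFrame(rows).set_index("asv_id")


@dataclass(frozen=True)
class SyntheticDataset:
    design: SyntheticDesign
    asv_table: pd.DataFrame
    soil: SoilData
    guild_map: pd.DataFrame
    latents: pd.DataFrame
    truth_partition: pd.Series
    truth_module_types: dict[str, str]

    @property
    def groups(self) -> pd.Series:
        return self.soil.groups


def generate_dataset(design: SyntheticDesign, seed: int | None = None) -> SyntheticDataset:
    """Generate one complete synthetic study (bit-identical for fixed seed)."""
    seed = design.seed if seed is None else seed
    soil = generate_soil_and_sieving(design, seed)
    latents = generate_latents(design, soil, seed)
    table, truth = generate_asv_table(design, latents, seed)
    guilds = generate_guild_map(design, truth, seed)
    return SyntheticDataset(
        design=design,
        asv_table=table,
        soil=soil,
        guild_map=guilds,
        latents=latents,
        truth_partition=truth,
        truth_module_types=design.truth_module_types(),
    )


# ---------------------------------------------------------------------------
# Ground-truth recovery helpers (used by tests and the acceptance script)


def recovered_module_map(truth: pd.Series, assignment: Mapping[str, int]) -> dict[str, int | None]:
    """Match each planted module to the detected module holding most of its
    members (None when no member made it into the network)."""
    out: dict[str, int | None] = {}
    for lab in sorted(set(truth) - {"background"}):
        members = truth.index[truth == lab]
        detected = [assignment[a] for a in members if a in assignment]
        if not detected:
            out[lab] = None
            continue
        vals, counts = np.unique(detected, return_counts=True)
        out[lab] = int(vals[np.argmax(counts)])
    return out


def planted_ari(truth: pd.Series, assignment: Mapping[str, int]) -> float:
    """Adjusted Rand index between planted and detected modules, restricted
    to planted ASVs that entered the network."""
    from sklearn.metrics import adjusted_rand_score

    planted = truth.index[(truth != "background")]
    kept = [a for a in planted if a in assignment]
    if not kept:
        return 0.0
    return float(adjusted_rand_score(
        truth.loc[kept].to_numpy(), [assignment[a] for a in kept]
    ))
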