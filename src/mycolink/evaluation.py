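"""Study-level evaluation harnesses: recovery and calibration experiments.

These run the full pipeline over many seeded synthetic studies and score it
against the planted ground truth: module recovery (adjusted Rand index),
MUCA/MRC/MRCA label accuracy, trophic-pattern reproduction, and the type-I
error calibration of the permutation tests.  They back both the test suite
and the reproduction script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ._rng import child_rng
from .community import anosim, mantel
from .linkage import compare_trophic_across_types
from .pipeline import RunConfig, run_pipeline
from .simulate import SyntheticDesign, default_design, planted_ari, recovered_module_map

__all__ = [
    "SeedOutcome",
    "run_recovery_study",
    "null_design",
    "mantel_type_one_error",
    "anosim_type_one_error",
]

#: which module type was planted to dominate each trophic mode
PLANTED_HIGH = {"symbiotroph": "MRC", "pathotroph": "MRCA", "saprotroph": "MUCA"}


@dataclass
class SeedOutcome:
    seed: int
    ari: float
    n_modules: int
    n_nodes: int
    n_edges: int
    labels: dict[str, tuple[str, str]]  # planted module -> (truth, predicted)
    trophic_order_ok: bool | None
    trophic_distinct_ok: bool | None
    type_shares: pd.DataFrame | None

    @property
    def n_correct(self) -> int:
        return sum(t == p for t, p in self.labels.values())


def null_design(design: SyntheticDesign | None = None) -> SyntheticDesign:
    """The same study with every soil linkage disabled."""
    design = design or default_design()
    return dataclasses.replace(
        design,
        linkage_plan=("none",) * len(design.module_sizes),
        latent_effect=(0.0,) * len(design.module_sizes),
    )


def evaluate_seed(design: SyntheticDesign, seed: int, trophic: bool = True) -> SeedOutcome:
    """Run the pipeline on one synthetic study and score it against truth."""
    res = run_pipeline(RunConfig(design=design, seed=seed))
    ds = res.dataset
    truth = ds.truth_partition
    mapping = recovered_module_map(truth, res.partition.assignment)

    labels: dict[str, tuple[str, str]] = {}
    for lab, truth_type in ds.truth_module_types.items():
        det = mapping[lab]
        pred = "LOST" if det is None else str(res.module_types.loc[det, "module_type"])
        labels[lab] = (truth_type, pred)

    order_ok = distinct_ok = None
    type_shares = None
    if trophic:
        order_ok, distinct_ok, type_shares = _score_trophic(res, ds, mapping)

    return SeedOutcome(
        seed=seed,
        ari=planted_ari(truth, res.partition.assignment),
        n_modules=res.partition.n_modules,
        n_nodes=res.summary["n_nodes"],
        n_edges=res.summary["n_edges"],
        labels=labels,
        trophic_order_ok=order_ok,
        trophic_distinct_ok=distinct_ok,
        type_shares=type_shares,
    )


def _score_trophic(res, ds, mapping):
    """Score the planted trophic pattern on recovered modules.

    Recovered modules are grouped by the *planted* type of the planted
    module they match, so the trophic check measures composition recovery
    rather than compounding classification noise.
    """
    inv: dict[int, str] = {}
    for lab, det in mapping.items():
        if det is None or det in inv:
            return False, False, None
        inv[det] = lab
    comp = res.trophic_composition.loc[list(inv)]
    types = pd.DataFrame(
        {"module_type": [ds.truth_module_types[inv[m]] for m in comp.index]},
        index=comp.index,
    )
    shares = comp.join(types).groupby("module_type").mean()
    if set(shares.index) != {"MUCA", "MRC", "MRCA"}:
        return False, False, shares
    order_ok = all(
        shares.loc[high, mode] == shares[mode].max()
        for mode, high in PLANTED_HIGH.items()
    )
    try:
        tests = compare_trophic_across_types(comp, types)
    except ValueError:
        return order_ok, False, shares
    distinct_ok = all(
        all(
            tests[mode]["tukey"].letters[high] != tests[mode]["tukey"].letters[other]
            for other in shares.index
            if other != high
        )
        for mode, high in PLANTED_HIGH.items()
    )
    return order_ok, distinct_ok, shares


def run_recovery_study(
    seeds, design: SyntheticDesign | None = None, trophic: bool = True
) -> list[SeedOutcome]:
    design = design or default_design()
    return [evaluate_seed(design, s, trophic=trophic) for s in seeds]


# ---------------------------------------------------------------------------
# Permutation-test calibration


def _random_distances(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


def mantel_type_one_error(
    n_reps: int = 800, n: int = 33, n_perm: int = 199,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of the Mantel test on independent distance matrices."""
    rng = child_rng(seed, "mantel-null")
    rejections = 0
    for rep in range(n_reps):
        d1 = _random_distances(rng, n)
        d2 = _random_distances(rng, n)
        _, p = mantel(d1, d2, n_perm=n_perm,
                      seed=int(rng.integers(2 ** 31)), alternative="greater")
        rejections += p < alpha
    return rejections / n_reps


def anosim_type_one_error(
    n_reps: int = 800, n_groups: int = 11, reps_per_group: int = 3,
    n_perm: int = 199, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of Anosim with labels independent of the distances."""
    rng = child_rng(seed, "anosim-null")
    n = n_groups * reps_per_group
    labels = pd.Series(
        [f"g{i // reps_per_group}" for i in range(n)],
        index=[f"s{i}" for i in range(n)],
    )
    rejections = 0
    for rep in range(n_reps):
        d = _random_distances(rng, n)
        _, p = anosim(d, labels, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rejections += p < alpha
    return rejections / n_reps
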