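"""Linking network modules to soil properties and trophic modes.

Each detected module is summarised by the summed percent relative abundance
of its member ASVs over all samples (reported on a log10 scale), then
linked to every soil variable with a Mantel test: Bray-Curtis distances on
the module's member sub-table against absolute-difference distances on the
z-standardised variable.  The pattern of significant links, split by
variable block, classifies every module:

* **MUCA** — no significant link to any variable;
* **MRC**  — at least one significant chemical link, no aggregate link;
* **MRCA** — significant chemical *and* aggregate links;
* **MRA**  — aggregate-only links; reported with a warning because the
  three-type scheme above has no such class (aggregate stability is not
  expected to act on modules alone).

Trophic composition is the abundance-weighted share of pathotroph,
saprotroph and symbiotroph (plus unassigned) among member ASVs, using a
FUNGuild-style map in which composite mode strings split their weight
equally and low-confidence assignments count as unassigned.

Per-(module x variable) Mantel tests are not multiplicity-corrected by
default: the classification operates at a plain per-test alpha.  A
BH-corrected mode (within the whole linkage grid) is available via
``bh_correct=True`` for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ._rng import child_seed
from .community import euclidean_1d, mantel_many, one_way_anova, tukey_hsd, TukeyResult
from .network import ModulePartition, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SoilTable",
    "module_abundance",
    "module_bray_curtis",
    "module_soil_linkage",
    "classify_module_types",
    "parse_guilds",
    "trophic_composition",
    "type_composition",
    "compare_trophic_across_types",
]

BLOCKS = ("chemical", "aggregate")
MODULE_TYPES = ("MUCA", "MRC", "MRCA", "MRA")
CONFIDENCE_ORDER = {"Possible": 0, "Probable": 1, "Highly Probable": 2}
_MODE_TOKEN = {
    "pathotroph": "pathotroph",
    "saprotroph": "saprotroph",
    "symbiotroph": "symbiotroph",
}


@dataclass(frozen=True)
class SoilTable:
    """Soil variables (samples x variables) with a block tag per variable."""

    values: pd.DataFrame
    blocks: dict[str, str]

    def __post_init__(self) -> None:
        untag = [v for v in self.values.columns if v not in self.blocks]
        if untag:
            raise ValueError(f"variables without block assignment: {untag}")
        bad = {v: b for v, b in self.blocks.items() if b not in BLOCKS}
        if bad:
            raise ValueError(f"unknown blocks: {bad}")

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.values.columns]


def module_abundance(rel_table: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """Summed percent relative abundance per module, with log10.

    The sum runs over member ASVs and over *all* samples, so a module
    containing everything in a 33-sample table would score 3300 (%).
    """
    missing = [a for a in partition.assignment if a not in rel_table.index]
    if missing:
        raise ValueError(f"partition nodes absent from table: {missing[:5]}")
    percent = rel_table * 100.0
    rows = []
    for m, members in partition.modules().items():
        total = float(percent.loc[members].to_numpy().sum())
        if total <= 0:
            raise ValueError(f"module {m} has zero abundance")
        rows.append({
            "module_id": m,
            "n_asvs": len(members),
            "summed_abundance": total,
            "log_abundance": float(np.log10(total)),
        })
    return pd.DataFrame(rows).set_index("module_id")


def module_bray_curtis(rel_table: pd.DataFrame, members: list[str]) -> DistanceMatrix:
    """Bray-Curtis distances on a module's member sub-table.

    Abundances are taken from the full-table normalisation (not
    renormalised within the module), preserving the module's abundance
    context.  A pair of samples where no member occurs has an undefined
    Bray-Curtis ratio; such pairs get distance 0 (identical emptiness).
    """
    x = rel_table.loc[members].to_numpy(dtype=float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(x, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in rel_table.columns])


def module_soil_linkage(
    rel_table: pd.DataFrame,
    partition: ModulePartition,
    soil: SoilTable,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Mantel r and p for every (module, soil variable) pair.

    One permutation set per module is shared across all of its variables
    (common random numbers), which keeps the grid cheap and makes the
    per-variable decisions comparable.  Zero-variance variables and
    constant module distance matrices are flagged (``tested=False``), never
    silently dropped.  Returns a tidy frame with columns module_id,
    variable, block, r, p, significant, tested.
    """
    samples = [str(c) for c in rel_table.columns]
    if set(samples) != set(str(i) for i in soil.values.index):
        raise ValueError("ASV table and soil table cover different samples")
    soil_vals = soil.values.loc[[c for c in rel_table.columns]]

    var_dms, tested_vars, skipped = [], [], []
    for v in soil.variables:
        col = soil_vals[v].astype(float)
        if col.std() == 0:
            skipped.append(v)
            continue
        z = (col - col.mean()) / col.std()
        var_dms.append(euclidean_1d(z))
        tested_vars.append(v)
    if skipped:
        logger.warning("zero-variance soil variable(s) not tested: %s", skipped)

    rows = []
    for m, members in partition.modules().items():
        dm = module_bray_curtis(rel_table, members)
        v = squareform(np.asarray(dm.data), checks=False)
        if v.std() == 0:
            logger.warning("module %s has a constant distance matrix; not tested", m)
            for var in soil.variables:
                rows.append({"module_id": m, "variable": var,
                             "block": soil.blocks[var], "r": np.nan, "p": np.nan,
                             "significant": False, "tested": False})
            continue
        r, p = mantel_many(
            dm, var_dms, n_perm=n_perm,
            seed=child_seed(seed, f"linkage-module-{m}"),
            alternative="greater",
        )
        res = {var: (float(ri), float(pi)) for var, ri, pi in zip(tested_vars, r, p)}
        for var in soil.variables:
            if var in res:
                ri, pi = res[var]
                rows.append({"module_id": m, "variable": var,
                             "block": soil.blocks[var], "r": ri, "p": pi,
                             "significant": bool(pi < alpha), "tested": True})
            else:
                rows.append({"module_id": m, "variable": var,
                             "block": soil.blocks[var], "r": np.nan, "p": np.nan,
                             "significant": False, "tested": False})
    out = pd.DataFrame(rows)
    if bh_correct:
        tested = out["tested"].to_numpy()
        q = np.full(len(out), np.nan)
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
        out["q"] = q
        out["significant"] = tested & (out["q"] < alpha)
    return out


def classify_module_types(linkage: pd.DataFrame) -> pd.DataFrame:
    """MUCA/MRC/MRCA (and flagged MRA) labels from the significance pattern."""
    rows = []
    for m, grp in linkage.groupby("module_id"):
        sig = grp[grp["significant"]]
        chem = (sig["block"] == "chemical").any()
        agg = (sig["block"] == "aggregate").any()
        if chem and agg:
            t = "MRCA"
        elif chem:
            t = "MRC"
        elif agg:
            t = "MRA"
            logger.warning(
                "module %s links to aggregate stability alone (MRA): outside "
                "the three-type MUCA/MRC/MRCA scheme", m,
            )
        else:
            t = "MUCA"
        rows.append({"module_id": m, "module_type": t})
    return pd.DataFrame(rows).set_index("module_id")


def parse_guilds(
    guild_table: pd.DataFrame, min_confidence: str = "Probable"
) -> pd.DataFrame:
    """Fractional trophic-mode weights per ASV from a FUNGuild-style table.

    Expects columns ``trophic_mode`` and ``confidence`` (index: ASV id).
    Single modes map to weight 1; composite strings such as
    "Pathotroph-Saprotroph" split equally; entries below ``min_confidence``
    or with unrecognised tokens become unassigned (weight on the
    ``unassigned`` column — nothing is dropped).
    """
    if min_confidence not in CONFIDENCE_ORDER:
        raise ValueError(f"unknown confidence rank {min_confidence!r}")
    need = CONFIDENCE_ORDER[min_confidence]
    cols = ["pathotroph", "saprotroph", "symbiotroph", "unassigned"]
    out = pd.DataFrame(0.0, index=guild_table.index, columns=cols)
    for asv, row in guild_table.iterrows():
        mode = str(row["trophic_mode"]).strip()
        conf = str(row["confidence"]).strip()
        if mode in {"-", "", "nan"} or CONFIDENCE_ORDER.get(conf, -1) < need:
            out.at[asv, "unassigned"] = 1.0
            continue
        tokens = [t.strip().lower() for t in mode.split("-") if t.strip()]
        known = [t for t in tokens if t in _MODE_TOKEN]
        unknown = [t for t in tokens if t not in _MODE_TOKEN]
        if unknown:
            logger.warning("ASV %s: unknown trophic token(s) %s", asv, unknown)
        if not known:
            out.at[asv, "unassigned"] = 1.0
            continue
        w = 1.0 / len(known)
        for t in known:
            out.at[asv, t] += w
    return out


def trophic_composition(
    rel_table: pd.DataFrame,
    partition: ModulePartition,
    guild_weights: pd.DataFrame,
    count_weighted: bool = False,
) -> pd.DataFrame:
    """Per-module trophic shares.

    Abundance-weighted by default: each member contributes its total
    relative abundance times its fractional mode weights, divided by the
    module's summed abundance.  ``count_weighted=True`` weights every
    member ASV equally instead.
    """
    missing = [a for a in partition.assignment if a not in guild_weights.index]
    if missing:
        raise ValueError(f"ASVs without guild entry: {missing[:5]}")
    totals = rel_table.sum(axis=1)
    rows = []
    for m, members in partition.modules().items():
        w = pd.Series(1.0, index=members) if count_weighted else totals.loc[members]
        denom = float(w.sum())
        shares = guild_weights.loc[members].mul(w, axis=0).sum(axis=0) / denom
        rows.append({"module_id": m, **{c: float(shares[c]) for c in guild_weights.columns}})
    return pd.DataFrame(rows).set_index("module_id")


def type_composition(
    composition: pd.DataFrame,
    types: pd.DataFrame,
    abundance: pd.DataFrame,
) -> pd.DataFrame:
    """Abundance-weighted aggregate of module compositions per module type."""
    joined = composition.join(types).join(abundance["summed_abundance"])
    rows = []
    for t, grp in joined.groupby("module_type"):
        w = grp["summed_abundance"]
        shares = grp[composition.columns].mul(w, axis=0).sum(axis=0) / float(w.sum())
        rows.append({"module_type": t, "n_modules": len(grp),
                     **{c: float(shares[c]) for c in composition.columns}})
    return pd.DataFrame(rows).set_index("module_type")


def compare_trophic_across_types(
    composition: pd.DataFrame,
    types: pd.DataFrame,
    alpha: float = 0.05,
    modes: tuple[str, ...] = ("pathotroph", "saprotroph", "symbiotroph"),
) -> dict[str, dict]:
    """One-way ANOVA + Tukey letters per trophic mode across module types.

    Modules are the replicates.  Types with fewer than 2 modules are
    excluded (with a warning); at least two eligible types are required.
    """
    joined = composition.join(types)
    sizes = joined.groupby("module_type").size()
    small = list(sizes.index[sizes < 2])
    if small:
        logger.warning("module type(s) with < 2 modules excluded from ANOVA: %s", small)
    eligible = joined[~joined["module_type"].isin(small)]
    if eligible["module_type"].nunique() < 2:
        raise ValueError("need at least 2 module types with >= 2 modules each")
    out: dict[str, dict] = {}
    for mode in modes:
        vals = eligible[mode].to_numpy()
        labs = eligible["module_type"].to_numpy()
        try:
            f, p = one_way_anova(vals, labs)
            tk: TukeyResult = tukey_hsd(vals, labs, alpha=alpha)
        except ValueError:
            # degenerate: a constant mode carries no evidence of differences
            means = {g: float(vals[labs == g].mean()) for g in np.unique(labs)}
            tk = TukeyResult(
                pairwise=pd.DataFrame(
                    columns=["group1", "group2", "meandiff", "p_adj", "reject"]
                ),
                letters={g: "a" for g in means},
                group_means=means,
            )
            f, p = 0.0, 1.0
        out[mode] = {"F": f, "p": p, "tukey": tk}
    return out
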