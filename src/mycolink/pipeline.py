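"""End-to-end orchestration with seeded reproducibility.

``run_pipeline`` executes the full analysis in a fixed stage order —
rarefaction, prevalence filtering, aggregate indices, correlation network,
Louvain modules, Zi-Pi roles, module-soil Mantel linkage, MUCA/MRC/MRCA
classification, trophic comparison — on either a synthetic design or a set
of input files.  One master seed deterministically derives a child seed
per stage (see :mod:`mycolink._rng`), so two runs with the same
configuration produce byte-identical outputs, and adding a stage never
perturbs the randomness of earlier ones.  No output file contains
timestamps for the same reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._rng import child_seed
from . import community as comm
from . import network as net
from . import linkage as lk
from . import io as mio
from .aggregates import indices_table, read_sieving_csv
from .linkage import SoilTable
from .simulate import SyntheticDesign, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_inputs",
           "ValidationReport"]


@dataclass(frozen=True)
class InputPaths:
    asv: str
    soil: str
    blocks: str
    groups: str
    sieving: str | None = None
    guilds: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs: data source, thresholds, seed, output dir.

    Exactly one of ``design`` (synthetic study) or ``inputs`` (file paths)
    must be set.  Threshold defaults are the analysis defaults throughout
    the package: |rho| >= 0.6 with BH q < 0.05 for edges, Louvain
    resolution 1.0, Zi/Pi role thresholds 2.5/0.62, alpha 0.05 and 999
    permutations for linkage tests.
    """

    design: SyntheticDesign | None = None
    inputs: InputPaths | None = None
    seed: int = 0
    out_dir: str | None = None
    rarefaction_depth: int | None = None  # None = minimum sample total
    min_prevalence: float = 0.20
    r_min: float = 0.6
    q_max: float = 0.05
    resolution: float = 1.0
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    alpha: float = 0.05
    n_perm: int = 999

    def __post_init__(self) -> None:
        if (self.design is None) == (self.inputs is None):
            raise ValueError("exactly one of design / inputs must be set")
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError("r_min must lie in [0, 1]")
        for name in ("q_max", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} out of range: {v}")
        if not 0.0 <= self.min_prevalence < 1.0:
            raise ValueError(f"min_prevalence out of range: {self.min_prevalence}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def hashable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = raw.pop("synthetic", None)
        inputs = raw.pop("inputs", None)
        kwargs = dict(raw)
        if design is not None:
            for key in ("module_sizes", "linkage_plan", "latent_effect", "depth_range"):
                if key in design and isinstance(design[key], list):
                    design[key] = tuple(design[key])
            if "trophic_plan" in design:
                design["trophic_plan"] = tuple(design["trophic_plan"])
            kwargs["design"] = SyntheticDesign(**design)
        if inputs is not None:
            kwargs["inputs"] = InputPaths(**inputs)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: RunConfig
    summary: dict
    rarefied: pd.DataFrame
    retained: pd.DataFrame
    rel_table: pd.DataFrame
    soil: SoilTable
    aggregate_indices: pd.DataFrame | None
    network: "net.nx.Graph"
    partition: net.ModulePartition
    topology: pd.DataFrame
    module_abundance: pd.DataFrame
    linkage: pd.DataFrame
    module_types: pd.DataFrame
    trophic_composition: pd.DataFrame | None
    type_composition: pd.DataFrame | None
    trophic_tests: dict | None
    dataset: SyntheticDataset | None = None


def _load_inputs(config: RunConfig):
    if config.design is not None:
        ds = generate_dataset(config.design, seed=child_seed(config.seed, "simulate"))
        soil = SoilTable(ds.soil.soil_table, ds.soil.blocks)
        return ds.asv_table, soil, ds.soil.profiles, ds.guild_map, ds.groups, ds
    paths = config.inputs
    report = validate_inputs(paths)
    if not report.ok:
        raise ValueError("input validation failed:\n" + report.text())
    table = mio.read_asv_tsv(paths.asv)
    soil = mio.read_soil(paths.soil, paths.blocks)
    groups = mio.read_groups_tsv(paths.groups)
    profiles = tuple(read_sieving_csv(paths.sieving)) if paths.sieving else None
    guilds = mio.read_guild_tsv(paths.guilds) if paths.guilds else None
    return table, soil, profiles, guilds, groups, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage; optionally write all artifacts under ``out_dir``."""
    table, soil, profiles, guilds, groups, dataset = _load_inputs(config)

    # rarefaction + normalisation
    rarefied = comm.rarefy(table, depth=config.rarefaction_depth,
                           seed=child_seed(config.seed, "rarefy"))
    depth = int(rarefied.sum(axis=0).iloc[0])
    rel = comm.relative_abundance(rarefied)
    retained = comm.prevalence_filter(rarefied, config.min_prevalence)

    # aggregate indices (from sieving masses when available)
    agg_idx = indices_table(profiles) if profiles is not None else None
    soil_vals = soil.values.loc[[c for c in rarefied.columns]]
    blocks = dict(soil.blocks)
    if agg_idx is not None:
        for src, var in (("wsa", "WSA"), ("mwd_mm", "MWD"), ("gmd_mm", "GMD")):
            if var not in soil_vals.columns:
                soil_vals[var] = agg_idx.loc[soil_vals.index, src]
                blocks[var] = "aggregate"
    soil = SoilTable(soil_vals, blocks)

    # community-level dissimilarity across plant-species groups
    bc = comm.bray_curtis(comm.relative_abundance(retained))
    anosim_r, anosim_p = comm.anosim(
        bc, groups.astype(str), n_perm=config.n_perm,
        seed=child_seed(config.seed, "anosim"),
    )

    # co-occurrence network and modules
    corr = net.pairwise_spearman(retained)
    graph = net.build_network(corr, r_min=config.r_min, q_max=config.q_max)
    if graph.number_of_nodes() == 0:
        raise ValueError("no edges survive the correlation thresholds")
    partition = net.detect_modules(graph, resolution=config.resolution,
                                   seed=child_seed(config.seed, "louvain"))
    topology = net.classify_roles(
        net.zipi(graph, partition),
        zi_threshold=config.zi_threshold, pi_threshold=config.pi_threshold,
    )

    # module abundance, soil linkage, classification
    mod_abund = lk.module_abundance(rel, partition)
    linkage = lk.module_soil_linkage(
        rel, partition, soil, n_perm=config.n_perm, alpha=config.alpha,
        seed=child_seed(config.seed, "linkage"),
    )
    module_types = lk.classify_module_types(linkage)

    # trophic composition
    trophic = type_comp = trophic_tests = None
    if guilds is not None:
        weights = lk.parse_guilds(guilds)
        trophic = lk.trophic_composition(rel, partition, weights)
        type_comp = lk.type_composition(trophic, module_types, mod_abund)
        try:
            trophic_tests = lk.compare_trophic_across_types(
                trophic, module_types, alpha=config.alpha
            )
        except ValueError as exc:
            logger.warning("trophic comparison skipped: %s", exc)

    role_counts = topology["role"].value_counts()
    n_nodes = graph.number_of_nodes()
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": mio.config_hash(config.hashable()),
        "n_samples": int(rarefied.shape[1]),
        "rarefaction_depth": depth,
        "n_asvs_input": int(table.shape[0]),
        "n_asvs_retained": int(retained.shape[0]),
        "community_anosim": {"R": anosim_r, "p": anosim_p},
        "n_nodes": n_nodes,
        "n_edges": graph.number_of_edges(),
        "n_modules": partition.n_modules,
        "modularity": partition.modularity,
        "role_fractions": {
            r: float(role_counts.get(r, 0)) / n_nodes
            for r in ("peripheral", "connector", "module_hub", "network_hub")
        },
        "module_type_counts": module_types["module_type"].value_counts().to_dict(),
        "mean_log_abundance_by_type": (
            mod_abund.join(module_types)
            .groupby("module_type")["log_abundance"].mean().round(6).to_dict()
        ),
    }
    if trophic_tests is not None:
        summary["trophic_anova"] = {
            mode: {"F": res["F"], "p": res["p"],
                   "letters": res["tukey"].letters}
            for mode, res in trophic_tests.items()
        }

    result = PipelineResult(
        config=config, summary=summary, rarefied=rarefied, retained=retained,
        rel_table=rel, soil=soil, aggregate_indices=agg_idx, network=graph,
        partition=partition, topology=topology, module_abundance=mod_abund,
        linkage=linkage, module_types=module_types,
        trophic_composition=trophic, type_composition=type_comp,
        trophic_tests=trophic_tests, dataset=dataset,
    )
    if config.out_dir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def save(frame: pd.DataFrame, name: str, **kw) -> None:
        frame.to_csv(out / name, sep="\t", **kw)
        files.append(name)

    if result.dataset is not None:
        for p in mio.write_dataset(result.dataset, out / "inputs").values():
            files.append(str(Path("inputs") / p.name))

    save(result.retained, "asv_retained.tsv")
    if result.aggregate_indices is not None:
        save(result.aggregate_indices, "aggregate_indices.tsv")
    net.write_edge_list(result.network, out / "edge_list.tsv")
    files.append("edge_list.tsv")
    net.write_graphml(result.network, out / "network.graphml")
    files.append("network.graphml")
    part = pd.Series(result.partition.assignment, name="module_id").rename_axis("asv_id")
    save(part.to_frame(), "module_partition.tsv")
    save(result.topology, "node_topology.tsv")
    save(result.module_abundance, "module_abundance.tsv")
    save(result.linkage, "module_soil_linkage.tsv", index=False)
    save(result.module_types, "module_types.tsv")
    if result.trophic_composition is not None:
        save(result.trophic_composition, "trophic_composition.tsv")
        save(result.type_composition, "type_composition.tsv")
    if result.trophic_tests is not None:
        rows = []
        for mode, res in result.trophic_tests.items():
            for g, letter in res["tukey"].letters.items():
                rows.append({"trophic_mode": mode, "module_type": g,
                             "mean_share": res["tukey"].group_means[g],
                             "F": res["F"], "p": res["p"], "letters": letter})
        save(pd.DataFrame(rows), "trophic_anova.tsv", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append("summary.json")
    with open(out / "run.log", "w") as fh:
        fh.write(f"mycolink {__version__}\n")
        fh.write(f"master_seed {result.config.seed}\n")
        fh.write(f"config_hash {result.summary['config_hash']}\n")
        for k, v in sorted(result.config.hashable().items()):
            fh.write(f"param {k} = {v}\n")
    files.append("run.log")
    mio.write_manifest(out, {
        "config_hash": result.summary["config_hash"],
        "master_seed": result.config.seed,
        "version": __version__,
        "files": sorted(files),
    })


# ---------------------------------------------------------------------------
# Input validation


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def text(self) -> str:
        lines = [f"FATAL: {m}" for m in self.fatal]
        lines += [f"WARNING: {m}" for m in self.warnings]
        return "\n".join(lines) if lines else "all inputs consistent"


def validate_inputs(paths: InputPaths) -> ValidationReport:
    """Cross-check all input tables; enumerate every problem, not just the
    first."""
    rep = ValidationReport()

    def try_read(fn, path, what):
        if path is None:
            return None
        try:
            return fn(path)
        except FileNotFoundError:
            rep.fatal.append(f"{what}: file not found: {path}")
        except ValueError as exc:
            rep.fatal.append(f"{what}: {exc}")
        return None

    table = try_read(mio.read_asv_tsv, paths.asv, "ASV table")
    soil = try_read(lambda p: mio.read_soil(p, paths.blocks), paths.soil, "soil table")
    groups = try_read(mio.read_groups_tsv, paths.groups, "group labels")
    guilds = try_read(mio.read_guild_tsv, paths.guilds, "guild map")
    sieving = try_read(read_sieving_csv, paths.sieving, "sieving table")

    if table is None:
        return rep
    samples = set(map(str, table.columns))

    def compare(name, other: set[str]) -> None:
        missing = sorted(samples - other)
        extra = sorted(other - samples)
        if missing:
            rep.fatal.append(f"{name}: missing sample(s) {missing}")
        if extra:
            rep.warnings.append(f"{name}: extra sample(s) {extra}")

    if soil is not None:
        compare("soil table", set(map(str, soil.values.index)))
    if groups is not None:
        compare("group labels", set(map(str, groups.index)))
    if sieving is not None:
        compare("sieving table", {p.sample_id for p in sieving})
    if guilds is not None:
        orphan = sorted(set(map(str, table.index)) - set(map(str, guilds.index)))
        if orphan:
            rep.warnings.append(
                f"guild map: {len(orphan)} ASV(s) without entry (treated as "
                f"unassigned), e.g. {orphan[:3]}"
            )
    return rep
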