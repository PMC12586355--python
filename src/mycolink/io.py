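"""Reading and writing the pipeline's flat-file formats.

Everything is plain text: ASV counts as a QIIME-style flat TSV (first
column ``asv_id``, one column per sample, integer cells), group labels and
guild maps as TSV, soil properties as CSV plus a two-column block-tag TSV,
sieving masses as tidy CSV (see :mod:`mycolink.aggregates`), and study
designs as YAML.  Writers are deterministic (fixed column order, pandas
default float repr) so identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .linkage import SoilTable
from .simulate import SyntheticDesign, SyntheticDataset

__all__ = [
    "read_asv_tsv", "write_asv_tsv",
    "read_groups_tsv", "write_groups_tsv",
    "read_soil", "write_soil",
    "read_guild_tsv", "write_guild_tsv",
    "read_design_yaml", "write_design_yaml",
    "write_dataset", "config_hash", "write_manifest",
]

GUILD_COLUMNS = {"ASV ID": "asv_id", "Trophic Mode": "trophic_mode",
                 "Guild": "guild", "Confidence Ranking": "confidence"}


def read_asv_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "asv_id"
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate ASV id(s): {dupes[:5]}")
    try:
        df = df.astype("int64")
    except ValueError as exc:
        raise ValueError(f"ASV table is not integer-valued: {exc}") from exc
    if (df.to_numpy() < 0).any():
        raise ValueError("ASV table contains negative counts")
    return df


def write_asv_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_groups_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("groups TSV needs columns sample_id and group")
    s = df.set_index("sample_id")["group"].astype(str)
    s.index = s.index.astype(str)
    return s


def write_groups_tsv(groups: pd.Series, path) -> None:
    df = groups.rename("group").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_soil(values_path, blocks_path) -> SoilTable:
    values = pd.read_csv(values_path, index_col=0)
    values.index = values.index.astype(str)
    values.index.name = "sample_id"
    blocks_df = pd.read_csv(blocks_path, sep="\t")
    if not {"variable", "block"} <= set(blocks_df.columns):
        raise ValueError("blocks TSV needs columns variable and block")
    blocks = dict(zip(blocks_df["variable"].astype(str), blocks_df["block"].astype(str)))
    return SoilTable(values=values, blocks=blocks)


def write_soil(soil: SoilTable, values_path, blocks_path) -> None:
    out = soil.values.copy()
    out.index.name = "sample_id"
    out.to_csv(values_path)
    pd.DataFrame(
        [{"variable": v, "block": soil.blocks[v]} for v in soil.variables]
    ).to_csv(blocks_path, sep="\t", index=False)


def read_guild_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    renames = {c: GUILD_COLUMNS[c] for c in df.columns if c in GUILD_COLUMNS}
    df = df.rename(columns=renames)
    if "asv_id" not in df.columns:
        raise ValueError("guild TSV needs an 'ASV ID' (or asv_id) column")
    for col in ("trophic_mode", "confidence"):
        if col not in df.columns:
            raise ValueError(f"guild TSV missing column for {col}")
    return df.set_index("asv_id")


def write_guild_tsv(guilds: pd.DataFrame, path) -> None:
    inv = {v: k for k, v in GUILD_COLUMNS.items()}
    out = guilds.reset_index().rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def read_design_yaml(path) -> SyntheticDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("module_sizes", "linkage_plan", "latent_effect", "depth_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "trophic_plan" in raw:
        raw["trophic_plan"] = tuple(raw["trophic_plan"])
    return SyntheticDesign(**raw)


def write_design_yaml(design: SyntheticDesign, path) -> None:
    raw = dataclasses.asdict(design)
    for k, v in raw.items():
        if isinstance(v, tuple):
            raw[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a synthetic study in exactly the formats the pipeline reads,
    plus the ground truth and the serialised design."""
    from .aggregates import write_sieving_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "asv": outdir / "asv_counts.tsv",
        "soil": outdir / "soil_properties.csv",
        "blocks": outdir / "soil_blocks.tsv",
        "sieving": outdir / "sieving_masses.csv",
        "guilds": outdir / "guild_map.tsv",
        "groups": outdir / "sample_groups.tsv",
        "truth": outdir / "truth_partition.tsv",
        "design": outdir / "design.yaml",
    }
    write_asv_tsv(dataset.asv_table, paths["asv"])
    write_soil(SoilTable(dataset.soil.soil_table, dataset.soil.blocks),
               paths["soil"], paths["blocks"])
    write_sieving_csv(dataset.soil.profiles, paths["sieving"])
    write_guild_tsv(dataset.guild_map, paths["guilds"])
    write_groups_tsv(dataset.groups, paths["groups"])
    truth = dataset.truth_partition.rename("planted_module").rename_axis("asv_id").reset_index()
    truth["module_type"] = truth["planted_module"].map(
        lambda m: dataset.truth_module_types.get(m, "background")
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_design_yaml(dataset.design, paths["design"])
    return paths


def config_hash(payload) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf8")).hexdigest()[:16]


def write_manifest(outdir, payload: dict) -> Path:
    """Sidecar declaring the config hash, master seed and produced files."""
    path = Path(outdir) / "MANIFEST.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
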