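"""Readers and writers for the pipeline's plain-text formats.

All generator outputs are CSV/TSV with an optional leading ``#`` comment line
carrying the generating configuration hash; readers skip comment lines.
OTU tables follow the usual amplicon convention: rows = OTUs, one column per
sample, and a trailing ``taxonomy`` column with the semicolon lineage string.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .community import DEFAULT_GUILDS, OtuTable

FLUX_COLUMNS = ["trap_id", "lake", "zone", "date", "temp_C", "flux"]
CHEM_COLUMNS = [
    "sample", "core", "lake", "zone", "depth_cm", "TOC_pct", "d13C_TOC",
    "CH4_uM", "DIC_uM", "d13C_CH4", "d13C_DIC", "S_pct", "TOC_TS",
]


class SchemaError(ValueError):
    pass


def _header(config_hash: str | None) -> str:
    return f"# limnoch4 synthetic output; config={config_hash}\n" if config_hash else ""


def write_flux_csv(records: pd.DataFrame, path, config_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        records[FLUX_COLUMNS].to_csv(fh, index=False)


def read_flux_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    missing = set(FLUX_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"flux CSV missing columns: {sorted(missing)}")
    if (df["flux"] < 0).any():
        raise SchemaError("negative flux values")
    if not df["temp_C"].between(-5, 40).all():
        raise SchemaError("temperature outside the physical range (-5..40 C)")
    return df


def write_chem_csv(chem: pd.DataFrame, path, config_hash: str | None = None) -> None:
    path = Path(path)
    out = chem.reset_index() if chem.index.name == "sample" else chem.copy()
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        out.to_csv(fh, index=False)


def read_chem_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(CHEM_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"chemistry CSV missing columns: {sorted(missing)}")
    for col in ("CH4_uM", "DIC_uM", "TOC_pct", "S_pct"):
        if (df[col] < 0).any():
            raise SchemaError(f"negative values in {col}")
    for col in ("d13C_TOC", "d13C_CH4", "d13C_DIC"):
        if not df[col].between(-120, 30).all():
            raise SchemaError(f"{col} outside (-120, +30) permil")
    return df.set_index("sample")


def write_otu_tsv(table: OtuTable, path, config_hash: str | None = None) -> None:
    path = Path(path)
    wide = table.counts.T.copy()  # rows = OTUs
    wide["taxonomy"] = table.taxonomy.loc[wide.index]
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        wide.to_csv(fh, sep="\t", index_label="otu_id")


def read_otu_tsv(path, sample_meta: pd.DataFrame) -> OtuTable:
    wide = pd.read_csv(path, sep="\t", comment="#", index_col="otu_id")
    if "taxonomy" not in wide.columns:
        raise SchemaError("OTU TSV must end with a taxonomy column")
    taxonomy = wide.pop("taxonomy")
    taxonomy.index.name = None
    counts = wide.T
    counts.index.name = None
    counts.columns.name = None
    missing = [s for s in counts.index if s not in sample_meta.index]
    if missing:
        raise SchemaError(f"samples without metadata: {missing}")
    return OtuTable(counts, taxonomy, sample_meta.loc[counts.index])


def write_meta_csv(meta: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_header(config_hash))
        meta.to_csv(fh, index_label="sample")


def read_meta_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="sample")
    missing = {"core", "lake", "zone", "depth_cm"} - set(df.columns)
    if missing:
        raise SchemaError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def write_qpcr_csv(
    standards: pd.DataFrame, samples: pd.DataFrame, std_path, sample_path,
    config_hash: str | None = None,
) -> None:
    with open(Path(std_path), "w") as fh:
        fh.write(_header(config_hash))
        standards.to_csv(fh, index=False)
    with open(Path(sample_path), "w") as fh:
        fh.write(_header(config_hash))
        samples.to_csv(fh, index=False)


def read_qpcr_csv(std_path, sample_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    standards = pd.read_csv(std_path, comment="#")
    samples = pd.read_csv(sample_path, comment="#")
    if {"dilution", "ct"} - set(standards.columns):
        raise SchemaError("qPCR standards need 'dilution' and 'ct' columns")
    need = {"sample", "ct", "template_dilution", "sediment_g", "elution_uL"}
    if need - set(samples.columns):
        raise SchemaError(f"qPCR samples missing: {sorted(need - set(samples.columns))}")
    return standards, samples


def write_guilds_yaml(path, guilds=None) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(dict(guilds or DEFAULT_GUILDS), fh, sort_keys=False)


def read_guilds_yaml(path) -> dict:
    with open(Path(path)) as fh:
        guilds = yaml.safe_load(fh)
    if not isinstance(guilds, dict) or not guilds:
        raise SchemaError("guild YAML must map guild names to pattern lists")
    for g, pats in guilds.items():
        if not isinstance(pats, list) or not pats:
            raise SchemaError(f"guild {g!r} must list at least one pattern")
    return guilds
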