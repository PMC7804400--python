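"""Reading and writing the pipeline's table formats.

Plate exports follow a minimal instrument-style CSV dialect: one row per
replicate reaction with both dye-channel Ct values, and censored reactions
written as the literal token ``Undetermined`` (represented as ``NaN`` in
memory).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

UNDETERMINED_TOKEN = "Undetermined"

PLATE_COLUMNS = ["plate_id", "well", "sample_id", "assay_id", "replicate",
                 "ct_fam", "ct_vic"]
META_COLUMNS = ["sample_id", "donor_id", "tissue", "material", "diagnosis"]


def parse_ct_column(values: pd.Series) -> pd.Series:
    """Parse a Ct column where ``Undetermined`` (or blank) encodes censoring."""
    vals = values.astype(str).str.strip()
    undet = vals.str.lower().isin({"undetermined", "undet", "na", "nan", ""})
    return pd.to_numeric(vals.where(~undet, other=None), errors="raise")


def write_plate_csv(wells: pd.DataFrame, path: str | Path) -> None:
    """Write a plate table, encoding censored Cts as ``Undetermined``."""
    out = wells.loc[:, PLATE_COLUMNS].copy()
    for col in ("ct_fam", "ct_vic"):
        out[col] = out[col].map(
            lambda v: UNDETERMINED_TOKEN if pd.isna(v) else f"{v:.6f}"
        )
    out.to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read a plate table; ``Undetermined`` (any case) becomes ``NaN``."""
    wells = pd.read_csv(path, dtype={"plate_id": str, "well": str,
                                     "sample_id": str, "assay_id": str})
    missing = [c for c in PLATE_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"plate file {path} lacks required columns: {missing}")
    for col in ("ct_fam", "ct_vic"):
        wells[col] = parse_ct_column(wells[col])
    wells["replicate"] = wells["replicate"].astype(int)
    return wells


def write_meta_csv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.loc[:, META_COLUMNS].to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata {path} lacks required columns: {missing}")
    return meta


def write_config_yaml(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config_yaml(path: str | Path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    if not isinstance(loaded, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return loaded


def read_assay_metadata(path: str | Path) -> pd.DataFrame:
    """Assay annotation table: assay_id, gene, risk_allele, fam_allele, vic_allele."""
    assays = pd.read_csv(path, sep="\t", dtype=str)
    required = ["assay_id", "gene", "risk_allele", "fam_allele", "vic_allele"]
    missing = [c for c in required if c not in assays.columns]
    if missing:
        raise ValueError(f"assay metadata {path} lacks required columns: {missing}")
    return assays
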