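"""Reading, validation and writing of the pipeline's standard-format inputs.

Inputs handled here: per-sample CDS multi-FASTA files, tab-separated sample
metadata / gene-set membership / bioclimatic / dN-dS tables, and bedMethyl-like
per-site 5mC call tables.  All tabular output goes through :func:`write_table`
so that a written table re-reads to the same records.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

CLIMATE_ZONES = ("alpine", "cold_temperate", "mediterranean")

#: Zones ordered from coldest to warmest; used to report methylation direction.
ZONE_COLDNESS = {"alpine": 2, "cold_temperate": 1, "mediterranean": 0}

REGIONS = ("europe", "california", "other")
GENE_SETS = ("single_copy_orthologue", "other")
DNDS_GENE_GROUPS = ("cafe_family", "other")

#: Default column order of bedMethyl-like input (0-based indices).
DEFAULT_METHYLATION_COLUMNS: Mapping[str, int] = {
    "contig": 0,
    "start": 1,
    "end": 2,
    "coverage": 3,
    "mod_score": 4,
    "methylated": 5,
}

METADATA_COLUMNS = ("sample_id", "species", "climate_zone", "elevation", "region")
BIOCLIM_VARIABLES = tuple(f"BIO{i}" for i in range(1, 12))


class FormatError(ValueError):
    """Malformed input file (syntax, column count, non-numeric field)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant (duplicates, bad enum)."""


# ---------------------------------------------------------------------------
# FASTA

def read_cds_fasta(path: str | os.PathLike, sample_id: str | None = None) -> dict[str, str]:
    """Read a CDS multi-FASTA into an ordered ``{gene_id: sequence}`` mapping.

    Sequences are uppercased with U mapped to T.  The gene id is the first
    whitespace-delimited token of the header.  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CDS FASTA not found: {path}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: FASTA must start with a '>' header"
                    )
                break
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            gene_id = rec.id
            if gene_id in records:
                raise ValidationError(
                    f"{path}: duplicate gene id {gene_id!r}"
                    + (f" (sample {sample_id})" if sample_id else "")
                )
            records[gene_id] = str(rec.seq).upper().replace("U", "T")
    except ValueError as exc:  # Biopython parse failure
        if isinstance(exc, (FormatError, ValidationError)):
            raise
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    return records


def write_cds_fasta(records: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as out:
        for gene_id, seq in records.items():
            out.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs

def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a tab-separated table with header, no index."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Sample metadata: sample_id, species, climate_zone, elevation, region."""
    df = read_table(path)
    _require_columns(df, METADATA_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample_id(s): {dups}")
    bad_zone = set(df["climate_zone"]) - set(CLIMATE_ZONES)
    if bad_zone:
        raise ValidationError(
            f"{path}: unknown climate_zone value(s) {sorted(bad_zone)}; "
            f"expected one of {CLIMATE_ZONES}"
        )
    if (df["elevation"] < 0).any():
        raise ValidationError(f"{path}: negative elevation")
    bad_region = set(df["region"]) - set(REGIONS)
    if bad_region:
        raise ValidationError(f"{path}: unknown region value(s) {sorted(bad_region)}")
    return df


def read_membership(path: str | os.PathLike) -> pd.DataFrame:
    """Gene-set membership: gene_id, gene_set in {single_copy_orthologue, other}."""
    df = read_table(path)
    _require_columns(df, ("gene_id", "gene_set"), path)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValidationError(f"{path}: gene_id(s) listed more than once, e.g. {dups}")
    bad = set(df["gene_set"]) - set(GENE_SETS)
    if bad:
        raise ValidationError(f"{path}: unknown gene_set value(s) {sorted(bad)}")
    return df


def read_bioclim(path: str | os.PathLike) -> pd.DataFrame:
    """Bioclimatic table: sample_id plus the 11 temperature variables BIO1-BIO11."""
    df = read_table(path)
    _require_columns(df, ("sample_id",) + BIOCLIM_VARIABLES, path)
    precip = [c for c in df.columns if c.startswith("BIO") and c not in BIOCLIM_VARIABLES]
    if precip:
        raise ValidationError(
            f"{path}: unexpected bioclim column(s) {precip}; only the 11 "
            "temperature variables BIO1-BIO11 are accepted"
        )
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    if (df["BIO7"] < 0).any():
        raise ValidationError(f"{path}: BIO7 (annual temperature range) must be >= 0")
    if (df["BIO5"] < df["BIO6"]).any():
        raise ValidationError(f"{path}: BIO5 must be >= BIO6 for every sample")
    return df


def read_dnds(path: str | os.PathLike) -> pd.DataFrame:
    """Per-gene dN/dS records: gene_id, climate_zone, gene_group, dnds."""
    df = read_table(path)
    _require_columns(df, ("gene_id", "climate_zone", "gene_group", "dnds"), path)
    bad_zone = set(df["climate_zone"]) - set(CLIMATE_ZONES)
    if bad_zone:
        raise ValidationError(f"{path}: unknown climate_zone value(s) {sorted(bad_zone)}")
    bad_group = set(df["gene_group"]) - set(DNDS_GENE_GROUPS)
    if bad_group:
        raise ValidationError(f"{path}: unknown gene_group value(s) {sorted(bad_group)}")
    if (df["dnds"] < 0).any():
        raise ValidationError(f"{path}: negative dN/dS value")
    return df


# ---------------------------------------------------------------------------
# Methylation calls (bedMethyl-like)

def read_methylation_calls(
    path: str | os.PathLike,
    columns: Mapping[str, int] | None = None,
    methylated_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Read per-site 5mC calls from a bed-like tab-separated file.

    Positions are 0-based half-open (bed convention).  The ``methylated``
    column may hold a boolean (0/1, true/false) or a methylation fraction in
    [0, 1], reduced to a boolean call with ``methylated_cutoff``.

    Returns a DataFrame with columns contig, start, coverage, mod_score,
    methylated (bool).
    """
    colmap = dict(DEFAULT_METHYLATION_COLUMNS if columns is None else columns)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            columns=["contig", "start", "coverage", "mod_score", "methylated"]
        ).astype({"start": int, "coverage": int, "mod_score": float, "methylated": bool})
    n_needed = max(colmap.values()) + 1
    if raw.shape[1] < n_needed:
        raise FormatError(
            f"{path}: expected at least {n_needed} tab-separated columns, "
            f"found {raw.shape[1]} (row 1)"
        )

    def numeric(name: str) -> pd.Series:
        col = pd.to_numeric(raw.iloc[:, colmap[name]], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0]) + 1
            raise FormatError(f"{path}: non-numeric {name} value at row {row}")
        return col

    start = numeric("start")
    coverage = numeric("coverage")
    mod_score = numeric("mod_score")
    meth_raw = raw.iloc[:, colmap["methylated"]].astype(str).str.strip().str.lower()
    as_num = pd.to_numeric(meth_raw, errors="coerce")
    methylated = pd.Series(index=raw.index, dtype=bool)
    is_num = as_num.notna()
    methylated[is_num] = as_num[is_num] >= methylated_cutoff
    text = meth_raw[~is_num]
    bad = ~text.isin(["true", "false", "t", "f", "yes", "no"])
    if bad.any():
        row = int(text.index[bad][0]) + 1
        raise FormatError(f"{path}: unreadable methylated value at row {row}")
    methylated[~is_num] = text.isin(["true", "t", "yes"])

    df = pd.DataFrame(
        {
            "contig": raw.iloc[:, colmap["contig"]].astype(str),
            "start": start.astype(int),
            "coverage": coverage,
            "mod_score": mod_score.astype(float),
            "methylated": methylated.astype(bool),
        }
    )
    if (df["start"] < 0).any():
        raise ValidationError(f"{path}: negative site position")
    if (df["coverage"] < 0).any():
        raise ValidationError(f"{path}: negative coverage")
    df["coverage"] = df["coverage"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Elevation -> climate zone helper

def classify_zone_from_elevation(elevation: float, region: str) -> str:
    """Map sampling elevation (masl) to a climate zone for a known region.

    European sites: Mediterranean below ~900 m, cold temperate ~900-1900 m,
    alpine above the tree line (~1900 m).  Californian sites: Mediterranean
    below ~1200 m, cold temperate above; there is no alpine zone at the
    Californian sampling locations.  Boundaries are half-open with the lower
    zone owning its upper bound exclusively.  Explicit zone labels in the
    metadata always take precedence over this helper.
    """
    if elevation < 0:
        raise ValidationError("elevation must be non-negative")
    if region == "europe":
        if elevation < 900:
            return "mediterranean"
        if elevation < 1900:
            return "cold_temperate"
        return "alpine"
    if region == "california":
        if elevation < 1200:
            return "mediterranean"
        return "cold_temperate"
    raise ValidationError(
        f"no elevation-zone convention for region {region!r}; "
        "assign climate_zone explicitly in the metadata"
    )
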