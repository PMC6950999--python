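"""Readers and writers for the pipeline's tabular formats.

Conventions: manifests and CGI CSVs are 1-based inclusive (matching the
``chr19:11998804-11999131`` style of published island coordinates and the
Illumina manifest); BED I/O converts to/from 0-based half-open. Beta
matrices are TSV with probes as rows and samples as columns.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_cgi_csv",
    "write_cgi_csv",
    "read_cgi_bed",
    "write_cgi_bed",
    "read_genes",
    "write_genes",
    "read_beta",
    "write_beta",
    "read_sample_sheet",
    "read_gmt",
    "parse_region_string",
    "load_dna_binding_gene_table",
]

# Illumina manifest column -> internal name
_MANIFEST_COLS = {
    "IlmnID": "probe_id",
    "Name": "probe_id",
    "CHR": "chrom",
    "MAPINFO": "pos",
    "Strand": "strand",
    "Infinium_Design_Type": "design_type",
}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest CSV (Illumina column names or internal ones)."""
    df = pd.read_csv(path)
    rename = {c: _MANIFEST_COLS[c] for c in df.columns if c in _MANIFEST_COLS}
    df = df.rename(columns=rename)
    required = {"probe_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must provide {sorted(required)}; found {list(df.columns)}")
    df["pos"] = df["pos"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path, illumina_names: bool = True) -> None:
    df = manifest.copy()
    if illumina_names:
        inv = {"probe_id": "IlmnID", "chrom": "CHR", "pos": "MAPINFO",
               "strand": "Strand", "design_type": "Infinium_Design_Type"}
        df = df.rename(columns={k: v for k, v in inv.items() if k in df.columns})
    df.to_csv(path, index=False)


def parse_region_string(s: str) -> tuple[str, int, int]:
    """Parse 'chr19:11998804-11999131' into (chrom, start, end), 1-based."""
    m = re.fullmatch(r"\s*([\w.]+):(\d+)-(\d+)\s*", s)
    if not m:
        raise ValueError(f"cannot parse region {s!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_cgi_csv(path: str | Path) -> pd.DataFrame:
    """CGI CSV, 1-based inclusive: chrom,start,end[,cgi_id] or a 'region' column."""
    df = pd.read_csv(path)
    if "region" in df.columns and "start" not in df.columns:
        parsed = df["region"].map(parse_region_string)
        df["chrom"] = [p[0] for p in parsed]
        df["start"] = [p[1] for p in parsed]
        df["end"] = [p[2] for p in parsed]
    if "cgi_id" not in df.columns:
        df["cgi_id"] = [f"CGI_{i + 1}" for i in range(len(df))]
    out = df[["chrom", "start", "end", "cgi_id"]].copy()
    out[["start", "end"]] = out[["start", "end"]].astype(int)
    if (out["start"] > out["end"]).any():
        raise ValueError("CGI intervals must have start <= end")
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_cgi_csv(cgis: pd.DataFrame, path: str | Path) -> None:
    cgis[["chrom", "start", "end", "cgi_id"]].to_csv(path, index=False)


def read_cgi_bed(path: str | Path) -> pd.DataFrame:
    """CGI BED (0-based half-open) -> internal 1-based inclusive frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "cgi_id"][: df.shape[1]]
    if "cgi_id" not in df.columns:
        df["cgi_id"] = [f"CGI_{i + 1}" for i in range(len(df))]
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_cgi_bed(cgis: pd.DataFrame, path: str | Path) -> None:
    out = cgis.copy()
    out["start"] = out["start"].astype(int) - 1
    out[["chrom", "start", "end", "cgi_id"]].to_csv(path, sep="\t", header=False, index=False)


_GENE_COLS = ["name", "chrom", "strand", "tx_start", "tx_end",
              "first_exon_start", "first_exon_end", "cds_start", "cds_end"]


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene model file missing columns: {sorted(missing)}")
    for c in _GENE_COLS[3:]:
        df[c] = df[c].astype(int)
    return df[_GENE_COLS]


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[_GENE_COLS].to_csv(path, index=False)


def read_beta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "group", "stage"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must provide {sorted(required)}")
    bad = set(df["group"]) - {"T21", "control"}
    if bad:
        raise ValueError(f"unknown groups in sample sheet: {sorted(bad)}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def load_dna_binding_gene_table() -> pd.DataFrame:
    """The published 37-gene DNA-binding summary for trisomy-21 neural lines.

    Columns: group, gene, cgi_chrom, cgi_start, cgi_end (hg19, 1-based),
    state (hyper/hypo), n_dmp, deg (up/down/empty). Shipped as package data
    so downstream counts (e.g. the differential-expression cross-count) can
    be recomputed from the printed table.
    """
    with resources.files("dmppipe.data").joinpath("t21_dna_binding_genes.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    df[["cgi_start", "cgi_end", "n_dmp"]] = df[["cgi_start", "cgi_end", "n_dmp"]].astype(int)
    return df
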