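"""Probe classification relative to CpG islands and gene models.

CpG-island geometry follows the usual shore/shelf convention: a probe is
in an Island when it lies inside the interval, in a shore when its distance
to the nearest island edge is 1-2000 bp, in a shelf at 2001-4000 bp, and in
the open sea beyond 4 kb. N and S denote the lower- and higher-coordinate
sides of the island. CGI+ means anything but open sea. Gene regions are the
Illumina-manifest classes (TSS200, TSS1500, 5'UTR, first exon, body,
3'UTR), assigned strand-aware with a fixed priority, taking the first
matching gene in ascending tx_start order when several genes overlap.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "RegionClass",
    "GeneRegion",
    "REGION_CLASSES",
    "GENE_REGIONS",
    "classify_cgi_relation",
    "classify_cgi_relations",
    "assign_gene_region",
    "assign_gene_regions",
    "annotate_dmps",
    "genes_from_cgiplus",
]

REGION_CLASSES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_REGIONS = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic")

SHORE_MAX = 2000
SHELF_MAX = 4000


class RegionClass(NamedTuple):
    region: str
    assigned_cgi: str | None
    distance: int


class GeneRegion(NamedTuple):
    region: str
    gene: str | None


def classify_cgi_relation(chrom: str, pos: int, cgis: pd.DataFrame) -> RegionClass:
    """Classify one position; see :func:`classify_cgi_relations`."""
    probe = pd.DataFrame({"probe_id": ["_p"], "chrom": [chrom], "pos": [pos]})
    row = classify_cgi_relations(probe, cgis).iloc[0]
    cgi = row["assigned_cgi"]
    return RegionClass(row["region_class"], None if pd.isna(cgi) else cgi, int(row["cgi_distance"]))


def classify_cgi_relations(probes: pd.DataFrame, cgis: pd.DataFrame) -> pd.DataFrame:
    """Vectorised island/shore/shelf/open-sea classification.

    Nearest island is chosen by edge distance; ties between equidistant
    islands go to the lower-coordinate one. Chromosomes with no islands are
    open sea (distance reported as -1).

    Returns a frame indexed like ``probes`` with columns region_class,
    assigned_cgi, cgi_distance.
    """
    region = np.full(len(probes), "OpenSea", dtype=object)
    assigned = np.full(len(probes), None, dtype=object)
    distance = np.full(len(probes), -1, dtype=np.int64)

    pos_all = probes["pos"].to_numpy(dtype=np.int64)
    for chrom, grp_idx in probes.groupby("chrom", sort=False).indices.items():
        sub = cgis[cgis["chrom"] == chrom].sort_values("start")
        if sub.empty:
            continue
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        ids = sub["cgi_id"].to_numpy()
        pos = pos_all[grp_idx]
        # candidate islands: the one starting at/before pos and the next one
        right = np.searchsorted(starts, pos, side="right")
        left = right - 1
        d_left = np.where(left >= 0, np.maximum(pos - ends[np.clip(left, 0, None)], 0), np.iinfo(np.int64).max)
        d_left = np.where(left >= 0, d_left, np.iinfo(np.int64).max)
        d_right = np.where(right < len(starts), starts[np.clip(right, None, len(starts) - 1)] - pos, np.iinfo(np.int64).max)
        pick_left = d_left <= d_right  # tie -> lower-coordinate island
        d = np.where(pick_left, d_left, d_right)
        which = np.where(pick_left, np.clip(left, 0, None), np.clip(right, None, len(starts) - 1))

        side_n = np.where(pick_left, False, True)  # right island: pos < start -> N side
        inside = d == 0
        cls = np.empty(len(pos), dtype=object)
        cls[inside] = "Island"
        shore = (~inside) & (d <= SHORE_MAX)
        shelf = (~inside) & (d > SHORE_MAX) & (d <= SHELF_MAX)
        open_sea = d > SHELF_MAX
        cls[shore & side_n] = "N_Shore"
        cls[shore & ~side_n] = "S_Shore"
        cls[shelf & side_n] = "N_Shelf"
        cls[shelf & ~side_n] = "S_Shelf"
        cls[open_sea] = "OpenSea"
        region[grp_idx] = cls
        distance[grp_idx] = d
        ass = ids[which].astype(object)
        ass[open_sea] = None
        assigned[grp_idx] = ass

    return pd.DataFrame(
        {"region_class": region, "assigned_cgi": assigned, "cgi_distance": distance},
        index=probes.index,
    )


def _gene_region_flags(pos: np.ndarray, g: pd.Series) -> np.ndarray:
    """Class of each position relative to one gene ('' where outside)."""
    out = np.full(len(pos), "", dtype=object)
    plus = g["strand"] == "+"
    tss = g["tx_start"] if plus else g["tx_end"]
    upstream = (tss - pos) if plus else (pos - tss)
    in_tx = (pos >= g["tx_start"]) & (pos <= g["tx_end"])
    if plus:
        utr5 = in_tx & (pos < g["cds_start"])
        utr3 = in_tx & (pos > g["cds_end"])
    else:
        utr5 = in_tx & (pos > g["cds_end"])
        utr3 = in_tx & (pos < g["cds_start"])
    first_exon = (pos >= g["first_exon_start"]) & (pos <= g["first_exon_end"])
    # priority: TSS200 > TSS1500 > UTR5 > FirstExon > Body > UTR3
    out[in_tx & utr3] = "UTR3"
    out[in_tx] = np.where(out[in_tx] == "", "Body", out[in_tx])
    out[first_exon] = "FirstExon"
    out[utr5] = "UTR5"
    out[(upstream >= 201) & (upstream <= 1500)] = "TSS1500"
    out[(upstream >= 1) & (upstream <= 200)] = "TSS200"
    return out


def assign_gene_region(chrom: str, pos: int, genes: pd.DataFrame) -> GeneRegion:
    """Classify one position; see :func:`assign_gene_regions`."""
    probe = pd.DataFrame({"probe_id": ["_p"], "chrom": [chrom], "pos": [pos]})
    row = assign_gene_regions(probe, genes).iloc[0]
    g = row["gene"]
    return GeneRegion(row["gene_region"], None if pd.isna(g) else g)


def assign_gene_regions(probes: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware gene-region assignment with the first-gene rule.

    Genes on each chromosome are visited in ascending tx_start order and
    the first gene yielding a non-intergenic class wins; within a gene the
    class priority is TSS200 > TSS1500 > 5'UTR > first exon > body > 3'UTR.
    """
    region = np.full(len(probes), "Intergenic", dtype=object)
    gene_name = np.full(len(probes), None, dtype=object)
    pos_all = probes["pos"].to_numpy(dtype=np.int64)

    for chrom, grp_idx in probes.groupby("chrom", sort=False).indices.items():
        sub = genes[genes["chrom"] == chrom].sort_values("tx_start")
        if sub.empty:
            continue
        pos = pos_all[grp_idx]
        unset = np.ones(len(pos), dtype=bool)
        cls = np.full(len(pos), "Intergenic", dtype=object)
        name = np.full(len(pos), None, dtype=object)
        for _, g in sub.iterrows():
            if not unset.any():
                break
            flags = _gene_region_flags(pos, g)
            hit = unset & (flags != "")
            cls[hit] = flags[hit]
            name[hit] = g["name"]
            unset &= ~hit
        region[grp_idx] = cls
        gene_name[grp_idx] = name

    return pd.DataFrame({"gene_region": region, "gene": gene_name}, index=probes.index)


# Illumina-manifest annotation column names accepted in pass-through mode
_PASSTHROUGH_REGION = {
    "island": "Island",
    "n_shore": "N_Shore",
    "s_shore": "S_Shore",
    "n_shelf": "N_Shelf",
    "s_shelf": "S_Shelf",
    "": "OpenSea",
    "opensea": "OpenSea",
    "open_sea": "OpenSea",
}
_PASSTHROUGH_GENE_REGION = {
    "tss200": "TSS200",
    "tss1500": "TSS1500",
    "5'utr": "UTR5",
    "utr5": "UTR5",
    "1stexon": "FirstExon",
    "firstexon": "FirstExon",
    "body": "Body",
    "3'utr": "UTR3",
    "utr3": "UTR3",
    "": "Intergenic",
}


def annotate_dmps(
    dmps: pd.DataFrame,
    cgis: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    recompute: bool = True,
) -> pd.DataFrame:
    """Attach CGI-relative and gene-region classes to DMP records.

    With ``recompute=True`` (default) classes are computed from geometry
    (``cgis``/``genes``; coordinates taken from the records or joined from
    ``manifest``). With ``recompute=False``, precomputed Illumina-style
    annotation columns (Relation_to_UCSC_CpG_Island, UCSC_RefGene_Name,
    UCSC_RefGene_Group) are passed through instead — useful for exact
    replication of a published annotation.

    Adds columns: region_class, assigned_cgi, cgi_distance, gene,
    gene_region, cgi_plus, gene_assigned. A gene-assigned DMP is one that
    is CGI+ *and* has a gene name (the CGI+ -> gene funnel).
    """
    out = dmps.copy()
    if manifest is not None and ("chrom" not in out.columns or "pos" not in out.columns):
        out = out.merge(manifest[["probe_id", "chrom", "pos"]], on="probe_id", how="left")

    if not recompute:
        rel = out.get("Relation_to_UCSC_CpG_Island", pd.Series("", index=out.index)).fillna("")
        out["region_class"] = rel.astype(str).str.lower().map(_PASSTHROUGH_REGION).fillna("OpenSea")
        out["assigned_cgi"] = out.get("UCSC_CpG_Islands_Name", pd.Series(None, index=out.index))
        out["cgi_distance"] = -1
        grp = out.get("UCSC_RefGene_Group", pd.Series("", index=out.index)).fillna("")
        grp = grp.astype(str).str.split(";").str[0].str.lower()
        out["gene_region"] = grp.map(_PASSTHROUGH_GENE_REGION).fillna("Intergenic")
        gene = out.get("UCSC_RefGene_Name", pd.Series(None, index=out.index))
        gene = gene.astype("string").str.split(";").str[0]
        out["gene"] = gene.where(gene.notna() & (gene != ""), None)
        out.loc[out["gene"].isna(), "gene_region"] = "Intergenic"
    else:
        if cgis is None or genes is None:
            raise ValueError("recompute=True requires cgis and genes")
        if out.empty:
            for col in ("region_class", "assigned_cgi", "cgi_distance", "gene", "gene_region"):
                out[col] = pd.Series(dtype=object)
        else:
            known = set(cgis["chrom"]) | set(genes["chrom"])
            unknown = set(out["chrom"]) - known
            if unknown:
                warnings.warn(
                    f"chromosomes absent from annotation: {sorted(unknown)}; "
                    "classified as OpenSea/Intergenic",
                    stacklevel=2,
                )
            out = pd.concat([out, classify_cgi_relations(out, cgis)], axis=1)
            out = pd.concat([out, assign_gene_regions(out, genes)], axis=1)

    out["cgi_plus"] = out["region_class"] != "OpenSea"
    out["gene_assigned"] = out["cgi_plus"] & out["gene"].notna()
    return out


def genes_from_cgiplus(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary over gene-assigned (CGI+) DMPs.

    One row per gene with at least one CGI+ DMP: the DMP count and the
    dominant methylation state (majority direction; ties labelled mixed).
    """
    sub = annotated[annotated.get("gene_assigned", False) & annotated["gene"].notna()]
    if sub.empty:
        return pd.DataFrame(columns=["gene", "n_dmps", "state"])
    rows = []
    for gene, grp in sub.groupby("gene", sort=True):
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        state = "hyper" if n_hyper > n_hypo else ("hypo" if n_hypo > n_hyper else "mixed")
        rows.append({"gene": gene, "n_dmps": len(grp), "state": state})
    return pd.DataFrame(rows).sort_values(["n_dmps", "gene"], ascending=[False, True]).reset_index(drop=True)
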