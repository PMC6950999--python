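"""End-to-end orchestration: simulate/ingest -> preprocess -> call ->
annotate -> enrich -> report.

The central artefact is the :class:`FunnelReport`, mirroring the DMP
funnel: probes tested -> DMPs -> hyper/hypo split -> CGI-relative classes
-> CGI+ subset -> gene-assigned subset -> genes. Its invariants
(hyper + hypo = DMPs; region classes partition the DMP set;
gene-assigned <= CGI+ <= DMPs) are checked on every run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .annotate import REGION_CLASSES, annotate_dmps, classify_cgi_relations, genes_from_cgiplus
from .dmp import DifferentialMethylation
from .enrich import chromosome_enrichment, direction_proportion_test, region_class_enrichment
from .preprocess import compute_beta, detection_filter, normalize_within_array
from .simulate import (
    ChromSpec,
    MixtureSpec,
    PlantingSpec,
    default_sample_sheet,
    generate_dataset,
    generate_intensities,
    generate_manifest,
)

logger = logging.getLogger("dmppipe")

__all__ = ["RunConfig", "SimulationSpec", "FunnelReport", "run_pipeline",
           "import_supplementary_dmps", "export_manhattan_table"]

CHROM_ORDER = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


@dataclass
class SimulationSpec:
    """Synthetic-input description for a pipeline run."""

    n_probes: int = 20_000
    chroms: list[ChromSpec] = field(
        default_factory=lambda: [ChromSpec("chr1", 60_000_000), ChromSpec("chr2", 40_000_000)]
    )
    cgi_density: float = 9.0
    genes_per_chrom: int = 300
    planting: PlantingSpec = field(default_factory=PlantingSpec)
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    precision: float = 200.0
    total_mean: float = 4000.0
    fail_rate: float = 0.003
    from_intensities: bool = True


@dataclass
class RunConfig:
    """Thresholds, inputs and modes for one pipeline run.

    Either ``simulation`` is given (synthetic run) or the input paths
    (beta/sheet/manifest/cgis/genes) are.
    """

    simulation: SimulationSpec | None = None
    beta_path: str | None = None
    sheet_path: str | None = None
    manifest_path: str | None = None
    cgi_path: str | None = None
    genes_path: str | None = None
    detection_p: float = 0.01
    delta_screen: float = 0.1
    delta_min: float = 0.15
    q_max: float = 0.05
    mode: str = "pooled"
    normalize: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.detection_p < 1:
            raise ValueError("detection_p must be in (0, 1)")
        for name in ("delta_screen", "delta_min"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.q_max <= 1:
            raise ValueError("q_max must be in [0, 1]")
        if self.simulation is None:
            missing = [n for n in ("beta_path", "sheet_path", "manifest_path", "cgi_path", "genes_path")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError(f"no simulation spec and missing input files: {missing}")


@dataclass
class FunnelReport:
    """Counts down the DMP funnel plus the attached result tables."""

    seed: int
    n_tested: int
    n_dmps: int
    n_hyper: int
    n_hypo: int
    region_class_counts: dict[str, int]
    n_cgi_plus: int
    n_gene_assigned_dmps: int
    n_genes: int
    call_rates: dict[str, float]
    direction_p_binomial: float | None
    thresholds: dict[str, float]
    per_gene: pd.DataFrame
    annotated_dmps: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]
    truth_recovery: dict[str, float] | None = None

    def validate(self) -> None:
        assert self.n_hyper + self.n_hypo == self.n_dmps, "direction split must partition DMPs"
        assert sum(self.region_class_counts.values()) == self.n_dmps, "region classes must partition DMPs"
        assert self.n_gene_assigned_dmps <= self.n_cgi_plus <= self.n_dmps, "funnel must be nested"

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "n_tested": self.n_tested,
            "n_dmps": self.n_dmps,
            "n_hyper": self.n_hyper,
            "n_hypo": self.n_hypo,
            "region_class_counts": self.region_class_counts,
            "n_cgi_plus": self.n_cgi_plus,
            "n_gene_assigned_dmps": self.n_gene_assigned_dmps,
            "n_genes": self.n_genes,
            "call_rates": {k: round(v, 6) for k, v in self.call_rates.items()},
            "direction_p_binomial": self.direction_p_binomial,
            "thresholds": self.thresholds,
        }
        if self.truth_recovery is not None:
            d["truth_recovery"] = self.truth_recovery
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> FunnelReport:
    """Execute the full cascade and (optionally) write all artefacts."""
    truth = None
    call_rates: dict[str, float] = {}

    if config.simulation is not None:
        sim = config.simulation
        logger.info("simulating %d probes (seed %d)", sim.n_probes, config.seed)
        manifest, cgis, genes = generate_manifest(
            sim.n_probes, sim.chroms, sim.cgi_density, sim.genes_per_chrom, seed=config.seed
        )
        sheet = default_sample_sheet()
        beta, truth = generate_dataset(
            manifest, sheet, sim.planting, sim.mixture, sim.precision, seed=config.seed + 1
        )
        if sim.from_intensities:
            m, u, detp = generate_intensities(beta, sim.total_mean, sim.fail_rate, seed=config.seed + 2)
            beta = pd.DataFrame(
                compute_beta(m.to_numpy(), u.to_numpy()), index=beta.index, columns=beta.columns
            )
            mask, rates, failed = detection_filter(detp, config.detection_p)
            call_rates = rates.to_dict()
            beta = beta.drop(index=failed)
            logger.info("detection filter: dropped %d probes", len(failed))
    else:
        beta = dio.read_beta(config.beta_path)
        sheet = dio.read_sample_sheet(config.sheet_path)
        manifest = dio.read_manifest(config.manifest_path)
        cgis = dio.read_cgi_csv(config.cgi_path)
        genes = dio.read_genes(config.genes_path)

    if config.normalize and "design_type" in manifest.columns:
        types = manifest.set_index("probe_id")["design_type"].reindex(beta.index)
        if types.notna().all() and types.nunique() > 1:
            beta = normalize_within_array(beta, types)

    model = DifferentialMethylation(
        beta,
        sheet,
        delta_screen=config.delta_screen,
        delta_min=config.delta_min,
        q_max=config.q_max,
        mode=config.mode,
    )
    results = model.fit()
    dmps = results.dmps
    logger.info("called %d DMPs from %d tested probes", len(dmps), len(results.table))

    annotated = annotate_dmps(dmps, cgis, genes, manifest=manifest)
    per_gene = genes_from_cgiplus(annotated)

    manifest_classes = classify_cgi_relations(manifest, cgis)["region_class"]
    enrichment = {}
    for direction in ("hyper", "hypo"):
        enrichment[f"chromosome_{direction}"] = chromosome_enrichment(annotated, manifest, direction)
    class_df, dir_df = region_class_enrichment(annotated, manifest_classes)
    enrichment["region_class"] = class_df
    enrichment["region_direction"] = dir_df

    n_dmps = len(annotated)
    n_hyper = int((annotated["direction"] == "hyper").sum())
    n_hypo = n_dmps - n_hyper
    counts = {cls: int((annotated["region_class"] == cls).sum()) for cls in REGION_CLASSES}
    direction_p = direction_proportion_test(n_hyper, n_hypo) if n_dmps else None

    recovery = None
    if truth is not None and len(truth):
        called = set(annotated["probe_id"])
        planted = set(truth["probe_id"])
        tested = set(beta.index)
        recoverable = planted & tested
        tp = len(called & planted)
        recovery = {
            "sensitivity": tp / len(recoverable) if recoverable else float("nan"),
            "false_discovery_fraction": (len(called) - tp) / len(called) if called else 0.0,
            "n_planted": len(planted),
        }

    report = FunnelReport(
        seed=config.seed,
        n_tested=len(results.table),
        n_dmps=n_dmps,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        region_class_counts=counts,
        n_cgi_plus=int(annotated["cgi_plus"].sum()),
        n_gene_assigned_dmps=int(annotated["gene_assigned"].sum()),
        n_genes=len(per_gene),
        call_rates=call_rates,
        direction_p_binomial=direction_p,
        thresholds={
            "detection_p": config.detection_p,
            "delta_screen": config.delta_screen,
            "delta_min": config.delta_min,
            "q_max": config.q_max,
        },
        per_gene=per_gene,
        annotated_dmps=annotated,
        enrichment=enrichment,
        truth_recovery=recovery,
    )
    report.validate()

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        if config.simulation is not None:
            dio.write_manifest(manifest, out / "manifest.csv")
            dio.write_cgi_csv(cgis, out / "cgis.csv")
            dio.write_genes(genes, out / "genes.csv")
            dio.write_beta(beta, out / "beta.tsv")
            sheet.to_csv(out / "sample_sheet.csv", index=False)
            if truth is not None:
                truth.to_csv(out / "truth.csv", index=False)
        results.table.to_csv(out / "probe_stats.tsv", sep="\t", index=False)
        annotated.to_csv(out / "annotated_dmps.tsv", sep="\t", index=False)
        per_gene.to_csv(out / "gene_summary.tsv", sep="\t", index=False)
        for name, df in enrichment.items():
            df.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        export_manhattan_table(results.table.merge(manifest[["probe_id", "chrom", "pos"]], on="probe_id")).to_csv(
            out / "manhattan.tsv", sep="\t", index=False
        )
        (out / "report.json").write_text(report.to_json() + "\n")
    return report


def export_manhattan_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-probe (chrom, pos, -log10 p) ready for a Manhattan plot.

    Zero p-values are floored at 1e-300 (-log10 = 300). Rows are sorted by
    chromosome rank (1-22, X, Y) then position.
    """
    out = table[["probe_id", "chrom", "pos", "p_value"]].copy()
    p = out["p_value"].clip(lower=1e-300)
    out["neg_log10_p"] = -np.log10(p)
    rank = {c: i for i, c in enumerate(CHROM_ORDER)}
    rank |= {c.removeprefix("chr"): i for i, c in enumerate(CHROM_ORDER)}
    out["_rank"] = out["chrom"].astype(str).map(lambda c: rank.get(c, 999))
    out = out.sort_values(["_rank", "pos"], kind="mergesort").drop(columns="_rank")
    return out.reset_index(drop=True)


_PROBE_COL_CANDIDATES = ("probe_id", "IlmnID", "Name", "TargetID", "ID_REF")


def import_supplementary_dmps(
    path: str | Path,
    cgis: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Load a published DMP list and annotate it for downstream reporting.

    Two dialects are accepted: Illumina-manifest-style annotation columns
    (Relation_to_UCSC_CpG_Island, UCSC_RefGene_Name, UCSC_RefGene_Group)
    which are passed through; or bare coordinates (CHR/MAPINFO or
    chrom/pos) plus ``cgis``/``genes`` tables, from which the classes are
    recomputed geometrically. Direction comes from a ``direction`` column
    or the sign of a delta-beta column.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        return annotate_dmps(
            pd.DataFrame(columns=["probe_id", "chrom", "pos", "delta_beta", "direction"]),
            recompute=False,
        ).iloc[0:0]

    probe_col = next((c for c in _PROBE_COL_CANDIDATES if c in df.columns), None)
    if probe_col is None:
        raise ValueError(f"no probe-id column recognised; headers: {list(df.columns)}")
    df = df.rename(columns={probe_col: "probe_id", "CHR": "chrom", "MAPINFO": "pos",
                            "deltaBeta": "delta_beta", "delta": "delta_beta"})

    if "direction" not in df.columns:
        if "delta_beta" in df.columns:
            df["direction"] = np.where(df["delta_beta"] > 0, "hyper", "hypo")
        elif "state" in df.columns:
            df["direction"] = df["state"].str.lower()
        else:
            raise ValueError(
                f"cannot determine direction (need direction/state/delta column); headers: {list(df.columns)}"
            )

    has_annotation = "Relation_to_UCSC_CpG_Island" in df.columns
    has_coords = {"chrom", "pos"} <= set(df.columns)
    if has_annotation:
        return annotate_dmps(df, recompute=False)
    if has_coords:
        if cgis is None or genes is None:
            raise ValueError("coordinate-only DMP table requires cgis and genes for annotation")
        df["pos"] = df["pos"].astype(int)
        return annotate_dmps(df, cgis, genes)
    raise ValueError(
        "unrecognised DMP table dialect (no annotation columns and no coordinates); "
        f"headers: {list(df.columns)}"
    )
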