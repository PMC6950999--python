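"""CGI-relative and gene-region classification against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from dmppipe import (
    annotate_dmps,
    assign_gene_region,
    classify_cgi_relation,
    genes_from_cgiplus,
)
from dmppipe.annotate import (
    GENE_REGIONS,
    REGION_CLASSES,
    assign_gene_regions,
    classify_cgi_relations,
)

from conftest import make_random_cgis

# a published hg19 island (ZNF69 promoter region) used as a fixed geometry case
ISLAND = pd.DataFrame(
    {"chrom": ["chr19"], "start": [11998804], "end": [11999131], "cgi_id": ["CGI_ZNF69"]}
)


def oracle_classify(chrom, pos, cgis):
    """All-pairs distance scan, independent of the searchsorted path."""
    best = None
    for _, row in cgis[cgis["chrom"] == chrom].iterrows():
        if row["start"] <= pos <= row["end"]:
            d, side = 0, None
        elif pos < row["start"]:
            d, side = row["start"] - pos, "N"
        else:
            d, side = pos - row["end"], "S"
        if best is None or d < best[0]:
            best = (d, side, row["cgi_id"])
    if best is None or best[0] > 4000:
        return "OpenSea"
    d, side, _ = best
    if d == 0:
        return "Island"
    return f"{side}_Shore" if d <= 2000 else f"{side}_Shelf"


def oracle_gene_region(pos, g):
    """Exhaustive window check for one gene, written independently."""
    plus = g["strand"] == "+"
    tss = g["tx_start"] if plus else g["tx_end"]
    up = (tss - pos) if plus else (pos - tss)
    if 1 <= up <= 200:
        return "TSS200"
    if 201 <= up <= 1500:
        return "TSS1500"
    if not (g["tx_start"] <= pos <= g["tx_end"]):
        return None
    if plus and pos < g["cds_start"]:
        return "UTR5"
    if not plus and pos > g["cds_end"]:
        return "UTR5"
    if g["first_exon_start"] <= pos <= g["first_exon_end"]:
        return "FirstExon"
    if plus and pos > g["cds_end"]:
        return "UTR3"
    if not plus and pos < g["cds_start"]:
        return "UTR3"
    return "Body"


class TestCgiClassification:
    @pytest.mark.parametrize(
        "pos,expected,distance",
        [
            (11998900, "Island", 0),
            (11996900, "N_Shore", 1904),
            (12002000, "S_Shelf", 2869),
            (12003200, "OpenSea", 4069),
            (11998804, "Island", 0),
            (11999131, "Island", 0),
        ],
    )
    def test_published_island_geometry(self, pos, expected, distance):
        r = classify_cgi_relation("chr19", pos, ISLAND)
        assert r.region == expected
        assert r.distance == distance

    @pytest.mark.parametrize(
        "d,expected",
        [(1, "S_Shore"), (2000, "S_Shore"), (2001, "S_Shelf"), (4000, "S_Shelf"), (4001, "OpenSea")],
    )
    def test_boundaries_closed_at_2k_and_4k(self, d, expected):
        r = classify_cgi_relation("chr19", 11999131 + d, ISLAND)
        assert r.region == expected

    def test_no_island_chromosome_is_open_sea(self):
        r = classify_cgi_relation("chrX", 500, ISLAND)
        assert r.region == "OpenSea"
        assert r.assigned_cgi is None

    def test_tie_broken_to_lower_coordinate_island(self):
        two = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1000, 3001], "end": [1400, 3400],
             "cgi_id": ["low", "high"]}
        )
        r = classify_cgi_relation("chr1", 2200, two)  # 800 from low end, 801 from high start
        assert r.assigned_cgi == "low"
        r = classify_cgi_relation("chr1", 2201, two)  # 801 vs 800: high wins
        assert r.assigned_cgi == "high"
        r_tie = classify_cgi_relation(
            "chr1", 2200, two.assign(start=[1000, 3000], end=[1400, 3400])
        )  # equidistant (800 both sides)
        assert r_tie.assigned_cgi == "low"

    def test_matches_brute_force_scan_on_random_instances(self):
        rng = np.random.default_rng(17)
        cgis = pd.concat(
            [make_random_cgis(rng, c, 40, 2_000_000) for c in ("chr1", "chr2")],
            ignore_index=True,
        )
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(800)],
                "chrom": rng.choice(["chr1", "chr2", "chr3"], size=800),
                "pos": rng.integers(1, 2_000_000, size=800),
            }
        )
        got = classify_cgi_relations(probes, cgis)
        for i in range(len(probes)):
            expected = oracle_classify(probes.loc[i, "chrom"], probes.loc[i, "pos"], cgis)
            assert got.loc[i, "region_class"] == expected, i

    def test_classes_partition(self, small_manifest):
        manifest, cgis, _ = small_manifest
        classes = classify_cgi_relations(manifest, cgis)["region_class"]
        assert set(classes) <= set(REGION_CLASSES)
        assert classes.value_counts().sum() == len(manifest)

    def test_order_independent(self, small_manifest):
        manifest, cgis, _ = small_manifest
        shuffled = manifest.sample(frac=1, random_state=1)
        a = classify_cgi_relations(manifest.set_index("probe_id"), cgis)
        b = classify_cgi_relations(shuffled.set_index("probe_id"), cgis)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestGeneRegion:
    GENE = pd.DataFrame(
        [
            {
                "name": "GENE1", "chrom": "chr1", "strand": "+",
                "tx_start": 10_000, "tx_end": 30_000,
                "first_exon_start": 10_000, "first_exon_end": 10_400,
                "cds_start": 10_200, "cds_end": 28_000,
            }
        ]
    )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (9_900, "TSS200"),      # 100 bp upstream
            (9_000, "TSS1500"),     # 1000 bp upstream
            (8_400, "Intergenic"),  # 1600 bp upstream
            (10_100, "UTR5"),       # before CDS, inside first exon -> UTR5 priority
            (10_300, "FirstExon"),
            (20_000, "Body"),
            (29_000, "UTR3"),
        ],
    )
    def test_plus_strand_windows(self, pos, expected):
        r = assign_gene_region("chr1", pos, self.GENE)
        assert r.region == expected

    def test_minus_strand_tss_at_tx_end(self):
        gene = self.GENE.assign(
            strand="-", first_exon_start=29_600, first_exon_end=30_000,
            cds_start=12_000, cds_end=29_800,
        )
        assert assign_gene_region("chr1", 30_100, gene).region == "TSS200"
        assert assign_gene_region("chr1", 31_000, gene).region == "TSS1500"
        assert assign_gene_region("chr1", 29_900, gene).region == "UTR5"
        assert assign_gene_region("chr1", 11_000, gene).region == "UTR3"

    def test_first_gene_rule_ascending_tx_start(self):
        g2 = self.GENE.assign(name="GENE0", tx_start=5_000, tx_end=25_000,
                              first_exon_start=5_000, first_exon_end=5_300,
                              cds_start=5_100, cds_end=24_000)
        both = pd.concat([self.GENE, g2], ignore_index=True)
        r = assign_gene_region("chr1", 20_000, both)  # inside both
        assert r.gene == "GENE0"

    def test_matches_exhaustive_oracle_on_random_instances(self, small_manifest):
        manifest, _, genes = small_manifest
        rng = np.random.default_rng(23)
        probes = manifest.sample(500, random_state=4).reset_index(drop=True)
        got = assign_gene_regions(probes, genes)
        for i in range(len(probes)):
            chrom, pos = probes.loc[i, "chrom"], probes.loc[i, "pos"]
            expected_region, expected_gene = "Intergenic", None
            for _, g in genes[genes["chrom"] == chrom].sort_values("tx_start").iterrows():
                cls = oracle_gene_region(pos, g)
                if cls is not None:
                    expected_region, expected_gene = cls, g["name"]
                    break
            assert got.loc[i, "gene_region"] == expected_region, i
            assert got.loc[i, "gene"] == expected_gene, i

    def test_intergenic_iff_no_gene(self, small_manifest):
        manifest, _, genes = small_manifest
        out = assign_gene_regions(manifest, genes)
        assert (out["gene"].isna() == (out["gene_region"] == "Intergenic")).all()
        assert set(out["gene_region"]) <= set(GENE_REGIONS)


class TestAnnotateDmps:
    @staticmethod
    def _dmps(manifest, probe_ids, direction="hypo"):
        sub = manifest[manifest["probe_id"].isin(probe_ids)]
        return pd.DataFrame(
            {
                "probe_id": sub["probe_id"].to_numpy(),
                "delta_beta": -0.2 if direction == "hypo" else 0.2,
                "direction": direction,
            }
        )

    def test_far_from_islands_zero_cgi_plus(self):
        manifest = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "chrom": "chr1", "pos": [100_000, 200_000]}
        )
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1500], "cgi_id": ["c"]})
        genes = pd.DataFrame(columns=["name", "chrom", "strand", "tx_start", "tx_end",
                                      "first_exon_start", "first_exon_end", "cds_start", "cds_end"])
        dmps = self._dmps(manifest, ["p1", "p2"])
        out = annotate_dmps(dmps, cgis, genes, manifest=manifest)
        assert out["cgi_plus"].sum() == 0
        assert out["gene_assigned"].sum() == 0

    def test_funnel_counts_match_independent_classification(self, small_manifest):
        manifest, cgis, genes = small_manifest
        dmps = self._dmps(manifest, manifest["probe_id"].iloc[::20])
        out = annotate_dmps(dmps, cgis, genes, manifest=manifest)
        classes = classify_cgi_relations(
            manifest[manifest["probe_id"].isin(dmps["probe_id"])], cgis
        )["region_class"]
        assert int(out["cgi_plus"].sum()) == int((classes != "OpenSea").sum())
        assert (out["gene_assigned"] <= out["cgi_plus"]).all()

    def test_pass_through_mode_uses_supplied_columns(self):
        dmps = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "direction": ["hypo", "hyper", "hypo"],
                "Relation_to_UCSC_CpG_Island": ["Island", "N_Shore", ""],
                "UCSC_RefGene_Name": ["ZNF69", "ZNF69;OTHER", ""],
                "UCSC_RefGene_Group": ["TSS200", "Body;5'UTR", ""],
            }
        )
        out = annotate_dmps(dmps, recompute=False)
        assert list(out["region_class"]) == ["Island", "N_Shore", "OpenSea"]
        assert list(out["gene_region"]) == ["TSS200", "Body", "Intergenic"]
        assert list(out["gene"])[:2] == ["ZNF69", "ZNF69"]
        assert list(out["cgi_plus"]) == [True, True, False]

    def test_unknown_chromosome_warns_open_sea(self, small_manifest):
        _, cgis, genes = small_manifest
        dmps = pd.DataFrame(
            {"probe_id": ["p1"], "chrom": ["chrZ"], "pos": [1000],
             "delta_beta": [0.2], "direction": ["hyper"]}
        )
        with pytest.warns(UserWarning, match="absent from annotation"):
            out = annotate_dmps(dmps, cgis, genes)
        assert out.loc[0, "region_class"] == "OpenSea"
        assert out.loc[0, "gene_region"] == "Intergenic"


class TestGeneSummary:
    def test_majority_state(self):
        annotated = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "gene": ["ZNF69"] * 3,
                "direction": ["hypo", "hypo", "hypo"],
                "cgi_plus": [True] * 3,
                "gene_assigned": [True] * 3,
            }
        )
        out = genes_from_cgiplus(annotated)
        assert len(out) == 1
        assert out.loc[0, "n_dmps"] == 3
        assert out.loc[0, "state"] == "hypo"

    def test_tie_is_mixed(self):
        annotated = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "gene": ["G"] * 2,
                "direction": ["hypo", "hyper"],
                "cgi_plus": [True] * 2,
                "gene_assigned": [True] * 2,
            }
        )
        assert genes_from_cgiplus(annotated).loc[0, "state"] == "mixed"

    def test_empty_input(self):
        out = genes_from_cgiplus(pd.DataFrame(columns=["probe_id", "gene", "direction",
                                                       "cgi_plus", "gene_assigned"]))
        assert out.empty

    def test_clustered_island_planting_counts(self, small_manifest, sheet):
        """10 DMPs planted on one gene's island report n_dmps = 10."""
        from dmppipe import PlantingSpec, call_dmps, generate_dataset

        manifest, cgis, genes = small_manifest
        # find a gene whose island hosts >= 10 probes
        classes = classify_cgi_relations(manifest, cgis)
        island_probes = manifest[classes["region_class"] == "Island"]
        regions = assign_gene_regions(island_probes, genes)
        island_probes = island_probes.assign(gene=regions["gene"].to_numpy())
        counts = island_probes.dropna(subset=["gene"]).groupby("gene").size()
        # synthetic layouts are sparse; fall back to densest available gene
        gene = counts.idxmax()
        chosen = island_probes.loc[island_probes["gene"] == gene, "probe_id"].iloc[:10]
        n_expected = len(chosen)
        beta, truth = generate_dataset(
            manifest, sheet, PlantingSpec(probe_ids=list(chosen), direction_mix=1.0), seed=13
        )
        dmps = call_dmps(beta, sheet)
        out = annotate_dmps(dmps, cgis, genes, manifest=manifest)
        summary = genes_from_cgiplus(out)
        assert summary.set_index("gene").loc[gene, "n_dmps"] == n_expected
        assert summary.set_index("gene").loc[gene, "state"] == "hypo"
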