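"""Core/background region-set construction and annotation."""

import numpy as np
import pandas as pd
import pytest

from hrescan.regions import (ConservedElement, GeneModel, GenomicRegion,
                             annotate_location, build_background,
                             conserved_hbs, elements_from_bed, extend_region,
                             filter_by_induction, flat_expression_genes,
                             matching_report, overlap_core, read_bed,
                             regions_to_bed)

from conftest import make_region


def gr(region_id, chrom, start, end, **kw):
    return GenomicRegion(region_id, chrom, start, end, **kw)


class TestOverlapCore:
    def test_two_of_four_kept_one_dropped(self):
        shared = (100, 200)
        sets = {
            "hela": [gr("a", "chr1", *shared), gr("b", "chr1", 5000, 5100)],
            "hepg2": [gr("c", "chr1", *shared)],
            "mcf7": [gr("d", "chr2", 100, 200)],
            "u87": [gr("e", "chr3", 100, 200)],
        }
        kept = overlap_core(sets, min_studies=2)
        assert {r.region_id for r in kept} == {"a", "c"}
        assert all(r.extras["n_studies"] == 2 for r in kept)

    def test_min_studies_one_returns_union(self):
        sets = {
            "s1": [gr("a", "chr1", 0, 10)],
            "s2": [gr("b", "chr2", 0, 10)],
        }
        assert len(overlap_core(sets, min_studies=1)) == 2

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(17)
        sets = {}
        for s in range(4):
            regions = []
            for i in range(60):
                start = int(rng.integers(0, 5000))
                regions.append(gr(f"s{s}_{i}", f"chr{rng.integers(1, 3)}",
                                  start, start + int(rng.integers(50, 300))))
            sets[f"study{s}"] = regions
        kept = overlap_core(sets, min_studies=2)
        # brute-force oracle: pairwise interval intersection
        all_ids = set()
        for study, regions in sets.items():
            for r in regions:
                support = 0
                for other, oregions in sets.items():
                    if any(o.chrom == r.chrom and o.start < r.end and r.start < o.end
                           for o in oregions):
                        support += 1
                if support >= 2:
                    all_ids.add(r.region_id)
        assert {r.region_id for r in kept} == all_ids

    def test_empty_input(self):
        assert overlap_core({"a": [], "b": []}) == []


class TestConservedHbs:
    def test_containment_rule(self):
        region = make_region("TTTTTACGTGTTTTT", start=1000)  # ACGTG at 5
        inside = [ConservedElement("chr1", 1004, 1011)]
        outside = [ConservedElement("chr1", 1006, 1020)]  # starts 1 bp late
        assert len(conserved_hbs(region, inside)) == 1
        assert conserved_hbs(region, outside) == []

    def test_empty_elements(self):
        region = make_region("TTTTTACGTGTTTTT")
        assert conserved_hbs(region, []) == []

    def test_two_motifs_one_conserved(self):
        seq = "ACGTGTTTTTTTTTTGCGTG"
        mouse = "ACGTGTTTTTTTTTTTTTTT"  # second motif not conserved in mouse
        region = make_region(seq, {"mouse": mouse}, start=0)
        elements = [ConservedElement("chr1", 0, 20)]
        hbs = conserved_hbs(region, elements, both_strands=False)
        assert [(h.offset, h.strand) for h in hbs] == [(0, "+")]


class TestExtendRegion:
    def test_no_elements_returns_hbs_itself(self):
        out = extend_region("chr1", 1147, 1152, [])
        assert (out.start, out.end) == (1147, 1152)

    def test_centered_element_growth_stops_at_half_coverage(self):
        # 300 bp element; growth continues until covered/span <= 0.5,
        # i.e. the span just below 2x the element length
        elements = [ConservedElement("chr1", 1000, 1300)]
        out = extend_region("chr1", 1147, 1152, elements)
        assert out.start <= 1147 and out.end >= 1152
        assert (out.start, out.end) == (857, 1442)  # span 585, next step 605
        span = out.end - out.start
        assert 300 / span > 0.5 and 300 / (span + 20) <= 0.5

    def test_gap_equal_to_combined_length_not_spanned(self):
        elements = [ConservedElement("chr1", 1000, 1150),
                    ConservedElement("chr1", 1450, 1600)]
        out = extend_region("chr1", 1070, 1075, elements)
        assert out.end < 1450 and out.start >= 1000 - 150
        assert (out.start, out.end) == (930, 1215)

    def test_contains_seed_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = int(rng.integers(1000, 5000))
            elements = [ConservedElement("chr1", int(rng.integers(0, 6000)),
                                         int(rng.integers(6000, 9000)))
                        for _ in range(3)]
            out = extend_region("chr1", s, s + 5, elements, max_span=2000)
            assert out.start <= s and out.end >= s + 5
            assert out.end - out.start <= 2000


class TestInductionFilter:
    def test_threshold(self):
        regions = [gr("a", "chr1", 0, 10, gene_id="g1"),
                   gr("b", "chr1", 0, 10, gene_id="g2")]
        calls = {"g1": (0.001, 0.01), "g2": (0.01, 0.05)}
        kept = filter_by_induction(regions, calls, max_fdr=0.02)
        assert [r.region_id for r in kept] == ["a"]

    def test_missing_gene_dropped_with_warning(self, caplog):
        regions = [gr("a", "chr1", 0, 10, gene_id="gX")]
        with caplog.at_level("WARNING"):
            assert filter_by_induction(regions, {}) == []
        assert "gX" in caplog.text


class TestBackground:
    def make_fold_tables(self, rng, n_genes=300, n_datasets=4, outliers=(),
                         n_flat=150):
        # genes are consistently flat or consistently variable across
        # datasets, as real expression data would be
        flat_mask = np.arange(n_genes) < n_flat
        tables = []
        for d in range(n_datasets):
            folds = rng.normal(0, 1, n_genes)
            folds[flat_mask] = rng.normal(0, 0.05, flat_mask.sum())
            genes = [f"g{i}" for i in range(n_genes)]
            for gene, sd_units in outliers:
                folds[genes.index(gene)] = sd_units
            tables.append(pd.DataFrame({
                "gene_id": genes,
                "probe_id": [f"g{i}_p" for i in range(n_genes)],
                "fold": folds,
            }))
        return tables

    def test_center_gene_eligible_outlier_vetoed(self):
        rng = np.random.default_rng(2)
        tables = self.make_fold_tables(rng, outliers=[("g0", 0.0), ("g1", 3.0)])
        flat = flat_expression_genes(tables)
        assert "g0" in flat
        assert "g1" not in flat  # +3 SD in every dataset

    def test_single_dataset_veto(self):
        rng = np.random.default_rng(3)
        tables = self.make_fold_tables(rng)
        # push g5 out in only the last dataset
        tables[-1].loc[tables[-1]["gene_id"] == "g5", "fold"] = 4.0
        assert "g5" not in flat_expression_genes(tables)

    def test_location_matched_sampling(self):
        rng = np.random.default_rng(4)
        core = [gr(f"c{i}", "chr1", i * 10, i * 10 + 5, gene_id=f"core{i}",
                   location_class="promoter" if i < 10 else "intron",
                   label="core") for i in range(20)]
        candidates = []
        for i in range(1000):
            candidates.append(gr(f"b{i}", "chr2", i * 10, i * 10 + 5,
                                 gene_id=f"g{i % 140}",
                                 location_class="promoter" if i % 2 else "intron"))
        tables = self.make_fold_tables(np.random.default_rng(5))
        flat = flat_expression_genes(tables)
        chosen = build_background(candidates, tables, core, seed=1, n_target=100)
        classes = pd.Series([c.location_class for c in chosen]).value_counts()
        assert abs(classes.get("promoter", 0) - 50) <= 1
        assert abs(classes.get("intron", 0) - 50) <= 1
        assert all(c.label == "background" for c in chosen)
        assert {c.gene_id for c in chosen} <= flat

    def test_core_background_genes_disjoint(self):
        core = [gr("c0", "chr1", 0, 10, gene_id="g0",
                   location_class="promoter", label="core")]
        candidates = [gr("b0", "chr2", 0, 10, gene_id="g0", location_class="promoter"),
                      gr("b1", "chr2", 20, 30, gene_id="g1", location_class="promoter")]
        tables = self.make_fold_tables(np.random.default_rng(6), n_genes=10)
        chosen = build_background(candidates, tables, core, n_target=2)
        assert all(c.gene_id != "g0" for c in chosen)


class TestAnnotateLocation:
    def models(self):
        return [
            GeneModel("gA", "chr1", "+", tss=10_000,
                      utr5=(10_000, 10_200), introns=[(10_400, 11_000)],
                      utr3=(11_200, 11_400)),
            GeneModel("gB", "chr1", "-", tss=50_000),
        ]

    def test_promoter_window(self):
        region = gr("r", "chr1", 9_300, 9_700)  # midpoint 9500, 500 bp upstream
        assert annotate_location(region, self.models()) == "promoter"
        assert region.gene_id == "gA"

    def test_intron_containment(self):
        region = gr("r", "chr1", 10_500, 10_600)
        assert annotate_location(region, self.models()) == "intron"

    def test_utr5_precedence_over_intron(self):
        # straddles the UTR5/intron boundary region; midpoint inside UTR5
        region = gr("r", "chr1", 10_100, 10_220)  # midpoint 10160 in UTR5
        assert annotate_location(region, self.models()) == "UTR5"

    def test_minus_strand_promoter(self):
        region = gr("r", "chr1", 50_400, 50_600)  # midpoint 50500, downstream coords
        assert annotate_location(region, self.models()) == "promoter"
        assert region.gene_id == "gB"

    def test_nearest_gene_fallback(self, caplog):
        region = gr("r", "chr1", 30_000, 30_100)
        with caplog.at_level("WARNING"):
            cls = annotate_location(region, self.models())
        assert cls == "promoter" and "nearest" in caplog.text


def test_bed_round_trip_and_matching_report():
    regions = [gr("a", "chr1", 0, 100, location_class="promoter", label="core"),
               gr("b", "chr2", 50, 150, location_class="intron", label="background")]
    bed = regions_to_bed(regions)
    parsed = read_bed(bed)
    assert parsed[0] == ("chr1", 0, 100, "a")
    elements = elements_from_bed("chr1\t5\t50\nchr3\t0\t10\n")
    assert elements[0].start == 5
    rep = matching_report([regions[0]], [regions[1]],
                          {"a": "ACGT" * 25, "b": "GGCC" * 25})
    assert set(rep["label"]) == {"core", "background"}
    gc_core = rep[(rep.label == "core") & (rep.location_class == "promoter")]["gc_mean"]
    assert float(gc_core.iloc[0]) == 0.5
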