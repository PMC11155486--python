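"""Gene-body redefinition, operon detection, classification, TAS location
and trans-splicing ratio."""

import numpy as np
import pytest

from outronscan import geneclass, statcore
from outronscan.geneclass import (
    GeneModel,
    STATUS_AMBIGUOUS,
    STATUS_NON_TS,
    STATUS_TS,
    Transcript,
    classify_gene,
    compute_ts_ratio,
    detect_operons,
    first_as_enrichment_test,
    locate_tas,
    redefine_gene_bodies,
    select_major_tas,
    split_high_low,
)
from outronscan.ioformats import Interval
from outronscan.tagcall import TransSpliceSite


def tx(tx_id, chrom, strand, exon_pairs, status="non-SL"):
    return Transcript(tx_id, chrom, strand,
                      [Interval(chrom, s, e, strand) for s, e in exon_pairs], status)


def gene(gid, chrom, strand, exon_pairs, status="non-SL"):
    return GeneModel(gid, chrom, strand, [tx(f"{gid}.t1", chrom, strand, exon_pairs, status)])


class TestRedefineGeneBodies:
    def test_extension_moves_start_five_prime(self):
        known = [gene("g1", "c", "+", [(500, 600), (700, 800)], status="SL")]
        novel = [tx("n1", "c", "+", [(300, 600)])]
        (out,) = redefine_gene_bodies(known, novel)
        assert out.body.start == 300 and out.body.end == 800

    def test_identity_without_novel(self):
        known = [gene("g1", "c", "+", [(500, 600)])]
        (out,) = redefine_gene_bodies(known, [])
        assert out.body == known[0].body

    def test_gene_count_invariant_and_unassigned_dropped(self):
        known = [gene("g1", "c", "+", [(500, 600)]), gene("g2", "c", "-", [(900, 1000)])]
        novel = [tx("far", "c", "+", [(5000, 5100)]),  # no overlap: dropped
                 tx("n1", "c", "-", [(850, 950)])]
        out = redefine_gene_bodies(known, novel)
        assert len(out) == 2
        assert {g.gene_id for g in out} == {"g1", "g2"}

    def test_two_gene_overlap_goes_to_larger(self):
        known = [gene("g1", "c", "+", [(100, 300)]), gene("g2", "c", "+", [(300, 700)])]
        novel = [tx("n1", "c", "+", [(250, 600)])]  # 50 bp vs 300 bp overlap
        out = redefine_gene_bodies(known, novel)
        g2 = next(g for g in out if g.gene_id == "g2")
        assert len(g2.transcripts) == 2
        assert g2.body.start == 250


def operon_oracle(models, tas_sites):
    """Independent brute force: a gene is operonic iff it belongs to some
    genomically contiguous range of >= 2 same-strand genes with all
    adjacent gaps <= 0 in which every transcriptionally non-first gene's
    5' end is a TAS."""
    tas = {(s.chrom, s.strand, s.pos) for s in tas_sites}
    flags = {m.gene_id: False for m in models}
    by_chrom = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.body.start, g.body.end))
        n = len(genes)
        for i in range(n):
            for j in range(i + 1, n):
                block = genes[i: j + 1]
                if len({g.strand for g in block}) != 1:
                    continue
                if any(b.body.start - a.body.end > 0 for a, b in zip(block, block[1:])):
                    continue
                strand = block[0].strand
                ordered = block if strand == "+" else block[::-1]
                if all((chrom, strand, g.five_prime) in tas for g in ordered[1:]):
                    for g in block:
                        flags[g.gene_id] = True
    return flags


class TestDetectOperons:
    def test_gap_zero_with_tas_both_operonic(self):
        models = [gene("g1", "c", "+", [(100, 200)]), gene("g2", "c", "+", [(200, 300)])]
        tas = [TransSpliceSite("c", 200, "+", 10)]
        flags = detect_operons(models, tas)
        assert flags == {"g1": True, "g2": True}

    def test_gap_one_not_operonic(self):
        models = [gene("g1", "c", "+", [(100, 200)]), gene("g2", "c", "+", [(201, 300)])]
        tas = [TransSpliceSite("c", 201, "+", 10)]
        assert detect_operons(models, tas) == {"g1": False, "g2": False}

    def test_no_tas_not_operonic(self):
        models = [gene("g1", "c", "+", [(100, 200)]), gene("g2", "c", "+", [(200, 300)])]
        assert detect_operons(models, []) == {"g1": False, "g2": False}

    def test_minus_strand_run(self):
        # transcription right-to-left: g1 (left) is downstream, needs TAS at
        # its 5' end (its right edge, position 199)
        models = [gene("g1", "c", "-", [(100, 200)]), gene("g2", "c", "-", [(200, 300)])]
        tas = [TransSpliceSite("c", 199, "-", 5)]
        assert detect_operons(models, tas) == {"g1": True, "g2": True}

    def test_random_layouts_match_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            models, cursor = [], 0
            for i in range(int(rng.integers(2, 9))):
                cursor += int(rng.integers(0, 3))  # gaps 0..2
                length = int(rng.integers(50, 150))
                strand = "+" if rng.random() < 0.5 else "-"
                models.append(gene(f"g{i}", "c", strand,
                                   [(cursor, cursor + length)]))
                cursor += length
            tas = []
            for m in models:
                if rng.random() < 0.6:
                    tas.append(TransSpliceSite("c", m.five_prime, m.strand, 1))
            assert detect_operons(models, tas) == operon_oracle(models, tas)


class TestClassifyGene:
    def setup_method(self):
        self.g = gene("g1", "c", "+", [(100, 200), (300, 400)])

    def test_primary_tas_trans_spliced(self):
        assert classify_gene(self.g, [TransSpliceSite("c", 150, "+", 3)]) == STATUS_TS

    def test_no_tas_non_trans_spliced(self):
        assert classify_gene(self.g, [], []) == STATUS_NON_TS

    def test_secondary_only_ambiguous(self):
        sec = [TransSpliceSite("c", 150, "+", 1)]
        assert classify_gene(self.g, [], sec) == STATUS_AMBIGUOUS

    def test_statuses_partition(self, small_sim, called_sites):
        models = geneclass.gene_models_from_gff(small_sim["annotation"])
        cls = geneclass.classify_genes(models, called_sites["tas_sites"],
                                       called_sites["tss_clusters"])
        assert len(cls) == len(models)
        assert all(c.status in (STATUS_TS, STATUS_NON_TS, STATUS_AMBIGUOUS) for c in cls)


class TestSelectMajorTas:
    def test_max_count_wins(self):
        sites = [TransSpliceSite("c", p, "+", n) for p, n in [(10, 100), (20, 20), (30, 5)]]
        assert select_major_tas(sites).pos == 10

    def test_single_site_identity(self):
        s = TransSpliceSite("c", 10, "+", 1)
        assert select_major_tas([s]) is s

    def test_tie_breaks_five_prime_strand_aware(self):
        sites = [TransSpliceSite("c", 10, "+", 50), TransSpliceSite("c", 20, "+", 50)]
        assert select_major_tas(sites).pos == 10
        sites = [TransSpliceSite("c", 10, "-", 50), TransSpliceSite("c", 20, "-", 50)]
        assert select_major_tas(sites).pos == 20

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_major_tas([])


class TestLocateTas:
    def test_categories_plus_strand(self):
        g = gene("g", "c", "+", [(100, 200), (300, 400), (500, 600)])
        assert locate_tas(g, TransSpliceSite("c", 300, "+", 1)) == "AS_1"
        assert locate_tas(g, TransSpliceSite("c", 500, "+", 1)) == "AS_2"
        assert locate_tas(g, TransSpliceSite("c", 150, "+", 1)) == "5UTR_first_exon"
        assert locate_tas(g, TransSpliceSite("c", 350, "+", 1)) == "internal_exon"
        assert locate_tas(g, TransSpliceSite("c", 250, "+", 1)) == "other"

    def test_categories_minus_strand(self):
        g = gene("g", "c", "-", [(100, 200), (300, 400), (500, 600)])
        # transcript order right-to-left: first exon is [500,600)
        assert locate_tas(g, TransSpliceSite("c", 399, "-", 1)) == "AS_1"
        assert locate_tas(g, TransSpliceSite("c", 199, "-", 1)) == "AS_2"
        assert locate_tas(g, TransSpliceSite("c", 550, "-", 1)) == "5UTR_first_exon"

    def test_nd_when_reference_not_tss_anchored(self):
        g = gene("g", "c", "+", [(100, 200), (300, 400)], status="SL")
        assert locate_tas(g, TransSpliceSite("c", 300, "+", 1)) == "AS_nd"
        assert locate_tas(g, TransSpliceSite("c", 150, "+", 1)) == "5UTR_nd"

    def test_planted_groups_recovered_from_simulation(self, small_sim, called_sites):
        models = geneclass.gene_models_from_gff(small_sim["annotation"])
        cls = {c.gene_id: c for c in geneclass.classify_genes(
            models, called_sites["tas_sites"], called_sites["tss_clusters"])}
        truth = small_sim["truth"]
        checked = 0
        for g in truth.genes:
            if g.group in ("TS-1stAS", "TS-5UTR"):
                assert cls[g.gene_id].group == g.group
                checked += 1
        assert checked >= 10


class TestFirstAsTest:
    def _models(self, n_genes=10, n_introns=3):
        return [gene(f"g{i}", "c", "+",
                     [(100 + 500 * j, 200 + 500 * j) for j in range(n_introns + 1)])
                for i in range(n_genes)]

    def test_k_equals_n_closed_form(self):
        models = self._models(10, 3)  # p0 = 10 / 30
        k, n, p0, p = first_as_enrichment_test(["AS_1"] * 10, models)
        assert (k, n) == (10, 10)
        assert p0 == pytest.approx(1 / 3)
        assert p == pytest.approx(p0 ** 10)

    def test_k_zero_is_one(self):
        models = self._models(5, 2)
        _, _, _, p = first_as_enrichment_test(["AS_2"] * 5, models)
        assert p == 1.0

    def test_matches_enumeration(self):
        import math
        models = self._models(10, 3)
        locations = ["AS_1"] * 8 + ["AS_2"] * 2
        k, n, p0, p = first_as_enrichment_test(locations, models)
        # direct pmf summation with p0 = 0.3333...
        oracle = sum(math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_per_gene_mode(self):
        models = self._models(4, 1) + self._models_with_introns()
        locations = ["AS_1"] * 3
        _, _, p0_site, _ = first_as_enrichment_test(locations, models, "per_site")
        _, _, p0_gene, _ = first_as_enrichment_test(locations, models, "per_gene")
        assert p0_gene >= p0_site  # 1/n is convex in n

    def _models_with_introns(self):
        return [gene("h0", "c", "+", [(0 + 300 * j, 100 + 300 * j) for j in range(5)])]

    def test_no_as_genes_raises(self):
        with pytest.raises(ValueError):
            first_as_enrichment_test(["5UTR_first_exon"], self._models(2, 1))


class TestRatio:
    def test_arithmetic(self):
        assert compute_ts_ratio(10, 30) == pytest.approx(0.75)
        assert compute_ts_ratio(0, 5) == 1.0

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            compute_ts_ratio(0, 0)

    def test_split_boundary_inclusive(self):
        assert split_high_low([0.75, 0.5, 0.49], 0.5) == ["TS_High", "TS_High", "TS_Low"]

    def test_split_is_partition(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(0, 1, 50)
        labels = split_high_low(ratios, 0.3)
        assert len(labels) == 50 and set(labels) <= {"TS_High", "TS_Low"}

    def test_ratio_recovery_on_simulation(self, small_sim, called_sites):
        models = geneclass.gene_models_from_gff(small_sim["annotation"])
        cls = {c.gene_id: c for c in geneclass.classify_genes(
            models, called_sites["tas_sites"], called_sites["tss_clusters"])}
        truth = small_sim["truth"]
        ok = tot = 0
        for g in truth.genes:
            c = cls[g.gene_id]
            if not (g.is_ts and g.tss is not None) or c.ts_ratio is None:
                continue
            tot += 1
            n = c.tss_tags + c.tas_tags
            se = np.sqrt(max(g.ts_ratio * (1 - g.ts_ratio), 1e-9) / n)
            if abs(c.ts_ratio - g.ts_ratio) <= 3 * se:
                ok += 1
        assert tot >= 10
        assert ok / tot >= 0.9
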