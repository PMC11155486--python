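"""Read classification, exact mapping, clustering and site calling."""

import numpy as np
import pytest

from outronscan import synthdata, tagcall
from outronscan.ioformats import BedRecord, FastqRead, Interval, revcomp
from outronscan.tagcall import TagAlignment, TagCluster


SL = "ATTCTATTTGAATAAG"


class TestClassifyReads:
    def test_sl_read_trimmed(self):
        genomic = "ACGTACGTACGTACGTACGTACGTACGTACGTAC"
        reads = [FastqRead("r1", SL + genomic)]
        sl, capped, stats = tagcall.classify_reads(reads, SL, 16)
        assert len(sl) == 1 and not capped
        assert sl[0].seq == genomic

    def test_non_sl_read_untrimmed(self):
        reads = [FastqRead("r1", "CCCC" + SL)]
        sl, capped, _ = tagcall.classify_reads(reads, SL, 16)
        assert not sl and capped[0].seq == "CCCC" + SL

    def test_short_suffix_match(self):
        # truncated SL tail: last 8 bases of the SL at the read start
        reads = [FastqRead("r1", SL[-8:] + "ACGTACGT")]
        sl, capped, _ = tagcall.classify_reads(reads, SL, 8)
        assert len(sl) == 1 and sl[0].seq == "ACGTACGT"

    def test_empty_read_skipped(self):
        sl, capped, stats = tagcall.classify_reads([FastqRead("r", "")], SL)
        assert stats.n_empty_skipped == 1 and not sl and not capped

    def test_invalid_min_prefix(self):
        with pytest.raises(ValueError):
            tagcall.classify_reads([], SL, 17)

    def test_simulated_reads_fully_recovered(self, small_sim, called_sites):
        truth_cat = dict(zip(small_sim["read_truth"].read_id,
                             small_sim["read_truth"].category))
        assert all(truth_cat[r.read_id] == "SL" for r in called_sites["sl"])
        assert all(truth_cat[r.read_id] == "capped" for r in called_sites["capped"])
        total = called_sites["cstats"].n_sl + called_sites["cstats"].n_capped
        assert total == len(small_sim["reads"])


def brute_force_occurrences(genome: dict[str, str], pattern: str):
    """Independent O(L*m) scan of both strands."""
    fwd, rev = [], []
    rc = revcomp(pattern)
    for chrom, seq in genome.items():
        for i in range(len(seq) - len(pattern) + 1):
            if seq[i: i + len(pattern)] == pattern:
                fwd.append((chrom, i))
            if seq[i: i + len(pattern)] == rc:
                rev.append((chrom, i + len(pattern) - 1))
    return fwd, rev


class TestMapFivePrime:
    def test_forward_read(self, small_sim):
        genome = small_sim["genome"]
        read = FastqRead("r", genome["chr1"][1000:1050])
        aln, stats = tagcall.map_five_prime([read], genome, "capped")
        if stats.n_mapped:  # unique in the random background
            assert aln[0].pos == 1000 and aln[0].strand == "+"

    def test_reverse_read_five_prime_coordinate(self):
        rng = np.random.default_rng(0)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=4000))}
        read = FastqRead("r", revcomp(genome["c"][2000:2050]))
        aln, stats = tagcall.map_five_prime([read], genome, "SL")
        assert stats.n_mapped == 1
        assert (aln[0].pos, aln[0].strand) == (2049, "-")

    def test_multimapper_dropped(self):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), size=40))
        filler = "".join(rng.choice(list("ACGT"), size=500))
        genome = {"c": filler + core + filler[::-1] + core + filler}
        aln, stats = tagcall.map_five_prime([FastqRead("r", core)], genome, "SL")
        assert stats.n_multimapped == 1 and not aln

    def test_unmapped_counted(self):
        genome = {"c": "A" * 1000}
        aln, stats = tagcall.map_five_prime([FastqRead("r", "C" * 30)], genome, "SL")
        assert stats.n_unmapped == 1 and not aln

    def test_matches_brute_force_on_random_reads(self):
        rng = np.random.default_rng(7)
        genome = {f"c{i}": "".join(rng.choice(list("ACGT"), size=3000)) for i in range(2)}
        reads = []
        expected = {}
        for i in range(30):
            chrom = f"c{rng.integers(2)}"
            s = int(rng.integers(0, 3000 - 40))
            seq = genome[chrom][s: s + 40]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(FastqRead(f"r{i}", seq))
        aln, stats = tagcall.map_five_prime(reads, genome, "capped", required_unique=True)
        got = {(a.chrom, a.pos, a.strand): a.count for a in aln}
        # rebuild expectation by brute force
        from collections import Counter
        exp = Counter()
        n_multi = 0
        for r in reads:
            fwd, rev = brute_force_occurrences(genome, r.seq)
            if len(fwd) + len(rev) == 1:
                if fwd:
                    exp[(fwd[0][0], fwd[0][1], "+")] += 1
                else:
                    exp[(rev[0][0], rev[0][1], "-")] += 1
            else:
                n_multi += 1
        assert got == dict(exp)
        assert stats.n_multimapped == n_multi


class TestClusterTags:
    def test_two_positions_one_cluster(self):
        aln = [TagAlignment("c", 100, "+", "SL", 5), TagAlignment("c", 103, "+", "SL", 2)]
        (cl,) = tagcall.cluster_tags(aln, max_gap=50)
        assert (cl.mode_pos, cl.total_tags) == (100, 7)
        assert (cl.interval.start, cl.interval.end) == (100, 104)

    def test_gap_splits_clusters(self):
        aln = [TagAlignment("c", 100, "+", "SL"), TagAlignment("c", 200, "+", "SL")]
        assert len(tagcall.cluster_tags(aln, max_gap=50)) == 2

    def test_mode_tie_breaks_five_prime(self):
        aln = [TagAlignment("c", 10, "+", "SL", 3), TagAlignment("c", 20, "+", "SL", 3)]
        assert tagcall.cluster_tags(aln)[0].mode_pos == 10
        aln = [TagAlignment("c", 10, "-", "SL", 3), TagAlignment("c", 20, "-", "SL", 3)]
        assert tagcall.cluster_tags(aln)[0].mode_pos == 20

    def test_matches_quadratic_chaining_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            positions = sorted(set(rng.integers(0, 2000, size=40).tolist()))
            max_gap = int(rng.integers(1, 100))
            aln = [TagAlignment("c", p, "+", "SL", int(rng.integers(1, 5)))
                   for p in positions]
            clusters = tagcall.cluster_tags(aln, max_gap)
            # O(n^2) single-linkage oracle: two tags share a cluster iff
            # they are connected through steps of <= max_gap
            import networkx as nx
            g = nx.Graph()
            g.add_nodes_from(positions)
            for a in positions:
                for b in positions:
                    if a < b and b - a <= max_gap:
                        g.add_edge(a, b)
            oracle = sorted(tuple(sorted(c)) for c in nx.connected_components(g))
            got = sorted(tuple(sorted(cl.positions)) for cl in clusters)
            assert got == oracle

    def test_input_order_invariance(self):
        rng = np.random.default_rng(12)
        aln = [TagAlignment("c", int(p), "+", "SL", int(c))
               for p, c in zip(rng.integers(0, 500, 30), rng.integers(1, 9, 30))]
        a = tagcall.cluster_tags(aln)
        perm = [aln[i] for i in rng.permutation(len(aln))]
        b = tagcall.cluster_tags(perm)
        assert [(c.interval, c.mode_pos, c.total_tags, c.positions) for c in a] == [
            (c.interval, c.mode_pos, c.total_tags, c.positions) for c in b]


class TestCallTas:
    def _cluster(self, positions, strand="+"):
        lo, hi = min(positions), max(positions)
        counts = {p: c for p, c in positions.items()} if isinstance(positions, dict) else None
        d = positions if isinstance(positions, dict) else {p: 1 for p in positions}
        mode = max(d, key=lambda p: (d[p], -p))
        return TagCluster(Interval("c", min(d), max(d) + 1, strand), "SL",
                          mode, sum(d.values()), d)

    def test_ag_position_kept(self):
        genome = {"c": "TTTTAGCCCC"}
        cl = self._cluster({6: 4})  # upstream dinucleotide genome[4:6] == AG
        sites, stats = tagcall.call_tas([cl], genome)
        assert len(sites) == 1 and sites[0].pos == 6 and sites[0].tag_count == 4

    def test_non_ag_cluster_dropped(self):
        genome = {"c": "TTTTGGCCCC"}
        cl = self._cluster({6: 4})
        sites, stats = tagcall.call_tas([cl], genome)
        assert not sites and stats.n_clusters_dropped == 1

    def test_minus_strand_ag(self):
        # on '-', upstream AG means genomic CT immediately 3' of pos
        genome = {"c": "CCCCCTAAAA"}
        cl = TagCluster(Interval("c", 3, 4, "-"), "SL", 3, 2, {3: 2})
        sites, _ = tagcall.call_tas([cl], genome)
        assert len(sites) == 1 and sites[0].pos == 3

    def test_rejects_capped_clusters(self):
        cl = TagCluster(Interval("c", 3, 4, "+"), "capped", 3, 1, {3: 1})
        with pytest.raises(ValueError):
            tagcall.call_tas([cl], {"c": "A" * 10})


class TestCallTss:
    def test_cluster_in_peak_kept(self):
        cl = TagCluster(Interval("c", 100, 110, "+"), "capped", 100, 5, {100: 5})
        peaks = [BedRecord(Interval("c", 50, 150))]
        assert tagcall.call_tss([cl], peaks) == [cl]

    def test_cluster_outside_peak_rejected(self):
        cl = TagCluster(Interval("c", 300, 310, "+"), "capped", 300, 5, {300: 5})
        peaks = [BedRecord(Interval("c", 50, 150))]
        assert tagcall.call_tss([cl], peaks) == []

    def test_representative_tss_picks_highest_count(self):
        a = TagCluster(Interval("c", 100, 110, "+"), "capped", 100, 5, {100: 5})
        b = TagCluster(Interval("c", 130, 140, "+"), "capped", 130, 9, {130: 9})
        region = Interval("c", 90, 200, "+")
        assert tagcall.representative_tss([a, b], region) is b

    def test_simulation_decoys_all_rejected(self, small_sim, called_sites):
        truth = small_sim["truth"]
        decoy_pos = {(c, p, s) for c, p, s in truth.decoy_tag_sites}
        for cl in called_sites["tss_clusters"]:
            assert (cl.interval.chrom, cl.mode_pos, cl.strand) not in decoy_pos


def test_called_tas_recover_simulated_truth(small_sim, called_sites):
    truth, genome = small_sim["truth"], small_sim["genome"]
    called = {(s.chrom, s.pos, s.strand) for s in called_sites["tas_sites"]}
    ts_genes = [g for g in truth.genes if g.is_ts]
    recovered = sum(1 for g in ts_genes if (g.chrom, g.major_tas, g.strand) in called)
    assert recovered / len(ts_genes) >= 0.95
    for s in called_sites["tas_sites"]:
        assert tagcall.ag_upstream(genome, s.chrom, s.pos, s.strand)
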