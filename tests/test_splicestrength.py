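"""Splice-site models: window extraction, PWM/MEM training, scoring and
group comparison."""

import itertools

import numpy as np
import pytest

from outronscan import splicestrength as ss
from outronscan.geneclass import GeneModel, Transcript
from outronscan.ioformats import Interval, revcomp


def _gene(gid, chrom, strand, exon_pairs, status="non-SL"):
    exons = [Interval(chrom, s, e, strand) for s, e in exon_pairs]
    return GeneModel(gid, chrom, strand,
                     [Transcript(f"{gid}.t", chrom, strand, exons, status)])


class TestExtractSites:
    def test_plus_strand_windows(self):
        rng = np.random.default_rng(0)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=1000))}
        g = _gene("g", "c", "+", [(100, 200), (300, 400)])
        (donor,) = ss.extract_sites([g], genome, "donor")
        (acceptor,) = ss.extract_sites([g], genome, "acceptor")
        assert donor == genome["c"][197:206]  # exon-terminal 3 + intron-initial 6
        assert acceptor == genome["c"][280:303]  # intron-terminal 20 + exon-initial 3

    def test_minus_strand_equals_mirrored_genome(self):
        """Extraction on '-' equals '+' extraction from the reverse-
        complemented genome with mirrored coordinates."""
        rng = np.random.default_rng(1)
        L = 1000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        genome = {"c": seq}
        mirrored = {"c": revcomp(seq)}
        exons = [(100, 200), (300, 400), (500, 600)]
        g_minus = _gene("g", "c", "-", exons)
        mirror_exons = [(L - e, L - s) for s, e in exons][::-1]
        g_plus = _gene("g", "c", "+", mirror_exons)
        for site_type in ("donor", "acceptor"):
            for scope in ("first", "all"):
                got = ss.extract_sites([g_minus], genome, site_type, scope)
                exp = ss.extract_sites([g_plus], mirrored, site_type, scope)
                assert got == exp

    def test_intronless_gene_yields_nothing(self):
        genome = {"c": "A" * 500}
        g = _gene("g", "c", "+", [(100, 200)])
        assert ss.extract_sites([g], genome, "donor") == []

    def test_contig_edge_windows_dropped(self):
        genome = {"c": "A" * 320}
        g = _gene("g", "c", "+", [(0, 2), (300, 320)])  # donor window would start at -1
        assert ss.extract_sites([g], genome, "donor") == []


class TestTrainPwm:
    def test_single_site_zero_pseudocount_indicator(self):
        m = ss.train_pwm(["ACG"], pseudocount=0.0)
        assert np.allclose(m.matrix, [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]])

    def test_large_pseudocount_limits_to_uniform(self):
        m = ss.train_pwm(["AAAA"], pseudocount=1e9)
        assert np.allclose(m.matrix, 0.25, atol=1e-6)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(2)
        sites = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(30)]
        m = ss.train_pwm(sites, pseudocount=0.7)
        assert np.allclose(m.matrix.sum(axis=1), 1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ss.train_pwm(["ACG", "ACGT"])


class TestTrainMem:
    def test_singles_only_equals_pwm(self):
        rng = np.random.default_rng(3)
        sites = ["".join(rng.choice(list("ACGT"), p=[0.4, 0.3, 0.2, 0.1], size=5))
                 for _ in range(100)]
        mem = ss.train_mem(sites, ss.single_position_constraints(5))
        pwm = ss.train_pwm(sites)
        probe = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        for tail in probe[:8]:
            kmer = "ACG" + tail
            assert mem.log2_prob(kmer) == pytest.approx(pwm.log2_prob(kmer), abs=1e-6)

    def test_uniform_sites_give_zero_scores(self):
        sites = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        mem = ss.train_mem(sites, ss.single_position_constraints(2))
        bg = ss.uniform_background(2)
        for k in ("AA", "CG", "TT"):
            assert ss.score_site(mem, bg, k) == pytest.approx(0.0, abs=1e-9)

    def test_pairwise_marginals_matched(self):
        rng = np.random.default_rng(4)
        sites = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(200)]
        constraints = ss.single_position_constraints(5) + [(0, 1), (2, 3)]
        mem = ss.train_mem(sites, constraints, tol=1e-10)
        for c in [(0, 1), (2, 3)]:
            emp = ss._empirical_marginal(sites, c, 0.5)
            assert np.allclose(mem.marginal(c), emp, atol=1e-8)

    def test_matches_direct_constrained_maxent_solve(self):
        """IPF result equals a brute-force constrained maximum-entropy
        optimization on an enumerable toy problem (width 3, one pair
        constraint)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(5)
        sites = ["".join(rng.choice(list("ACGT"), p=[0.5, 0.25, 0.15, 0.1], size=3))
                 for _ in range(60)]
        constraints = ss.single_position_constraints(3) + [(1, 2)]
        mem = ss.train_mem(sites, constraints, tol=1e-12)
        emp = {c: ss._empirical_marginal(sites, c, 0.5) for c in constraints}

        def neg_entropy(q):
            q = np.clip(q, 1e-12, None)
            return float(np.sum(q * np.log(q)))

        cons = [{"type": "eq", "fun": lambda q: q.sum() - 1.0}]
        states = list(itertools.product(range(4), repeat=3))

        def marg_fun(c, vals):
            def f(q, c=c, vals=vals):
                out = []
                for v in vals:
                    mask = [all(st[p] == vi for p, vi in zip(c, v)) for st in states]
                    out.append(q[mask].sum())
                return np.array(out) - np.array(
                    [emp[c][tuple(v)] if len(c) > 1 else emp[c][v[0]] for v in vals])
            return f

        # non-redundant system: the pair (1,2) implies the (1,) and (2,)
        # singles, and each marginal's last category is implied by the sum
        for c in [(0,), (1, 2)]:
            vals = list(itertools.product(range(4), repeat=len(c)))[:-1]
            cons.append({"type": "eq", "fun": marg_fun(c, vals)})
        res = minimize(neg_entropy, np.full(64, 1 / 64), constraints=cons,
                       bounds=[(1e-12, 1.0)] * 64,
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        assert res.success
        assert np.allclose(mem.joint.ravel(), res.x, atol=5e-4)

    def test_nonconvergence_raises(self):
        with pytest.raises((ss.ConvergenceError, ValueError)):
            ss.train_mem(["AA", "CC"], [(0,), (1,)], tol=0.0, max_iter=1)

    def test_constraint_cover_required(self):
        with pytest.raises(ValueError):
            ss.train_mem(["AAA"], [(0,), (1,)])


class TestFactorizedMem:
    def test_block_product_probabilities(self):
        rng = np.random.default_rng(6)
        sites = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(50)]
        model = ss.train_factorized_mem(sites, block_size=2, pseudocount=0.0)
        # log-prob is the sum of block log-probs
        k = sites[0]
        blocks = [(0, 1), (2, 3), (4,)]
        total = 0.0
        for blk, dist in zip(model.blocks, model.dists):
            idx = tuple("ACGT".index(k[p]) for p in blk)
            total += np.log2(dist[idx])
        assert blocks == list(model.blocks)
        assert model.log2_prob(k) == pytest.approx(total)

    def test_acceptor_width_supported(self):
        rng = np.random.default_rng(7)
        sites = ["".join(rng.choice(list("ACGT"), size=23)) for _ in range(40)]
        model = ss.train_factorized_mem(sites)
        assert model.width == 23
        assert np.isfinite(model.log2_prob(sites[0]))


class TestScoring:
    def test_signal_equals_background_zero(self):
        bg = ss.uniform_background(4)
        assert ss.score_site(bg, bg, "ACGT") == 0.0

    def test_half_probability_against_uniform_9mer(self):
        # P_signal = 0.5 vs uniform 0.25^9: log2(0.5 * 4^9) = 17
        joint = np.full((4,) * 9, 0.5 / (4 ** 9 - 1))
        idx = tuple([0] * 9)
        joint[idx] = 0.5
        mem = ss.MemModel(joint, tuple())
        assert ss.score_site(mem, ss.uniform_background(9), "A" * 9) == pytest.approx(17.0)

    def test_planted_strong_vs_weak_ranking(self):
        from outronscan.experiments import sample_sites_from_pwm
        from outronscan.synthdata import DONOR_FIXED_POSITIONS, DONOR_PWM, _weaken

        rng = np.random.default_rng(8)
        strong = sample_sites_from_pwm(DONOR_PWM.matrix, 150, rng)
        weak = sample_sites_from_pwm(
            _weaken(DONOR_PWM.matrix, 0.6, DONOR_FIXED_POSITIONS), 150, rng)
        model = ss.train_pwm(sample_sites_from_pwm(DONOR_PWM.matrix, 300, rng))
        bg = ss.uniform_background(9)
        assert ss.score_sites(model, bg, strong).mean() > ss.score_sites(model, bg, weak).mean()


class TestCompareStrength:
    def test_identical_groups_high_p(self):
        sites = ["ACGTACGTA"] * 5 + ["GGGTAAGTA"] * 5
        model = ss.train_pwm(sites)
        cmp_ = ss.compare_strength(sites, list(sites), model)
        assert cmp_.pvalue > 0.9

    def test_disjoint_supports_match_enumeration(self):
        # group A scores all strictly below group B: one-sided "less"
        # p-value is 1 / C(n+m, n)
        import math
        a = ["AAAA"] * 3
        b = ["CCCC"] * 3
        model = ss.train_pwm(["CCCC"] * 10, pseudocount=0.5)
        cmp_ = ss.compare_strength(a, b, model, alternative="less")
        assert cmp_.pvalue == pytest.approx(1 / math.comb(6, 3))

    def test_too_few_sites_raises(self):
        with pytest.raises(ValueError):
            ss.compare_strength(["AAAA"], ["CCCC", "GGGG"], ss.uniform_background(4))

    def test_batch_fdr_adjustment(self):
        sites = ["ACGT"] * 4
        model = ss.train_pwm(sites)
        c1 = ss.compare_strength(["AAAA"] * 5, ["CCCC"] * 5, model)
        c2 = ss.compare_strength(sites, list(sites), model)
        out = ss.adjust_comparisons([c1, c2])
        assert all(c.fdr is not None and c.fdr >= c.pvalue - 1e-12 for c in out)


def test_score_invariant_to_training_site_order():
    rng = np.random.default_rng(9)
    sites = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(40)]
    m1 = ss.train_pwm(sites)
    m2 = ss.train_pwm(sites[::-1])
    probe = sites[0]
    assert m1.log2_prob(probe) == m2.log2_prob(probe)
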