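"""PWMs, exact p-values, bipartite scanning, Gibbs discovery, terminators."""

import itertools
import math

import numpy as np
import pytest

from txarch.io import GenomeSequence, TxArchError
from txarch.motifs import (PWM, BipartiteDiscoveryParams, BipartiteMotifModel,
                           GibbsParams, assign_sigma, best_hairpin,
                           best_pwm_hit, default_sigma_models,
                           discover_bipartite, estimate_pwm, gibbs_discover,
                           pwm_from_consensus, pwm_pvalue, scan_upstream_genome,
                           scan_window, seq_to_idx, terminator_features)

from conftest import make_annotation, make_site

MODELS = {m.sigma_name: m for m in default_sigma_models()}


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestEstimatePwm:
    def test_pure_counts_no_pseudocount(self):
        pwm = estimate_pwm(["AA", "AA"], pseudocount=0)
        assert pwm.probs[0, 0] == 1.0 and pwm.probs[1, 0] == 1.0

    def test_pseudocount_formula(self):
        pwm = estimate_pwm(["A", "C"], pseudocount=1)
        assert np.allclose(pwm.probs[0],
                           [2 / 6, 2 / 6, 1 / 6, 1 / 6])

    def test_single_site_delta(self):
        pwm = estimate_pwm(["G"], pseudocount=0)
        assert pwm.probs[0, 2] == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(TxArchError, match="equal"):
            estimate_pwm(["AA", "AAA"])


class TestPwmPvalue:
    def test_extreme_scores(self):
        pwm = pwm_from_consensus("TATAAT")
        assert pwm_pvalue(pwm, float("-inf")) == 1.0
        max_score = pwm.log_odds.max(axis=1).sum()
        assert pwm_pvalue(pwm, max_score + 1.0) == 0.0

    def test_width_two_uniform_background_equals_word_fraction(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(4), size=2)
        pwm = PWM(probs=probs)
        for s in [-3.0, -1.0, 0.0, 1.0, 2.0]:
            n_ge = sum(1 for w in itertools.product("ACGT", repeat=2)
                       if pwm.score("".join(w)) >= s)
            assert pwm_pvalue(pwm, s) == pytest.approx(n_ge / 16, abs=1e-6)

    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_enumeration_oracle_within_discretization(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.full(4, 0.7), size=width)
        bg = rng.dirichlet(np.full(4, 10.0))
        pwm = PWM(probs=probs, background=bg)
        words = ["".join(w) for w in itertools.product("ACGT", repeat=width)]
        scores = np.array([pwm.score(w) for w in words])
        pw = np.array([np.prod([bg["ACGT".index(c)] for c in w])
                       for w in words])
        lo = pwm.log_odds
        delta = width * (lo.max(axis=1).sum() - lo.min(axis=1).sum()) / 9999
        for q in np.quantile(scores, [0.05, 0.3, 0.6, 0.9, 0.99]):
            p = pwm_pvalue(pwm, float(q))
            upper = pw[scores >= q - delta].sum()
            lower = pw[scores >= q + delta].sum()
            assert lower - 1e-9 <= p <= upper + 1e-9

    def test_monotone_non_increasing(self):
        pwm = pwm_from_consensus("AGGAGG")
        grid = np.linspace(-20, 15, 50)
        ps = [pwm_pvalue(pwm, float(s)) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_low_resolution_rejected(self):
        with pytest.raises(TxArchError, match="resolution"):
            pwm_pvalue(pwm_from_consensus("ACGT"), 0.0, resolution=5)


class TestScanWindow:
    def test_sigl_consensus_fires_with_spacer_six(self):
        rng = np.random.default_rng(2)
        win = random_seq(rng, 20) + "TGGCA" + random_seq(rng, 6) + "TTGC" \
            + random_seq(rng, 10)
        hit = scan_window(win, MODELS["SigL"])
        assert hit is not None
        assert hit.spacer == 6 and hit.up_start == 20
        assert hit.down_start - (hit.up_start + 5) == 6

    def test_uninformative_window_misses_strict_model(self):
        assert scan_window("A" * 50, MODELS["SigA"]) is None

    def test_equal_placements_report_five_prime_most(self):
        model = MODELS["SigL"]
        core = "TGGCA" + "A" * 6 + "TTGC"
        win = core + "CC" + core + "CC"
        hit = scan_window(win, model)
        assert hit.up_start == 0

    def test_score_invariant_to_flanks(self):
        rng = np.random.default_rng(3)
        core = "TGGCA" + random_seq(rng, 6) + "TTGC"
        h1 = scan_window("A" * 12 + core + "A" * 8, MODELS["SigL"])
        h2 = scan_window("G" * 12 + core + "C" * 8, MODELS["SigL"])
        assert h1.score == pytest.approx(h2.score)

    def test_window_below_minimum_span_returns_none(self):
        assert scan_window("ACGT", MODELS["SigA"]) is None


class TestAssignSigma:
    def test_planted_siga_consensus_recognized(self):
        rng = np.random.default_rng(4)
        core = "TTGACA" + random_seq(rng, 17) + "TATAAT"
        residues = random_seq(rng, 200) + core + random_seq(rng, 9) + \
            random_seq(rng, 300)
        genome = GenomeSequence("g", residues)
        tss_pos = 200 + len(core) + 9 + 1
        site = make_site(tss_pos, site_id="TSS-1")
        hits, props = assign_sigma([site], genome, [MODELS["SigA"]])
        assert [h.sigma_name for h in hits["TSS-1"]] == ["SigA"]

    def test_two_planted_motifs_give_two_hits(self):
        rng = np.random.default_rng(5)
        sigh = "AGGA" + random_seq(rng, 17) + "GAAT"
        siga = "TTGACA" + random_seq(rng, 17) + "TATAAT"
        # both cores need 25+29 nt, so scan a 60-nt promoter window
        window = sigh + siga + random_seq(rng, 60 - len(sigh) - len(siga))
        genome = GenomeSequence("g", random_seq(rng, 100) + window
                                + random_seq(rng, 100))
        site = make_site(161, site_id="TSS-1")
        hits, props = assign_sigma([site], genome,
                                   [MODELS["SigA"], MODELS["SigH"]],
                                   window_len=60)
        assert {h.sigma_name for h in hits["TSS-1"]} == {"SigA", "SigH"}

    def test_random_windows_count_as_no_motif(self):
        rng = np.random.default_rng(6)
        genome = GenomeSequence("g", random_seq(rng, 400))
        sites = [make_site(200, site_id="TSS-1"),
                 make_site(320, site_id="TSS-2")]
        hits, props = assign_sigma(sites, genome, [MODELS["SigA"]])
        assert props["no_motif"] == 1.0


class TestGibbs:
    def test_fixed_seed_bit_reproducible(self):
        rng = np.random.default_rng(7)
        seqs = []
        for _ in range(20):
            s = random_seq(rng, 40)
            off = rng.integers(0, 34)
            seqs.append(s[:off] + "TATAAT" + s[off + 6:])
        p = GibbsParams(width=6, iterations=60, restarts=2, seed=5)
        pwm1, sites1 = gibbs_discover(seqs, p)
        pwm2, sites2 = gibbs_discover(seqs, p)
        assert np.array_equal(pwm1.probs, pwm2.probs) and sites1 == sites2

    def test_random_sequences_yield_low_information(self):
        rng = np.random.default_rng(8)
        seqs = [random_seq(rng, 40) for _ in range(30)]
        pwm, _ = gibbs_discover(seqs, GibbsParams(width=6, iterations=60,
                                                  restarts=2, seed=1))
        planted_ic = pwm_from_consensus("TATAAT", 0.95).information_content()
        assert pwm.information_content() <= planted_ic

    def test_width_longer_than_sequences_rejected(self):
        with pytest.raises(TxArchError, match="width"):
            gibbs_discover(["ACGT"], GibbsParams(width=8))

    def test_fixed_spacer_discovery_concentrates_prior(self):
        rng = np.random.default_rng(9)
        seqs = []
        for _ in range(40):
            s = list(random_seq(rng, 50))
            g = 50 - int(rng.integers(5, 13))
            u = g - 17 - 4
            s[u:u + 4] = "AGGA"
            s[g:g + 4] = "GAAT"
            seqs.append("".join(s))
        model = discover_bipartite(seqs, BipartiteDiscoveryParams(
            gibbs=GibbsParams(iterations=80, restarts=3, seed=3)))
        assert model.spacer_lengths == {17: 1.0}
        assert model.pwm_down.consensus == "GAAT"
        assert model.pwm_up.consensus == "AGGA"

    def test_shuffled_promoters_fail_or_stay_uninformative(self):
        rng = np.random.default_rng(10)
        seqs = [random_seq(rng, 50) for _ in range(40)]
        try:
            model = discover_bipartite(seqs, BipartiteDiscoveryParams(
                gibbs=GibbsParams(iterations=60, restarts=2, seed=2)))
        except TxArchError as e:
            assert "stage" in str(e)
        else:
            planted = pwm_from_consensus("GAAT", 0.95).information_content()
            assert model.pwm_down.information_content() <= planted


class TestUpstreamScan:
    def test_planted_sigh_found_upstream_of_gene(self):
        rng = np.random.default_rng(11)
        core = "AGGA" + random_seq(rng, 17) + "GAAT"
        residues = random_seq(rng, 500) + core + random_seq(rng, 80 - 25) \
            + random_seq(rng, 400)
        genome = GenomeSequence("g", residues)
        ann = make_annotation([("g1", "+", 581, 900)], genome.length)
        hits = scan_upstream_genome(ann, genome, MODELS["SigH"], 200)
        assert (hits["locus_tag"] == "g1").any()

    def test_zero_threshold_reports_nothing(self):
        rng = np.random.default_rng(12)
        genome = GenomeSequence("g", random_seq(rng, 1000))
        ann = make_annotation([("g1", "+", 500, 800)], 1000)
        hits = scan_upstream_genome(ann, genome, MODELS["SigH"], 200,
                                    pvalue_threshold=0.0)
        assert len(hits) == 0

    def test_hit_count_matches_naive_enumeration(self):
        rng = np.random.default_rng(13)
        genome = GenomeSequence("g", random_seq(rng, 5000))
        ann = make_annotation([("g1", "+", 1000, 1500),
                               ("g2", "-", 2000, 2600),
                               ("g3", "+", 4000, 4500)], 5000)
        model = MODELS["SigH"]
        thr = 1e-3
        hits = scan_upstream_genome(ann, genome, model, 200,
                                    pvalue_threshold=thr)
        combined = model.combined_pwm()
        n_naive = 0
        for g in ann:
            if g.strand == "+":
                win = genome.window(g.five_prime - 200, g.five_prime - 1, "+")
            else:
                win = genome.window(g.five_prime + 1, g.five_prime + 200, "-")
            for spacer in model.spacer_lengths:
                span = 4 + spacer + 4
                for i in range(len(win) - span + 1):
                    word = win[i:i + 4] + win[i + 4 + spacer:i + span]
                    if pwm_pvalue(combined, combined.score(word)) <= thr:
                        n_naive += 1
        assert len(hits) == n_naive


def brute_hairpin(window, stem_min=5, loop_range=(3, 10)):
    """Naive enumeration over every (stem_start, stem_len, loop_len)."""
    pair = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
            ("G", "T"): 1, ("T", "G"): 1}
    n = len(window)
    best = 0
    for a in range(n):
        for loop in range(loop_range[0], loop_range[1] + 1):
            for k in range(stem_min, n):
                # 5' stem = window[a-k+1..a], loop, 3' stem pairs outward
                left_end = a
                right_start = a + loop + 1
                if left_end - k + 1 < 0 or right_start + k - 1 >= n:
                    continue
                score = 0
                ok = True
                for t in range(k):
                    p = (window[left_end - t], window[right_start + t])
                    if p not in pair:
                        ok = False
                        break
                    score += pair[p]
                if ok:
                    best = max(best, score)
    return best


class TestTerminatorFeatures:
    def test_u_tract_fraction(self):
        genome = GenomeSequence("g", "ACGT" * 10 + "TTTTTTTT" + "ACGT" * 10)
        feats = terminator_features([make_site(48, site_class="TEP")], genome)
        assert feats[0].u_fraction == 1.0

    def test_planted_gc_stem_scores_twenty_four(self):
        from txarch.io import revcomp
        stem, loop = "CCCCGGCC", "CTAA"
        # flanks chosen so the planted stem cannot extend (C/A vs C/T ends)
        hairpin = "A" + stem + loop + revcomp(stem) + "C"
        residues = "C" * 60 + hairpin + "TTTTTTTT"
        genome = GenomeSequence("g", residues)
        tep = len(residues)
        f = terminator_features([make_site(tep, site_class="TEP")],
                                genome)[0]
        assert (f.stem_len, f.loop_len, f.hairpin_score) == (8, 4, 24)
        assert f.u_fraction == 1.0

    def test_poly_a_window_scores_zero(self):
        genome = GenomeSequence("g", "A" * 120)
        f = terminator_features([make_site(100, site_class="TEP")], genome)[0]
        assert f.hairpin_score == 0 and f.stem_len == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(14)
        for _ in range(15):
            window = random_seq(rng, 60)
            stem, loop, score = best_hairpin(window)
            assert score == brute_hairpin(window)

    def test_truncated_window_flagged(self):
        genome = GenomeSequence("g", "ACGT" * 30)
        f = terminator_features([make_site(5, site_class="TEP")], genome)[0]
        assert f.truncated
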