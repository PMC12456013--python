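"""Positional classification: rule examples, brute-force oracle, symmetry."""

import numpy as np
import pytest

from txarch.classify import (ClassificationParams, category_counts,
                             classify_tep, classify_tss, composition,
                             rbs_scan, utr_stats)
from txarch.io import GeneModel, GenomeAnnotation, GenomeSequence, revcomp
from txarch.motifs import default_rbs_pwm

from conftest import make_annotation, make_site

PARAMS = ClassificationParams()


# ---------------------------------------------------------------------------
# independent brute-force classifier (naive re-statement of the category
# definitions, used as the oracle)
# ---------------------------------------------------------------------------

def _ps_window(gene, pos, which):
    if which == "TSS":
        fp = gene.five_prime
        lo, hi = ((fp - 300, fp + 100) if gene.strand == "+"
                  else (fp - 100, fp + 300))
    else:
        tp = gene.three_prime
        lo, hi = ((tp, tp + 300) if gene.strand == "+"
                  else (tp - 300, tp))
    return lo <= pos <= hi


def _anchor(gene, which):
    return gene.five_prime if which == "TSS" else gene.three_prime


def brute_classify(sites, genes, which, primary_tss=None):
    """Returns list of (category, gene_tag_or_None, utr_or_None)."""
    owner = {}
    for i, s in enumerate(sites):
        cands = [g for g in genes
                 if g.strand == s.strand and _ps_window(g, s.position, which)]
        if cands:
            owner[i] = min(cands, key=lambda g: (abs(_anchor(g, which)
                                                     - s.position), g.start))
    results: dict[int, tuple] = {}
    for g in genes:
        idxs = [i for i, og in owner.items() if og is g]
        if not idxs:
            continue
        def height(i):
            return max(sites[i].per_condition_height.values())
        def five_most(i):
            p = sites[i].position
            return p if g.strand == "+" else -p
        prim = min(idxs, key=lambda i: (-height(i),
                                        abs(_anchor(g, which)
                                            - sites[i].position),
                                        five_most(i)))
        for i in idxs:
            if which == "TSS":
                d = (g.five_prime - sites[i].position if g.strand == "+"
                     else sites[i].position - g.five_prime)
            else:
                d = (sites[i].position - g.three_prime if g.strand == "+"
                     else g.three_prime - sites[i].position)
            results[i] = ("P" if i == prim else "S", g.locus_tag, max(d, 0))
    for i, s in enumerate(sites):
        if i in results:
            continue
        if which == "TEP" and primary_tss:
            c_best = None
            for g in genes:
                if g.strand != s.strand or g.locus_tag not in primary_tss:
                    continue
                t = primary_tss[g.locus_tag]
                if g.strand == "+":
                    ok = t < s.position < g.five_prime
                else:
                    ok = g.five_prime < s.position < t
                if ok:
                    key = (abs(g.five_prime - s.position), g.start)
                    if c_best is None or key < c_best[0]:
                        c_best = (key, g)
            if c_best is not None:
                results[i] = ("C", c_best[1].locus_tag, None)
                continue
        if any(g.strand == s.strand and g.start <= s.position <= g.end
               for g in genes):
            results[i] = ("I", None, None)
        elif any(g.strand != s.strand
                 and g.start - 100 <= s.position <= g.end + 100
                 for g in genes):
            results[i] = ("A", None, None)
        else:
            results[i] = ("N", None, None)
    return [results[i] for i in range(len(sites))]


def random_layout(rng, genome_len=10_000, which="TSS"):
    genes = []
    cursor = 1
    for k in range(rng.integers(2, 6)):
        gap = int(rng.integers(150, 900))
        length = int(rng.integers(150, 800))
        start = cursor + gap
        if start + length > genome_len - 50:
            break
        genes.append((f"g{k}", "+" if rng.random() < 0.5 else "-",
                      start, start + length - 1))
        cursor = start + length
    ann = make_annotation(genes, genome_len)
    sites = [make_site(int(p), "+" if rng.random() < 0.5 else "-",
                       float(rng.integers(1, 6)),
                       site_class=which, site_id=f"{which}-{j}")
             for j, p in enumerate(rng.integers(1, genome_len + 1,
                                                rng.integers(5, 15)))]
    return ann, sites


def assert_matches_oracle(ann, sites, which, primary_tss=None,
                          tss_annotated=None):
    genes = list(ann)
    expected = brute_classify(sites, genes, which, primary_tss)
    if which == "TSS":
        got = classify_tss(sites, ann, GenomeSequence("g", "A" * 10_000),
                           PARAMS)
    else:
        got = classify_tep(sites, ann, tss_annotated or [], PARAMS)
    for a, (cat, gene, utr) in zip(got, expected):
        assert a.category == cat, (a, cat, gene)
        if cat in ("P", "S", "C"):
            assert a.gene == gene
        if cat in ("P", "S"):
            assert a.utr_len == utr


class TestRuleExamples:
    def test_sole_upstream_tss_is_primary(self):
        ann = make_annotation([("g1", "+", 500, 900)], 2000)
        got = classify_tss([make_site(450)], ann,
                           GenomeSequence("g", "A" * 2000), PARAMS)
        assert (got[0].category, got[0].gene, got[0].utr_len) == \
            ("P", "g1", 50)

    def test_higher_site_is_primary_other_secondary(self):
        ann = make_annotation([("g1", "+", 500, 900)], 2000)
        sites = [make_site(400, height=10), make_site(450, height=40)]
        got = classify_tss(sites, ann, GenomeSequence("g", "A" * 2000),
                           PARAMS)
        assert [a.category for a in got] == ["S", "P"]

    def test_tss_inside_gene_body_opposite_strand_is_antisense(self):
        ann = make_annotation([("g1", "+", 500, 900)], 2000)
        got = classify_tss([make_site(700, strand="-")], ann,
                           GenomeSequence("g", "A" * 2000), PARAMS)
        assert got[0].category == "A"

    def test_downstream_tss_utr_clamped_to_zero(self):
        ann = make_annotation([("g1", "+", 500, 900)], 2000)
        got = classify_tss([make_site(530)], ann,
                           GenomeSequence("g", "A" * 2000), PARAMS)
        assert (got[0].category, got[0].utr_len) == ("P", 0)

    def test_sole_downstream_tep_is_primary_with_utr(self):
        ann = make_annotation([("g1", "+", 500, 900)], 3000)
        got = classify_tep([make_site(960, site_class="TEP")], ann, [],
                           PARAMS)
        assert (got[0].category, got[0].gene, got[0].utr_len) == \
            ("P", "g1", 60)

    def test_tep_inside_five_prime_utr_is_cis_regulatory(self):
        ann = make_annotation([("g1", "+", 500, 900)], 3000)
        genome = GenomeSequence("g", "A" * 3000)
        tss_ann = classify_tss([make_site(380)], ann, genome, PARAMS)
        got = classify_tep([make_site(450, site_class="TEP")], ann, tss_ann,
                           PARAMS)
        assert (got[0].category, got[0].gene) == ("C", "g1")

    def test_far_tep_is_intergenic(self):
        ann = make_annotation([("g1", "+", 500, 900)], 20_000)
        got = classify_tep([make_site(12_000, site_class="TEP")], ann, [],
                           PARAMS)
        assert got[0].category == "N"

    def test_category_counts_partition_sites(self):
        rng = np.random.default_rng(8)
        ann, sites = random_layout(rng)
        got = classify_tss(sites, ann, GenomeSequence("g", "A" * 10_000),
                           PARAMS)
        assert sum(category_counts(got).values()) == len(sites)


class TestOracleEquivalence:
    def test_randomized_layouts_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            ann, sites = random_layout(rng, which="TSS")
            assert_matches_oracle(ann, sites, "TSS")

    def test_tep_layouts_with_cis_regulatory(self):
        rng = np.random.default_rng(43)
        genome = GenomeSequence("g", "A" * 10_000)
        for _ in range(100):
            ann, tss_sites = random_layout(rng, which="TSS")
            tss_ann = classify_tss(tss_sites, ann, genome, PARAMS)
            primary = {a.gene: a.site.position for a in tss_ann
                       if a.category == "P"}
            _, tep_sites = random_layout(rng, which="TEP")
            assert_matches_oracle(ann, tep_sites, "TEP", primary_tss=primary,
                                  tss_annotated=tss_ann)


def mirror_case(ann, sites, genome_len=10_000):
    flip = lambda s: "-" if s == "+" else "+"
    genes_m = [GeneModel(g.locus_tag, g.feature_type, flip(g.strand),
                         genome_len + 1 - g.end, genome_len + 1 - g.start)
               for g in ann]
    sites_m = [make_site(genome_len + 1 - s.position, flip(s.strand),
                         max(s.per_condition_height.values()),
                         site_class=s.site_class, site_id=s.site_id)
               for s in sites]
    return GenomeAnnotation(genes_m, genome_len), sites_m


def has_distance_tie(ann, sites, which):
    for s in sites:
        dists = sorted(abs(_anchor(g, which) - s.position) for g in ann
                       if g.strand == s.strand and _ps_window(g, s.position,
                                                              which))
        if len(dists) >= 2 and dists[0] == dists[1]:
            return True
    return False


class TestMirrorSymmetry:
    def test_categories_and_utrs_mirror(self, uniform_genome):
        rng = np.random.default_rng(77)
        genome_rc = GenomeSequence("toy_rc", revcomp(uniform_genome.residues))
        n_run = 0
        for _ in range(60):
            ann, sites = random_layout(rng)
            # asymmetric coordinate tie-breaks only matter for exact
            # distance ties; skip those rare layouts
            if has_distance_tie(ann, sites, "TSS"):
                continue
            n_run += 1
            fwd = classify_tss(sites, ann, uniform_genome, PARAMS)
            ann_m, sites_m = mirror_case(ann, sites)
            rev = classify_tss(sites_m, ann_m, genome_rc, PARAMS)
            for a, b in zip(fwd, rev):
                assert (a.category, a.gene, a.utr_len) == \
                    (b.category, b.gene, b.utr_len)
        assert n_run >= 30


class TestSummaries:
    def test_median_of_single_and_three(self):
        def summary(utrs):
            # distinct genes so every site is primary
            genes = [(f"g{u}", "+", 500 + 1000 * i, 900 + 1000 * i)
                     for i, u in enumerate(utrs)]
            ann = make_annotation(genes, 100_000)
            sites = [make_site(500 + 1000 * i - u, site_id=f"s{u}",
                               height=10)
                     for i, u in enumerate(utrs)]
            g = GenomeSequence("g", "A" * 100_000)
            return utr_stats(classify_tss(sites, ann, g, PARAMS), PARAMS)

        assert summary([45])["TSS"].median == 45
        assert summary([20, 45, 64])["TSS"].median == 45

    def test_leaderless_threshold(self):
        genes = [("gA", "+", 500, 900), ("gB", "+", 5000, 5400)]
        ann = make_annotation(genes, 10_000)
        g = GenomeSequence("g", "A" * 10_000)
        sites = [make_site(495), make_site(4955, site_id="x")]  # utr 5 and 45
        out = utr_stats(classify_tss(sites, ann, g, PARAMS), PARAMS)
        assert out["TSS"].leaderless_count == 1
        assert out["TSS"].histogram == {"0-9": 1, "40-49": 1}


class TestComposition:
    def test_plus_strand_indexing(self):
        genome = GenomeSequence("g", "AACGT")
        t = composition([make_site(3)], genome)
        # offsets -2,-1 are A,A; +1 is the TSS base C; +2 is G
        assert t.table.loc[1, "C"] == 1.0
        assert t.table.loc[-1, "A"] == 1.0
        assert t.table.loc[2, "G"] == 1.0

    def test_minus_strand_complements(self):
        genome = GenomeSequence("g", "AACGT")
        t = composition([make_site(3, strand="-")], genome)
        assert t.table.loc[1, "G"] == 1.0  # complement of C
        assert t.table.loc[-1, "C"] == 1.0  # complement of G at pos 4

    def test_frequencies_average_over_sites(self):
        genome = GenomeSequence("g", "TTATTTGTT")
        t = composition([make_site(3), make_site(7)], genome)  # +1 bases A, G
        assert t.table.loc[1, "A"] == 0.5 and t.table.loc[1, "G"] == 0.5
        assert np.allclose(t.table.sum(axis=1), 1.0)

    def test_edge_sites_skipped(self):
        genome = GenomeSequence("g", "ACGTACGT")
        t = composition([make_site(1), make_site(4)], genome)
        assert t.n_skipped == 1 and t.n_used == 1


class TestRbsScan:
    def _setup(self, upstream_seq):
        # gene starts at 501; upstream_seq becomes positions 481..500
        assert len(upstream_seq) == 20
        genome = GenomeSequence("g", "A" * 480 + upstream_seq + "C" * 520)
        ann = make_annotation([("g1", "+", 501, 900)], genome.length)
        tss_ann = classify_tss([make_site(456)], ann, genome, PARAMS)
        return genome, ann, tss_ann

    def test_exact_consensus_hits(self):
        genome, ann, tss_ann = self._setup("CCCCCCCAGGAGGCCCCCCC")
        frac, df = rbs_scan(tss_ann, ann, genome, default_rbs_pwm(), PARAMS)
        assert frac == 1.0 and bool(df["hit"].all())

    def test_all_c_upstream_misses(self):
        genome, ann, tss_ann = self._setup("C" * 20)
        frac, df = rbs_scan(tss_ann, ann, genome, default_rbs_pwm(), PARAMS)
        assert frac == 0.0

    def test_fraction_counts_hits_over_leadered(self):
        g1 = "C" * 480 + "CCCCCCCAGGAGGCCCCCCC"
        genome = GenomeSequence("g", g1 + "A" * 500 + "C" * 20 + "G" * 1000)
        ann = make_annotation([("gHit", "+", 501, 700),
                               ("gMiss", "+", 1021, 1400)], genome.length)
        sites = [make_site(456), make_site(976, site_id="t2")]
        tss_ann = classify_tss(sites, ann, genome, PARAMS)
        frac, df = rbs_scan(tss_ann, ann, genome, default_rbs_pwm(), PARAMS)
        assert frac == 0.5
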