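"""Positional classification of merged sites relative to the annotation.

TSS categories follow the usual dRNA-seq scheme: primary (P) and secondary
(S) for sites in the promoter window of a gene, internal (I) inside a gene
body on the sense strand, antisense (A) on the opposite strand of a gene
body or its flanks, and intergenic (N) otherwise.  TEPs use the same scheme
plus a cis-regulatory (C) category for 3' ends that fall inside a gene's
5'-UTR (e.g. riboswitch-mediated premature termination).  Precedence is
P/S > (C) > I > A > N and every site receives exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, GeneModel, GenomeSequence, TxArchError
from .peaks import MergedSite


@dataclass(frozen=True)
class ClassificationParams:
    """Window sizes (nt) for positional classification.

    The promoter window for P/S TSSs runs from ``tss_upstream_nt`` upstream
    to ``tss_downstream_nt`` downstream of a gene's 5' end; P/S TEPs lie
    within ``tep_downstream_nt`` of a gene's 3' end.  A 5'-UTR of at most
    ``leaderless_max_utr_nt`` marks a leaderless transcript.
    """

    tss_upstream_nt: int = 300
    tss_downstream_nt: int = 100
    tep_downstream_nt: int = 300
    antisense_flank_nt: int = 100
    leaderless_max_utr_nt: int = 10
    rbs_search_nt: int = 20
    rbs_pvalue_threshold: float = 1e-3


@dataclass(frozen=True)
class AnnotatedSite:
    site: MergedSite
    category: str  # P, S, I, A, N, C
    gene: str | None = None
    utr_len: int | None = None


def _site_height(site: MergedSite) -> float:
    return max(site.per_condition_height.values())


def _in_ps_window_tss(pos: int, gene: GeneModel, params: ClassificationParams
                      ) -> bool:
    fp = gene.five_prime
    if gene.strand == "+":
        return fp - params.tss_upstream_nt <= pos <= fp + params.tss_downstream_nt
    return fp - params.tss_downstream_nt <= pos <= fp + params.tss_upstream_nt


def _in_ps_window_tep(pos: int, gene: GeneModel, params: ClassificationParams
                      ) -> bool:
    tp = gene.three_prime
    if gene.strand == "+":
        return tp <= pos <= tp + params.tep_downstream_nt
    return tp - params.tep_downstream_nt <= pos <= tp


def _tss_utr_len(pos: int, gene: GeneModel) -> int:
    d = gene.five_prime - pos if gene.strand == "+" else pos - gene.five_prime
    return max(d, 0)


def _tep_utr_len(pos: int, gene: GeneModel) -> int:
    d = pos - gene.three_prime if gene.strand == "+" else gene.three_prime - pos
    return max(d, 0)


def _fallback_category(site: MergedSite, annotation: GenomeAnnotation,
                       params: ClassificationParams) -> str:
    """I/A/N assignment for sites outside any P/S (or C) window."""
    pos = site.position
    sense = annotation.overlapping(pos, pos, site.strand)
    if sense:
        return "I"
    anti_strand = "-" if site.strand == "+" else "+"
    flank = params.antisense_flank_nt
    anti = annotation.overlapping(pos - flank, pos + flank, anti_strand)
    if anti:
        return "A"
    return "N"


def _assign_ps(sites: Sequence[MergedSite], annotation: GenomeAnnotation,
               params: ClassificationParams, which: str
               ) -> dict[int, tuple[str, GeneModel]]:
    """Map site index -> (P or S, gene) for sites inside a P/S window.

    A site inside two genes' windows goes to the gene with the nearest 5'
    (TSS) or 3' (TEP) end; per gene, the highest site is P, the rest S
    (ties: closest to the gene end, then 5'-most).
    """
    in_window = _in_ps_window_tss if which == "TSS" else _in_ps_window_tep
    anchor = ((lambda g: g.five_prime) if which == "TSS"
              else (lambda g: g.three_prime))
    per_gene: dict[str, list[int]] = {}
    gene_of: dict[int, GeneModel] = {}
    for i, s in enumerate(sites):
        cands = [g for g in annotation
                 if g.strand == s.strand and in_window(s.position, g, params)]
        if not cands:
            continue
        best = min(cands, key=lambda g: (abs(anchor(g) - s.position), g.start))
        gene_of[i] = best
        per_gene.setdefault(best.locus_tag, []).append(i)
    out: dict[int, tuple[str, GeneModel]] = {}
    for tag, idxs in per_gene.items():
        gene = annotation.get(tag)
        five_most = (lambda i: sites[i].position) if gene.strand == "+" else \
                    (lambda i: -sites[i].position)
        primary = min(idxs, key=lambda i: (-_site_height(sites[i]),
                                           abs(anchor(gene) - sites[i].position),
                                           five_most(i)))
        for i in idxs:
            out[i] = ("P" if i == primary else "S", gene)
    return out


def classify_tss(sites: Sequence[MergedSite], annotation: GenomeAnnotation,
                 genome: GenomeSequence,
                 params: ClassificationParams = ClassificationParams()
                 ) -> list[AnnotatedSite]:
    """Assign P/S/I/A/N categories and 5'-UTR lengths to merged TSSs."""
    if any(s.site_class != "TSS" for s in sites):
        raise TxArchError("classify_tss requires TSS-class sites")
    ps = _assign_ps(sites, annotation, params, "TSS")
    out = []
    for i, s in enumerate(sites):
        if i in ps:
            cat, gene = ps[i]
            out.append(AnnotatedSite(site=s, category=cat, gene=gene.locus_tag,
                                     utr_len=_tss_utr_len(s.position, gene)))
        else:
            out.append(AnnotatedSite(site=s,
                                     category=_fallback_category(s, annotation,
                                                                 params)))
    return out


def classify_tep(sites: Sequence[MergedSite], annotation: GenomeAnnotation,
                 tss_annotated: Sequence[AnnotatedSite],
                 params: ClassificationParams = ClassificationParams()
                 ) -> list[AnnotatedSite]:
    """Assign P/S/C/I/A/N categories and 3'-UTR lengths to merged TEPs.

    The cis-regulatory (C) category needs the primary TSS of each gene
    (from ``tss_annotated``): a TEP strictly between a gene's primary TSS
    and its 5' end, on the sense strand, terminates within the 5'-UTR.
    """
    if any(s.site_class != "TEP" for s in sites):
        raise TxArchError("classify_tep requires TEP-class sites")
    primary_tss: dict[str, int] = {
        a.gene: a.site.position for a in tss_annotated
        if a.category == "P" and a.gene is not None}
    ps = _assign_ps(sites, annotation, params, "TEP")
    out = []
    for i, s in enumerate(sites):
        if i in ps:
            cat, gene = ps[i]
            out.append(AnnotatedSite(site=s, category=cat, gene=gene.locus_tag,
                                     utr_len=_tep_utr_len(s.position, gene)))
            continue
        c_gene = _cis_regulatory_gene(s, annotation, primary_tss)
        if c_gene is not None:
            out.append(AnnotatedSite(site=s, category="C",
                                     gene=c_gene.locus_tag))
            continue
        out.append(AnnotatedSite(site=s,
                                 category=_fallback_category(s, annotation,
                                                             params)))
    return out


def _cis_regulatory_gene(site: MergedSite, annotation: GenomeAnnotation,
                         primary_tss: Mapping[str, int]) -> GeneModel | None:
    pos = site.position
    best: GeneModel | None = None
    for g in annotation:
        if g.strand != site.strand or g.locus_tag not in primary_tss:
            continue
        tss = primary_tss[g.locus_tag]
        if g.strand == "+":
            inside = tss < pos < g.five_prime
        else:
            inside = g.five_prime < pos < tss
        if inside and (best is None or
                       (abs(g.five_prime - pos), g.start) <
                       (abs(best.five_prime - pos), best.start)):
            best = g
    return best


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UTRSummary:
    site_class: str
    n: int
    median: float | None
    histogram: Mapping[str, int]  # "0-9", "10-19", ...
    leaderless_count: int | None  # TSS only


def utr_stats(annotated_sites: Sequence[AnnotatedSite],
              params: ClassificationParams = ClassificationParams()
              ) -> dict[str, UTRSummary]:
    """Median, 10-nt-binned histogram and leaderless count of UTR lengths.

    Operates on primary (P) sites only; returns one summary per site class
    present in the input.  Leaderless transcripts are those with a 5'-UTR of
    at most ``leaderless_max_utr_nt``.
    """
    out: dict[str, UTRSummary] = {}
    for cls in ("TSS", "TEP"):
        lens = [a.utr_len for a in annotated_sites
                if a.site.site_class == cls and a.category == "P"
                and a.utr_len is not None]
        if not lens:
            continue
        arr = np.array(lens)
        hist: dict[str, int] = {}
        for lo in range(0, int(arr.max()) + 10, 10):
            c = int(((arr >= lo) & (arr < lo + 10)).sum())
            if c:
                hist[f"{lo}-{lo + 9}"] = c
        leaderless = (int((arr <= params.leaderless_max_utr_nt).sum())
                      if cls == "TSS" else None)
        out[cls] = UTRSummary(site_class=cls, n=len(arr),
                              median=float(np.median(arr)), histogram=hist,
                              leaderless_count=leaderless)
    return out


@dataclass(frozen=True)
class CompositionTable:
    """Base frequencies at offsets around the +1 (TSS) position.

    Offsets follow promoter numbering (no zero): -2, -1, +1, +2, where +1 is
    the TSS base itself.  Each row sums to 1; sites whose window crosses a
    genome end are skipped and counted in ``n_skipped``.
    """

    table: pd.DataFrame  # index: offsets, columns: A,C,G,T
    n_used: int
    n_skipped: int


_OFFSETS = (-2, -1, 1, 2)


def composition(sites: Sequence[MergedSite], genome: GenomeSequence
                ) -> CompositionTable:
    """Strand-aware nucleotide composition at the -2..+2 positions."""
    if not sites:
        raise TxArchError("composition requires at least one site")
    counts = {o: {b: 0 for b in "ACGT"} for o in _OFFSETS}
    used = skipped = 0
    for s in sites:
        bases = {}
        ok = True
        for o in _OFFSETS:
            step = o if o < 0 else o - 1  # +1 is the site position itself
            gpos = s.position + step if s.strand == "+" else s.position - step
            if not (1 <= gpos <= genome.length):
                ok = False
                break
            b = genome.residues[gpos - 1]
            if s.strand == "-":
                b = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(b, "N")
            if b == "N":
                ok = False
                break
            bases[o] = b
        if not ok:
            skipped += 1
            continue
        used += 1
        for o, b in bases.items():
            counts[o][b] += 1
    rows = {o: {b: counts[o][b] / max(used, 1) for b in "ACGT"}
            for o in _OFFSETS}
    table = pd.DataFrame.from_dict(rows, orient="index")[list("ACGT")]
    return CompositionTable(table=table, n_used=used, n_skipped=skipped)


def rbs_scan(tss_annotated: Sequence[AnnotatedSite],
             annotation: GenomeAnnotation, genome: GenomeSequence,
             rbs_pwm, params: ClassificationParams = ClassificationParams()
             ) -> tuple[float, pd.DataFrame]:
    """Fraction of leadered transcripts with a ribosome-binding-site hit.

    For each leadered P/S transcript (5'-UTR >= 10 nt) the
    ``rbs_search_nt`` nt upstream of the start codon are scanned with the
    AG-rich RBS weight matrix; a hit is a placement whose exact p-value is at
    most ``rbs_pvalue_threshold``.
    """
    from .motifs import best_pwm_hit  # deferred import (motifs uses io only)

    rows = []
    for a in tss_annotated:
        if a.category not in ("P", "S") or a.utr_len is None:
            continue
        if a.utr_len < 10:
            continue
        gene = annotation.get(a.gene)
        fp = gene.five_prime
        if gene.strand == "+":
            window = genome.window(fp - params.rbs_search_nt, fp - 1, "+")
        else:
            window = genome.window(fp + 1, fp + params.rbs_search_nt, "-")
        if len(window) < rbs_pwm.width:
            continue
        score, pval, offset = best_pwm_hit(window, rbs_pwm)
        rows.append({"site_id": a.site.site_id, "gene": a.gene,
                     "best_score": score, "pvalue": pval, "offset": offset,
                     "hit": pval <= params.rbs_pvalue_threshold})
    df = pd.DataFrame(rows, columns=["site_id", "gene", "best_score",
                                     "pvalue", "offset", "hit"])
    frac = float(df["hit"].mean()) if len(df) else float("nan")
    return frac, df


def category_counts(annotated: Sequence[AnnotatedSite]) -> dict[str, int]:
    """Counts per category; values always sum to the number of sites."""
    out: dict[str, int] = {}
    for a in annotated:
        out[a.category] = out.get(a.category, 0) + 1
    return out
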