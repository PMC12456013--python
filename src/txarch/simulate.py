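"""Synthetic transcriptome-architecture data with planted ground truth.

The generator emulates the track structure the pipeline consumes: sharp
TEX-enriched 5'-end peaks at true TSSs, TEX-depleted processed 5' ends,
3'-end peaks at intrinsic terminators, plateau RNA-seq coverage across each
transcription unit, replicate noise and Poisson background.  Every gene gets
a planted sigma-factor promoter (site sequences sampled from the model
PWMs), a 5'-UTR drawn from a mixture with a 20-29 nt mode and 45 nt median,
an AG-rich RBS shortly upstream of the start codon, a 3'-UTR with 64 nt
median, and a stem-loop + U-tract terminator ending at the TEP.

All randomness flows from a single seeded generator with a fixed draw order
(genome -> gene placement -> planted elements -> heights -> noise), so
outputs are byte-identical for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (GeneModel, GenomeAnnotation, GenomeSequence, LibraryMeta,
                 StrandedSignal, TxArchError, revcomp, write_annotation_gff3,
                 write_genome_fasta, write_library_table,
                 write_signal_bedgraph)
from .motifs import BipartiteMotifModel, default_sigma_models, pwm_pvalue

BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic dataset.

    Heights are negative-binomial raw read counts (``tss_height_mean`` with
    dispersion/size ``tss_height_dispersion``); ``total_mapped_reads`` fixes
    the count->RPM scale (one read = 0.2 RPM at the default 5e6).
    """

    genome_len: int = 100_000
    n_genes: int = 80
    gc_content: float = 0.474
    gene_len_range: tuple[int, int] = (200, 700)
    frac_sigA: float = 0.75
    frac_sigH: float = 0.25
    tss_height_mean: float = 50.0
    tss_height_dispersion: float = 10.0
    tex_enrichment: float = 5.0
    processed_site_rate: float = 0.2      # per kb
    background_rate_per_nt: float = 0.05  # Poisson, per position per strand
    jitter_sd: float = 0.5                # nt of positional smear
    abundance_lognorm_sd: float = 0.8     # per-gene intensity spread (log-scale)
    n_replicates: int = 2
    n_conditions: int = 2
    condition_specific_fraction: float = 0.3
    tu_coverage_rpm: float = 15.0
    total_mapped_reads: int = 5_000_000
    utr5_target_median: int = 45
    utr3_target_median: int = 64
    seed: int = 7

    def __post_init__(self) -> None:
        for f in (self.gc_content, self.frac_sigA, self.frac_sigH,
                  self.condition_specific_fraction):
            if not (0 <= f <= 1):
                raise TxArchError("fractions must be in [0, 1]")
        if self.genome_len < 10 * self.gene_len_range[1]:
            raise TxArchError("genome_len must exceed 10x the max gene length")

    @property
    def conditions(self) -> tuple[str, ...]:
        names = ("CO2", "betaine", "formate", "methanol")
        return names[: self.n_conditions]


@dataclass
class GroundTruth:
    """Planted sites, units and motif instances (positions 1-based)."""

    tss: pd.DataFrame        # position, strand, gene, conditions, sigma
    tep: pd.DataFrame        # position, strand, gene, conditions
    tus: pd.DataFrame        # tss_position, tep_position, strand, gene, conditions
    motifs: pd.DataFrame     # gene, sigma, spacer
    rbs: pd.DataFrame        # gene, gap_nt
    processed: pd.DataFrame  # position, strand
    genome_id: str = "synthetic"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("tss", "tep", "tus", "motifs", "rbs", "processed"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                       index=False)


@dataclass
class SyntheticDataset:
    genome: GenomeSequence
    annotation: GenomeAnnotation
    signals: list[StrandedSignal]
    truth: GroundTruth
    config: SyntheticConfig

    def signals_for(self, condition: str, role: str,
                    tex_status: str | None = None) -> list[StrandedSignal]:
        out = [s for s in self.signals
               if s.meta.condition == condition and s.meta.role == role
               and (tex_status is None or s.meta.tex_status == tex_status)]
        return sorted(out, key=lambda s: s.meta.replicate)

    def write(self, outdir: str | Path) -> None:
        """Emit genome.fa, genes.gff3, signals/*.bedgraph, truth/, libraries.tsv."""
        outdir = Path(outdir)
        (outdir / "signals").mkdir(parents=True, exist_ok=True)
        write_genome_fasta(self.genome, outdir / "genome.fa")
        write_annotation_gff3(self.annotation, outdir / "genes.gff3",
                              seq_id=self.genome.seq_id)
        write_library_table([s.meta for s in self.signals],
                            outdir / "libraries.tsv")
        for s in self.signals:
            base = outdir / "signals" / s.meta.library_id
            write_signal_bedgraph(s, f"{base}.plus.bedgraph",
                                  f"{base}.minus.bedgraph", self.genome.seq_id)
        self.truth.write(outdir / "truth")


# ---------------------------------------------------------------------------
# UTR-length samplers (targets: 5'-UTR mode 20-29 nt / median 45 nt;
# 3'-UTR median 64 nt, bulk in the 40s-60s)
# ---------------------------------------------------------------------------

def sample_utr5(rng: np.random.Generator, size: int | None = None):
    """Mixture 0.4 * Uniform{20..29} + 0.6 * Uniform{30..121}; the discrete
    median is exactly 45 nt and the modal 10-nt bin is 20-29."""
    n = size or 1
    pick = rng.random(n) < 0.4
    short = rng.integers(20, 30, n)
    long = rng.integers(30, 122, n)
    out = np.where(pick, short, long)
    return out if size is not None else int(out[0])


def sample_utr3(rng: np.random.Generator, size: int | None = None):
    """Shifted gamma (shape 2.5, scale 20.3, shift 20) rounded, clipped to
    [30, 250]; median ~64 nt.  The lower clip reserves room for the planted
    terminator and only moves values already below the median."""
    n = size or 1
    draw = np.round(20 + rng.gamma(2.5, 20.3, n)).astype(int)
    out = np.clip(draw, 30, 250)
    return out if size is not None else int(out[0])


def _sample_pwm_site(rng: np.random.Generator, pwm) -> str:
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm.probs)


def _sample_promoter_site(rng: np.random.Generator,
                          model: "BipartiteMotifModel",
                          max_tries: int = 50) -> tuple[str, str]:
    """Sample -35/-10 block sequences from the model PWMs, rejecting draws
    whose own-model block score is not scanner-detectable.

    Annotated motif instances in real studies are by definition the ones the
    scanner finds; planting only detectable instances mirrors that selection.
    Rejection uses half the model's p-value threshold as margin (scanning
    later re-estimates the background from the promoter windows).
    """
    combined = model.combined_pwm()
    for _ in range(max_tries):
        up = _sample_pwm_site(rng, model.pwm_up)
        down = _sample_pwm_site(rng, model.pwm_down)
        score = model.pwm_up.score(up) + model.pwm_down.score(down)
        if pwm_pvalue(combined, score) <= 0.5 * model.pvalue_threshold:
            return up, down
    return model.pwm_up.consensus, model.pwm_down.consensus


def _jitter_offsets(rng: np.random.Generator, count: int, sd: float
                    ) -> np.ndarray:
    """Multinomial split of *count* reads over offsets -2..+2 with weights
    from a discretized normal of width *sd*."""
    if sd <= 0 or count <= 0:
        out = np.zeros(5, dtype=int)
        out[2] = max(count, 0)
        return out
    offs = np.arange(-2, 3)
    w = np.exp(-0.5 * (offs / sd) ** 2)
    return rng.multinomial(count, w / w.sum())


def _negbin(rng: np.random.Generator, mean: float, size_param: float,
            n: int | None = None):
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, n)


def simulate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate the full synthetic dataset (genome, annotation, tracks, truth)."""
    # background noise gets its own spawned stream so that changing its rate
    # leaves the genome, placement and height draws untouched (common random
    # numbers for seeded what-if comparisons)
    _main_ss, _bg_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(_main_ss)
    rng_bg = np.random.default_rng(_bg_ss)
    n = config.genome_len
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    # 1. genome
    genome_arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n,
                            p=base_p).astype("U1")

    # 2. gene placement (territory = promoter | 5'UTR | gene | 3'UTR | term)
    models = {m.sigma_name: m for m in default_sigma_models()}
    sig_names = ["SigA", "SigH"]
    sig_p = np.array([config.frac_sigA, config.frac_sigH])
    sig_p = sig_p / sig_p.sum()

    genes: list[dict] = []
    cursor = 1
    for gi in range(config.n_genes):
        gap = int(rng.integers(250, 601))
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(config.gene_len_range[0],
                                config.gene_len_range[1] + 1))
        utr5 = sample_utr5(rng)
        utr3 = sample_utr3(rng)
        sigma = sig_names[int(rng.choice(2, p=sig_p))]
        span = 55 + utr5 + glen + utr3 + 10
        start_t = cursor + gap
        if start_t + span > n - 100:
            raise TxArchError(
                f"gene placement infeasible after {gi} genes; "
                "increase genome_len or reduce n_genes")
        # transcription-direction coordinates t0..t0+span, mapped per strand
        if strand == "+":
            tss = start_t + 55
            gstart = tss + utr5
            gend = gstart + glen - 1
            tep = gend + utr3
        else:
            tep = start_t + 10
            gstart = tep + utr3
            gend = gstart + glen - 1
            tss = gend + utr5
        active = _draw_conditions(rng, config)
        abundance = float(rng.lognormal(0.0, config.abundance_lognorm_sd))
        genes.append(dict(idx=gi, strand=strand, gstart=gstart, gend=gend,
                          tss=tss, tep=tep, utr5=utr5, utr3=utr3,
                          sigma=sigma, conditions=active,
                          abundance=abundance))
        cursor = start_t + span

    # 3. planted sequence elements (written into the genome array)
    motif_rows, rbs_rows = [], []
    for g in genes:
        model = models[g["sigma"]]
        spacer = int(rng.choice(sorted(model.spacer_lengths)))
        site_up, site_down = _sample_promoter_site(rng, model)
        gap10 = int(rng.integers(6, 9))  # nt between -10 block 3' end and TSS
        _write_oriented(genome_arr, g["tss"], g["strand"],
                        -(gap10 + model.pwm_down.width), site_down)
        _write_oriented(genome_arr, g["tss"], g["strand"],
                        -(gap10 + model.pwm_down.width + spacer
                          + model.pwm_up.width), site_up)
        motif_rows.append({"gene": _tag(g), "sigma": g["sigma"],
                           "spacer": spacer, "gap10": gap10})
        rbs_gap = int(rng.integers(5, 10))
        gene5 = g["gstart"] if g["strand"] == "+" else g["gend"]
        _write_oriented(genome_arr, gene5, g["strand"], -(rbs_gap + 6),
                        "AGGAGG")
        rbs_rows.append({"gene": _tag(g), "gap_nt": rbs_gap})
        # intrinsic terminator: 8-bp GC-biased stem, 4-nt loop, U8 tract
        stem = "".join(BASES[i] for i in rng.choice(
            4, size=8, p=[0.15, 0.35, 0.35, 0.15]))
        loop = "".join(BASES[i] for i in rng.choice(4, size=4))
        term = stem + loop + revcomp(stem) + "T" * 8
        _write_oriented(genome_arr, g["tep"], g["strand"], -(len(term) - 1),
                        term)

    genome = GenomeSequence(seq_id="synthetic", residues="".join(genome_arr))
    ann = GenomeAnnotation(
        [GeneModel(locus_tag=_tag(g), feature_type="CDS", strand=g["strand"],
                   start=g["gstart"], end=g["gend"]) for g in genes],
        genome_length=n)

    # 4. processed (TEX-depleted) 5' ends: negatives for the enrichment test
    n_proc = rng.poisson(config.processed_site_rate * n / 1000)
    processed = []
    for _ in range(n_proc):
        processed.append((int(rng.integers(1, n + 1)),
                          "+" if rng.random() < 0.5 else "-"))

    # 5. signal tracks
    signals: list[StrandedSignal] = []
    disp = config.tss_height_dispersion
    for cond in config.conditions:
        cond_genes = [g for g in genes if cond in g["conditions"]]
        for rep in range(1, config.n_replicates + 1):
            tex_p = _blank(n)
            tex_m = _blank(n)
            for g in cond_genes:
                mean_p = config.tss_height_mean * g["abundance"]
                h = int(_negbin(rng, mean_p, disp))
                _add_jittered(tex_p[g["strand"]], rng, g["tss"], h,
                              config.jitter_sd)
                hm = int(_negbin(rng, mean_p / config.tex_enrichment, disp))
                _add_jittered(tex_m[g["strand"]], rng, g["tss"], hm,
                              config.jitter_sd)
            for pos, strand in processed:
                hm = int(_negbin(rng, 40.0, disp))
                ratio = 2.0 + 2.0 * rng.random()
                hp = int(hm / ratio)
                _add_jittered(tex_m[strand], rng, pos, hm, config.jitter_sd)
                _add_jittered(tex_p[strand], rng, pos, hp, config.jitter_sd)
            for sig, tex in ((tex_p, "plus"), (tex_m, "minus")):
                _add_background(sig, rng_bg, config.background_rate_per_nt)
                signals.append(_mk_signal(
                    sig, f"dRNA_{cond}_TEX{'p' if tex == 'plus' else 'm'}_r{rep}",
                    cond, "five_prime", tex, rep, config))

            term = _blank(n)
            for g in cond_genes:
                h = int(_negbin(rng, config.tss_height_mean * g["abundance"],
                                disp))
                _add_jittered(term[g["strand"]], rng, g["tep"], h,
                              config.jitter_sd)
            _add_background(term, rng_bg, config.background_rate_per_nt)
            signals.append(_mk_signal(term, f"term_{cond}_r{rep}", cond,
                                      "three_prime", "na", rep, config))

            cov = _blank(n)
            reads_per_rpm = config.total_mapped_reads / 1e6
            for g in cond_genes:
                lo = min(g["tss"], g["tep"])
                hi = max(g["tss"], g["tep"])
                level = (config.tu_coverage_rpm * reads_per_rpm
                         * g["abundance"] * rng.lognormal(0.0, 0.2))
                cov[g["strand"]][lo - 1 : hi] += rng.poisson(level,
                                                             hi - lo + 1)
            _add_background(cov, rng_bg, config.background_rate_per_nt)
            signals.append(_mk_signal(cov, f"rnaseq_{cond}_r{rep}", cond,
                                      "coverage", "na", rep, config))

    truth = GroundTruth(
        tss=pd.DataFrame([{
            "position": g["tss"], "strand": g["strand"], "gene": _tag(g),
            "conditions": ",".join(sorted(g["conditions"])),
            "sigma": g["sigma"], "category": "P"} for g in genes]),
        tep=pd.DataFrame([{
            "position": g["tep"], "strand": g["strand"], "gene": _tag(g),
            "conditions": ",".join(sorted(g["conditions"])),
            "category": "P"} for g in genes]),
        tus=pd.DataFrame([{
            "tss_position": g["tss"], "tep_position": g["tep"],
            "strand": g["strand"], "gene": _tag(g),
            "conditions": ",".join(sorted(g["conditions"]))} for g in genes]),
        motifs=pd.DataFrame(motif_rows),
        rbs=pd.DataFrame(rbs_rows),
        processed=pd.DataFrame(processed, columns=["position", "strand"]),
        genome_id=genome.seq_id)
    return SyntheticDataset(genome=genome, annotation=ann, signals=signals,
                            truth=truth, config=config)


def _tag(g: Mapping) -> str:
    return f"SYN_{g['idx'] + 1:04d}"


def _draw_conditions(rng: np.random.Generator, config: SyntheticConfig
                     ) -> frozenset[str]:
    conds = config.conditions
    if len(conds) == 1 or rng.random() >= config.condition_specific_fraction:
        return frozenset(conds)
    return frozenset([conds[int(rng.integers(len(conds)))]])


def _write_oriented(arr: np.ndarray, anchor: int, strand: str, offset: int,
                    seq: str) -> None:
    """Write *seq* so that, read 5'->3' on *strand*, it starts at
    ``anchor + offset`` (offsets count in the transcription direction;
    negative = upstream of the anchor)."""
    n = len(arr)
    if strand == "+":
        start = anchor + offset
        if start < 1 or start + len(seq) - 1 > n:
            return
        arr[start - 1 : start - 1 + len(seq)] = list(seq)
    else:
        rc = revcomp(seq)
        end = anchor - offset  # genomic coordinate of seq's first (5') base
        start = end - len(seq) + 1
        if start < 1 or end > n:
            return
        arr[start - 1 : end] = list(rc)


def _blank(n: int) -> dict[str, np.ndarray]:
    return {"+": np.zeros(n), "-": np.zeros(n)}


def _add_jittered(vec: np.ndarray, rng: np.random.Generator, pos: int,
                  count: int, sd: float) -> None:
    split = _jitter_offsets(rng, count, sd)
    for off, c in zip(range(-2, 3), split):
        p = pos + off
        if 1 <= p <= len(vec) and c:
            vec[p - 1] += c


def _add_background(sig: dict[str, np.ndarray], rng: np.random.Generator,
                    rate: float) -> None:
    if rate > 0:
        for s in ("+", "-"):
            sig[s] += rng.poisson(rate, len(sig[s]))


def _mk_signal(vecs: dict[str, np.ndarray], lib_id: str, cond: str, role: str,
               tex: str, rep: int, config: SyntheticConfig) -> StrandedSignal:
    meta = LibraryMeta(library_id=lib_id, condition=cond, role=role,
                       tex_status=tex, replicate=rep,
                       total_mapped_reads=config.total_mapped_reads)
    return StrandedSignal(meta=meta, plus=vecs["+"], minus=vecs["-"])


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    tss_recall: float
    tss_precision: float
    tep_recall: float
    tep_precision: float
    tu_exact_recovery: float
    label_agreement: float | None
    tss_matches: dict[int, str]  # true tss index -> called site_id
    tep_matches: dict[int, str]
    category_confusion: pd.DataFrame | None = None
    zero_calls: bool = False


def _greedy_match(true_df: pd.DataFrame, called_sites, tolerance: int
                  ) -> dict[int, str]:
    """One-to-one nearest-first matching of called to true sites."""
    cands = []
    for ti, row in true_df.iterrows():
        for s in called_sites:
            if s.strand != row["strand"]:
                continue
            d = abs(s.position - row["position"])
            if d <= tolerance:
                cands.append((d, ti, s.site_id))
    cands.sort()
    used_t: set[int] = set()
    used_c: set[str] = set()
    out: dict[int, str] = {}
    for d, ti, sid in cands:
        if ti in used_t or sid in used_c:
            continue
        out[ti] = sid
        used_t.add(ti)
        used_c.add(sid)
    return out


def score_recovery(truth: GroundTruth, called_tss, called_tep, called_tus,
                   tolerance_nt: int = 1,
                   tss_annotated=None) -> RecoveryReport:
    """Recall/precision of site calls, exact TU recovery and label agreement.

    Matching is greedy one-to-one, nearest first, within ``tolerance_nt``.
    A TU counts as recovered when both its endpoints matched called sites
    and a called TU pairs exactly those two sites.  Precision with zero
    calls is reported as 1.0 with ``zero_calls`` set.
    """
    tss_m = _greedy_match(truth.tss, called_tss, tolerance_nt)
    tep_m = _greedy_match(truth.tep, called_tep, tolerance_nt)

    def prec(matches, called):
        if len(called) == 0:
            return 1.0, True
        return len(matches) / len(called), False

    tss_prec, zc1 = prec(tss_m, called_tss)
    tep_prec, zc2 = prec(tep_m, called_tep)

    called_pairs = {(t.tss_ref, t.tep_ref) for t in called_tus}
    n_tu = len(truth.tus)
    recovered = 0
    for i in range(n_tu):
        row = truth.tus.iloc[i]
        ti = truth.tss.index[truth.tss["position"] == row["tss_position"]]
        pi = truth.tep.index[truth.tep["position"] == row["tep_position"]]
        ti = next((x for x in ti if truth.tss.loc[x, "strand"] == row["strand"]),
                  None)
        pi = next((x for x in pi if truth.tep.loc[x, "strand"] == row["strand"]),
                  None)
        if ti in tss_m and pi in tep_m and \
                (tss_m[ti], tep_m[pi]) in called_pairs:
            recovered += 1

    by_id = {s.site_id: s for s in called_tss}
    agree = total = 0
    for ti, sid in tss_m.items():
        true_multi = "," in truth.tss.loc[ti, "conditions"]
        called_multi = by_id[sid].condition_label == "constitutive"
        total += 1
        agree += true_multi == called_multi
    label_agreement = agree / total if total else None

    confusion = None
    if tss_annotated is not None:
        cat_by_id = {a.site.site_id: a.category for a in tss_annotated}
        rows = []
        for ti, sid in tss_m.items():
            rows.append({"true": truth.tss.loc[ti, "category"],
                         "called": cat_by_id.get(sid, "?")})
        if rows:
            df = pd.DataFrame(rows)
            confusion = pd.crosstab(df["true"], df["called"])

    return RecoveryReport(
        tss_recall=len(tss_m) / max(len(truth.tss), 1),
        tss_precision=tss_prec,
        tep_recall=len(tep_m) / max(len(truth.tep), 1),
        tep_precision=tep_prec,
        tu_exact_recovery=recovered / max(n_tu, 1),
        label_agreement=label_agreement,
        tss_matches=tss_m, tep_matches=tep_m,
        category_confusion=confusion,
        zero_calls=zc1 or zc2)
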