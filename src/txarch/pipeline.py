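"""End-to-end orchestration: tracks in, architecture tables out.

Runs per-condition TSS/TEP calling, cross-condition merging, positional
classification, transcription-unit assembly and sigma-motif assignment, and
bundles the results.  This is the library surface behind the ``txarch``
command-line interface and the synthetic-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (AnnotatedSite, ClassificationParams, CompositionTable,
                       UTRSummary, category_counts, classify_tep,
                       classify_tss, composition, rbs_scan, utr_stats)
from .io import (GenomeAnnotation, GenomeSequence, LibraryMeta,
                 StrandedSignal, TxArchError)
from .motifs import (BipartiteMotifModel, MotifHit, TerminatorFeatures,
                     default_rbs_pwm, default_sigma_models,
                     terminator_features)
from .motifs import assign_sigma as _assign_sigma
from .peaks import (EndPeak, MergedSite, MergeParams, PeakCallParams,
                    ReproducibilityReport, call_tep_peaks, call_tss_peaks,
                    merge_sites, reproducibility)
from .tu import TranscriptionUnit, TUCluster, TUParams, assemble_tus, cluster_tus


@dataclass
class PipelineParams:
    peaks: PeakCallParams = field(default_factory=PeakCallParams)
    merge: MergeParams = field(default_factory=MergeParams)
    classify: ClassificationParams = field(default_factory=ClassificationParams)
    tu: TUParams = field(default_factory=TUParams)
    promoter_window_nt: int = 50


@dataclass
class PipelineResult:
    tss_by_condition: dict[str, list[EndPeak]]
    tep_by_condition: dict[str, list[EndPeak]]
    tss_merged: list[MergedSite]
    tep_merged: list[MergedSite]
    tss_annotated: list[AnnotatedSite]
    tep_annotated: list[AnnotatedSite]
    tus: list[TranscriptionUnit]
    clusters: list[TUCluster]
    sigma_hits: dict[str, list[MotifHit]]
    sigma_proportions: dict[str, float]
    utr_summary: dict[str, UTRSummary]
    tss_composition: CompositionTable | None
    rbs_fraction: float
    rbs_table: pd.DataFrame
    terminators: list[TerminatorFeatures]
    reproducibility_tss: ReproducibilityReport | None
    reproducibility_tep: ReproducibilityReport | None

    def summary(self) -> dict:
        """Headline numbers of the inferred architecture."""
        n_tss = len(self.tss_merged)
        n_const = sum(1 for s in self.tss_merged
                      if s.condition_label == "constitutive")
        out = {
            "n_tss": n_tss,
            "n_tep": len(self.tep_merged),
            "tss_constitutive_fraction": n_const / n_tss if n_tss else 0.0,
            "n_tus": len(self.tus),
            "n_tu_clusters": len(self.clusters),
            "tss_categories": category_counts(self.tss_annotated),
            "tep_categories": category_counts(self.tep_annotated),
            "rbs_fraction": self.rbs_fraction,
            "sigma_proportions": self.sigma_proportions,
        }
        for cls, key in (("TSS", "median_utr5"), ("TEP", "median_utr3")):
            if cls in self.utr_summary:
                out[key] = self.utr_summary[cls].median
                if cls == "TSS":
                    out["leaderless_count"] = \
                        self.utr_summary[cls].leaderless_count
        if self.reproducibility_tss is not None:
            out["tss_median_pearson_r"] = self.reproducibility_tss.median_r
        if self.reproducibility_tep is not None:
            out["tep_median_pearson_r"] = self.reproducibility_tep.median_r
        return out


def _group_signals(signals: Sequence[StrandedSignal]
                   ) -> dict[str, dict[str, list[StrandedSignal]]]:
    out: dict[str, dict[str, list[StrandedSignal]]] = {}
    for s in signals:
        cond = out.setdefault(s.meta.condition, {})
        key = s.meta.role if s.meta.role != "five_prime" else \
            f"five_prime_{s.meta.tex_status}"
        cond.setdefault(key, []).append(s)
    for cond in out.values():
        for group in cond.values():
            group.sort(key=lambda s: s.meta.replicate)
    return out


def _mean_signal(signals: Sequence[StrandedSignal]) -> StrandedSignal:
    """Replicate-averaged track (same total_mapped_reads scale)."""
    plus = np.mean([s.plus for s in signals], axis=0)
    minus = np.mean([s.minus for s in signals], axis=0)
    return StrandedSignal(meta=signals[0].meta, plus=plus, minus=minus)


def _max_rpm_signal(signals: Sequence[StrandedSignal]) -> StrandedSignal:
    """Element-wise max RPM across condition coverages, as a pseudo-track.

    Used for TU support so that condition-specific units are judged against
    the coverage of the condition where they are expressed.
    """
    plus = np.max([s.rpm("+") for s in signals], axis=0)
    minus = np.max([s.rpm("-") for s in signals], axis=0)
    meta = LibraryMeta(library_id="coverage_combined",
                       condition=signals[0].meta.condition, role="coverage",
                       tex_status="na", replicate=1,
                       total_mapped_reads=1_000_000)  # counts == RPM
    return StrandedSignal(meta=meta, plus=plus, minus=minus)


def run_pipeline(genome: GenomeSequence, annotation: GenomeAnnotation,
                 signals: Sequence[StrandedSignal],
                 params: PipelineParams = PipelineParams(),
                 sigma_models: Sequence[BipartiteMotifModel] | None = None
                 ) -> PipelineResult:
    """Run the full architecture inference on a set of library tracks."""
    groups = _group_signals(signals)
    if not groups:
        raise TxArchError("no signal tracks supplied")
    tss_by_cond: dict[str, list[EndPeak]] = {}
    tep_by_cond: dict[str, list[EndPeak]] = {}
    coverages: list[StrandedSignal] = []
    for cond, roles in sorted(groups.items()):
        cov = _mean_signal(roles["coverage"]) if "coverage" in roles else None
        if cov is not None:
            coverages.extend(roles["coverage"])
        if "five_prime_plus" in roles and "five_prime_minus" in roles:
            tss_by_cond[cond] = call_tss_peaks(
                roles["five_prime_plus"], roles["five_prime_minus"], cov,
                params.peaks)
        if "three_prime" in roles:
            tep_by_cond[cond] = call_tep_peaks(roles["three_prime"], cov,
                                               params.peaks)

    tss_merged = merge_sites(tss_by_cond, params.merge) if tss_by_cond else []
    tep_merged = merge_sites(tep_by_cond, params.merge) if tep_by_cond else []

    rep_tss = _reproducibility_over_conditions(
        groups, "five_prime_plus", tss_merged)
    rep_tep = _reproducibility_over_conditions(
        groups, "three_prime", tep_merged)

    tss_annotated = classify_tss(tss_merged, annotation, genome,
                                 params.classify)
    tep_annotated = classify_tep(tep_merged, annotation, tss_annotated,
                                 params.classify)

    if coverages:
        combined_cov = _max_rpm_signal(coverages)
        tus = assemble_tus(tss_annotated, tep_annotated, combined_cov,
                           annotation, params.tu)
    else:
        tus = []
    clusters = cluster_tus(tus)

    models = list(sigma_models) if sigma_models is not None else \
        default_sigma_models()
    sigma_hits, sigma_props = _assign_sigma(
        tss_merged, genome, models, window_len=params.promoter_window_nt)

    utrs = utr_stats(list(tss_annotated) + list(tep_annotated),
                     params.classify)
    comp = composition(tss_merged, genome) if tss_merged else None
    rbs_frac, rbs_df = rbs_scan(tss_annotated, annotation, genome,
                                default_rbs_pwm(), params.classify)
    terms = terminator_features(tep_merged, genome)

    return PipelineResult(
        tss_by_condition=tss_by_cond, tep_by_condition=tep_by_cond,
        tss_merged=tss_merged, tep_merged=tep_merged,
        tss_annotated=tss_annotated, tep_annotated=tep_annotated,
        tus=tus, clusters=clusters, sigma_hits=sigma_hits,
        sigma_proportions=sigma_props, utr_summary=utrs,
        tss_composition=comp, rbs_fraction=rbs_frac, rbs_table=rbs_df,
        terminators=terms, reproducibility_tss=rep_tss,
        reproducibility_tep=rep_tep)


def _reproducibility_over_conditions(groups, key: str, merged_sites
                                     ) -> ReproducibilityReport | None:
    """Median Pearson r of site heights between replicate pairs, pooled
    over conditions (pairs are formed within a condition)."""
    if len(merged_sites) < 2:
        return None
    pairs: list[tuple[str, str, float]] = []
    for cond, roles in sorted(groups.items()):
        reps = roles.get(key, [])
        if len(reps) < 2:
            continue
        rep = reproducibility(reps, merged_sites)
        pairs.extend(rep.pairs)
    if not pairs:
        return None
    median = float(np.median([r for _, _, r in pairs]))
    return ReproducibilityReport(pairs=tuple(pairs), median_r=median)


def sigma_assignment_accuracy(truth_tss: pd.DataFrame,
                              tss_matches: Mapping[int, str],
                              sigma_hits: Mapping[str, list[MotifHit]]
                              ) -> float:
    """Fraction of matched planted promoters whose top-scoring motif hit
    names the planted sigma factor."""
    ok = total = 0
    for ti, sid in tss_matches.items():
        planted = truth_tss.loc[ti, "sigma"]
        hits = sigma_hits.get(sid, [])
        total += 1
        if hits and max(hits, key=lambda h: h.score).sigma_name == planted:
            ok += 1
    return ok / total if total else float("nan")
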