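"""Transcription-unit assembly and clustering.

A transcription unit (TU) is the connected region between a TSS and its
nearest downstream same-strand TEP, kept only when RNA-seq coverage supports
the span (a minimum fraction of positions above a coverage floor and no long
sub-threshold gap).  Overlapping same-strand TUs form TU clusters
(single-linkage over >= 1 nt overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import AnnotatedSite
from .io import GenomeAnnotation, StrandedSignal, TxArchError


@dataclass(frozen=True)
class TUParams:
    """Coverage-support thresholds for accepting a TSS-TEP span as a TU."""

    min_cov_rpm: float = 1.0
    min_support_fraction: float = 0.8
    max_gap_nt: int = 50
    max_len_nt: int = 15_000
    pairing: str = "nearest"  # or "all"

    def __post_init__(self) -> None:
        if not (0 < self.min_support_fraction <= 1):
            raise TxArchError("min_support_fraction must be in (0, 1]")
        if self.max_len_nt <= 0:
            raise TxArchError("max_len_nt must be > 0")
        if self.pairing not in ("nearest", "all"):
            raise TxArchError("pairing must be 'nearest' or 'all'")


@dataclass(frozen=True)
class TranscriptionUnit:
    tu_id: str
    tss_ref: str
    tep_ref: str
    strand: str
    span: tuple[int, int]  # 1-based inclusive, span[0] <= span[1]
    genes: tuple[str, ...]  # sense-strand genes fully contained in the span


@dataclass(frozen=True)
class TUCluster:
    cluster_id: str
    members: tuple[str, ...]
    strand: str
    span: tuple[int, int]


def _span_supported(cov_rpm: np.ndarray, start: int, end: int,
                    params: TUParams) -> bool:
    seg = cov_rpm[start - 1 : end]
    above = seg >= params.min_cov_rpm
    if above.mean() < params.min_support_fraction:
        return False
    # longest run of sub-threshold positions
    if (~above).any():
        padded = np.concatenate([[True], above, [True]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        runs = edges[1::2] - edges[::2]
        if runs.max() > params.max_gap_nt:
            return False
    return True


def assemble_tus(tss_annotated: Sequence[AnnotatedSite],
                 tep_annotated: Sequence[AnnotatedSite],
                 coverage: StrandedSignal, annotation: GenomeAnnotation,
                 params: TUParams = TUParams()) -> list[TranscriptionUnit]:
    """Pair each TSS with downstream TEP(s) and keep coverage-supported spans.

    With ``pairing='nearest'`` (default) only the nearest downstream
    same-strand TEP within ``max_len_nt`` is considered.  All TSS categories
    seed TUs; antisense/intergenic TUs simply carry an empty gene list.
    The gene list holds sense-strand genes fully contained in the span,
    ordered 5' to 3'.
    """
    if coverage.genome_length != annotation.genome_length:
        raise TxArchError("coverage and annotation genome lengths differ")
    tus: list[TranscriptionUnit] = []
    for strand in ("+", "-"):
        tss_list = sorted((a for a in tss_annotated
                           if a.site.strand == strand),
                          key=lambda a: a.site.position)
        tep_pos = sorted(a.site.position for a in tep_annotated
                         if a.site.strand == strand)
        tep_by_pos = {a.site.position: a for a in tep_annotated
                      if a.site.strand == strand}
        tep_arr = np.array(tep_pos, dtype=int)
        cov_rpm = coverage.rpm(strand)
        for a in tss_list:
            p = a.site.position
            if strand == "+":
                i = np.searchsorted(tep_arr, p + 1, side="left")
                cands = tep_arr[i:]
                cands = cands[cands - p <= params.max_len_nt]
            else:
                i = np.searchsorted(tep_arr, p, side="left")
                cands = tep_arr[:i][::-1]
                cands = cands[p - cands <= params.max_len_nt]
            if params.pairing == "nearest":
                cands = cands[:1]
            for q in cands:
                start, end = (p, int(q)) if strand == "+" else (int(q), p)
                if not _span_supported(cov_rpm, start, end, params):
                    continue
                genes = [g.locus_tag for g in annotation.overlapping(
                            start, end, strand)
                         if g.start >= start and g.end <= end]
                if strand == "-":
                    genes = genes[::-1]
                tus.append(TranscriptionUnit(
                    tu_id="", tss_ref=a.site.site_id,
                    tep_ref=tep_by_pos[int(q)].site.site_id, strand=strand,
                    span=(start, end), genes=tuple(genes)))
    tus.sort(key=lambda t: (t.span[0], t.span[1], t.strand))
    from dataclasses import replace
    return [replace(t, tu_id=f"TU-{i + 1:04d}") for i, t in enumerate(tus)]


def cluster_tus(tus: Sequence[TranscriptionUnit],
                strand_aware: bool = True) -> list[TUCluster]:
    """Group TUs into clusters by single-linkage over >= 1 nt span overlap.

    Clustering is strand-aware by default (a strandless variant is available
    via ``strand_aware=False``).  Cluster ids are ordered by leftmost span.
    """
    clusters: list[TUCluster] = []
    groups = (["+", "-"] if strand_aware else [None])
    proto: list[tuple[int, int, str, list[str]]] = []
    for strand in groups:
        members = [t for t in tus if strand is None or t.strand == strand]
        members.sort(key=lambda t: (t.span[0], t.span[1]))
        cur: list[TranscriptionUnit] = []
        cur_end = -1
        for t in members:
            if cur and t.span[0] > cur_end:
                proto.append(_close(cur, strand))
                cur = []
            cur.append(t)
            cur_end = max(cur_end, t.span[1])
        if cur:
            proto.append(_close(cur, strand))
    proto.sort(key=lambda x: (x[0], x[1], x[2]))
    for i, (s, e, strand, ids) in enumerate(proto):
        clusters.append(TUCluster(cluster_id=f"TUC-{i + 1:03d}",
                                  members=tuple(ids), strand=strand,
                                  span=(s, e)))
    return clusters


def _close(cur, strand):
    s = min(t.span[0] for t in cur)
    e = max(t.span[1] for t in cur)
    return (s, e, strand if strand is not None else ".",
            [t.tu_id for t in cur])
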