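"""TSS and TEP peak calling from 5'/3'-end count tracks.

TSS calling compares terminator-exonuclease treated (TEX+) against untreated
(TEX-) 5'-end libraries: TEX degrades processed 5'-monophosphate ends, so a
genuine transcription start shows TEX+/TEX- enrichment, while a processed
site is TEX-depleted.  TEP calling uses 3'-end (Term-seq) libraries without
an enrichment test.  Both apply an RNA-seq coverage-support filter as an
automated surrogate for manual curation of candidate peaks.

Thresholds on heights are in RPM (reads per million mapped); the enrichment
ratio is computed on raw counts with a pseudocount added to numerator and
denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import StrandedSignal, Strand, TxArchError

STRANDS: tuple[Strand, Strand] = ("+", "-")


@dataclass(frozen=True)
class PeakCallParams:
    """Thresholds for end-peak calling.

    min_height_rpm
        Minimum normalized 5'/3'-end height at the peak position.
    enrichment_min
        Minimum (TEX+ + pseudocount)/(TEX- + pseudocount) count ratio
        (TSS calling only).
    pseudocount
        Raw-count pseudocount added to both sides of the enrichment ratio.
    local_max_window
        Radius (nt) within which the peak must be the strict per-strand
        maximum; ties go to the 5'-most position for TSSs, 3'-most for TEPs.
    replicate_min_fraction
        Fraction of replicate (pairs) in which all per-replicate rules must
        hold.
    downstream_support_len / downstream_support_min_cov
        Length and minimum mean RPM of the RNA-seq window downstream of a
        TSS (upstream of a TEP) required to keep the peak.  Set
        ``downstream_support_min_cov`` to 0 to disable.
    """

    min_height_rpm: float = 1.5
    enrichment_min: float = 2.0
    pseudocount: float = 1.0
    local_max_window: int = 2
    replicate_min_fraction: float = 0.5
    downstream_support_len: int = 50
    downstream_support_min_cov: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.replicate_min_fraction <= 1):
            raise TxArchError("replicate_min_fraction must be in (0, 1]")
        if min(self.min_height_rpm, self.enrichment_min, self.pseudocount) <= 0:
            raise TxArchError("thresholds must be > 0")


@dataclass(frozen=True)
class EndPeak:
    """A called 5' or 3' end in one condition."""

    position: int
    strand: Strand
    height_rpm: float
    enrichment: float | None
    n_replicates_passing: int
    condition: str
    site_class: str  # "TSS" or "TEP"


@dataclass(frozen=True)
class MergeParams:
    tolerance_nt: int = 5

    def __post_init__(self) -> None:
        if self.tolerance_nt < 0:
            raise TxArchError("tolerance_nt must be >= 0")


@dataclass(frozen=True)
class MergedSite:
    """A TSS or TEP merged across conditions.

    The representative ``position`` is the member peak position with the
    highest height; ``condition_label`` is ``constitutive`` when members come
    from two or more conditions, else ``condition-specific:<name>``.
    """

    site_id: str
    position: int
    strand: Strand
    site_class: str
    conditions: frozenset[str]
    condition_label: str
    per_condition_height: Mapping[str, float]


@dataclass(frozen=True)
class ReproducibilityReport:
    pairs: tuple[tuple[str, str, float], ...]
    median_r: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _local_max_positions(rpm: np.ndarray, window: int, tie_to_left: bool
                         ) -> np.ndarray:
    """Boolean mask of positions that are the strict window maximum.

    A position qualifies when its value equals the maximum over
    ``[i-window, i+window]`` and, among tied positions in its window, it is
    the left-most (``tie_to_left``) or right-most one.
    """
    n = len(rpm)
    if n == 0:
        return np.zeros(0, dtype=bool)
    # sliding window maximum via padded strided max
    pad = np.full(window, -np.inf)
    padded = np.concatenate([pad, rpm, pad])
    win = np.lib.stride_tricks.sliding_window_view(padded, 2 * window + 1)
    winmax = win.max(axis=1)
    is_max = (rpm >= winmax) & (rpm > 0)
    # break ties: a tied equal value within the window on the favored side
    # disqualifies this position
    idx = np.nonzero(is_max)[0]
    keep = np.ones(len(idx), dtype=bool)
    for k, i in enumerate(idx):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        ties = np.nonzero(rpm[lo:hi] == rpm[i])[0] + lo
        ties = ties[ties != i]
        if tie_to_left:
            keep[k] = not (ties < i).any()
        else:
            keep[k] = not (ties > i).any()
    out = np.zeros(n, dtype=bool)
    out[idx[keep]] = True
    return out


def _mean_downstream(cov_rpm: np.ndarray, pos_idx: np.ndarray, length: int,
                     direction: int) -> np.ndarray:
    """Mean coverage over *length* nt starting one position after/before each
    index (direction +1 = increasing coordinates)."""
    csum = np.concatenate([[0.0], np.cumsum(cov_rpm)])
    n = len(cov_rpm)
    out = np.empty(len(pos_idx))
    for k, i in enumerate(pos_idx):
        if direction > 0:
            lo, hi = min(i + 1, n), min(i + 1 + length, n)
        else:
            lo, hi = max(i - length, 0), max(i, 0)
        out[k] = (csum[hi] - csum[lo]) / max(hi - lo, 1)
    return out


def _pair_replicates(tex_plus: Sequence[StrandedSignal],
                     tex_minus: Sequence[StrandedSignal]
                     ) -> list[tuple[StrandedSignal, StrandedSignal]]:
    minus_by_rep = {s.meta.replicate: s for s in tex_minus}
    pairs = []
    for sp in sorted(tex_plus, key=lambda s: s.meta.replicate):
        sm = minus_by_rep.get(sp.meta.replicate)
        if sm is not None:
            pairs.append((sp, sm))
    if not pairs:
        raise TxArchError("no TEX+/TEX- replicate pairs (matching replicate "
                          "indices) found")
    return pairs


def _check_lengths(signals: Iterable[StrandedSignal]) -> int:
    lengths = {s.genome_length for s in signals}
    if len(lengths) != 1:
        raise TxArchError(f"mismatched signal vector lengths: {sorted(lengths)}")
    return lengths.pop()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def call_tss_peaks(tex_plus: Sequence[StrandedSignal],
                   tex_minus: Sequence[StrandedSignal],
                   coverage: StrandedSignal | None,
                   params: PeakCallParams) -> list[EndPeak]:
    """Call TSS peaks for one condition from paired TEX+/TEX- libraries.

    A position is a peak when, in at least ``replicate_min_fraction`` of
    replicate pairs, all of: TEX+ height >= ``min_height_rpm``;
    pseudocounted TEX+/TEX- raw-count ratio >= ``enrichment_min``; the TEX+
    height is the strict local maximum within ``local_max_window``; and mean
    RNA-seq coverage over the downstream support window passes (when a
    coverage track is supplied and the threshold is > 0).
    """
    pairs = _pair_replicates(tex_plus, tex_minus)
    sigs = [s for p in pairs for s in p]
    if coverage is not None:
        sigs.append(coverage)
    n = _check_lengths(sigs)
    condition = tex_plus[0].meta.condition
    need = int(np.ceil(params.replicate_min_fraction * len(pairs)))

    peaks: list[EndPeak] = []
    for strand in STRANDS:
        tie_left = strand == "+"  # 5'-most: lowest coordinate on +, highest on -
        pass_count = np.zeros(n, dtype=int)
        heights = np.zeros(n)
        enrich = np.zeros(n)
        for sp, sm in pairs:
            rpm_p = sp.rpm(strand)
            cnt_p = sp.strand(strand)
            cnt_m = sm.strand(strand)
            ok = rpm_p >= params.min_height_rpm
            ratio = (cnt_p + params.pseudocount) / (cnt_m + params.pseudocount)
            ok &= ratio >= params.enrichment_min
            ok &= _local_max_positions(rpm_p, params.local_max_window,
                                       tie_to_left=tie_left)
            passing = ok
            pass_count += passing
            heights += np.where(passing, rpm_p, 0.0)
            enrich += np.where(passing, ratio, 0.0)
        idx = np.nonzero(pass_count >= need)[0]
        if coverage is not None and params.downstream_support_min_cov > 0 \
                and len(idx):
            cov_rpm = coverage.rpm(strand)
            direction = 1 if strand == "+" else -1
            support = _mean_downstream(cov_rpm, idx,
                                       params.downstream_support_len, direction)
            idx = idx[support >= params.downstream_support_min_cov]
        for i in idx:
            k = pass_count[i]
            peaks.append(EndPeak(
                position=int(i) + 1, strand=strand,
                height_rpm=float(heights[i] / k),
                enrichment=float(enrich[i] / k),
                n_replicates_passing=int(k), condition=condition,
                site_class="TSS"))
    peaks.sort(key=lambda p: (p.strand, p.position))
    return peaks


def call_tep_peaks(termseq: Sequence[StrandedSignal],
                   coverage: StrandedSignal | None,
                   params: PeakCallParams) -> list[EndPeak]:
    """Call TEP peaks for one condition from Term-seq 3'-end libraries.

    Same rule as TSS calling but without the enrichment test; the
    coverage-support window lies *upstream* of the 3' end, and local-maximum
    ties break to the 3'-most position.
    """
    if not termseq:
        raise TxArchError("no Term-seq libraries supplied")
    sigs = list(termseq) + ([coverage] if coverage is not None else [])
    n = _check_lengths(sigs)
    condition = termseq[0].meta.condition
    need = int(np.ceil(params.replicate_min_fraction * len(termseq)))

    peaks: list[EndPeak] = []
    for strand in STRANDS:
        tie_left = strand == "-"  # 3'-most: highest coordinate on +, lowest on -
        pass_count = np.zeros(n, dtype=int)
        heights = np.zeros(n)
        for sig in termseq:
            rpm = sig.rpm(strand)
            ok = rpm >= params.min_height_rpm
            ok &= _local_max_positions(rpm, params.local_max_window,
                                      tie_to_left=tie_left)
            pass_count += ok
            heights += np.where(ok, rpm, 0.0)
        idx = np.nonzero(pass_count >= need)[0]
        if coverage is not None and params.downstream_support_min_cov > 0 \
                and len(idx):
            cov_rpm = coverage.rpm(strand)
            direction = -1 if strand == "+" else 1  # upstream of the 3' end
            support = _mean_downstream(cov_rpm, idx,
                                       params.downstream_support_len, direction)
            idx = idx[support >= params.downstream_support_min_cov]
        for i in idx:
            k = pass_count[i]
            peaks.append(EndPeak(
                position=int(i) + 1, strand=strand,
                height_rpm=float(heights[i] / k), enrichment=None,
                n_replicates_passing=int(k), condition=condition,
                site_class="TEP"))
    peaks.sort(key=lambda p: (p.strand, p.position))
    return peaks


def reproducibility(replicate_signals: Sequence[StrandedSignal],
                    sites: Sequence[EndPeak]) -> ReproducibilityReport:
    """Pearson correlation of normalized site heights between replicate pairs.

    For every pair of libraries, heights are the RPM values at the called
    site positions (strand-aware); pairs with a zero-variance height vector
    are excluded with a warning.
    """
    if len(replicate_signals) < 2:
        raise TxArchError("need >= 2 replicate signals")
    if len(sites) < 2:
        raise TxArchError("need >= 2 sites")
    vectors = []
    for sig in replicate_signals:
        v = np.array([sig.rpm(s.strand)[s.position - 1] for s in sites])
        vectors.append((sig.meta.library_id, v))
    pairs = []
    for a in range(len(vectors)):
        for b in range(a + 1, len(vectors)):
            ida, va = vectors[a]
            idb, vb = vectors[b]
            if np.std(va) == 0 or np.std(vb) == 0:
                warnings.warn(f"zero-variance heights for pair ({ida}, {idb}); "
                              "Pearson r undefined, pair excluded")
                continue
            r = float(stats.pearsonr(va, vb).statistic)
            pairs.append((ida, idb, r))
    median = float(np.median([r for _, _, r in pairs])) if pairs else float("nan")
    return ReproducibilityReport(pairs=tuple(pairs), median_r=median)


def merge_sites(per_condition: Mapping[str, Sequence[EndPeak]],
                params: MergeParams = MergeParams()) -> list[MergedSite]:
    """Merge per-condition peak lists into a unified site table.

    Same-strand peaks whose positions differ by at most ``tolerance_nt`` are
    merged transitively (single linkage).  The representative position is the
    member with the highest height (ties: lower position, then condition
    name); a site detected in >= 2 conditions is labelled constitutive.  The
    result is deterministic and independent of input order.
    """
    all_peaks = [p for peaks in per_condition.values() for p in peaks]
    classes = {p.site_class for p in all_peaks}
    if len(classes) > 1:
        raise TxArchError(f"mixed site_class in merge input: {sorted(classes)}")
    site_class = classes.pop() if classes else "TSS"

    merged: list[MergedSite] = []
    for strand in STRANDS:
        peaks = sorted((p for p in all_peaks if p.strand == strand),
                       key=lambda p: (p.position, p.condition, -p.height_rpm))
        cluster: list[EndPeak] = []
        clusters: list[list[EndPeak]] = []
        for p in peaks:
            if cluster and p.position - cluster[-1].position > params.tolerance_nt:
                clusters.append(cluster)
                cluster = []
            cluster.append(p)
        if cluster:
            clusters.append(cluster)
        for members in clusters:
            rep = min(members,
                      key=lambda p: (-p.height_rpm, p.position, p.condition))
            conditions = frozenset(p.condition for p in members)
            per_cond: dict[str, float] = {}
            for p in members:
                per_cond[p.condition] = max(per_cond.get(p.condition, 0.0),
                                            p.height_rpm)
            label = ("constitutive" if len(conditions) >= 2
                     else f"condition-specific:{next(iter(conditions))}")
            merged.append(MergedSite(
                site_id="", position=rep.position, strand=strand,
                site_class=site_class, conditions=conditions,
                condition_label=label, per_condition_height=per_cond))
    merged.sort(key=lambda s: (s.position, s.strand))
    prefix = site_class
    merged = [replace(s, site_id=f"{prefix}-{i + 1:04d}")
              for i, s in enumerate(merged)]
    return merged
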