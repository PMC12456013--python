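"""Sigma-factor promoter motif models, scanning, discovery and terminators.

Promoter motifs of the sigma-70 family are bipartite: a -35-side block and a
-10-side block separated by a constrained spacer.  Each block is a position
weight matrix (PWM) scored as log2 odds against a 0-order background; a hit's
score is the sum of both block scores plus the log2 prior of the observed
spacer length (plus an extended -10 "TG" bonus where enabled).  P-values are
exact per-placement tail probabilities of the block score under the
background, computed by the standard discretized dynamic-programming
convolution used by FIMO-style scanners.

De novo discovery uses a ZOOPS (zero-or-one-occurrence-per-sequence) Gibbs
site sampler; the -10 and -35 blocks of a bipartite motif are discovered in
two stages, with the spacer prior taken from the empirical spacer histogram.

Intrinsic-terminator features (U-tract fraction and the best stem-loop by a
simple pairing score) are computed by exhaustive enumeration; no
thermodynamic folding model is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, GenomeSequence, TxArchError

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def seq_to_idx(seq: str) -> np.ndarray:
    """Map an ACGT string to base indices; other characters become A with
    zero information (callers filter N-containing windows upstream)."""
    return np.fromiter((_BASE_IDX.get(c, 0) for c in seq), dtype=np.int8,
                       count=len(seq))


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (w x 4)."""

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise TxArchError("PWM probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise TxArchError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2 odds matrix; zero-probability cells map to a large negative
        finite value so scores stay finite."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs) - np.log2(self.background)[None, :]
        return np.where(np.isfinite(lo), lo, -100.0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total IC in bits (relative entropy to the background)."""
        p = np.clip(self.probs, 1e-12, None)
        return float((p * (np.log2(p) - np.log2(self.background))).sum())

    def score(self, word: str | np.ndarray) -> float:
        idx = seq_to_idx(word) if isinstance(word, str) else word
        if len(idx) != self.width:
            raise TxArchError("word length != PWM width")
        return float(self.log_odds[np.arange(self.width), idx].sum())


def estimate_pwm(aligned_sites: Sequence[str], pseudocount: float = 0.5,
                 background: np.ndarray | None = None) -> PWM:
    """Estimate a PWM from equal-length aligned sites.

    probs = (count + pseudocount) / (n + 4 * pseudocount) per position.
    """
    if len(aligned_sites) < 1:
        raise TxArchError("need at least one site")
    w = len(aligned_sites[0])
    if any(len(s) != w for s in aligned_sites):
        raise TxArchError("aligned sites must have equal lengths")
    counts = np.zeros((w, 4))
    for s in aligned_sites:
        idx = seq_to_idx(s)
        counts[np.arange(w), idx] += 1
    n = len(aligned_sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def pwm_from_consensus(consensus: str, concentration: float = 0.85,
                       background: np.ndarray | None = None) -> PWM:
    """Build a PWM from an IUPAC consensus: the allowed bases share
    ``concentration`` of the mass, the rest is spread over the others."""
    rows = []
    for c in consensus.upper():
        allowed = IUPAC.get(c)
        if allowed is None:
            raise TxArchError(f"bad consensus character {c!r}")
        row = np.empty(4)
        n_in = len(allowed)
        if n_in == 4:
            row[:] = 0.25
        else:
            row[:] = (1 - concentration) / (4 - n_in)
            for b in allowed:
                row[_BASE_IDX[b]] = concentration / n_in
        rows.append(row)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PWM(probs=np.array(rows), background=bg)


# ---------------------------------------------------------------------------
# exact p-values (discretized DP, FIMO-style)
# ---------------------------------------------------------------------------

def _score_distribution(pwm: PWM, resolution: int
                        ) -> tuple[np.ndarray, float, float]:
    """Distribution of the discretized log-odds score of a background word.

    Returns (prob array over integer score bins, total_min, bin_width):
    bin k holds P(discretized score == total_min + k * bin_width).
    """
    lo = pwm.log_odds
    total_min = float(lo.min(axis=1).sum())
    total_max = float(lo.max(axis=1).sum())
    rng = total_max - total_min
    if rng <= 0:
        return np.array([1.0]), total_min, 1.0
    bin_width = rng / (resolution - 1)
    cells = np.rint((lo - lo.min(axis=1)[:, None]) / bin_width).astype(int)
    dist = np.zeros(1)
    dist[0] = 1.0
    bg = pwm.background
    for i in range(pwm.width):
        new = np.zeros(len(dist) + cells[i].max())
        for b in range(4):
            new[cells[i, b] : cells[i, b] + len(dist)] += bg[b] * dist
        dist = new
    return dist, total_min, bin_width


_DIST_CACHE: dict[tuple, tuple[np.ndarray, float, float]] = {}


def _cached_distribution(pwm: PWM, resolution: int):
    key = (pwm.probs.tobytes(), pwm.background.tobytes(), resolution)
    hit = _DIST_CACHE.get(key)
    if hit is None:
        hit = _score_distribution(pwm, resolution)
        _DIST_CACHE[key] = hit
    return hit


def pwm_pvalue(pwm: PWM, score: float, resolution: int = 10_000) -> float:
    """Exact p-value P(background word scores >= *score*).

    The per-position log-odds scores are discretized to ``resolution`` bins
    across the attainable range and convolved position-wise under the
    background, giving the full null distribution; monotone non-increasing
    in *score*.
    """
    if resolution < 10:
        raise TxArchError("resolution must be >= 10 bins")
    if not np.isfinite(score):
        return 1.0 if score < 0 else 0.0
    dist, total_min, bin_width = _cached_distribution(pwm, resolution)
    if score <= total_min:
        return 1.0
    k = math.ceil((score - total_min) / bin_width - 1e-9)
    if k >= len(dist):
        return 0.0
    return float(dist[k:].sum())


def best_pwm_hit(window: str, pwm: PWM, resolution: int = 10_000
                 ) -> tuple[float, float, int]:
    """Best-scoring placement of a single PWM in a window.

    Returns (score, p-value, 0-based offset); ties go to the 5'-most
    placement.  The window must already be oriented 5'->3'.
    """
    idx = seq_to_idx(window)
    w = pwm.width
    if len(idx) < w:
        raise TxArchError("window shorter than PWM width")
    lo = pwm.log_odds
    m = len(idx) - w + 1
    wins = np.lib.stride_tricks.sliding_window_view(idx, w)
    scores = lo[np.arange(w)[None, :], wins].sum(axis=1)
    best = int(np.argmax(scores))  # argmax returns first (5'-most) maximum
    s = float(scores[best])
    return s, pwm_pvalue(pwm, s, resolution), best


# ---------------------------------------------------------------------------
# bipartite models
# ---------------------------------------------------------------------------

@dataclass
class BipartiteMotifModel:
    """Two-block sigma-factor promoter model with a spacer-length prior."""

    sigma_name: str
    pwm_up: PWM
    pwm_down: PWM
    spacer_lengths: Mapping[int, float]  # length -> prior weight, sums to 1
    score_threshold: float = 0.0  # bits
    pvalue_threshold: float = 1e-4
    extended_minus10_bonus: bool = False  # +1 bit for TG just 5' of the -10

    def __post_init__(self) -> None:
        total = sum(self.spacer_lengths.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise TxArchError("spacer prior weights must sum to 1")

    @property
    def min_span(self) -> int:
        return (self.pwm_up.width + min(self.spacer_lengths)
                + self.pwm_down.width)

    def combined_pwm(self) -> PWM:
        """Concatenated up+down blocks, used for the block-score null."""
        return PWM(probs=np.vstack([self.pwm_up.probs, self.pwm_down.probs]),
                   background=self.pwm_up.background)

    def with_background(self, background: np.ndarray) -> "BipartiteMotifModel":
        bg = np.asarray(background, dtype=float)
        return replace(self,
                       pwm_up=PWM(self.pwm_up.probs, bg),
                       pwm_down=PWM(self.pwm_down.probs, bg))


@dataclass(frozen=True)
class MotifHit:
    tss_or_gene: str
    sigma_name: str
    up_start: int    # 0-based offset within the scanned window
    down_start: int
    spacer: int
    score: float     # bits: both blocks + log2 spacer prior (+ TG bonus)
    pvalue: float    # per-placement exact p-value of the block score


def scan_window(window: str, model: BipartiteMotifModel, ref: str = "",
                resolution: int = 10_000) -> MotifHit | None:
    """Best bipartite placement in a 5'->3' oriented window, or None.

    All (up_start, spacer) placements are evaluated exhaustively; the best
    total score is reported when it reaches ``score_threshold`` and its
    block-score p-value is at most ``pvalue_threshold``.  Equal scores break
    to the 5'-most placement (then shortest spacer).
    """
    idx = seq_to_idx(window)
    n = len(idx)
    if n < model.min_span:
        return None
    lo_up = model.pwm_up.log_odds
    lo_down = model.pwm_down.log_odds
    wu, wd = model.pwm_up.width, model.pwm_down.width

    def block_scores(lo, w):
        if n < w:
            return np.empty(0)
        wins = np.lib.stride_tricks.sliding_window_view(idx, w)
        return lo[np.arange(w)[None, :], wins].sum(axis=1)

    s_up = block_scores(lo_up, wu)
    s_down = block_scores(lo_down, wd)
    best: tuple[float, int, int] | None = None  # (total, up_start, spacer)
    for spacer, weight in sorted(model.spacer_lengths.items()):
        if weight <= 0:
            continue
        lw = math.log2(weight)
        for up_start in range(0, n - (wu + spacer + wd) + 1):
            down_start = up_start + wu + spacer
            total = float(s_up[up_start] + s_down[down_start]) + lw
            if model.extended_minus10_bonus and down_start >= 2:
                if window[down_start - 2 : down_start].upper() == "TG":
                    total += 1.0
            if best is None or total > best[0] + 1e-12:
                best = (total, up_start, spacer)
            elif abs(total - best[0]) <= 1e-12 and (up_start, spacer) < \
                    (best[1], best[2]):
                best = (total, up_start, spacer)
    if best is None:
        return None
    total, up_start, spacer = best
    down_start = up_start + wu + spacer
    block = float(s_up[up_start] + s_down[down_start])
    pval = pwm_pvalue(model.combined_pwm(), block, resolution)
    if total < model.score_threshold or pval > model.pvalue_threshold:
        return None
    return MotifHit(tss_or_gene=ref, sigma_name=model.sigma_name,
                    up_start=up_start, down_start=down_start, spacer=spacer,
                    score=total, pvalue=pval)


def estimate_background(windows: Sequence[str]) -> np.ndarray:
    counts = np.zeros(4)
    for wseq in windows:
        idx = seq_to_idx(wseq)
        counts += np.bincount(idx, minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def promoter_window(genome: GenomeSequence, position: int, strand: str,
                    length: int = 50) -> str:
    """The *length* nt immediately upstream of a TSS (inclusive of -1),
    oriented 5'->3'; truncated at genome ends."""
    if strand == "+":
        return genome.window(position - length, position - 1, "+")
    return genome.window(position + 1, position + length, "-")


def assign_sigma(tss_sites, genome: GenomeSequence,
                 models: Sequence[BipartiteMotifModel],
                 window_len: int = 50,
                 background: str = "windows") -> tuple[
                     dict[str, list[MotifHit]], dict[str, float]]:
    """Scan each TSS promoter window with every sigma model independently.

    A TSS may carry hits for several sigma factors.  Returns
    (hits per site_id, per-sigma proportions over total hits; the fraction
    of TSSs with no hit is under the key ``no_motif`` computed over TSSs).
    With ``background='windows'`` the 0-order background is re-estimated
    from the scanned windows (``'model'`` keeps each model's own).
    """
    windows = {s.site_id: promoter_window(genome, s.position, s.strand,
                                          window_len)
               for s in tss_sites}
    if background == "windows":
        bg = estimate_background(list(windows.values()))
        models = [m.with_background(bg) for m in models]
    hits: dict[str, list[MotifHit]] = {sid: [] for sid in windows}
    for model in models:
        for sid, wseq in windows.items():
            h = scan_window(wseq, model, ref=sid)
            if h is not None:
                hits[sid].append(h)
    n_hits_total = sum(len(v) for v in hits.values())
    proportions: dict[str, float] = {}
    for model in models:
        c = sum(1 for v in hits.values()
                for h in v if h.sigma_name == model.sigma_name)
        proportions[model.sigma_name] = (c / n_hits_total if n_hits_total
                                         else 0.0)
    n_sites = max(len(windows), 1)
    proportions["no_motif"] = sum(1 for v in hits.values() if not v) / n_sites
    return hits, proportions


def default_sigma_models(concentration: float = 0.85
                         ) -> list[BipartiteMotifModel]:
    """The six sigma-factor models.

    SigA (TTGHHW / TATAAT, 17-nt spacer, extended -10 TG bonus), SigH
    (AGGA / GAAT, 17-18 nt), SigL (sigma-54: TGGCA / TTGC, 6 nt) follow the
    organism's reported consensi; SigF/SigE/SigK are B. subtilis-inspired
    placeholders with 14-15 nt spacers, configurable per model.
    """
    def mk(name, up, down, spacers, **kw):
        n = len(spacers)
        return BipartiteMotifModel(
            sigma_name=name,
            pwm_up=pwm_from_consensus(up, concentration),
            pwm_down=pwm_from_consensus(down, concentration),
            spacer_lengths={s: 1.0 / n for s in spacers}, **kw)

    return [
        mk("SigA", "TTGHHW", "TATAAT", [17], extended_minus10_bonus=True),
        mk("SigH", "AGGA", "GAAT", [17, 18]),
        mk("SigF", "GCATA", "GGTATA", [14, 15]),
        mk("SigE", "ATATTC", "CATACA", [14, 15]),
        mk("SigK", "ACTTCA", "CATACT", [14, 15]),
        mk("SigL", "TGGCA", "TTGC", [6]),
    ]


def default_rbs_pwm(concentration: float = 0.8) -> PWM:
    """AG-rich Shine-Dalgarno-like ribosome-binding-site matrix (AGGAGG)."""
    return pwm_from_consensus("AGGAGG", concentration)


# ---------------------------------------------------------------------------
# Gibbs sampling motif discovery (ZOOPS)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GibbsParams:
    width: int = 6
    iterations: int = 150
    restarts: int = 4
    seed: int = 0
    zoops_prior: float = 0.9
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise TxArchError("iterations must be >= 1")
        if not (0 < self.zoops_prior <= 1):
            raise TxArchError("zoops_prior must be in (0, 1]")


def gibbs_discover(seqs: Sequence[str], params: GibbsParams
                   ) -> tuple[PWM, list[int | None]]:
    """ZOOPS Gibbs site sampler: one motif occurrence per sequence or none.

    Iterates leave-one-out PWM estimation and site resampling proportional
    to the log-odds; keeps the best complete-data log-likelihood state
    across restarts.  Deterministic given ``params.seed``.  Returns the PWM
    estimated from the best state's sites and the per-sequence best site
    offsets (None where no site was assigned).
    """
    w = params.width
    if any(len(s) < w for s in seqs):
        raise TxArchError("motif width exceeds a sequence length")
    n = len(seqs)
    idx_seqs = [seq_to_idx(s) for s in seqs]
    windows = [np.lib.stride_tricks.sliding_window_view(x, w)
               for x in idx_seqs]
    m = [wv.shape[0] for wv in windows]
    all_counts = np.zeros(4)
    for x in idx_seqs:
        all_counts += np.bincount(x, minlength=4)
    bg = all_counts / all_counts.sum()
    log_bg = np.log2(np.clip(bg, 1e-12, None))
    q = params.zoops_prior
    pc = params.pseudocount
    jr = np.arange(w)

    def counts_of(z: np.ndarray) -> tuple[np.ndarray, int]:
        counts = np.zeros((w, 4))
        k = 0
        for i in range(n):
            if z[i] >= 0:
                counts[jr, windows[i][z[i]]] += 1
                k += 1
        return counts, k

    def loglik(z: np.ndarray) -> float:
        counts, k = counts_of(z)
        if k == 0:
            return -np.inf
        logp = np.log2((counts + pc) / (k + 4 * pc))
        lo = logp - log_bg[None, :]
        ll = 0.0
        for i in range(n):
            if z[i] >= 0:
                ll += lo[jr, windows[i][z[i]]].sum() + math.log2(q / m[i])
            else:
                ll += math.log2(max(1 - q, 1e-12))
        return ll

    def try_shifts(z: np.ndarray, ll: float) -> tuple[np.ndarray, float]:
        """Greedy column-shift move: slide all sites together by +-1..2 nt
        (clamped per sequence) and keep the shift if the likelihood improves.
        Cures the phase ambiguity Gibbs samplers are prone to."""
        improved = True
        while improved:
            improved = False
            for shift in (-2, -1, 1, 2):
                z2 = z.copy()
                for i in range(n):
                    if z2[i] >= 0:
                        z2[i] = min(max(z2[i] + shift, 0), m[i] - 1)
                ll2 = loglik(z2)
                if ll2 > ll:
                    z, ll = z2, ll2
                    improved = True
        return z, ll

    rng = np.random.default_rng(params.seed)
    best_ll, best_z = -np.inf, None
    for _ in range(params.restarts):
        z = np.array([rng.integers(0, mi) for mi in m])
        counts, k = counts_of(z)
        for it in range(params.iterations):
            for i in range(n):
                if z[i] >= 0:
                    counts[jr, windows[i][z[i]]] -= 1
                    k -= 1
                logp = np.log2((counts + pc) / (k + 4 * pc))
                lo = logp - log_bg[None, :]
                scores = lo[jr[None, :], windows[i]].sum(axis=1)
                lw = scores + math.log2(q / m[i])
                options = np.concatenate([lw,
                                          [math.log2(max(1 - q, 1e-12))]])
                p = np.exp2(options - options.max())
                p /= p.sum()
                choice = rng.choice(len(p), p=p)
                z[i] = choice if choice < m[i] else -1
                if z[i] >= 0:
                    counts[jr, windows[i][z[i]]] += 1
                    k += 1
            ll = loglik(z)
            if (it + 1) % 20 == 0 or it == params.iterations - 1:
                z, ll = try_shifts(z, ll)
                counts, k = counts_of(z)
            if ll > best_ll:
                best_ll, best_z = ll, z.copy()
    assert best_z is not None
    # deterministic polish: set each site to its argmax under the best PWM
    counts, k = counts_of(best_z)
    if k:
        logp = np.log2((counts + pc) / (k + 4 * pc))
        lo = logp - log_bg[None, :]
        for i in range(n):
            scores = lo[jr[None, :], windows[i]].sum(axis=1)
            best_pos = int(scores.argmax())
            take = scores[best_pos] + math.log2(q / m[i]) >= \
                math.log2(max(1 - q, 1e-12))
            best_z[i] = best_pos if take else -1
        counts, k = counts_of(best_z)
    sites = [seqs[i][best_z[i] : best_z[i] + w] for i in range(n)
             if best_z[i] >= 0]
    if not sites:
        raise TxArchError("Gibbs sampler assigned no sites")
    pwm = estimate_pwm(sites, pseudocount=pc, background=bg)
    return pwm, [int(zi) if zi >= 0 else None for zi in best_z]


@dataclass(frozen=True)
class BipartiteDiscoveryParams:
    down_width: int = 4
    up_width: int = 4
    stage1_window: int = 20   # nt nearest the TSS searched for the -10 block
    spacer_min: int = 13
    spacer_max: int = 21
    min_spacer_freq: float = 0.05
    ic_floor_per_col: float = 0.35  # bits; below this a stage fails
    gibbs: GibbsParams = GibbsParams()


def discover_bipartite(promoter_seqs: Sequence[str],
                       params: BipartiteDiscoveryParams =
                       BipartiteDiscoveryParams()) -> BipartiteMotifModel:
    """Two-stage bipartite motif discovery on fixed-length promoter windows.

    Stage 1 finds the -10-side block in the ``stage1_window`` nt nearest the
    TSS (the windows' 3' ends); stage 2 aligns on the -10 hits and searches
    the spacer band upstream for the -35-side block.  The spacer prior is
    the empirical histogram over sequences carrying both blocks (spacers
    below ``min_spacer_freq`` frequency are dropped).
    """
    g = params.gibbs
    stage1 = [s[-params.stage1_window:] for s in promoter_seqs]
    pwm_down, sites1 = gibbs_discover(
        stage1, replace(g, width=params.down_width))
    if pwm_down.information_content() < params.ic_floor_per_col * \
            params.down_width:
        raise TxArchError("bipartite discovery failed at stage 1 (-10 block): "
                          "information content below floor")
    down_abs = {}
    for i, off in enumerate(sites1):
        if off is not None:
            down_abs[i] = len(promoter_seqs[i]) - params.stage1_window + off

    stage2_seqs, stage2_owner = [], []
    band = params.spacer_max - params.spacer_min + params.up_width
    for i, d in down_abs.items():
        lo = d - params.spacer_max - params.up_width
        hi = d - params.spacer_min
        if lo < 0:
            continue
        sub = promoter_seqs[i][lo:hi]
        if len(sub) == band:
            stage2_seqs.append(sub)
            stage2_owner.append(i)
    if len(stage2_seqs) < 2:
        raise TxArchError("bipartite discovery failed at stage 2 (-35 block): "
                          "too few aligned sequences")
    pwm_up, sites2 = gibbs_discover(
        stage2_seqs, replace(g, width=params.up_width, seed=g.seed + 1))
    if pwm_up.information_content() < params.ic_floor_per_col * \
            params.up_width:
        raise TxArchError("bipartite discovery failed at stage 2 (-35 block): "
                          "information content below floor")
    spacer_counts: dict[int, int] = {}
    for k, off in enumerate(sites2):
        if off is None:
            continue
        i = stage2_owner[k]
        d = down_abs[i]
        up_abs = d - params.spacer_max - params.up_width + off
        spacer = d - (up_abs + params.up_width)
        spacer_counts[spacer] = spacer_counts.get(spacer, 0) + 1
    total = sum(spacer_counts.values())
    weights = {s: c / total for s, c in spacer_counts.items()
               if c / total >= params.min_spacer_freq}
    norm = sum(weights.values())
    weights = {s: v / norm for s, v in weights.items()}
    return BipartiteMotifModel(sigma_name="discovered", pwm_up=pwm_up,
                               pwm_down=pwm_down, spacer_lengths=weights)


# ---------------------------------------------------------------------------
# genome-wide upstream scan
# ---------------------------------------------------------------------------

def scan_upstream_genome(annotation: GenomeAnnotation, genome: GenomeSequence,
                         model: BipartiteMotifModel, upstream_len: int = 200,
                         pvalue_threshold: float | None = None
                         ) -> pd.DataFrame:
    """FIMO-style scan of each gene's upstream window with one sigma model.

    Every (placement, spacer) combination with a block-score p-value at or
    below the threshold is reported; ``offset`` is the position of the
    upstream block start relative to the gene start (negative = upstream).
    """
    thr = model.pvalue_threshold if pvalue_threshold is None else \
        pvalue_threshold
    combined = model.combined_pwm()
    rows = []
    for gene in annotation:
        fp = gene.five_prime
        if gene.strand == "+":
            wseq = genome.window(fp - upstream_len, fp - 1, "+")
        else:
            wseq = genome.window(fp + 1, fp + upstream_len, "-")
        n = len(wseq)
        if n < model.min_span:
            continue
        idx = seq_to_idx(wseq)
        wu, wd = model.pwm_up.width, model.pwm_down.width
        lo_up, lo_down = model.pwm_up.log_odds, model.pwm_down.log_odds
        s_up = lo_up[np.arange(wu)[None, :],
                     np.lib.stride_tricks.sliding_window_view(idx, wu)
                     ].sum(axis=1)
        s_down = lo_down[np.arange(wd)[None, :],
                         np.lib.stride_tricks.sliding_window_view(idx, wd)
                         ].sum(axis=1)
        for spacer, weight in sorted(model.spacer_lengths.items()):
            if weight <= 0:
                continue
            for up_start in range(0, n - (wu + spacer + wd) + 1):
                down_start = up_start + wu + spacer
                block = float(s_up[up_start] + s_down[down_start])
                pval = pwm_pvalue(combined, block)
                if pval <= thr:
                    rows.append({
                        "locus_tag": gene.locus_tag,
                        "sigma_name": model.sigma_name,
                        "offset": up_start - n,
                        "spacer": spacer,
                        "score": block + math.log2(weight),
                        "pvalue": pval,
                    })
    return pd.DataFrame(rows, columns=["locus_tag", "sigma_name", "offset",
                                       "spacer", "score", "pvalue"])


# ---------------------------------------------------------------------------
# intrinsic terminator features
# ---------------------------------------------------------------------------

_PAIR_SCORE = {("G", "C"): 3, ("C", "G"): 3,
               ("A", "T"): 2, ("T", "A"): 2,
               ("G", "T"): 1, ("T", "G"): 1}


@dataclass(frozen=True)
class TerminatorFeatures:
    site_id: str
    u_fraction: float
    stem_len: int
    loop_len: int
    hairpin_score: int
    truncated: bool = False


def best_hairpin(window: str, stem_min: int = 5,
                 loop_range: tuple[int, int] = (3, 10)
                 ) -> tuple[int, int, int]:
    """Best stem-loop in a 5'->3' window by exhaustive enumeration.

    Pairing scores: G-C=3, A-T(U)=2, G-T(U wobble)=1; stems extend outward
    from each candidate loop until the first non-pairing position (no
    bulges).  Returns (stem_len, loop_len, score); stems shorter than
    ``stem_min`` give (0, 0, 0).  Ties prefer higher score, longer stem,
    shorter loop, 5'-most placement.
    """
    n = len(window)
    best = (0, 0, 0)  # stem_len, loop_len, score
    best_key = None
    for loop_len in range(loop_range[0], loop_range[1] + 1):
        for loop_start in range(1, n - loop_len):
            i = loop_start - 1          # last 5' stem base
            j = loop_start + loop_len   # first 3' stem base
            stem = 0
            score = 0
            while i - stem >= 0 and j + stem < n:
                pair = (window[i - stem], window[j + stem])
                s = _PAIR_SCORE.get(pair)
                if s is None:
                    break
                score += s
                stem += 1
            if stem < stem_min:
                continue
            key = (score, stem, -loop_len, -loop_start)
            if best_key is None or key > best_key:
                best_key = key
                best = (stem, loop_len, score)
    return best


def terminator_features(tep_sites, genome: GenomeSequence,
                        stem_min: int = 5, loop_range: tuple[int, int] = (3, 10),
                        search_len: int = 60, u_window: int = 8
                        ) -> list[TerminatorFeatures]:
    """U-tract and stem-loop features of each TEP's upstream sequence.

    ``u_fraction`` is the T fraction of the ``u_window`` coding-strand nt
    ending at the TEP; the hairpin is searched in the ``search_len`` nt
    ending at the TEP.  Windows truncated at a genome end are flagged.
    """
    out = []
    for s in tep_sites:
        pos, strand = s.position, s.strand
        if strand == "+":
            u_seq = genome.window(pos - u_window + 1, pos, "+")
            h_seq = genome.window(pos - search_len + 1, pos, "+")
        else:
            u_seq = genome.window(pos, pos + u_window - 1, "-")
            h_seq = genome.window(pos, pos + search_len - 1, "-")
        truncated = len(u_seq) < u_window or len(h_seq) < search_len
        u_frac = (u_seq.count("T") / len(u_seq)) if u_seq else 0.0
        stem, loop, score = best_hairpin(h_seq, stem_min, loop_range)
        out.append(TerminatorFeatures(
            site_id=getattr(s, "site_id", ""), u_fraction=u_frac,
            stem_len=stem, loop_len=loop, hairpin_score=score,
            truncated=truncated))
    return out
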