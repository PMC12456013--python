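"""Genome, annotation and stranded-signal containers plus readers/writers.

All coordinates are 1-based inclusive (GFF3 convention) throughout the
package; BED/bedGraph files are converted at the boundary.  Per-position
signal vectors are numpy arrays indexed by ``position - 1``.

The pipeline assumes a single chromosome; multi-record FASTA inputs are
rejected.  Circularity is not modelled: windows are truncated at the genome
ends.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

Strand = Literal["+", "-"]

_VALID_BASES = set("ACGTN")

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "ncRNA")


class TxArchError(ValueError):
    """Base error for malformed inputs."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome held as an upper-case ACGTN string."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise TxArchError("empty genome sequence")

    @property
    def length(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice, truncated at the genome ends."""
        start = max(1, start)
        end = min(self.length, end)
        if end < start:
            return ""
        return self.residues[start - 1 : end]

    def window(self, start: int, end: int, strand: Strand) -> str:
        """Strand-oriented 1-based inclusive slice (reverse-complemented on -)."""
        s = self.subseq(start, end)
        return revcomp(s) if strand == "-" else s


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene with strand-aware transcriptional ends."""

    locus_tag: str
    feature_type: str
    strand: Strand
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise TxArchError(
                f"gene {self.locus_tag}: end {self.end} < start {self.start}"
            )

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class GenomeAnnotation:
    """Ordered gene collection with strand-aware interval/nearest queries."""

    def __init__(self, genes: Sequence[GeneModel], genome_length: int):
        tags = [g.locus_tag for g in genes]
        if len(set(tags)) != len(tags):
            raise TxArchError("duplicate locus_tags in annotation")
        for g in genes:
            if g.end > genome_length:
                raise TxArchError(
                    f"gene {g.locus_tag} extends beyond genome "
                    f"({g.end} > {genome_length})"
                )
        self.genes: list[GeneModel] = sorted(genes, key=lambda g: (g.start, g.end))
        self.genome_length = genome_length
        self._by_tag = {g.locus_tag: g for g in self.genes}
        self._starts = np.array([g.start for g in self.genes], dtype=int)
        self._ends = np.array([g.end for g in self.genes], dtype=int)
        self._strands = np.array([g.strand for g in self.genes])

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, locus_tag: str) -> GeneModel:
        return self._by_tag[locus_tag]

    def overlapping(self, start: int, end: int, strand: Strand | None = None
                    ) -> list[GeneModel]:
        """Genes overlapping [start, end] (1-based inclusive), optionally by strand."""
        if len(self.genes) == 0:
            return []
        mask = (self._starts <= end) & (self._ends >= start)
        if strand is not None:
            mask &= self._strands == strand
        return [self.genes[i] for i in np.nonzero(mask)[0]]

    def nearest_five_prime(self, pos: int, strand: Strand,
                           candidates: Iterable[GeneModel]) -> GeneModel | None:
        """Among *candidates*, the gene whose 5' end is nearest to *pos*.

        Ties broken by lower start coordinate.
        """
        best = None
        for g in candidates:
            key = (abs(g.five_prime - pos), g.start)
            if best is None or key < best[0]:
                best = (key, g)
        return None if best is None else best[1]


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one sequencing library track."""

    library_id: str
    condition: str
    role: Literal["five_prime", "three_prime", "coverage"]
    tex_status: Literal["plus", "minus", "na"]
    replicate: int
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if (self.tex_status != "na") != (self.role == "five_prime"):
            raise TxArchError(
                f"library {self.library_id}: tex_status must be plus/minus for "
                "five_prime libraries and na otherwise"
            )
        if self.total_mapped_reads <= 0:
            raise TxArchError(f"library {self.library_id}: total_mapped_reads <= 0")
        if self.replicate < 1:
            raise TxArchError(f"library {self.library_id}: replicate < 1")


@dataclass
class StrandedSignal:
    """Per-strand, per-position raw read counts for one library.

    ``plus``/``minus`` hold counts with index ``position - 1``.  RPM views
    normalize by the library's total mapped reads, not the track sum, so
    partial tracks normalize correctly.
    """

    meta: LibraryMeta
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise TxArchError("plus/minus vectors must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise TxArchError("negative counts in signal")

    @property
    def genome_length(self) -> int:
        return len(self.plus)

    @property
    def rpm_factor(self) -> float:
        return 1e6 / self.meta.total_mapped_reads

    def strand(self, strand: Strand) -> np.ndarray:
        return self.plus if strand == "+" else self.minus

    def rpm(self, strand: Strand) -> np.ndarray:
        return self.strand(strand) * self.rpm_factor


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeSequence:
    """Read a single-record FASTA; non-ACGTN characters map to N."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise TxArchError(f"{path}: no FASTA records found")
    if len(records) != 1:
        raise TxArchError(f"{path}: expected 1 record, found {len(records)}")
    rec = records[0]
    residues = "".join(
        c if c in _VALID_BASES else "N" for c in str(rec.seq).upper()
    )
    return GenomeSequence(seq_id=rec.id, residues=residues)


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_annotation(path: str | Path, genome: GenomeSequence) -> GenomeAnnotation:
    """Read gene models from GFF3 (CDS/tRNA/rRNA/ncRNA features).

    ``gene`` features are used only as locus_tag carriers for their children;
    each retained feature becomes one :class:`GeneModel`.  Features without a
    locus_tag get a synthesized stable id (with a warning).
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    n_anon = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            _, _, ftype, start_s, end_s, _, strand, _, attr = fields
            if ftype not in FEATURE_TYPES:
                continue
            start, end = int(start_s), int(end_s)
            if strand not in "+-":
                continue
            attrs = _parse_gff_attributes(attr)
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if tag is None:
                n_anon += 1
                tag = f"feature_{ftype}_{start}_{end}_{strand}"
                warnings.warn(f"{path}: feature at {start}-{end} lacks "
                              f"locus_tag; synthesized id {tag}")
            if tag in seen:
                continue  # e.g. multi-line CDS; keep first span
            seen.add(tag)
            genes.append(GeneModel(locus_tag=tag, feature_type=ftype,
                                   strand=strand, start=start, end=end))
    return GenomeAnnotation(genes, genome.length)


def _expand_bedgraph(df: pd.DataFrame, length: int, path) -> np.ndarray:
    vec = np.zeros(length, dtype=float)
    claimed = np.full(length, np.nan)
    for start, end, value in df.itertuples(index=False):
        start, end = int(start), int(end)
        if end > length:
            warnings.warn(f"{path}: interval {start}-{end} exceeds genome end "
                          f"{length}; clipped")
            end = length
        if start >= end:
            continue
        seg = claimed[start:end]
        conflict = ~np.isnan(seg) & (seg != value)
        if conflict.any():
            raise TxArchError(
                f"{path}: overlapping intervals with conflicting values "
                f"near position {start + int(np.argmax(conflict)) + 1}"
            )
        vec[start:end] = value
        claimed[start:end] = value
    return vec


def _read_bedgraph_frame(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["start", "end", "value"])
    df = df[pd.to_numeric(df["start"], errors="coerce").notna()]  # skip track lines
    return df[["start", "end", "value"]].astype(
        {"start": int, "end": int, "value": float})


def read_signal(
    path: str | Path | tuple[str | Path, str | Path],
    meta: LibraryMeta,
    genome: GenomeSequence,
    dialect: Literal["paired", "signed"] = "paired",
) -> StrandedSignal:
    """Read a bedGraph track into per-position vectors.

    ``paired`` dialect expects a (plus_path, minus_path) tuple with
    non-negative values; ``signed`` a single file where negative values mark
    the minus strand.  bedGraph 0-based half-open intervals become 1-based
    per-position counts; unlisted positions are 0.
    """
    n = genome.length
    if dialect == "paired":
        if not (isinstance(path, tuple) and len(path) == 2):
            raise TxArchError("paired dialect requires a (plus, minus) path pair")
        vecs = []
        for p in path:
            df = _read_bedgraph_frame(p)
            if (df["value"] < 0).any():
                raise TxArchError(f"{p}: negative values in unsigned dialect")
            vecs.append(_expand_bedgraph(df, n, p))
        plus, minus = vecs
    elif dialect == "signed":
        df = _read_bedgraph_frame(path)
        pos = df[df["value"] >= 0]
        neg = df[df["value"] < 0].copy()
        neg["value"] = -neg["value"]
        plus = _expand_bedgraph(pos, n, path)
        minus = _expand_bedgraph(neg, n, path)
    else:
        raise TxArchError(f"unknown signal dialect {dialect!r}")
    return StrandedSignal(meta=meta, plus=plus, minus=minus)


def write_signal_bedgraph(sig: StrandedSignal, plus_path: str | Path,
                          minus_path: str | Path, seq_id: str) -> None:
    """Write the nonzero runs of a signal as a pair of bedGraph files."""
    for vec, p in ((sig.plus, plus_path), (sig.minus, minus_path)):
        with open(p, "w") as fh:
            i = 0
            n = len(vec)
            while i < n:
                if vec[i] == 0:
                    i += 1
                    continue
                j = i
                while j < n and vec[j] == vec[i]:
                    j += 1
                val = vec[i]
                sval = f"{int(val)}" if float(val).is_integer() else f"{val:g}"
                fh.write(f"{seq_id}\t{i}\t{j}\t{sval}\n")
                i = j


def read_library_table(path: str | Path) -> list[LibraryMeta]:
    """Read a libraries.tsv metadata table."""
    df = pd.read_csv(path, sep="\t")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(LibraryMeta(
            library_id=str(row.library_id), condition=str(row.condition),
            role=str(row.role), tex_status=str(row.tex_status),
            replicate=int(row.replicate),
            total_mapped_reads=int(row.total_mapped_reads)))
    return metas


def write_library_table(metas: Sequence[LibraryMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{"library_id": m.library_id, "condition": m.condition, "role": m.role,
          "tex_status": m.tex_status, "replicate": m.replicate,
          "total_mapped_reads": m.total_mapped_reads} for m in metas]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site / TU writers (TSV is the round-trip format; BED6/GFF3 are exports)
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["site_id", "position", "strand", "site_class", "conditions",
                "condition_label", "per_condition_height"]


def write_sites(sites, tsv_path: str | Path, bed_path: str | Path | None = None,
                seq_id: str = "genome") -> None:
    """Write merged sites as TSV (round-trippable) and optionally BED6.

    The BED score is the maximum per-condition height normalized to the
    highest site, scaled to 0-1000.
    """
    rows = []
    for s in sites:
        rows.append({
            "site_id": s.site_id,
            "position": s.position,
            "strand": s.strand,
            "site_class": s.site_class,
            "conditions": ",".join(sorted(s.conditions)),
            "condition_label": s.condition_label,
            "per_condition_height": ";".join(
                f"{c}:{h:.6g}" for c, h in sorted(s.per_condition_height.items())),
        })
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        heights = [max(s.per_condition_height.values()) for s in sites] or [1.0]
        top = max(heights) or 1.0
        with open(bed_path, "w") as fh:
            for s in sites:
                score = int(round(1000 * max(s.per_condition_height.values()) / top))
                fh.write(f"{seq_id}\t{s.position - 1}\t{s.position}\t{s.site_id}"
                         f"\t{min(score, 1000)}\t{s.strand}\n")


def read_sites(tsv_path: str | Path):
    """Read a merged-site TSV back into MergedSite records."""
    from .peaks import MergedSite  # deferred to avoid an import cycle

    try:
        df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    sites = []
    for row in df.itertuples(index=False):
        pch = {}
        if isinstance(row.per_condition_height, str) and row.per_condition_height:
            for item in row.per_condition_height.split(";"):
                c, h = item.rsplit(":", 1)
                pch[c] = float(h)
        sites.append(MergedSite(
            site_id=row.site_id, position=int(row.position), strand=row.strand,
            site_class=row.site_class,
            conditions=frozenset(str(row.conditions).split(",")),
            condition_label=row.condition_label, per_condition_height=pch))
    return sites


TU_COLUMNS = ["tu_id", "tss_ref", "tep_ref", "strand", "span_start", "span_end",
              "genes"]


def write_tus(tus, clusters, tsv_path: str | Path,
              gff_path: str | Path | None = None,
              cluster_tsv_path: str | Path | None = None,
              seq_id: str = "genome") -> None:
    """Write transcription units as TSV (+ optional GFF3) and clusters as TSV."""
    rows = [{
        "tu_id": t.tu_id, "tss_ref": t.tss_ref, "tep_ref": t.tep_ref,
        "strand": t.strand, "span_start": t.span[0], "span_end": t.span[1],
        "genes": ",".join(t.genes),
    } for t in tus]
    pd.DataFrame(rows, columns=TU_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if gff_path is not None:
        by_tu = {}
        for cl in clusters:
            for m in cl.members:
                by_tu[m] = cl.cluster_id
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for cl in clusters:
                fh.write(f"{seq_id}\ttxarch\tTU_cluster\t{cl.span[0]}\t"
                         f"{cl.span[1]}\t.\t{cl.strand}\t.\t"
                         f"ID={cl.cluster_id}\n")
            for t in tus:
                parent = by_tu.get(t.tu_id, "")
                attrs = f"ID={t.tu_id}"
                if parent:
                    attrs += f";Parent={parent}"
                if t.genes:
                    attrs += f";genes={','.join(t.genes)}"
                fh.write(f"{seq_id}\ttxarch\ttranscription_unit\t{t.span[0]}\t"
                         f"{t.span[1]}\t.\t{t.strand}\t.\t{attrs}\n")
    if cluster_tsv_path is not None:
        pd.DataFrame([{
            "cluster_id": c.cluster_id, "members": ",".join(c.members),
            "strand": c.strand, "span_start": c.span[0], "span_end": c.span[1],
        } for c in clusters]).to_csv(cluster_tsv_path, sep="\t", index=False)


def read_tus(tsv_path: str | Path):
    from .tu import TranscriptionUnit

    try:
        df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    out = []
    for row in df.itertuples(index=False):
        genes = tuple(str(row.genes).split(",")) if isinstance(row.genes, str) \
            and row.genes else ()
        out.append(TranscriptionUnit(
            tu_id=row.tu_id, tss_ref=row.tss_ref, tep_ref=row.tep_ref,
            strand=row.strand,
            span=(int(row.span_start), int(row.span_end)), genes=genes))
    return out


def write_genome_fasta(genome: GenomeSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.seq_id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.residues[i : i + 70] + "\n")


def write_annotation_gff3(ann: GenomeAnnotation, path: str | Path,
                          seq_id: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann:
            fh.write(f"{seq_id}\ttxarch\t{g.feature_type}\t{g.start}\t{g.end}"
                     f"\t.\t{g.strand}\t0\tID={g.locus_tag};"
                     f"locus_tag={g.locus_tag}\n")
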