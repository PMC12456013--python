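"""Shared builders for small in-memory fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from txarch.io import (GeneModel, GenomeAnnotation, GenomeSequence,
                       LibraryMeta, StrandedSignal)
from txarch.peaks import EndPeak, MergedSite


def make_meta(library_id="lib1", condition="CO2", role="five_prime",
              tex_status="plus", replicate=1, total=1_000_000) -> LibraryMeta:
    if role != "five_prime":
        tex_status = "na"
    return LibraryMeta(library_id=library_id, condition=condition, role=role,
                       tex_status=tex_status, replicate=replicate,
                       total_mapped_reads=total)


def make_signal(n: int, plus: dict[int, float] | None = None,
                minus: dict[int, float] | None = None,
                **meta_kw) -> StrandedSignal:
    """Signal with counts at the given 1-based positions, zero elsewhere."""
    p = np.zeros(n)
    m = np.zeros(n)
    for pos, v in (plus or {}).items():
        p[pos - 1] = v
    for pos, v in (minus or {}).items():
        m[pos - 1] = v
    return StrandedSignal(meta=make_meta(**meta_kw), plus=p, minus=m)


def make_site(position: int, strand: str = "+", height: float = 10.0,
              site_class: str = "TSS", site_id: str | None = None,
              conditions=("CO2",)) -> MergedSite:
    conds = frozenset(conditions)
    label = ("constitutive" if len(conds) >= 2
             else f"condition-specific:{next(iter(conds))}")
    return MergedSite(
        site_id=site_id or f"{site_class}@{strand}{position}",
        position=position, strand=strand, site_class=site_class,
        conditions=conds, condition_label=label,
        per_condition_height={c: height for c in conds})


def make_peak(position: int, strand: str = "+", height: float = 10.0,
              condition: str = "CO2", site_class: str = "TSS",
              enrichment: float | None = 5.0) -> EndPeak:
    return EndPeak(position=position, strand=strand, height_rpm=height,
                   enrichment=enrichment if site_class == "TSS" else None,
                   n_replicates_passing=2, condition=condition,
                   site_class=site_class)


def make_annotation(genes: list[tuple], genome_length: int
                    ) -> GenomeAnnotation:
    """genes: (locus_tag, strand, start, end) tuples."""
    return GenomeAnnotation(
        [GeneModel(locus_tag=t, feature_type="CDS", strand=s, start=a, end=b)
         for t, s, a, b in genes], genome_length)


@pytest.fixture
def uniform_genome() -> GenomeSequence:
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
    return GenomeSequence(seq_id="toy", residues=seq)
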