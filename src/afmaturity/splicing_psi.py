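"""Reciprocal-junction detection, percent-spliced-in (PSI) computation, and
group comparison of splicing events from junction read counts.

A *reciprocal* event pairs an exclusion junction E with inclusion junctions
that each share exactly one splice site with E and end strictly inside E's
span.  Two inclusions flanking an implied internal exon (one sharing E's
start, one sharing E's end) form a cassette-exon event; a lone inclusion
forms an alternative 5'/3' splice-site event.  Detection is purely
coordinate-based: matching is exact at splice-site resolution and strand is
deliberately ignored (aligner-reported junction strand is unreliable).

PSI for an event in a sample is inclusion / (inclusion + exclusion) read
support, with cassette inclusion support taken as the average of the two
inclusion junction counts so PSI stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import JunctionRecord, SampleMetadata, ValidationError

JunctionKey = tuple[str, int, int]  # (chrom, intron_start, intron_end)


def make_event_id(chrom: str, exclusion: tuple[int, int],
                  inclusions: Sequence[tuple[int, int]]) -> str:
    """Deterministic event identifier from sorted junction coordinates."""
    incl = ",".join(f"{s}-{e}" for s, e in sorted(inclusions))
    return f"{chrom}:{exclusion[0]}-{exclusion[1]}|{incl}"


@dataclass(frozen=True)
class ReciprocalEvent:
    event_id: str
    chrom: str
    inclusion_junctions: tuple[JunctionKey, ...]  # 1 (alt site) or 2 (cassette)
    exclusion_junction: JunctionKey
    gene_id: str | None = None

    @property
    def kind(self) -> str:
        return "cassette" if len(self.inclusion_junctions) == 2 else "altsite"

    @property
    def shared_boundaries(self) -> tuple[int, ...]:
        _, es, ee = self.exclusion_junction
        shared = []
        for _, s, e in self.inclusion_junctions:
            shared.append(es if s == es else ee)
        return tuple(shared)


@dataclass
class PsiTable:
    """Event x sample PSI values (NaN where coverage is insufficient)."""

    psi: pd.DataFrame            # index: event ids, columns: sample ids
    events: dict[str, ReciprocalEvent]
    min_total_reads: int


@dataclass(frozen=True)
class PsiComparison:
    event_id: str
    mean_a: float
    mean_b: float
    delta_psi: float
    p: float
    n_a: int
    n_b: int
    is_regulated: bool
    gene_id: str | None = None


def detect_reciprocal_events(
    junctions: Iterable[JunctionRecord],
    gene_map: Mapping[JunctionKey, str] | None = None,
) -> list[ReciprocalEvent]:
    """Find all reciprocal events among the pooled unique junctions.

    For every candidate exclusion junction E, inclusion candidates are
    junctions sharing exactly one of E's boundaries with the other boundary
    strictly inside E's span.  A left candidate (sharing E's start) and a
    right candidate (sharing E's end) whose inner coordinates leave room for
    an internal exon merge into one cassette event; candidates that pair
    with no partner are emitted as single-inclusion alt-splice-site events.
    Junctions participating in no event are ignored.
    """
    keys = sorted({r.key for r in junctions})
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in keys:
        by_chrom.setdefault(chrom, []).append((s, e))

    events: list[ReciprocalEvent] = []
    for chrom, juncs in by_chrom.items():
        starts: dict[int, list[tuple[int, int]]] = {}
        ends: dict[int, list[tuple[int, int]]] = {}
        for j in juncs:
            starts.setdefault(j[0], []).append(j)
            ends.setdefault(j[1], []).append(j)
        for excl in juncs:
            es, ee = excl
            left = [j for j in starts.get(es, [])
                    if j != excl and es < j[1] < ee]
            right = [j for j in ends.get(ee, [])
                     if j != excl and es < j[0] < ee]
            paired: set[tuple[int, int]] = set()
            for lj in left:
                for rj in right:
                    if lj[1] < rj[0]:  # implied exon (lj[1], rj[0]) nonempty
                        paired.update((lj, rj))
                        events.append(_mk_event(chrom, excl, [lj, rj], gene_map))
            for j in left + right:
                if j not in paired:
                    events.append(_mk_event(chrom, excl, [j], gene_map))
    events.sort(key=lambda ev: ev.event_id)
    return events


def _mk_event(chrom: str, excl: tuple[int, int],
              inclusions: list[tuple[int, int]],
              gene_map: Mapping[JunctionKey, str] | None) -> ReciprocalEvent:
    gene = None
    if gene_map:
        for s, e in [excl, *inclusions]:
            gene = gene_map.get((chrom, s, e))
            if gene is not None:
                break
    return ReciprocalEvent(
        event_id=make_event_id(chrom, excl, inclusions),
        chrom=chrom,
        inclusion_junctions=tuple((chrom, s, e) for s, e in sorted(inclusions)),
        exclusion_junction=(chrom, *excl),
        gene_id=gene,
    )


def compute_psi(
    events: Sequence[ReciprocalEvent],
    junctions_by_sample: Mapping[str, Sequence[JunctionRecord]],
    min_total_reads: int = 10,
) -> PsiTable:
    """Per-event, per-sample PSI from junction read counts.

    Inclusion support is the mean of the event's inclusion-junction counts
    (so a cassette's two junctions are not double-counted); PSI is marked
    missing (NaN) when inclusion + exclusion support is below
    ``min_total_reads``.  Junctions absent from a sample count as zero.
    """
    sample_ids = list(junctions_by_sample)
    counts = {
        sid: {r.key: r.read_count for r in recs}
        for sid, recs in junctions_by_sample.items()
    }
    table = np.full((len(events), len(sample_ids)), np.nan)
    for i, ev in enumerate(events):
        for j, sid in enumerate(sample_ids):
            c = counts[sid]
            incl = float(np.mean([c.get(k, 0) for k in ev.inclusion_junctions]))
            excl = float(c.get(ev.exclusion_junction, 0))
            if incl + excl < min_total_reads:
                continue
            table[i, j] = incl / (incl + excl)
    df = pd.DataFrame(table, index=[ev.event_id for ev in events],
                      columns=sample_ids)
    return PsiTable(psi=df, events={ev.event_id: ev for ev in events},
                    min_total_reads=min_total_reads)


def compare_psi_groups(
    psi: PsiTable,
    metadata: Sequence[SampleMetadata],
    group_a: str,
    group_b: str,
    delta_min: float = 0.1,
    min_samples: int = 2,
    alpha: float = 0.05,
) -> list[PsiComparison]:
    """Contrast PSI between two sample groups.

    Groups are named either by stage ("PN"/"PT"/"FT") or by morbidity flag
    ("respiratory_support"/"gavage_feeding", selecting flagged samples).
    An event is regulated when |delta PSI| >= ``delta_min`` and a two-sided
    Mann-Whitney rank test gives p <= ``alpha`` (unadjusted: cohorts of this
    size leave no power to spare for multiplicity control).  Events with
    fewer than ``min_samples`` informative samples in either group are
    dropped.  ``delta_psi`` is mean(group B) - mean(group A).
    """
    cols_a = _group_samples(metadata, group_a)
    cols_b = _group_samples(metadata, group_b)
    cols_a = [c for c in cols_a if c in psi.psi.columns]
    cols_b = [c for c in cols_b if c in psi.psi.columns]
    out: list[PsiComparison] = []
    for event_id, row in psi.psi.iterrows():
        a = row[cols_a].dropna().to_numpy()
        b = row[cols_b].dropna().to_numpy()
        if len(a) < min_samples or len(b) < min_samples:
            continue
        delta = float(b.mean() - a.mean())
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out.append(
            PsiComparison(
                event_id=event_id,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                delta_psi=delta,
                p=p,
                n_a=len(a),
                n_b=len(b),
                is_regulated=bool(abs(delta) >= delta_min and p <= alpha),
                gene_id=psi.events[event_id].gene_id,
            )
        )
    return out


def _group_samples(metadata: Sequence[SampleMetadata], group: str) -> list[str]:
    if group in ("PN", "PT", "FT"):
        ids = [s.sample_id for s in metadata if s.stage == group]
    else:
        ids = [s.sample_id for s in metadata if group in s.morbidity_flags]
    if not ids:
        raise ValidationError(f"no samples match group {group!r}")
    return ids


def regulated_genes(comparisons: Iterable[PsiComparison]) -> set[str]:
    """Union of gene ids over regulated events (events without a gene id
    contribute their event id so they are not silently dropped)."""
    return {c.gene_id or c.event_id for c in comparisons if c.is_regulated}


def overlap_events(list_a: Iterable[str], list_b: Iterable[str]
                   ) -> tuple[int, int, int]:
    """Partition two id sets into (only in A, only in B, shared) sizes."""
    a, b = set(list_a), set(list_b)
    return len(a - b), len(b - a), len(a & b)


def filter_against_panel(
    events: Sequence[ReciprocalEvent],
    panel: Iterable[JunctionRecord],
) -> tuple[list[ReciprocalEvent], list[ReciprocalEvent]]:
    """Split events by presence in a deep reference junction panel.

    An event is *found* when its exclusion junction and at least one
    inclusion junction occur in the panel at exactly matching coordinates;
    events absent from a deeply sequenced adult/placental panel are
    candidate fetal-specific isoforms.
    """
    panel_keys = {r.key for r in panel}
    found, absent = [], []
    for ev in events:
        ok = ev.exclusion_junction in panel_keys and any(
            k in panel_keys for k in ev.inclusion_junctions
        )
        (found if ok else absent).append(ev)
    return found, absent
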