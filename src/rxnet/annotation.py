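"""Gene models from transcript models.

Transcripts (known or assembled de novo) are clustered into genes by
coding-sequence evidence in three phases: CDS-bearing transcripts are
joined whenever their CDS intervals overlap on the same chromosome and
strand; CDS-less transcripts are then attached to any such gene whose
exon union they overlap; whatever remains forms novel genes by exon
overlap.  Gene length — the RPKM denominator — is the number of bases
in the union of member exons.

Coordinates are 0-based half-open internally; GTF I/O converts to and
from the 1-based inclusive convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class InvalidModelError(ValueError):
    """Raised for malformed transcript or gene models."""


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Merge a list of half-open intervals into a sorted disjoint union."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intervals_overlap_bp(a: list[Interval], b: list[Interval]) -> int:
    """Number of bases shared between two interval sets."""
    bp = 0
    for s1, e1 in merge_intervals(a):
        for s2, e2 in merge_intervals(b):
            bp += max(0, min(e1, e2) - max(s1, s2))
    return bp


@dataclass
class TranscriptModel:
    """A transcript: exon structure plus an optional CDS annotation.

    ``provenance`` distinguishes database-known transcripts from novel
    assembled ones; only novel transcripts are subject to the minimum
    length filter.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] | None = None
    provenance: str = "known"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InvalidModelError(f"{self.id}: strand must be + or -")
        if not self.exons:
            raise InvalidModelError(f"{self.id}: transcript has no exons")
        exons = sorted(self.exons)
        for s, e in exons:
            if e <= s:
                raise InvalidModelError(f"{self.id}: empty exon [{s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise InvalidModelError(f"{self.id}: overlapping exons")
        self.exons = exons
        if self.provenance not in {"known", "novel"}:
            raise InvalidModelError(f"{self.id}: bad provenance {self.provenance!r}")
        if self.cds is not None:
            self.cds = sorted(self.cds)
            for c in self.cds:
                if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                    raise InvalidModelError(
                        f"{self.id}: CDS interval {c} not contained in an exon"
                    )

    @property
    def length(self) -> int:
        """Transcript length as summed exon bases."""
        return sum(e - s for s, e in self.exons)

    @property
    def has_cds(self) -> bool:
        return bool(self.cds)


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chromosome and strand."""

    id: str
    chrom: str
    strand: str
    members: list[str]
    exon_union: list[Interval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exon_union)


def gene_length(gene: GeneModel) -> int:
    """Total bases in the union of member exons (the RPKM denominator)."""
    if not gene.exon_union or gene.length <= 0:
        raise InvalidModelError(f"{gene.id}: empty exon union")
    return gene.length


def filter_short_novel(
    transcripts: list[TranscriptModel], min_len: int = 300
) -> list[TranscriptModel]:
    """Drop novel transcripts shorter than ``min_len`` summed exon bases.

    Known transcripts are always retained; the rule is strictly-less,
    so a novel transcript of exactly ``min_len`` survives.
    """
    return [
        t
        for t in transcripts
        if t.provenance == "known" or t.length >= min_len
    ]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _components(
    items: list[tuple[int, list[Interval]]],
) -> list[list[int]]:
    """Connected components under interval-set overlap, via a sweep.

    ``items`` are (index, intervals) on a single chromosome/strand.
    Uses the sorted-sweep trick: any two interval sets that share a base
    are linked through a chain of pairwise-overlapping primitive
    intervals, so it suffices to union neighbours in the sweep.
    """
    uf = _UnionFind(len(items))
    flat = []  # (start, end, local index)
    for local, (_, ivs) in enumerate(items):
        for s, e in ivs:
            flat.append((s, e, local))
    flat.sort()
    active_end = -1
    active_owner = -1
    for s, e, owner in flat:
        if s < active_end:
            uf.union(active_owner, owner)
            if e > active_end:
                active_end, active_owner = e, owner
        else:
            active_end, active_owner = e, owner
    groups: dict[int, list[int]] = {}
    for local, (orig, _) in enumerate(items):
        groups.setdefault(uf.find(local), []).append(orig)
    return list(groups.values())


def cluster_transcripts(transcripts: list[TranscriptModel]) -> list[GeneModel]:
    """Cluster transcripts into genes by CDS evidence.

    Phase 1: connected components of CDS-bearing transcripts under
    pairwise CDS overlap (same chromosome and strand).
    Phase 2: CDS-less transcripts join a phase-1 gene whose exon union
    they overlap; a transcript overlapping several genes goes to the
    one with the largest overlap in bases (ties: smaller gene id), and
    the conflict is logged.
    Phase 3: remaining transcripts form novel genes as exon-overlap
    connected components.

    The output is a partition: every transcript belongs to exactly one
    gene.  Gene ids are canonical — ``g:<smallest member id>`` — so the
    partition is invariant under input order.
    """
    by_id = {t.id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise InvalidModelError("duplicate transcript ids")

    order = sorted(by_id)  # canonical processing order
    coding = [tid for tid in order if by_id[tid].has_cds]
    noncoding = [tid for tid in order if not by_id[tid].has_cds]

    # Phase 1: CDS-overlap components per (chrom, strand).
    gene_members: list[list[str]] = []
    keyed: dict[tuple[str, str], list[tuple[int, list[Interval]]]] = {}
    for i, tid in enumerate(coding):
        t = by_id[tid]
        keyed.setdefault((t.chrom, t.strand), []).append((i, list(t.cds or [])))
    for items in keyed.values():
        for comp in _components(items):
            gene_members.append(sorted(coding[i] for i in comp))

    def make_gene(members: list[str]) -> GeneModel:
        members = sorted(members)
        first = by_id[members[0]]
        union = merge_intervals(
            [iv for m in members for iv in by_id[m].exons]
        )
        return GeneModel(
            id=f"g:{members[0]}",
            chrom=first.chrom,
            strand=first.strand,
            members=members,
            exon_union=union,
        )

    genes = sorted((make_gene(m) for m in gene_members), key=lambda g: g.id)

    # Phase 2: attach CDS-less transcripts to phase-1 genes by exon overlap.
    attached: dict[str, list[str]] = {g.id: [] for g in genes}
    remaining: list[str] = []
    for tid in noncoding:
        t = by_id[tid]
        best: tuple[int, str] | None = None
        n_hits = 0
        for g in genes:
            if (g.chrom, g.strand) != (t.chrom, t.strand):
                continue
            bp = intervals_overlap_bp(t.exons, g.exon_union)
            if bp > 0:
                n_hits += 1
                # largest overlap wins; ties fall to the smaller gene id
                if best is None or bp > best[0]:
                    best = (bp, g.id)
        if best is None:
            remaining.append(tid)
        else:
            if n_hits > 1:
                logger.warning(
                    "transcript %s overlaps %d genes; attached to %s "
                    "(largest overlap)", tid, n_hits, best[1]
                )
            attached[best[1]].append(tid)

    out: list[GeneModel] = []
    for g in genes:
        out.append(make_gene(g.members + attached[g.id]))

    # Phase 3: novel genes from the leftovers, by exon overlap.
    keyed2: dict[tuple[str, str], list[tuple[int, list[Interval]]]] = {}
    for i, tid in enumerate(remaining):
        t = by_id[tid]
        keyed2.setdefault((t.chrom, t.strand), []).append((i, list(t.exons)))
    for items in keyed2.values():
        for comp in _components(items):
            out.append(make_gene([remaining[i] for i in comp]))

    return sorted(out, key=lambda g: g.id)


# ---------------------------------------------------------------------------
# GTF I/O (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Exon and CDS features are grouped by ``transcript_id``.  Provenance
    is taken from the GTF source column when it is ``known``/``novel``
    (defaulting to known).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tid = feat.attributes["transcript_id"][0]
        prov = feat.source if feat.source in {"known", "novel"} else "known"
        meta[tid] = (feat.seqid, feat.strand, prov)
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    out = []
    for tid in sorted(meta):
        chrom, strand, prov = meta[tid]
        out.append(
            TranscriptModel(
                id=tid,
                chrom=chrom,
                strand=strand,
                exons=exons.get(tid, []),
                cds=cds.get(tid) or None,
                provenance=prov,
            )
        )
    return out


def write_gtf(transcripts: list[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            rows = [("exon", iv) for iv in t.exons]
            rows += [("CDS", iv) for iv in (t.cds or [])]
            for feat, (s, e) in rows:
                attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\t{t.provenance}\t{feat}\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def write_genes_tsv(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tlength\tmembers\n")
        for g in genes:
            fh.write(
                f"{g.id}\t{g.chrom}\t{g.strand}\t{g.length}\t"
                f"{','.join(g.members)}\n"
            )
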