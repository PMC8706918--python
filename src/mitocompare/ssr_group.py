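"""Cross-genome SSR grouping by flanking-sequence homology.

Two SSR loci from different genomes describe the same locus when their
repeat unit is identical and their probes (up to 60 bp of flank on each
side plus the repeat itself) align locally with a Karlin-Altschul
e-value at or below the cutoff (default 1e-10). Single-linkage
connected components over these edges form SSR groups, categorized as

* **common** — members from every input genome,
* **pairwise** — members from more than one but not all genomes,
* **singleton** — one member, i.e. a locus whose flanking context has
  diverged (or which simply does not exist) in the other genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

from Bio import Align

from .genome_io import CircularSequence, FlankTruncated, GenomeBundle, circular_substring
from .karlin import evalue, karlin_params
from .ssr_detect import SsrLocus

__all__ = ["FlankedSsr", "SsrGroup", "PairScore", "AlignScoring",
           "extract_flanks", "score_pair", "build_groups", "group_report"]


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment parameters used for probe comparison."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class FlankedSsr:
    """An SSR locus with its flanking-sequence probe."""

    source_genome: str
    locus: SsrLocus
    left_flank: str
    right_flank: str

    @property
    def probe(self) -> str:
        return self.left_flank + self._repeat() + self.right_flank

    def _repeat(self) -> str:
        l = self.locus
        return (l.unit_seq * l.repeat_count)[: l.total_len]


@dataclass(frozen=True)
class PairScore:
    e_value: float
    raw_score: int
    aligned_identity: float


@dataclass
class SsrGroup:
    group_id: str
    members: list[FlankedSsr]
    category: str  # common | pairwise | singleton


def extract_flanks(locus: SsrLocus, bundle: GenomeBundle, max_flank: int = 60) -> FlankedSsr:
    """Take up to *max_flank* bases on each side of the locus.

    Flanks wrap past the origin on a circular sequence and are truncated
    (never wrapped) on a linear one.
    """
    seq = bundle.sequence
    n = seq.length

    left_len = min(max_flank, n - locus.total_len)
    left_start = locus.start - left_len
    if left_start < 1:
        if seq.is_circular:
            left_start += n
        else:
            left_len = locus.start - 1
            left_start = 1
    left = _substr_or_trunc(seq, left_start, left_len) if left_len > 0 else ""

    end = locus.end if locus.end >= locus.start else locus.end + n  # wrapped locus
    right_start = end + 1
    right_len = min(max_flank, n - locus.total_len - len(left))
    if right_start > n:
        right_start -= n
    if not seq.is_circular:
        right_len = min(right_len, n - end)
    right = _substr_or_trunc(seq, right_start, right_len) if right_len > 0 else ""
    return FlankedSsr(seq.seq_id, locus, left, right)


def _substr_or_trunc(seq: CircularSequence, start: int, length: int) -> str:
    try:
        return circular_substring(seq, start, length)
    except FlankTruncated as exc:
        return exc.truncated


@lru_cache(maxsize=8)
def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    karlin_params(scoring.match, scoring.mismatch)  # validates the scheme
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def score_pair(a: FlankedSsr | str, b: FlankedSsr | str,
               scoring: AlignScoring | None = None) -> PairScore:
    """Optimal local alignment of two probes with its e-value.

    Orientation is not searched: probes are compared as read from the
    forward strand.
    """
    scoring = scoring or AlignScoring()
    pa = a if isinstance(a, str) else a.probe
    pb = b if isinstance(b, str) else b.probe
    if not pa or not pb:
        raise ValueError("probes must be non-empty")
    aligner = _aligner(scoring)
    aln = aligner.align(pa, pb)
    score = int(aln.score)
    best = aln[0]
    matches = sum(1 for x, y in zip(best[0], best[1]) if x == y and x != "-")
    cols = best.length
    return PairScore(
        e_value=evalue(score, len(pa), len(pb), scoring.match, scoring.mismatch),
        raw_score=score,
        aligned_identity=matches / cols if cols else 0.0,
    )


def _find(parent: list[int], i: int) -> int:
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


def build_groups(flanked: Sequence[FlankedSsr], cutoff: float = 1e-10,
                 scoring: AlignScoring | None = None,
                 match_unit: bool = True) -> list[SsrGroup]:
    """Single-linkage grouping of SSR loci across genomes.

    Candidate edges connect loci from *different* genomes whose repeat
    units are identical (when *match_unit*) and whose probes align with
    an e-value <= *cutoff*. If a component ends up holding two loci from
    one genome, the one with the better best-edge e-value stays and the
    other is re-seeded as its own component. Multi-member groups are
    numbered by leftmost member start; singletons are listed after them.
    """
    scoring = scoring or AlignScoring()
    items = list(flanked)
    n = len(items)
    parent = list(range(n))
    best_edge = [float("inf")] * n

    # deterministic candidate order, independent of input order
    order = sorted(range(n), key=lambda i: (items[i].source_genome, items[i].locus.start,
                                            items[i].locus.unit_seq))
    for ia, ib in combinations(order, 2):
        a, b = items[ia], items[ib]
        if a.source_genome == b.source_genome:
            continue
        if match_unit and a.locus.unit_seq != b.locus.unit_seq:
            continue
        ps = score_pair(a, b, scoring)
        if ps.e_value <= cutoff:
            best_edge[ia] = min(best_edge[ia], ps.e_value)
            best_edge[ib] = min(best_edge[ib], ps.e_value)
            ra, rb = _find(parent, ia), _find(parent, ib)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(_find(parent, i), []).append(i)

    # enforce at most one member per genome
    resolved: list[list[int]] = []
    for members in comps.values():
        per_genome: dict[str, list[int]] = {}
        for i in members:
            per_genome.setdefault(items[i].source_genome, []).append(i)
        keep, reseed = [], []
        for idxs in per_genome.values():
            idxs = sorted(idxs, key=lambda i: (best_edge[i], items[i].locus.start))
            keep.append(idxs[0])
            reseed.extend(idxs[1:])
        resolved.append(keep)
        resolved.extend([i] for i in reseed)

    genomes = {f.source_genome for f in items}
    groups: list[SsrGroup] = []
    multi = sorted((m for m in resolved if len(m) > 1),
                   key=lambda m: min(items[i].locus.start for i in m))
    single = sorted((m for m in resolved if len(m) == 1),
                    key=lambda m: items[m[0]].locus.start)
    for k, m in enumerate(multi, start=1):
        members = sorted((items[i] for i in m),
                         key=lambda f: (f.locus.start, f.source_genome))
        cat = "common" if {f.source_genome for f in members} == genomes else "pairwise"
        groups.append(SsrGroup(f"SSRGroup {k}", members, cat))
    for k, m in enumerate(single, start=1):
        groups.append(SsrGroup(f"Singleton {k}", [items[m[0]]], "singleton"))
    return groups


def group_report(groups: Iterable[SsrGroup]) -> dict:
    """Category tallies, Venn cells by genome subset, and a table of
    non-common groups (one row per member)."""
    groups = list(groups)
    tallies = {"common": 0, "pairwise": 0, "singleton": 0}
    venn: dict[tuple[str, ...], int] = {}
    rows = []
    for g in groups:
        tallies[g.category] += 1
        cell = tuple(sorted({m.source_genome for m in g.members}))
        venn[cell] = venn.get(cell, 0) + 1
        if g.category != "common":
            for m in g.members:
                l = m.locus
                rows.append({
                    "GroupId": g.group_id, "Genome": m.source_genome,
                    "SSRType": l.tier_label, "Type": l.type_name,
                    "SSRName": l.ssr_name, "Start": l.start, "End": l.end,
                    "UnitSequence": l.unit_seq, "Repeats": l.repeat_count,
                    "Genes": l.gene or "Intergenic",
                })
    return {"per_category": tallies, "venn": venn, "noncommon_table": rows,
            "n_groups": len(groups)}
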