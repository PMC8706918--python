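"""Heteroplasmy-candidate detection from per-base allele counts.

Deep mitogenome pileups (thousands of reads per base) expose positions
where two bases co-occur within one sample — true heteroplasmy, pooled
inter-individual polymorphism, or base-calling error. A site is called
a candidate when the minor allele both clears a fraction floor and is
statistically incompatible with the base-calling error rate: the
one-sided binomial tail P[X >= minor_count | n = depth, p = error/3]
(error divided by 3 because a specific wrong base is tested) must
survive a family-wise multiplicity correction over all tested columns.

Inputs are count tables, not read alignments, so strand-bias and
base-quality filters are out of reach here; candidates warrant
orthogonal confirmation (e.g. PCR + Sanger of individuals, which is
also the only way to separate true within-individual heteroplasmy from
pooled-sample polymorphism).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

from scipy.stats import binom

from .genome_io import CircularSequence, GenomeBundle
from .ssr_detect import ScanConfig, scan_ssrs
from .variant_compare import classify_effect

__all__ = ["PileupColumn", "HetCall", "HetParams", "read_pileup",
           "call_heteroplasmy", "annotate_het"]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PileupColumn:
    position: int
    ref_base: str
    depth: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.depth:
            raise ValueError(
                f"position {self.position}: counts sum {total} != depth {self.depth}"
            )


@dataclass(frozen=True)
class HetParams:
    min_depth: int = 50
    min_minor_fraction: float = 0.10
    error_rate: float = 0.01
    alpha: float = 0.05
    correction: Literal["bonferroni", "none"] = "bonferroni"


@dataclass(frozen=True)
class HetCall:
    position: int
    major_base: str
    minor_base: str
    minor_fraction: float
    depth: int
    p_value: float
    q_flag: bool
    gene: str = ""
    effect_major: str = "NA"
    effect_minor: str = "NA"
    ssr_note: str = ""


def read_pileup(path: str | Path,
                dialect: Literal["counts_tsv", "samtools_text"] = "counts_tsv") -> list[PileupColumn]:
    """Parse a pileup into columns; positions must be strictly increasing.

    ``counts_tsv`` columns: pos, ref, depth, A, C, G, T, N (header
    optional). ``samtools_text`` is the 6-column ``samtools mpileup``
    text format whose read-base string is decoded into counts (indel
    and read start/end markers are skipped).
    """
    columns: list[PileupColumn] = []
    last_pos = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if dialect == "counts_tsv":
                if ln == 1 and not parts[0].lstrip("-").isdigit():
                    continue  # header
                pos, ref, depth = int(parts[0]), parts[1].upper(), int(parts[2])
                counts = {b: int(parts[3 + i]) for i, b in enumerate(("A", "C", "G", "T", "N"))}
            elif dialect == "samtools_text":
                pos, ref = int(parts[1]), parts[2].upper()
                bases = _decode_readbases(parts[4], ref)
                counts = {b: bases.count(b) for b in ("A", "C", "G", "T", "N")}
                depth = sum(counts.values())
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if pos <= last_pos:
                raise ValueError(f"line {ln}: positions not strictly increasing ({pos})")
            last_pos = pos
            try:
                columns.append(PileupColumn(pos, ref, depth, counts))
            except ValueError as exc:
                raise ValueError(f"line {ln}: {exc}") from None
    return columns


def _decode_readbases(s: str, ref: str) -> str:
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c in ".,":
            out.append(ref)
        elif c.upper() in "ACGTN":
            out.append(c.upper())
        elif c == "^":
            i += 1  # skip mapping-quality char
        elif c in "+-":
            i += 1
            num = ""
            while i < len(s) and s[i].isdigit():
                num += s[i]
                i += 1
            i += int(num) - 1  # skip inserted/deleted bases
        # '$', '*', '<', '>' carry no base call
        i += 1
    return "".join(out)


def call_heteroplasmy(columns: Iterable[PileupColumn],
                      params: HetParams | None = None) -> list[HetCall]:
    """Scan sorted pileup columns for heteroplasmy candidates."""
    params = params or HetParams()
    cols = [c for c in columns if c.depth >= params.min_depth]
    n_tested = len(cols)
    calls: list[HetCall] = []
    for c in cols:
        ranked = sorted(BASES, key=lambda b: (-c.counts.get(b, 0), b))
        major, minor = ranked[0], ranked[1]
        maj_n, min_n = c.counts.get(major, 0), c.counts.get(minor, 0)
        if min_n == 0:
            continue
        frac = min_n / (maj_n + min_n)
        if frac < params.min_minor_fraction:
            continue
        p = float(binom.sf(min_n - 1, c.depth, params.error_rate / 3.0))
        adj = p * n_tested if params.correction == "bonferroni" else p
        if adj > params.alpha:
            continue
        calls.append(HetCall(c.position, major, minor, frac, c.depth, p, True))
    return calls


def annotate_het(call: HetCall, bundle: GenomeBundle, window: int = 60) -> HetCall:
    """Attach gene, per-allele coding effects, and an SSR note.

    The SSR note records whether substituting either allele creates or
    destroys an SSR locus within +/- *window* bp (the minor allele
    breaking a repeat mirrors a repeat-destroying substitution; the
    converse creates one).
    """
    from .genome_io import assign_feature

    gene = assign_feature(call.position, bundle)
    ref = bundle.sequence.residues[call.position - 1]

    def effect_of(base: str) -> str:
        if base == ref:
            return "reference"
        try:
            return classify_effect(call.position, ref, base, bundle)
        except ValueError:
            return "NA"

    note = _ssr_note(call, bundle, window)
    return replace(call, gene=gene, effect_major=effect_of(call.major_base),
                   effect_minor=effect_of(call.minor_base), ssr_note=note)


def _ssr_note(call: HetCall, bundle: GenomeBundle, window: int) -> str:
    n = bundle.sequence.length
    lo = max(1, call.position - window)
    hi = min(n, call.position + window)
    segment = bundle.sequence.residues[lo - 1 : hi]
    rel = call.position - lo  # 0-based within segment

    def loci_with(base: str) -> set[tuple[int, str, int]]:
        s = segment[:rel] + base + segment[rel + 1 :]
        if len(s) < 10:
            return set()
        from .genome_io import GenomeBundle as GB
        tmp = GB(CircularSequence("w", s, False))
        hit = set()
        for l in scan_ssrs(tmp, ScanConfig()):
            if l.start - 1 <= rel <= l.end - 1:
                hit.add((l.start, l.unit_seq, l.repeat_count))
        return hit

    with_major = loci_with(call.major_base)
    with_minor = loci_with(call.minor_base)
    if with_major and not with_minor:
        return "SSR destroyed by minor allele"
    if with_minor and not with_major:
        return "SSR created by minor allele"
    return ""
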