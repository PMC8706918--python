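"""Pairwise whole-mitogenome SNP and INDEL-region calling.

Intraspecific mitogenome pairs are nearly identical (>= 99% identity),
so a global affine-gap alignment restricted to a band around the main
diagonal recovers the optimal alignment at a fraction of the cost; the
band is auto-widened and the alignment retried whenever the optimal
path touches the band edge.

Variant semantics:

* a **SNP** is an alignment column where both rows carry differing
  non-gap, non-ambiguous residues;
* an **INDEL region** is a maximal run of consecutive gap-bearing
  columns, counted as ONE region regardless of its base length, by
  default even when the gaps switch rows mid-run (``split_by_row``
  gives the per-row alternative).

Coding effects are classified under the invertebrate mitochondrial
genetic code (translation table 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Data import CodonTable
from numba import njit

from .genome_io import CircularSequence, GenomeBundle, FeatureAnnotation, reverse_complement

__all__ = ["PairwiseAlignment", "Snp", "IndelRegion", "VariantSet", "AlignParams",
           "align_pair", "read_aligned_fasta_pair", "call_variants",
           "classify_effect", "pairwise_matrix"]

MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = -2
    gap_open: int = 6    # cost of the first gapped base
    gap_extend: int = 1  # cost of each further gapped base
    band_pad: int = 200
    max_retries: int = 3


@dataclass
class PairwiseAlignment:
    seq_ids: tuple[str, str]
    rows: tuple[str, str]
    score: int | None = None

    def __post_init__(self) -> None:
        r0, r1 = self.rows
        if len(r0) != len(r1):
            raise ValueError("alignment rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(r0, r1)):
            raise ValueError("column gapped in both rows")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class Snp:
    column: int          # 1-based alignment column
    pos_a: int
    pos_b: int
    base_a: str
    base_b: str
    gene: str = ""
    effect: str = "NA"   # synonymous | nonsynonymous | noncoding | NA


@dataclass(frozen=True)
class IndelRegion:
    col_start: int
    col_end: int
    length: int
    inserted_in: str     # seq_id carrying residues; "mixed" if gaps switch rows


@dataclass
class VariantSet:
    pair: tuple[str, str]
    snps: list[Snp] = field(default_factory=list)
    indel_regions: list[IndelRegion] = field(default_factory=list)

    @property
    def total_indel_bp(self) -> int:
        return sum(r.length for r in self.indel_regions)


# ---------------------------------------------------------------------------
# Banded global affine alignment

_NINF = -(10 ** 9)


@njit(cache=False)
def _banded_core(ac, bc, match, mismatch, gopen, gext, dlo, W):  # pragma: no cover
    la, lb = ac.shape[0], bc.shape[0]
    Mp = np.full(W, _NINF, np.int64)
    Xp = np.full(W, _NINF, np.int64)
    Yp = np.full(W, _NINF, np.int64)
    Mc = np.full(W, _NINF, np.int64)
    Xc = np.full(W, _NINF, np.int64)
    Yc = np.full(W, _NINF, np.int64)
    tbM = np.zeros((la + 1, W), np.uint8)
    tbX = np.zeros((la + 1, W), np.uint8)
    tbY = np.zeros((la + 1, W), np.uint8)
    for k in range(W):
        j = dlo + k
        if j == 0:
            Mp[k] = 0
        elif 1 <= j <= lb:
            Yp[k] = -(gopen + (j - 1) * gext)
            if j > 1:
                tbY[0, k] = 1
    for i in range(1, la + 1):
        for k in range(W):
            Mc[k] = _NINF
            Xc[k] = _NINF
            Yc[k] = _NINF
        for k in range(W):
            j = i + dlo + k
            if j < 0 or j > lb:
                continue
            if j >= 1:
                best = Mp[k]
                code = 0
                if Xp[k] > best:
                    best = Xp[k]
                    code = 1
                if Yp[k] > best:
                    best = Yp[k]
                    code = 2
                if best > _NINF // 2:
                    s = match if (ac[i - 1] == bc[j - 1] and ac[i - 1] < 4) else mismatch
                    Mc[k] = best + s
                    tbM[i, k] = code
            if k + 1 < W:
                op = Mp[k + 1] - gopen
                ex = Xp[k + 1] - gext
                if op >= ex:
                    if op > _NINF // 2:
                        Xc[k] = op
                        tbX[i, k] = 0
                else:
                    Xc[k] = ex
                    tbX[i, k] = 1
            if k - 1 >= 0 and j >= 1:
                op = Mc[k - 1] - gopen
                ex = Yc[k - 1] - gext
                if op >= ex:
                    if op > _NINF // 2:
                        Yc[k] = op
                        tbY[i, k] = 0
                else:
                    Yc[k] = ex
                    tbY[i, k] = 1
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp

    kend = lb - la - dlo
    score = Mp[kend]
    state = 0
    if Xp[kend] > score:
        score = Xp[kend]
        state = 1
    if Yp[kend] > score:
        score = Yp[kend]
        state = 2

    # traceback
    ops = np.empty(la + lb, np.uint8)
    nops = 0
    touched = False
    i = la
    k = kend
    while True:
        j = i + dlo + k
        if i == 0 and j == 0:
            break
        if k == 0 or k == W - 1:
            touched = True
        if state == 0:
            ops[nops] = 0
            nops += 1
            state = tbM[i, k]
            i -= 1
        elif state == 1:
            ops[nops] = 1
            nops += 1
            state = 1 if tbX[i, k] else 0
            i -= 1
            k += 1
        else:
            ops[nops] = 2
            nops += 1
            state = 2 if tbY[i, k] else 0
            k -= 1
    return score, ops[:nops], touched


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(s: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in s], dtype=np.int8)


def align_pair(a: CircularSequence, b: CircularSequence,
               params: AlignParams | None = None) -> PairwiseAlignment:
    """Global affine-gap alignment of two near-identical genomes within
    a diagonal band (band width = 2|len(a)-len(b)| + band_pad, widened
    and retried up to ``max_retries`` times if the optimum touches the
    band edge)."""
    params = params or AlignParams()
    ac, bc = _encode(a.residues), _encode(b.residues)
    la, lb = len(ac), len(bc)
    diff = lb - la
    margin = (params.band_pad + 2 * abs(diff)) // 2 + 1
    for attempt in range(params.max_retries + 1):
        dlo = min(0, diff) - margin
        dhi = max(0, diff) + margin
        dlo = max(dlo, -la)
        dhi = min(dhi, lb)
        W = dhi - dlo + 1
        score, ops, touched = _banded_core(
            ac, bc, params.match, params.mismatch,
            params.gap_open, params.gap_extend, dlo, W,
        )
        full_band = dlo == -la and dhi == lb
        if not touched or full_band:
            row_a, row_b = [], []
            i = j = 0
            for op in ops[::-1]:
                if op == 0:
                    row_a.append(a.residues[i]); row_b.append(b.residues[j])
                    i += 1; j += 1
                elif op == 1:
                    row_a.append(a.residues[i]); row_b.append("-")
                    i += 1
                else:
                    row_a.append("-"); row_b.append(b.residues[j])
                    j += 1
            return PairwiseAlignment((a.seq_id, b.seq_id),
                                     ("".join(row_a), "".join(row_b)), int(score))
        margin *= 2
    raise RuntimeError("banded optimum unstable after retries; supply an "
                       "external alignment (external_file mode)")


def read_aligned_fasta_pair(path, a: CircularSequence, b: CircularSequence) -> PairwiseAlignment:
    """Ingest a two-row aligned FASTA (e.g. from MAFFT) and validate it
    against the ungapped inputs."""
    from Bio import SeqIO
    rows = list(SeqIO.parse(str(path), "fasta"))
    if len(rows) != 2:
        raise ValueError(f"expected exactly 2 aligned rows, got {len(rows)}")
    r0 = str(rows[0].seq).upper().replace("U", "T")
    r1 = str(rows[1].seq).upper().replace("U", "T")
    if r0.replace("-", "") != a.residues or r1.replace("-", "") != b.residues:
        raise ValueError("alignment/sequence mismatch")
    return PairwiseAlignment((a.seq_id, b.seq_id), (r0, r1))


# ---------------------------------------------------------------------------
# Variant calling


def call_variants(aln: PairwiseAlignment, bundle_a: GenomeBundle | None = None,
                  split_by_row: bool = False) -> VariantSet:
    """Extract SNPs and merged INDEL regions from a pairwise alignment.

    With ``split_by_row`` a gap run that switches rows mid-run is split
    at the switch point into per-row regions.
    """
    row_a, row_b = aln.rows
    snps: list[Snp] = []
    regions: list[IndelRegion] = []
    pos_a = pos_b = 0
    run_start = None
    run_rows: set[str] = set()
    prev_gap_row = None

    def close_run(end_col: int) -> None:
        nonlocal run_start, run_rows
        if run_start is not None:
            carrier = "mixed" if len(run_rows) > 1 else run_rows.pop()
            regions.append(IndelRegion(run_start, end_col, end_col - run_start + 1, carrier))
        run_start = None
        run_rows = set()

    for col0, (x, y) in enumerate(zip(row_a, row_b)):
        col = col0 + 1
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        if x == "-" or y == "-":
            gap_row = aln.seq_ids[0] if x == "-" else aln.seq_ids[1]
            carrier = aln.seq_ids[1] if x == "-" else aln.seq_ids[0]
            if run_start is None:
                run_start = col
            elif split_by_row and prev_gap_row is not None and gap_row != prev_gap_row:
                close_run(col - 1)
                run_start = col
            run_rows.add(carrier)
            prev_gap_row = gap_row
            continue
        close_run(col - 1)
        prev_gap_row = None
        if x != y and x in "ACGT" and y in "ACGT":
            gene, effect = "", "NA"
            if bundle_a is not None and bundle_a.features:
                snp = Snp(col, pos_a, pos_b, x, y)
                gene, effect = _annotate_snp(snp, bundle_a)
            snps.append(Snp(col, pos_a, pos_b, x, y, gene, effect))
    close_run(len(row_a))
    # note: inserted_in names the row CARRYING residues opposite the gap
    return VariantSet((aln.seq_ids[0], aln.seq_ids[1]), snps, regions)


# ---------------------------------------------------------------------------
# Coding-effect classification


def _pcg_at(position: int, bundle: GenomeBundle) -> FeatureAnnotation | None:
    for f in bundle.features:
        if f.kind == "PCG" and f.contains(position):
            return f
    return None


def _feature_sequence(f: FeatureAnnotation, bundle: GenomeBundle) -> str:
    n = bundle.sequence.length
    s = bundle.sequence.residues
    if f.wraps:
        seq = s[f.start - 1:] + s[: f.end]
    else:
        seq = s[f.start - 1 : f.end]
    return reverse_complement(seq) if f.strand == "-" else seq


def _offset_in_feature(position: int, f: FeatureAnnotation, genome_length: int) -> int:
    if f.wraps and position <= f.end:
        fwd = genome_length - f.start + position
    else:
        fwd = position - f.start
    if f.strand == "-":
        return f.span_length(genome_length) - 1 - fwd
    return fwd


def classify_effect(position: int, base_from: str, base_to: str,
                    bundle: GenomeBundle) -> str:
    """Effect of substituting *base_to* for *base_from* at *position*.

    Returns ``synonymous``, ``nonsynonymous`` (stop gain/loss counts as
    nonsynonymous), ``noncoding`` for positions outside protein-coding
    genes, or ``NA`` when the containing gene's frame is broken.
    """
    f = _pcg_at(position, bundle)
    if f is None:
        return "noncoding"
    n = bundle.sequence.length
    if f.span_length(n) % 3 != 0 and not f.incomplete_stop:
        return "NA"
    cds = _feature_sequence(f, bundle)
    off = _offset_in_feature(position, f, n)
    if f.strand == "-":
        base_from = reverse_complement(base_from)
        base_to = reverse_complement(base_to)
    ci = off // 3
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:
        return "NA"
    if codon[off % 3] != base_from:
        raise ValueError(
            f"reference base mismatch at {position}: codon {codon!r}, expected {base_from!r}"
        )
    alt = codon[: off % 3] + base_to + codon[off % 3 + 1 :]
    return "synonymous" if _aa(codon) == _aa(alt) else "nonsynonymous"


def _aa(codon: str) -> str:
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table.get(codon, "X")


def _annotate_snp(snp: Snp, bundle: GenomeBundle) -> tuple[str, str]:
    from .genome_io import assign_feature
    gene = assign_feature(snp.pos_a, bundle)
    try:
        effect = classify_effect(snp.pos_a, snp.base_a, snp.base_b, bundle)
    except ValueError:
        effect = "NA"
    return gene, effect


def pairwise_matrix(bundles: list[GenomeBundle],
                    params: AlignParams | None = None,
                    split_by_row: bool = False) -> dict[tuple[str, str], VariantSet]:
    """One VariantSet per unordered pair of genomes."""
    if len(bundles) < 2:
        raise ValueError("need at least two genomes")
    out: dict[tuple[str, str], VariantSet] = {}
    for ba, bb in combinations(bundles, 2):
        aln = align_pair(ba.sequence, bb.sequence, params)
        out[(ba.sequence.seq_id, bb.sequence.seq_id)] = call_variants(
            aln, ba, split_by_row=split_by_row)
    return out
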