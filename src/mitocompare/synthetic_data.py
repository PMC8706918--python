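"""Synthetic mitogenomes, haplotype pairs, and pileups with known truth.

Emulated data characteristics: a ~16.6 kb circular, strongly AT-rich
genome (GC ~ 23.8%) carrying an even AT-richer control region
(GC ~ 17.5%), SSR loci of unit length 1-10 bp, derived haplotypes with
planted SNPs and multi-base INDELs (the longest in the control region),
and deep pileups (up to ~19,000x) with planted heteroplasmic sites at
chosen minor-allele fractions over a base-calling error floor.

The background is i.i.d. per base (no dinucleotide structure, no real
gene content) — sufficient to exercise every downstream operation, not
a biological sequence model. Base frequencies split the AT pool with a
mild A>T excess and the GC pool with C>G, mirroring the positive
AT-skew / negative GC-skew of the reference strand of insect
mitogenomes.

All generators are pure functions of (parameters, seed). Planted edits
keep >= 20 bp of separation so that the optimal pairwise alignment is
unique and truth recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CircularSequence, FeatureAnnotation, GenomeBundle

__all__ = ["TruthTable", "SsrSpec", "generate_mitogenome", "mutate_genome",
           "simulate_pileup", "pileup_to_tsv"]

#: minimum separation between planted edits (unique-alignment guarantee)
MIN_EDIT_SPACING = 20

AT_SKEW = 0.095   # A excess within the AT pool
GC_SKEW = -0.14   # G deficit within the GC pool


@dataclass(frozen=True)
class SsrSpec:
    start: int        # 1-based position of the first repeat base
    unit_seq: str
    repeat_count: int

    @property
    def total_len(self) -> int:
        return len(self.unit_seq) * self.repeat_count


@dataclass
class TruthTable:
    seed: int
    planted_ssrs: list[SsrSpec] = field(default_factory=list)
    planted_snps: list[tuple[int, str, str]] = field(default_factory=list)
    planted_indels: list[tuple[int, str, str]] = field(default_factory=list)  # (pos, seq, 'ins'/'del')
    planted_hets: list[tuple[int, str, float]] = field(default_factory=list)


def _base_probs(gc: float) -> np.ndarray:
    at = 1.0 - gc
    return np.array([
        at * (1 + AT_SKEW) / 2,   # A
        gc * (1 - GC_SKEW) / 2,   # C
        gc * (1 + GC_SKEW) / 2,   # G
        at * (1 - AT_SKEW) / 2,   # T
    ])


_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_base_probs(gc))


def generate_mitogenome(length: int = 16600, gc: float = 0.238,
                        control_region_length: int = 2219, control_region_gc: float = 0.175,
                        planted_ssrs: list[SsrSpec] | None = None,
                        seed: int = 0) -> tuple[GenomeBundle, TruthTable]:
    """Generate a circular AT-rich genome with an AT-richer control
    region at the 3' end, planted SSR loci, and dummy annotations.

    Each planted SSR is spliced in with a one-base disruptor on both
    sides so the planted run is maximal exactly as specified and cannot
    extend by accident.
    """
    planted_ssrs = planted_ssrs or []
    rng = np.random.default_rng(seed)
    if control_region_length >= length:
        raise ValueError("control region must be shorter than the genome")
    cr_start = length - control_region_length + 1
    # gc is the genome-wide target; the coding part compensates for the
    # AT-richer control region so the overall composition lands on gc
    coding_len = length - control_region_length
    coding_gc = (gc * length - control_region_gc * control_region_length) / coding_len
    if not 0 <= coding_gc <= 1:
        raise ValueError("incompatible genome-wide and control-region GC targets")
    arr = np.concatenate([
        _random_bases(rng, coding_len, coding_gc),
        _random_bases(rng, control_region_length, control_region_gc),
    ])

    spans = []
    for ssr in sorted(planted_ssrs, key=lambda s: s.start):
        lo, hi = ssr.start - 2, ssr.start + ssr.total_len  # incl. disruptors
        if lo < 0 or hi > length:
            raise ValueError(f"planted SSR at {ssr.start} does not fit")
        if spans and lo <= spans[-1][1]:
            raise ValueError("planted SSR loci overlap")
        spans.append((lo, hi))
        repeat = (ssr.unit_seq * ssr.repeat_count)[: ssr.total_len]
        arr[ssr.start - 1 : ssr.start - 1 + ssr.total_len] = list(repeat)
        # disruptors: differ from the unit base they would extend
        arr[ssr.start - 2] = _other(ssr.unit_seq[-1], rng)
        arr[ssr.start - 1 + ssr.total_len] = _other(ssr.unit_seq[0], rng)

    seq = CircularSequence(f"synth{seed}", "".join(arr), is_circular=True)

    # dummy in-frame PCGs on the coding part, away from planted loci
    features = [FeatureAnnotation("CR", "control_region", "AT-rich region",
                                  cr_start, length, "+")]
    pcg_names = ["PCG1", "PCG2", "PCG3"]
    block = (cr_start - 1) // 3
    for i, name in enumerate(pcg_names):
        start = i * block + 1
        span = (block - 200) // 3 * 3
        if span < 30:
            continue  # genome too short for dummy genes
        features.append(FeatureAnnotation(name, "PCG", name, start, start + span - 1,
                                          "-" if i == 2 else "+"))
    bundle = GenomeBundle(seq, features, source=f"synthetic(seed={seed})")
    return bundle, TruthTable(seed=seed, planted_ssrs=list(planted_ssrs))


def _other(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def mutate_genome(bundle: GenomeBundle, n_snps: int = 21,
                  indel_spec: list[tuple[int, str]] | None = None,
                  pcg_snp_fraction: float = 0.6,
                  seed: int = 0) -> tuple[GenomeBundle, TruthTable]:
    """Derive a haplotype carrying planted SNPs and INDELs.

    *indel_spec* is a list of ``(length, "ins"|"del")``; the longest
    INDEL is placed inside the control region (the most variable part
    of real mitogenomes), and about *pcg_snp_fraction* of SNPs fall in
    annotated PCGs. Edits keep >= 20 bp spacing in reference
    coordinates; positions are drawn deterministically from *seed*.
    """
    indel_spec = indel_spec or []
    rng = np.random.default_rng(seed)
    seq = bundle.sequence
    n = seq.length
    cr = next((f for f in bundle.features if f.kind == "control_region"), None)
    pcgs = [f for f in bundle.features if f.kind == "PCG"]

    taken: list[int] = []

    def place(lo: int, hi: int, width: int) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(lo, hi - width + 1))
            if all(abs(pos - t) >= MIN_EDIT_SPACING + width for t in taken):
                taken.append(pos)
                return pos
        raise ValueError("cannot satisfy edit spacing; reduce edit count")

    edits: list[tuple[int, str, str]] = []  # (pos, payload, kind)
    indels = sorted(indel_spec, key=lambda x: -x[0])
    for idx, (ln, kind) in enumerate(indels):
        if not 1 <= ln <= 42:
            raise ValueError("indel lengths must be 1..42")
        if idx == 0 and cr is not None:
            pos = place(cr.start + 5, cr.end - ln - 5, ln)
        else:
            pos = place(100, n - ln - 100, ln)
        payload = ("".join(_random_bases(rng, ln, 0.2)) if kind == "ins"
                   else seq.residues[pos - 1 : pos - 1 + ln])
        edits.append((pos, payload, kind))

    n_pcg = round(n_snps * pcg_snp_fraction) if pcgs else 0
    snps: list[tuple[int, str, str]] = []
    for i in range(n_snps):
        if i < n_pcg:
            f = pcgs[int(rng.integers(0, len(pcgs)))]
            pos = place(f.start, f.end, 1)
        else:
            pos = place(100, n - 100, 1)
        ref = seq.residues[pos - 1]
        alt = _other(ref, rng)
        snps.append((pos, ref, alt))
        edits.append((pos, alt, "snp"))

    # apply right-to-left so reference coordinates stay valid
    s = seq.residues
    for pos, payload, kind in sorted(edits, key=lambda e: -e[0]):
        i = pos - 1
        if kind == "snp":
            s = s[:i] + payload + s[i + 1 :]
        elif kind == "ins":
            s = s[:i] + payload + s[i:]
        else:  # del
            s = s[:i] + s[i + len(payload) :]

    derived = CircularSequence(seq.seq_id + ".derived", s, seq.is_circular)
    truth = TruthTable(seed=seed, planted_snps=sorted(snps),
                       planted_indels=sorted((p, q, k) for p, q, k in edits if k != "snp"))
    return GenomeBundle(derived, [], source="mutated"), truth


def simulate_pileup(bundle: GenomeBundle, depth: int = 1000, error_rate: float = 0.01,
                    hets: list[tuple[int, str, float]] | None = None,
                    seed: int = 0) -> tuple[list, TruthTable]:
    """Multinomial pileup counts over the genome.

    At ordinary positions each read shows the true base with
    probability 1 - error and each specific wrong base with error/3; at
    a het position the minor allele replaces the true base with
    probability ``minor_fraction`` before errors apply.
    """
    from .heteroplasmy_scan import PileupColumn

    hets = hets or []
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = bundle.sequence.length
    het_map = {}
    for pos, minor, frac in hets:
        if not 1 <= pos <= n:
            raise ValueError(f"het position {pos} out of range")
        if not 0 < frac <= 0.5:
            raise ValueError("minor fractions must be in (0, 0.5]")
        if minor == bundle.sequence.residues[pos - 1]:
            raise ValueError(f"minor base at {pos} equals the reference base")
        het_map[pos] = (minor, frac)

    rng = np.random.default_rng(seed)
    base_index = {b: i for i, b in enumerate("ACGT")}
    refs = np.frombuffer(bundle.sequence.residues.encode(), dtype="S1")
    counts_arr = np.zeros((n, 4), dtype=np.int64)
    het_pos0 = np.array(sorted(p - 1 for p in het_map), dtype=np.int64)

    # draw all ordinary columns sharing a reference base in one batch
    for base, bi in base_index.items():
        idx = np.flatnonzero(refs == base.encode())
        if het_pos0.size:
            idx = np.setdiff1d(idx, het_pos0, assume_unique=True)
        if idx.size == 0:
            continue
        probs = np.full(4, error_rate / 3.0)
        probs[bi] = 1 - error_rate
        counts_arr[idx] = rng.multinomial(depth, probs, size=idx.size)

    for pos in sorted(het_map):
        minor, frac = het_map[pos]
        ref = bundle.sequence.residues[pos - 1]
        ri, mi = base_index.get(ref, 0), base_index[minor]
        probs = np.full(4, error_rate / 3.0)
        probs[ri] = (1 - error_rate) * (1 - frac) + (error_rate / 3.0) * frac
        probs[mi] = (1 - error_rate) * frac + (error_rate / 3.0) * (1 - frac)
        counts_arr[pos - 1] = rng.multinomial(depth, probs / probs.sum())

    columns = [
        PileupColumn(pos, bundle.sequence.residues[pos - 1], depth,
                     {b: int(counts_arr[pos - 1, i]) for b, i in base_index.items()} | {"N": 0})
        for pos in range(1, n + 1)
    ]
    truth = TruthTable(seed=seed, planted_hets=sorted(hets))
    return columns, truth


def pileup_to_tsv(columns, path) -> None:
    """Write columns in the counts_tsv dialect (pos ref depth A C G T N)."""
    with open(path, "w") as fh:
        fh.write("pos\tref\tdepth\tA\tC\tG\tT\tN\n")
        for c in columns:
            fh.write(f"{c.position}\t{c.ref_base}\t{c.depth}\t"
                     + "\t".join(str(c.counts.get(b, 0)) for b in "ACGTN") + "\n")
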