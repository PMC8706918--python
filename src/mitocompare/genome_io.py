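"""Sequence and annotation I/O with circular-coordinate semantics.

Mitochondrial genomes are circular molecules, so every positional service
here (substring extraction, feature lookup) must be able to wrap past the
arbitrary linearization origin. Coordinates are 1-based inclusive
throughout, matching the convention of GenBank flat files and of every
printed mitogenome table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "FeatureAnnotation",
    "GenomeBundle",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "assign_feature",
    "circular_substring",
    "reverse_complement",
]

#: IUPAC ambiguity codes accepted on input beyond the core alphabet.
IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
CORE_ALPHABET = set("ACGTN")

FeatureKind = Literal["PCG", "tRNA", "rRNA", "control_region", "intergenic", "other"]

#: Lookup priority when a position is covered by several features.
_KIND_PRIORITY = {"PCG": 0, "tRNA": 0, "rRNA": 0, "other": 1, "control_region": 2, "intergenic": 3}


class FastaError(ValueError):
    """Raised for malformed FASTA input (empty file, illegal residues)."""


@dataclass(frozen=True)
class CircularSequence:
    """One mitogenome (or contig) with an explicit circularity flag."""

    seq_id: str
    residues: str
    is_circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        for i, ch in enumerate(self.residues):
            if ch not in CORE_ALPHABET and ch not in IUPAC_AMBIGUITY:
                raise FastaError(
                    f"illegal residue {ch!r} at position {i + 1} in {self.seq_id}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A gene/region annotation in 1-based inclusive coordinates.

    ``end < start`` is legal only for a feature wrapping the circular
    origin (e.g. a control region crossing position 1).
    """

    feature_id: str
    kind: FeatureKind
    name: str
    start: int
    end: int
    strand: str = "+"
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be >= 1 ({self.feature_id})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or - ({self.feature_id})")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def span_length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for a wrapped feature")
        return genome_length - self.start + 1 + self.end

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


@dataclass
class GenomeBundle:
    """A sequence plus its feature annotations."""

    sequence: CircularSequence
    features: list[FeatureAnnotation] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        n = self.sequence.length
        seen: set[str] = set()
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValueError(
                    f"feature {f.feature_id} ({f.start}..{f.end}) outside sequence of length {n}"
                )
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature_id {f.feature_id}")
            seen.add(f.feature_id)


# ---------------------------------------------------------------------------
# FASTA


def _normalize_residues(raw: str, seq_id: str) -> str:
    s = raw.upper().replace("U", "T")
    ambiguous = sorted({c for c in s if c in IUPAC_AMBIGUITY and c != "N"})
    if ambiguous:
        warnings.warn(
            f"{seq_id}: IUPAC ambiguity codes {ambiguous} present; they are "
            "excluded from SSR units and scored as mismatches in alignments",
            stacklevel=3,
        )
    return s


def read_fasta(path: str | Path, circular: bool | None = None) -> list[CircularSequence]:
    """Read FASTA records into :class:`CircularSequence` objects.

    Residues are uppercased and U is mapped to T.  Circularity is taken
    from *circular* when given, otherwise from a literal ``circular``
    token in the record description, otherwise ``False``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no records in {path}")
    out = []
    for rec in records:
        is_circ = circular
        if is_circ is None:
            is_circ = "circular" in rec.description.lower().split()
        out.append(
            CircularSequence(rec.id, _normalize_residues(str(rec.seq), rec.id), is_circ)
        )
    return out


def write_fasta(seqs: Iterable[CircularSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA, wrapped at *width* columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description="circular" if s.is_circular else "")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Annotations

_KIND_ALIASES = {
    "pcg": "PCG",
    "cds": "PCG",
    "gene": "PCG",
    "protein_coding_gene": "PCG",
    "trna": "tRNA",
    "trna_gene": "tRNA",
    "rrna": "rRNA",
    "rrna_gene": "rRNA",
    "control_region": "control_region",
    "d_loop": "control_region",
    "d-loop": "control_region",
    "at_rich_region": "control_region",
    "misc_feature": "other",
    "intergenic": "intergenic",
}


def _map_kind(raw: str, context: str) -> FeatureKind:
    kind = _KIND_ALIASES.get(raw.strip().lower())
    if kind is None:
        warnings.warn(f"unknown feature kind {raw!r} in {context}; mapped to 'other'", stacklevel=3)
        kind = "other"
    return kind


def _read_tsv_annotations(path: Path) -> list[FeatureAnnotation]:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.lower(): i for i, c in enumerate(header)}
        for required in ("name", "kind", "start", "end", "strand"):
            if required not in cols:
                raise ValueError(f"annotation TSV missing column {required!r}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[cols["name"]]
            feats.append(
                FeatureAnnotation(
                    feature_id=f"{name}.{ln}",
                    kind=_map_kind(parts[cols["kind"]], f"{path}:{ln}"),
                    name=name,
                    start=int(parts[cols["start"]].replace(",", "")),
                    end=int(parts[cols["end"]].replace(",", "")),
                    strand=parts[cols["strand"]],
                )
            )
    return feats


def _read_gff3_annotations(path: Path) -> list[FeatureAnnotation]:
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line has {len(parts)} columns")
            _, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            name = attr.get("Name") or attr.get("gene") or attr.get("ID") or ftype
            fid = attr.get("ID", f"{name}.{ln}")
            feats.append(
                FeatureAnnotation(
                    feature_id=fid,
                    kind=_map_kind(ftype, f"{path}:{ln}"),
                    name=name,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            )
    return feats


_GENBANK_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "control_region",
                 "misc_feature": "other"}


def _read_genbank_annotations(path: Path) -> list[FeatureAnnotation]:
    rec = SeqIO.read(str(path), "genbank")
    feats = []
    n = len(rec.seq)
    for i, f in enumerate(rec.features):
        if f.type not in _GENBANK_KIND:
            continue
        name = f.qualifiers.get("gene", f.qualifiers.get("product", [f.type]))[0]
        # compound (join) locations spanning the origin become one wrapped feature
        start = int(f.location.parts[0].start) + 1
        end = int(f.location.parts[-1].end)
        if end > n:  # SeqIO already normalizes, but guard anyway
            end -= n
        feats.append(
            FeatureAnnotation(
                feature_id=f"{name}.{i}",
                kind=_GENBANK_KIND[f.type],
                name=name,
                start=start,
                end=end,
                strand="-" if f.location.strand == -1 else "+",
            )
        )
    return feats


def read_annotations(
    path: str | Path, dialect: Literal["gff3", "tsv", "genbank_flat"] = "tsv"
) -> list[FeatureAnnotation]:
    """Read feature annotations; coordinates come back 1-based inclusive.

    Features are returned sorted by start.  Uncovered regions are not
    materialized — intergenic assignment is computed on demand by
    :func:`assign_feature`.
    """
    path = Path(path)
    if dialect == "tsv":
        feats = _read_tsv_annotations(path)
    elif dialect == "gff3":
        feats = _read_gff3_annotations(path)
    elif dialect == "genbank_flat":
        feats = _read_genbank_annotations(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return sorted(feats, key=lambda f: f.start)


# ---------------------------------------------------------------------------
# Coordinate services


def assign_feature(position: int, bundle: GenomeBundle) -> str:
    """Name of the feature covering *position*, or ``"Intergenic"``.

    Coding/structural features (PCG, tRNA, rRNA) take precedence over the
    control region when annotations overlap. A span query should pass the
    span's start.
    """
    n = bundle.sequence.length
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside [1, {n}]")
    best: FeatureAnnotation | None = None
    for f in bundle.features:
        if f.contains(position):
            if best is None or _KIND_PRIORITY[f.kind] < _KIND_PRIORITY[best.kind]:
                best = f
    if best is None or best.kind == "intergenic":
        return "Intergenic"
    return best.name


class FlankTruncated(ValueError):
    """A substring would wrap the origin of a non-circular sequence."""

    def __init__(self, truncated: str, message: str = "flank truncated"):
        super().__init__(message)
        self.truncated = truncated


def circular_substring(seq: CircularSequence, start: int, length: int) -> str:
    """Extract *length* residues starting at 1-based *start*, wrapping
    past the origin iff the sequence is circular.

    On a linear sequence a request past the end raises
    :class:`FlankTruncated` carrying the truncated string.
    """
    n = seq.length
    if length > n:
        raise ValueError(f"requested length {length} exceeds sequence length {n}")
    if not 1 <= start <= n:
        raise ValueError(f"start {start} outside [1, {n}]")
    i = start - 1
    if i + length <= n:
        return seq.residues[i : i + length]
    if not seq.is_circular:
        raise FlankTruncated(seq.residues[i:])
    return seq.residues[i:] + seq.residues[: i + length - n]


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]
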