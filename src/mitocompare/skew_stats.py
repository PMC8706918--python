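"""Nucleotide composition and strand-skew statistics.

GC-skew = (G - C) / (G + C) and AT-skew = (A - T) / (A + T), computed on
the reported strand. Insect mitogenome reference strands are typically
AT-rich with C over G, giving a negative GC-skew and positive AT-skew.
Ambiguity codes are excluded from both numerator and denominator; an
empty denominator yields NaN (undefined), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome_io import CircularSequence, FeatureAnnotation, circular_substring

__all__ = ["CompositionSummary", "composition"]


@dataclass(frozen=True)
class CompositionSummary:
    n_a: int
    n_c: int
    n_g: int
    n_t: int

    @property
    def counted(self) -> int:
        return self.n_a + self.n_c + self.n_g + self.n_t

    @property
    def gc_percent(self) -> float:
        if self.counted == 0:
            return math.nan
        return 100.0 * (self.n_g + self.n_c) / self.counted

    @property
    def gc_skew(self) -> float:
        gc = self.n_g + self.n_c
        return (self.n_g - self.n_c) / gc if gc else math.nan

    @property
    def at_skew(self) -> float:
        at = self.n_a + self.n_t
        return (self.n_a - self.n_t) / at if at else math.nan


def composition(seq: CircularSequence,
                region: FeatureAnnotation | tuple[int, int] | None = None) -> CompositionSummary:
    """Base counts and skews over the whole genome or a region.

    *region* may be a feature annotation or a 1-based inclusive
    ``(start, end)`` span; a span wrapping the origin is allowed on a
    circular sequence.
    """
    if region is None:
        s = seq.residues
    else:
        if isinstance(region, FeatureAnnotation):
            start, end = region.start, region.end
        else:
            start, end = region
        n = seq.length
        length = (end - start + 1) if end >= start else (n - start + 1 + end)
        if length <= 0:
            raise ValueError("empty region")
        s = circular_substring(seq, start, length)
    return CompositionSummary(s.count("A"), s.count("C"), s.count("G"), s.count("T"))
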