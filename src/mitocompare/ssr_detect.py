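"""Perfect tandem-repeat (SSR / microsatellite) detection and tiering.

The scanner reports every maximal perfect tandem run with a primitive
unit of 1-10 bp that clears its tier's floor:

* **normal** — units 1-4 bp with a total run length of at least 10 bp
  (so mono >= 10 repeats, di >= 5, tri >= 4, tetra >= 3);
* **potential** — units 5-6 bp repeated at least twice (a subset of the
  normal tier singled out because 2 x 5-6 bp already clears 10 bp);
* **extended** — units 7-10 bp repeated at least twice.

A run is *maximal* when it cannot be extended by one unit on either
side, and *primitive* when its unit is not itself a whole-number tandem
of a shorter unit (``AT`` is primitive, ``ATAT`` is not), so a
homopolymer is reported once under its 1 bp unit rather than again as a
di- or tri-nucleotide repeat. Runs whose maximal extent includes a
partial trailing unit are reported over whole units only, anchored at
the leftmost phase.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genome_io import GenomeBundle, assign_feature

__all__ = ["SsrLocus", "ScanConfig", "classify_ssr", "scan_ssrs", "ssr_census",
           "TYPE_NAMES", "NAME_PREFIXES"]

TYPE_NAMES = {1: "MonoSSR", 2: "DiSSR", 3: "TriSSR", 4: "TetraSSR", 5: "PentaSSR",
              6: "HexaSSR", 7: "HeptaSSR", 8: "OctaSSR", 9: "NonaSSR", 10: "DecaSSR"}

#: Per-type name prefixes. Mono..hexa follow the published inventories;
#: hepta..deca have no published precedent and are configurable.
NAME_PREFIXES = {1: "M", 2: "D", 3: "T", 4: "Te", 5: "P", 6: "H",
                 7: "Hp", 8: "O", 9: "N", 10: "De"}

TIER_LABELS = {"normal": "Normal SSR", "potential": "Potential SSR", "extended": "Extended SSR"}


@dataclass(frozen=True)
class ScanConfig:
    """Tunable thresholds for the SSR scan."""

    min_unit: int = 1
    max_unit: int = 10
    min_total_normal: int = 10   # bp floor for 1-4 bp units
    min_repeats_long: int = 2    # repeat floor for 5-10 bp units
    circular_scan: bool = False  # scan across the origin join
    prefixes: Mapping[int, str] = field(default_factory=lambda: dict(NAME_PREFIXES))


@dataclass(frozen=True)
class SsrLocus:
    """One perfect tandem repeat locus (1-based inclusive coordinates)."""

    ssr_name: str
    unit_seq: str
    unit_len: int
    repeat_count: int
    start: int
    end: int
    tier: str
    gene: str = ""

    @property
    def total_len(self) -> int:
        return self.unit_len * self.repeat_count

    @property
    def type_name(self) -> str:
        return TYPE_NAMES[self.unit_len]

    @property
    def tier_label(self) -> str:
        return TIER_LABELS[self.tier]


def classify_ssr(unit_len: int, repeat_count: int, config: ScanConfig | None = None) -> str:
    """Tier for a (unit length, repeat count) pair, or ``"rejected"``."""
    config = config or ScanConfig()
    if not 1 <= unit_len <= 10:
        raise ValueError(f"unit_len {unit_len} outside 1..10")
    if repeat_count < 2:
        return "rejected"
    if unit_len <= 4:
        return "normal" if unit_len * repeat_count >= config.min_total_normal else "rejected"
    floor = config.min_repeats_long
    if unit_len <= 6:
        return "potential" if repeat_count >= floor else "rejected"
    return "extended" if repeat_count >= floor else "rejected"


def is_primitive(unit: str) -> bool:
    """True iff *unit* is not a whole-number tandem of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _runs_for_unit(s: str, u: int) -> Iterable[tuple[int, int]]:
    """Yield (start0, matched) maximal runs where s[i] == s[i+u].

    ``matched`` is the number of consecutive True positions; the tandem
    run spans ``matched + u`` bases starting at ``start0`` (0-based).
    """
    n = len(s)
    i = 0
    limit = n - u
    while i < limit:
        if s[i] == s[i + u] and s[i] in "ACGT":
            j = i
            while j < limit and s[j] == s[j + u] and s[j] in "ACGT":
                j += 1
            yield i, j - i
            i = j + 1
        else:
            i += 1


def scan_ssrs(bundle: GenomeBundle, config: ScanConfig | None = None) -> list[SsrLocus]:
    """Scan a genome for SSR loci.

    Overlapping loci with different primitive units are all retained
    (a T-homopolymer can abut an A-homopolymer as two separate loci).
    Names are assigned per type in positional order, zero-padded to
    7 digits. With ``circular_scan`` the sequence is scanned across the
    origin join and wrapped coordinates are reported modulo the length.
    """
    config = config or ScanConfig()
    seq = bundle.sequence
    n = seq.length
    if n < 10:
        raise ValueError("sequence shorter than 10 bp")
    s = seq.residues
    extended = s
    if config.circular_scan and seq.is_circular:
        # append one window so runs crossing the origin are seen once
        pad = min(n, max(1000, config.max_unit * 64))
        extended = s + s[:pad]

    found: list[tuple[int, str, int, int]] = []  # (start0, unit, count, ulen)
    for u in range(config.min_unit, config.max_unit + 1):
        for start0, matched in _runs_for_unit(extended, u):
            total = matched + u
            count = total // u
            unit = extended[start0 : start0 + u]
            if not is_primitive(unit):
                continue
            if classify_ssr(u, count, config) == "rejected":
                continue
            if start0 >= n:  # wrapped duplicate of a run fully in the first copy
                continue
            found.append((start0, unit, count, u))

    wrapped = [f for f in found if f[0] + f[2] * f[3] > n]
    if wrapped:
        # a run crossing the origin subsumes its truncated head/tail pieces
        def _posset(st: int, ln: int) -> frozenset[int]:
            return frozenset((st + k) % n for k in range(ln))

        wsets = [(u, _posset(st, c * u)) for st, _, c, u in wrapped]
        found = [
            f for f in found
            if f in wrapped
            or not any(u2 == f[3] and _posset(f[0], f[2] * f[3]) < ws for u2, ws in wsets)
        ]

    found.sort(key=lambda t: (t[0], t[3]))
    counters: Counter[int] = Counter()
    loci = []
    for start0, unit, count, u in found:
        counters[u] += 1
        name = f"{config.prefixes[u]}{counters[u]:07d}"
        end = start0 + count * u  # 0-based exclusive
        start1 = start0 + 1
        end1 = end
        if end1 > n:
            end1 -= n  # wrapped locus
        gene = assign_feature(start1, bundle) if bundle.features else ""
        loci.append(
            SsrLocus(name, unit, u, count, start1, end1,
                     classify_ssr(u, count, config), gene)
        )
    return loci


def ssr_census(loci: Iterable[SsrLocus]) -> dict[str, dict]:
    """Tally loci per tier and per unit-length type."""
    loci = list(loci)
    tiers = Counter(l.tier for l in loci)
    types = Counter(l.type_name for l in loci)
    return {
        "per_tier": {t: tiers.get(t, 0) for t in ("normal", "potential", "extended")},
        "per_type": {TYPE_NAMES[u]: types.get(TYPE_NAMES[u], 0) for u in range(1, 11)},
        "total": len(loci),
    }
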