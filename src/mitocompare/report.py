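"""Reproduction-suite driver: computed values vs. the published ones.

Given locally saved copies of the three WBPH mitogenome records
(MK907866 = WBPHTA, NC_021417 = WBPHHN, KC512915 = WBPHYN; see
``scripts/fetch_accessions.py``), this driver re-runs composition
statistics, pairwise variant calling, the SSR scan, and cross-genome
SSR grouping, and emits a side-by-side comparison table with a
pass/fail verdict per row. Missing inputs skip their rows with status
``unavailable``; the suite itself never fails on absent data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

from . import published
from .genome_io import GenomeBundle, read_annotations, read_fasta
from .skew_stats import composition
from .ssr_detect import scan_ssrs, ssr_census
from .ssr_group import build_groups, extract_flanks, group_report
from .variant_compare import align_pair, call_variants

GENOMES = ("WBPHTA", "WBPHHN", "WBPHYN")

#: tolerance policy per quantity class
TOL = {"exact_int": 0, "skew": 5e-6, "gc_percent": 0.05, "groups": 2}


@dataclass
class Row:
    quantity: str
    computed: object
    published: object
    status: str  # pass | fail | unavailable

    def to_dict(self) -> dict:
        return asdict(self)


def _verdict(computed: float, expected: float, tol: float) -> str:
    return "pass" if abs(computed - expected) <= tol else "fail"


def _load_bundle(name: str, paths: dict, annotation_paths: dict | None) -> GenomeBundle | None:
    p = paths.get(name)
    if p is None or not Path(p).exists():
        return None
    seq = read_fasta(p, circular=True)[0]
    seq = type(seq)(name, seq.residues, True)  # normalize label
    feats = []
    if annotation_paths and name in annotation_paths and Path(annotation_paths[name]).exists():
        ap = Path(annotation_paths[name])
        dialect = "gff3" if ap.suffix.lower() in {".gff", ".gff3"} else "tsv"
        feats = read_annotations(ap, dialect)
    return GenomeBundle(seq, feats, source=str(p))


def reproduce(accession_paths: dict[str, str | Path],
              annotation_paths: dict[str, str | Path] | None = None) -> dict:
    """Run the full comparison suite on locally saved records.

    Returns a JSON-serializable report: one row per published quantity
    with the recomputed value and a pass/fail verdict, plus input
    checksums for provenance.
    """
    bundles = {n: _load_bundle(n, accession_paths, annotation_paths) for n in GENOMES}
    rows: list[Row] = []
    stats = published.genome_stats().set_index("name")

    for name in GENOMES:
        b = bundles[name]
        exp = stats.loc[name]
        if b is None:
            rows.append(Row(f"{name}.length_bp", None, int(exp.length_bp), "unavailable"))
            continue
        comp = composition(b.sequence)
        n = b.sequence.length
        rows.append(Row(f"{name}.length_bp", n, int(exp.length_bp),
                        _verdict(n, exp.length_bp, TOL["exact_int"])))
        rows.append(Row(f"{name}.gc_percent", round(comp.gc_percent, 1), float(exp.gc_percent),
                        _verdict(round(comp.gc_percent, 1), exp.gc_percent, TOL["gc_percent"])))
        rows.append(Row(f"{name}.gc_skew", round(comp.gc_skew, 5), float(exp.gc_skew),
                        _verdict(comp.gc_skew, exp.gc_skew, TOL["skew"])))
        rows.append(Row(f"{name}.at_skew", round(comp.at_skew, 6), float(exp.at_skew),
                        _verdict(comp.at_skew, exp.at_skew, TOL["skew"])))

    for a, b in combinations(GENOMES, 2):
        exp_snps, exp_regions, exp_bp = published.PAIRWISE_VARIANTS[(a, b)]
        if bundles[a] is None or bundles[b] is None:
            rows.append(Row(f"{a}-{b}.snps", None, exp_snps, "unavailable"))
            continue
        vs = call_variants(align_pair(bundles[a].sequence, bundles[b].sequence), bundles[a])
        rows.append(Row(f"{a}-{b}.snps", len(vs.snps), exp_snps,
                        _verdict(len(vs.snps), exp_snps, TOL["exact_int"])))
        rows.append(Row(f"{a}-{b}.indel_regions", len(vs.indel_regions), exp_regions,
                        _verdict(len(vs.indel_regions), exp_regions, TOL["exact_int"])))
        rows.append(Row(f"{a}-{b}.indel_bp", vs.total_indel_bp, exp_bp,
                        _verdict(vs.total_indel_bp, exp_bp, TOL["exact_int"])))
        if {a, b} == {"WBPHTA", "WBPHYN"} and vs.indel_regions:
            longest = max(r.length for r in vs.indel_regions)
            rows.append(Row(f"{a}-{b}.longest_indel_bp", longest, published.LONGEST_INDEL_BP,
                            _verdict(longest, published.LONGEST_INDEL_BP, TOL["exact_int"])))

    if bundles["WBPHTA"] is not None:
        census = ssr_census(scan_ssrs(bundles["WBPHTA"]))
        for tier, exp_count in published.SSR_CENSUS.items():
            got = census["per_tier"][tier]
            rows.append(Row(f"WBPHTA.ssr_{tier}", got, exp_count,
                            _verdict(got, exp_count, TOL["exact_int"])))

    if all(bundles[n] is not None for n in GENOMES):
        flanked = [extract_flanks(l, bundles[n])
                   for n in GENOMES for l in scan_ssrs(bundles[n])]
        rep = group_report(build_groups(flanked))
        exp = published.GROUP_SUMMARY
        rows.append(Row("ssr_groups.total", rep["n_groups"], exp["n_groups"],
                        _verdict(rep["n_groups"], exp["n_groups"], TOL["groups"])))
        rows.append(Row("ssr_groups.common", rep["per_category"]["common"], exp["common"],
                        _verdict(rep["per_category"]["common"], exp["common"], TOL["groups"])))
        for cat in ("pairwise", "singleton"):
            rows.append(Row(f"ssr_groups.{cat}", rep["per_category"][cat], exp[cat],
                            _verdict(rep["per_category"][cat], exp[cat], TOL["exact_int"])))

    checksums = {}
    for name, p in (accession_paths or {}).items():
        p = Path(p)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return {
        "rows": [r.to_dict() for r in rows],
        "inputs": checksums,
        "n_pass": sum(r.status == "pass" for r in rows),
        "n_fail": sum(r.status == "fail" for r in rows),
        "n_unavailable": sum(r.status == "unavailable" for r in rows),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
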