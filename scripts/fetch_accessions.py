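#!/usr/bin/env python
"""Opt-in downloader for the three WBPH mitogenome records.

Fetches MK907866 (WBPHTA), NC_021417 (WBPHHN) and KC512915 (WBPHYN)
from NCBI E-utilities into ``data/accessions/`` so the reproduction
suite (``mitocompare reproduce``) and the record-dependent acceptance
tests can run. Requires network access; the library itself never
touches the network.

Usage:  python scripts/fetch_accessions.py [--outdir data/accessions]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["MK907866", "NC_021417", "KC512915"]
EUTILS = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype={rettype}&retmode=text")


def fetch(acc: str, rettype: str, dest: Path) -> None:
    url = EUTILS.format(acc=acc, rettype=rettype)
    print(f"fetching {acc} ({rettype}) ...", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=60) as resp:
        data = resp.read()
    if not data.strip():
        raise RuntimeError(f"empty response for {acc}")
    dest.write_bytes(data)
    print(f"  -> {dest} ({len(data)} bytes)", file=sys.stderr)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path,
                    default=Path(__file__).resolve().parent.parent / "data" / "accessions")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        fetch(acc, "fasta", args.outdir / f"{acc}.fasta")
        fetch(acc, "gb", args.outdir / f"{acc}.gb")


if __name__ == "__main__":
    main()
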