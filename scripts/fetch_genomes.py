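#!/usr/bin/env python
"""Download the seven Chloranthus plastome GenBank records from NCBI.

Writes data/chloranthus/<accession>.gb (about 1 MB total).  Needs network
access; run once before the real-genome reproduction test.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "MW581013": "Chloranthus angustifolius",
    "NC_082096": "Chloranthus nervosus",
    "NC_009598": "Chloranthus spicatus",
    "NC_026565": "Chloranthus japonicus",
    "NC_039627": "Chloranthus erectus",
    "MK922064": "Chloranthus henryi",
    "NC_065306": "Chloranthus fortunei",
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str) -> str:
    params = urllib.parse.urlencode({
        "db": "nuccore", "id": accession, "rettype": "gbwithparts",
        "retmode": "text",
    })
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=120) as resp:
        return resp.read().decode()


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "chloranthus"
    out_dir.mkdir(parents=True, exist_ok=True)
    for accession, species in ACCESSIONS.items():
        target = out_dir / f"{accession}.gb"
        if target.exists():
            print(f"{accession} ({species}): already present")
            continue
        print(f"{accession} ({species}): downloading ...")
        text = fetch(accession)
        if "LOCUS" not in text[:200]:
            print(f"  unexpected response for {accession}", file=sys.stderr)
            return 1
        target.write_text(text)
        time.sleep(0.5)  # NCBI rate courtesy
    print(f"done; records in {out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
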