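#!/usr/bin/env python
"""Fetch the deposited genome (accession MT511058) into data/ so the
optional accession-gated test can run.  Requires network access; the
core package and test suite never download anything themselves.

    python scripts/fetch_genome.py [--accession MT511058] [--out data/MT511058.fasta]
"""

import argparse
import urllib.request
from pathlib import Path

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={accession}&rettype=fasta&retmode=text"
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--accession", default="MT511058")
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()
    out = args.out or Path(__file__).resolve().parent.parent / "data" / f"{args.accession}.fasta"
    out.parent.mkdir(parents=True, exist_ok=True)
    url = EFETCH.format(accession=args.accession)
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as response:
        text = response.read().decode()
    if not text.startswith(">"):
        raise SystemExit("unexpected response (not FASTA)")
    out.write_text(text)
    print(f"wrote {out} ({len(text)} bytes)")


if __name__ == "__main__":
    main()
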