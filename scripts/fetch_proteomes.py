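"""Download the pinned UniProt reference proteomes used by the acceptance tests.

Usage:  python scripts/fetch_proteomes.py [--out data/proteomes]

Fetches one FASTA per reference-proteome accession from the UniProt REST
stream endpoint.  Needs network access; the library itself never downloads
anything.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "UP000002311": "Saccharomyces cerevisiae (S288c)",
    "UP000005640": "Homo sapiens",
    "UP000000803": "Drosophila melanogaster",
    "UP000002485": "Schizosaccharomyces pombe (972)",
    "UP000000625": "Escherichia coli (K12)",
}

URL = (
    "https://rest.uniprot.org/uniprotkb/stream?format=fasta"
    "&query=proteome:{accession}"
)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/proteomes", type=Path)
    parser.add_argument("--accessions", nargs="*", default=list(ACCESSIONS))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in args.accessions:
        dest = args.out / f"{acc}.fasta"
        if dest.exists():
            print(f"{acc}: already present at {dest}")
            continue
        print(f"{acc} ({ACCESSIONS.get(acc, '?')}): downloading ...")
        try:
            with urllib.request.urlopen(URL.format(accession=acc), timeout=300) as resp:
                data = resp.read()
        except OSError as exc:
            print(f"{acc}: download failed ({exc})", file=sys.stderr)
            return 1
        dest.write_bytes(data)
        print(f"{acc}: wrote {len(data)//1024} KiB to {dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
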