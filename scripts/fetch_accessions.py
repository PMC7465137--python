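"""Maintainer script: fetch the two UniProt reference sequences once.

Downloads the α-gliadin (Q9ZP09) and LMW glutenin subunit (P10386)
records and stores them under tests/fixtures/ so the library and test
suite never need network access at runtime.  Run from the repository
root on a machine with internet access:

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ("Q9ZP09", "P10386")
FIXTURE_DIR = Path(__file__).resolve().parent.parent / "tests" / "fixtures"


def main() -> int:
    FIXTURE_DIR.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
        dest = FIXTURE_DIR / f"{acc}.fasta"
        print(f"fetching {url} -> {dest}")
        with urllib.request.urlopen(url, timeout=30) as resp:
            dest.write_bytes(resp.read())
    return 0


if __name__ == "__main__":
    sys.exit(main())
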