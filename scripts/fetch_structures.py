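#!/usr/bin/env python
"""Download the PDB entries used by the optional crystal-structure tests.

Usage:  python scripts/fetch_structures.py [--dest structures/]

Fetches 1H3T, 1KGC, 2CDF, 1HXM, 1OW0, 2WAH and 5M3V (mmCIF) from the
RCSB file server.  Network access is required; the core test suite
does not depend on these files.
"""

import argparse
import sys
import urllib.request
from pathlib import Path

CODES = ["1H3T", "1KGC", "2CDF", "1HXM", "1OW0", "2WAH", "5M3V"]
URL = "https://files.rcsb.org/download/{code}.cif"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", default="structures")
    args = parser.parse_args()
    dest = Path(args.dest)
    dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for code in CODES:
        out = dest / f"{code}.cif"
        if out.exists():
            print(f"{code}: already present")
            continue
        try:
            urllib.request.urlretrieve(URL.format(code=code), out)
            print(f"{code}: fetched -> {out}")
        except Exception as exc:
            failures += 1
            print(f"{code}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
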