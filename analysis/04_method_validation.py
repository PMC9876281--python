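#!/usr/bin/env python
"""Validation of the core algorithms and of parameter recovery.

Summarizes (a) agreement of the affine aligner, neighbor joining, motif
scanners, and contact census with independent brute-force oracles, and
(b) recovery of simulation truth (motif statuses, frozen columns, tree
bipartitions) over 20 replicates of the default 24-taxon configuration.
Writes results/validation.tsv. These are the same computations the
acceptance script performs; this driver exists to read them as a table.
"""

import json
import subprocess
import sys
import tempfile
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "acceptance.json"
        subprocess.run(
            [sys.executable, str(ROOT / "scripts" / "acceptance.py"),
             "--seed", "1", "--out", str(out)],
            check=True, stdout=subprocess.DEVNULL)
        numbers = json.loads(out.read_text())
    table = pd.DataFrame(
        [{"quantity": k, "value": v["value"], "n": v["n"]}
         for k, v in numbers.items()])
    dest = ROOT / "results" / "validation.tsv"
    dest.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(dest, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nwritten to {dest}")


if __name__ == "__main__":
    main()
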