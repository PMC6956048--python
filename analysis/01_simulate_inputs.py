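"""Generate the five-group synthetic study dataset.

Writes, under results/data/: three TEM-style micrographs (16-bit TIFF + truth
sidecar) per group, six tensile records and three DSC scans per group, and one
qPCR Ct table — all from the shipped preset, fully determined by --seed.
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    from corneaquant.cli import main as cli_main

    for stage in ("tem", "tensile", "dsc", "qpcr"):
        out = DATA / stage
        out.mkdir(parents=True, exist_ok=True)
        rc = cli_main.main(
            ["simulate", stage, "--seed", str(args.seed), "--out", str(out)],
            standalone_mode=False,
        )
        if rc not in (0, None):
            sys.exit(rc)
    n_files = sum(1 for _ in DATA.rglob("*") if _.is_file())
    print(f"wrote {n_files} files under {DATA}")


if __name__ == "__main__":
    main()
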