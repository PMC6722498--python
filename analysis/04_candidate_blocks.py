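#!/usr/bin/env python
"""Nominate candidate loci as SNP blocks from the scan's p-value track.

A block is a run of >= 3 SNPs with p < 1e-3, consecutive candidates less
than 30 kb apart, at least 2 members below 1e-4; the minimum-p member of
each block is its index SNP.
"""

import argparse
from pathlib import Path

import pandas as pd

from endoxpred.blocks import blocks_to_frame, find_blocks, select_index_snps


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scan", type=Path, default=Path("results/scan.tsv"))
    parser.add_argument("--gap", type=int, default=30_000)
    args = parser.parse_args()

    track = pd.read_csv(args.scan, sep="\t", comment="#")[["snp_id", "chrom", "pos", "p"]]
    blocks = find_blocks(track, gap_max=args.gap)
    frame = blocks_to_frame(blocks)
    out = args.scan.parent / "blocks.tsv"
    frame.to_csv(out, sep="\t", index=False)
    index_snps = select_index_snps(blocks)
    (args.scan.parent / "index_snps.txt").write_text("\n".join(index_snps) + ("\n" if index_snps else ""))

    print(f"{len(blocks)} qualifying blocks -> {out}")
    if len(frame):
        print(frame.to_string(index=False))
    print(f"index SNPs: {index_snps}")


if __name__ == "__main__":
    main()
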