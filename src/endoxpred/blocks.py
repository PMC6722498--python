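"""Candidate-locus selection from a GWAS p-value track.

A locus is nominated when associated SNPs form a block: a maximal
per-chromosome run of SNPs with p < ``p_block`` in which every gap between
position-adjacent candidate SNPs is strictly less than ``gap_max`` bp, the
run has at least ``min_size`` members, and at least ``min_core`` of them
reach p < ``p_core``. The member with the smallest p-value is the block's
index SNP (ties broken toward the lower position). Non-candidate SNPs lying
between candidates are ignored: the gap rule is evaluated over the
candidates only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class BlockError(ValueError):
    """Invalid block-finder input."""


@dataclass(frozen=True)
class Block:
    chrom: str
    snp_ids: tuple[str, ...]  # position-ordered members
    positions: tuple[int, ...]
    p_values: tuple[float, ...]
    span_bp: int
    n_below_block: int  # members with p < p_block
    n_below_core: int  # members with p < p_core
    index_snp: str


def find_blocks(
    snps: pd.DataFrame,
    p_block: float = 1e-3,
    p_core: float = 1e-4,
    gap_max: int = 30_000,
    min_size: int = 3,
    min_core: int = 2,
) -> list[Block]:
    """Find qualifying SNP blocks in a (snp_id, chrom, pos, p) track.

    Candidates (p < ``p_block``) are position-sorted per chromosome and split
    into runs wherever the gap between consecutive candidates is >=
    ``gap_max`` (a gap of exactly ``gap_max`` splits). Runs with >=
    ``min_size`` members of which >= ``min_core`` have p < ``p_core`` are
    returned as blocks, position-sorted.
    """
    required = {"snp_id", "chrom", "pos", "p"}
    if not required <= set(snps.columns):
        raise BlockError(f"track needs columns {sorted(required)}")
    if ((snps["p"] <= 0) | (snps["p"] > 1)).any():
        raise BlockError("p-values must lie in (0, 1]")
    if snps.duplicated(subset=["chrom", "pos"]).any():
        raise BlockError("duplicate (chrom, pos) in track")
    blocks: list[Block] = []
    candidates = snps[snps["p"] < p_block]
    for chrom, group in candidates.groupby("chrom", sort=True):
        group = group.sort_values("pos", kind="mergesort")
        run: list[tuple[str, int, float]] = []
        prev_pos: int | None = None
        for _, rec in group.iterrows():
            pos = int(rec["pos"])
            if prev_pos is not None and pos - prev_pos >= gap_max:
                _emit(run, str(chrom), p_core, min_size, min_core, blocks)
                run = []
            run.append((str(rec["snp_id"]), pos, float(rec["p"])))
            prev_pos = pos
        _emit(run, str(chrom), p_core, min_size, min_core, blocks)
    blocks.sort(key=lambda b: (b.chrom, b.positions[0]))
    return blocks


def _emit(run, chrom: str, p_core: float, min_size: int, min_core: int, out: list[Block]) -> None:
    if len(run) < min_size:
        return
    n_core = sum(1 for _, _, p in run if p < p_core)
    if n_core < min_core:
        return
    ids, positions, ps = zip(*run)
    index = min(range(len(run)), key=lambda i: (ps[i], positions[i]))
    out.append(
        Block(
            chrom=chrom,
            snp_ids=ids,
            positions=positions,
            p_values=ps,
            span_bp=positions[-1] - positions[0],
            n_below_block=len(run),
            n_below_core=n_core,
            index_snp=ids[index],
        )
    )


def select_index_snps(blocks: list[Block]) -> list[str]:
    """Index SNP (minimum p, ties to the lower position) per block."""
    return [b.index_snp for b in blocks]


def blocks_to_frame(blocks: list[Block]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.positions[0] for b in blocks],
            "end": [b.positions[-1] for b in blocks],
            "span_bp": [b.span_bp for b in blocks],
            "n_snps": [len(b.snp_ids) for b in blocks],
            "n_core": [b.n_below_core for b in blocks],
            "index_snp": [b.index_snp for b in blocks],
            "members": [",".join(b.snp_ids) for b in blocks],
        }
    )
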