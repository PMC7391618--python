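"""4-SNP haplotype blocks as multi-allelic markers.

SNP-array panels are ascertained on a handful of discovery breeds, which
biases single-SNP diversity estimates. Grouping consecutive SNPs into
short blocks and treating the 4-symbol haplotype words as alleles of one
multi-allelic marker reduces this bias while keeping within-block
recombination negligible: a block must span less than ``max_span`` bp
(default 150 kb) with every adjacent within-block gap shorter than
``max_gap`` bp (default 50 kb). Blocks never span chromosomes and never
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataError, HaplotypeMatrix, MarkerMap

__all__ = ["BlockDefinition", "BlockGenotypes", "build_blocks",
           "encode_block_alleles", "blocks_to_frame"]


@dataclass(frozen=True)
class BlockDefinition:
    """One block: chromosome, the member SNP indices (map order), bp span."""

    block_id: str
    chromosome: str
    snp_indices: tuple[int, ...]
    start_bp: int
    end_bp: int

    @property
    def span(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class BlockGenotypes:
    """Per-individual ordered block-allele pairs.

    ``alleles`` has shape (n_individuals, n_blocks, 2); each entry is a
    block allele encoded as an integer whose base-2 digits are the member
    SNP alleles in map order (word "0101" -> 5). The stored order is the
    haplotype order; all counting treats the pair as unordered.
    """

    individuals: list[str]
    blocks: list[BlockDefinition]
    alleles: np.ndarray
    block_size: int = 4

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles)
        if a.shape != (len(self.individuals), len(self.blocks), 2):
            raise DataError("block genotype array shape mismatch")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def word(self, code: int) -> str:
        return format(int(code), f"0{self.block_size}b")


def build_blocks(
    markers: MarkerMap,
    block_size: int = 4,
    max_span: int = 150_000,
    max_gap: int = 50_000,
    slide: bool = True,
) -> list[BlockDefinition]:
    """Tile each chromosome into non-overlapping blocks, greedily.

    A left-to-right scan considers the next ``block_size`` unconsumed
    consecutive SNPs: if the window spans less than ``max_span`` and every
    adjacent gap is shorter than ``max_gap`` (both strict), the block is
    emitted and all its SNPs consumed; otherwise the start advances by one
    SNP (``slide=True``, default) or past the whole window
    (``slide=False``).
    """
    blocks: list[BlockDefinition] = []
    chrom = markers.chromosome
    pos = markers.position_bp
    n = len(markers)
    start = 0
    while start <= n - block_size:
        end = start + block_size  # candidate window [start, end)
        if chrom[start] != chrom[end - 1]:
            start += 1
            continue
        window = pos[start:end]
        gaps = np.diff(window)
        if window[-1] - window[0] < max_span and (gaps < max_gap).all():
            blocks.append(
                BlockDefinition(
                    block_id=f"blk{len(blocks) + 1}",
                    chromosome=str(chrom[start]),
                    snp_indices=tuple(range(start, end)),
                    start_bp=int(window[0]),
                    end_bp=int(window[-1]),
                )
            )
            start = end
        else:
            start += 1 if slide else block_size
    return blocks


def encode_block_alleles(
    h: HaplotypeMatrix, blocks: list[BlockDefinition]
) -> BlockGenotypes:
    """Concatenate member-SNP alleles of each haplotype into block alleles."""
    if not blocks:
        raise DataError("no blocks to encode")
    size = len(blocks[0].snp_indices)
    weights = 1 << np.arange(size - 1, -1, -1)  # first SNP = most significant
    codes = np.empty((h.n_individuals, len(blocks), 2), dtype=np.int32)
    a = h.alleles
    for b, blk in enumerate(blocks):
        cols = np.asarray(blk.snp_indices)
        word = a[:, cols].astype(np.int32) @ weights  # per haplotype row
        codes[:, b, 0] = word[0::2]
        codes[:, b, 1] = word[1::2]
    return BlockGenotypes(list(h.individuals), list(blocks), codes,
                          block_size=size)


def blocks_to_frame(blocks: list[BlockDefinition],
                    markers: MarkerMap) -> pd.DataFrame:
    """BED-like table (chrom, start-1, end, block_id, member snp ids)."""
    return pd.DataFrame(
        {
            "chrom": [b.chromosome for b in blocks],
            "start": [b.start_bp - 1 for b in blocks],
            "end": [b.end_bp for b in blocks],
            "block_id": [b.block_id for b in blocks],
            "snp_ids": [
                ",".join(markers.snp_id[list(b.snp_indices)]) for b in blocks
            ],
        }
    )
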