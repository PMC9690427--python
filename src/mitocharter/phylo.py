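"""Concatenated amino-acid supermatrix preparation and a smoke tree.

Per-gene alignments come in as equal-length amino-acid blocks per taxon
(alignment itself is upstream of this package); they are concatenated in
a fixed canonical gene order with 1-based inclusive partition
bookkeeping, optionally cleaned with a transparent gap-fraction column
filter, and can be summarised as an uncorrected p-distance matrix and a
neighbor-joining tree for topology sanity checks.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

logger = logging.getLogger("mitocharter")

__all__ = [
    "CANONICAL_GENE_ORDER", "Supermatrix", "build_supermatrix",
    "filter_gap_columns", "p_distance_matrix", "nj_tree",
    "write_phylip", "write_partitions",
]

# fixed concatenation order for the 13 mitochondrial PCGs
CANONICAL_GENE_ORDER = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "nad4l",
    "atp6", "atp8",
)

GAP = "-"


@dataclass
class Supermatrix:
    """Equal-length amino-acid rows with a partition table.

    ``partitions`` maps gene token -> (first, last) column, 1-based
    inclusive; partitions tile [1, row length] without overlap.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
        width = self.width
        covered = 0
        prev_end = 0
        for gene, (a, b) in self.partitions.items():
            if not (1 <= a <= b <= width) or a != prev_end + 1:
                raise ValueError(f"partition {gene} = {a}-{b} does not tile")
            covered += b - a + 1
            prev_end = b
        if self.partitions and covered != width:
            raise ValueError("partitions do not cover the matrix")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def gene_slice(self, gene: str) -> dict[str, str]:
        a, b = self.partitions[gene]
        return {t: r[a - 1:b] for t, r in zip(self.taxa, self.rows)}


def build_supermatrix(per_gene_blocks: Mapping[str, Mapping[str, str]]
                      ) -> Supermatrix:
    """Concatenate per-gene aligned amino-acid blocks into one matrix.

    ``per_gene_blocks``: gene token -> {taxon: row}; every block must be
    internally equal-length. Genes are concatenated in
    :data:`CANONICAL_GENE_ORDER` (genes outside it follow, sorted). A
    taxon missing from a block receives an all-gap row (logged).
    """
    if not per_gene_blocks:
        raise ValueError("no gene blocks given")
    order = [g for g in CANONICAL_GENE_ORDER if g in per_gene_blocks]
    order += sorted(set(per_gene_blocks) - set(order))
    taxa = tuple(sorted({t for block in per_gene_blocks.values()
                         for t in block}))
    pieces = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene in order:
        block = per_gene_blocks[gene]
        widths = {len(r) for r in block.values()}
        if len(widths) != 1:
            raise ValueError(f"ragged block for gene {gene}: "
                             f"row lengths {sorted(widths)}")
        w = widths.pop()
        if w == 0:
            raise ValueError(f"empty block for gene {gene}")
        for t in taxa:
            if t in block:
                pieces[t].append(block[t])
            else:
                logger.warning("taxon %s missing from gene %s: gap-filled",
                               t, gene)
                pieces[t].append(GAP * w)
        partitions[gene] = (col + 1, col + w)
        col += w
    rows = tuple("".join(pieces[t]) for t in taxa)
    return Supermatrix(taxa=taxa, rows=rows, partitions=partitions)


def filter_gap_columns(matrix: Supermatrix, max_gap_fraction: float = 0.5
                       ) -> tuple[Supermatrix, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the filtered matrix (partition intervals recomputed) and the
    1-based indices of removed columns. Idempotent at a fixed threshold.
    This is a deliberately transparent stand-in for block-based alignment
    trimmers: it removes gap-rich columns only, not poorly conserved
    blocks.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n = len(matrix.taxa)
    keep, removed = [], []
    for j in range(matrix.width):
        gaps = sum(1 for r in matrix.rows if r[j] == GAP)
        (keep if gaps / n <= max_gap_fraction else removed).append(j)
    keep_set = set(keep)
    rows = tuple("".join(r[j] for j in keep) for r in matrix.rows)
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene, (a, b) in matrix.partitions.items():
        w = sum(1 for j in range(a - 1, b) if j in keep_set)
        if w:
            partitions[gene] = (col + 1, col + w)
            col += w
        else:
            logger.warning("gene %s lost all columns in gap filtering", gene)
    return (Supermatrix(taxa=matrix.taxa, rows=rows, partitions=partitions),
            [j + 1 for j in removed])


def p_distance_matrix(matrix: Supermatrix) -> DistanceMatrix:
    """Pairwise uncorrected p-distances over shared non-gap columns.

    For each taxon pair: the proportion of differing columns among the
    columns where neither row has a gap. Pairs sharing no such column
    get distance 0 (logged).
    """
    if len(matrix.taxa) < 2:
        raise ValueError("p-distance needs >= 2 taxa")
    arr = np.array([list(r) for r in matrix.rows])
    n = len(matrix.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] != GAP) & (arr[j] != GAP)
            m = int(shared.sum())
            if m == 0:
                logger.warning("taxa %s and %s share no ungapped column",
                               matrix.taxa[i], matrix.taxa[j])
                continue
            diff = int((arr[i][shared] != arr[j][shared]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, ids=list(matrix.taxa))


def nj_tree(distances: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    A smoke-test tree for topology sanity checks, not a substitute for
    model-based inference. Taxa are presented in sorted label order so
    agglomeration tie-breaking is deterministic.
    """
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ids = sorted(distances.ids)
    dm = distances.filter(ids)
    tree = _skbio_nj(dm)
    return str(tree).strip()


# --------------------------------------------------------------------------
# Writers

def write_phylip(matrix: Supermatrix) -> str:
    """Relaxed PHYLIP rendering (taxon name, two spaces, full row)."""
    out = io.StringIO()
    out.write(f" {len(matrix.taxa)} {matrix.width}\n")
    for t, r in zip(matrix.taxa, matrix.rows):
        out.write(f"{t.replace(' ', '_')}  {r}\n")
    return out.getvalue()


def write_partitions(matrix: Supermatrix) -> str:
    """RAxML-style partition lines, e.g. ``AA, cox1 = 1-516``."""
    return "".join(f"AA, {gene} = {a}-{b}\n"
                   for gene, (a, b) in matrix.partitions.items())
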