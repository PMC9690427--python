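"""Seeded generators of annotated circular mitogenomes and related data.

The simulator emulates the study system: a circular genome with the
canonical 37-gene complement laid out on two strands, AT-biased base
composition with controllable skew, ATG starts and TAA/TAG stops for
every protein-coding gene, mostly short intergenic gaps plus one long
non-coding spacer, plus gene-order rearrangement and low-divergence
amino-acid family generators for ground-truth recovery tests.

All randomness flows through one numpy Generator derived from the
spec's seed; identical spec + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from skbio import TreeNode
import io

from .codon import GeneticCode, default_code, translate
from .gene_order import RearrangementOp, SignedGeneOrder, apply_op
from .model import (
    GeneFeature, MitoAnnotation, MitoGenome, category_of, reverse_complement,
)

__all__ = ["GenomeSpec", "default_template", "simulate_genome",
           "apply_rearrangement", "random_reversal", "evolve_family"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def default_template() -> SignedGeneOrder:
    """The packaged reference gene order (all 37 genes with strands)."""
    from .fixtures import load_erumphii
    from .gene_order import extract_order
    return extract_order(load_erumphii(), subset="all")


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one simulated mitogenome.

    Lengths are bp ranges per gene category (PCG lengths are multiples
    of 3); ``at_content`` and ``at_skew`` are sense-strand base
    composition targets; most intergenic gaps are short but the gene
    named by ``spacer_before`` is preceded by one long non-coding
    spacer. Genome length is emergent from lengths plus gaps.
    """

    template: Optional[SignedGeneOrder] = None   # None -> packaged order
    pcg_length_range: tuple[int, int] = (165, 1731)
    trna_length_range: tuple[int, int] = (60, 75)
    rrna_length_range: tuple[int, int] = (700, 1500)
    gap_range: tuple[int, int] = (0, 30)
    spacer_range: tuple[int, int] = (200, 400)
    spacer_before: str = "cox3"
    at_content: float = 0.65
    at_skew: float = 0.08
    gc_skew: float = -0.17
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.pcg_length_range, self.trna_length_range,
                       self.rrna_length_range, self.spacer_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.gap_range[0] < 0 or self.gap_range[1] < self.gap_range[0]:
            raise ValueError("gap range must be non-negative and ordered")
        if not 0 < self.at_content < 1:
            raise ValueError("at_content must be in (0, 1)")


def _base_probs(spec: GenomeSpec) -> np.ndarray:
    at, gc = spec.at_content, 1.0 - spec.at_content
    return np.array([
        at * (1 + spec.at_skew) / 2,   # A
        gc * (1 - spec.gc_skew) / 2,   # C
        gc * (1 + spec.gc_skew) / 2,   # G
        at * (1 - spec.at_skew) / 2,   # T
    ])


_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)])


def _random_cds(rng: np.random.Generator, length: int, probs: np.ndarray,
                code: GeneticCode) -> str:
    """ATG + biased non-stop codons + a random stop; length multiple of 3."""
    assert length % 3 == 0 and length >= 9
    stops = code.stop_codons
    body = []
    while len(body) < length // 3 - 2:
        codon = _random_bases(rng, 3, probs)
        if codon not in stops:
            body.append(codon)
    stop = ["TAA", "TAG"][int(rng.integers(2))]
    return "ATG" + "".join(body) + stop


def simulate_genome(spec: GenomeSpec) -> MitoGenome:
    """Generate one annotated circular mitogenome from a spec.

    The annotation honours the template's gene order and strands; every
    PCG starts with ATG and ends with TAA/TAG on its sense strand, with
    no internal stop under the invertebrate mitochondrial code; the
    reference-strand AT content tracks the target (A<->T pairing makes
    AT content strand-invariant).
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template or default_template()
    probs = _base_probs(spec)
    code = default_code()

    lo3, hi3 = spec.pcg_length_range
    pcg_choices = np.arange((lo3 + 2) // 3, hi3 // 3 + 1) * 3

    pieces: list[str] = []        # reference-strand chunks, in genome order
    features: list[GeneFeature] = []
    pos = 1
    spacer_gene = spec.spacer_before if spec.spacer_before in {
        g for g, _ in template.genes} else template.genes[0][0]
    first = True
    first_gap = 0
    for gene, sign in template.genes:
        if gene == spacer_gene:
            gap = int(rng.integers(spec.spacer_range[0],
                                   spec.spacer_range[1] + 1))
        else:
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
        if first:
            # the first feature's gap becomes the tail of the circle
            first_gap = gap
            gap = 0
            first = False
        if gap:
            pieces.append(_random_bases(rng, gap, probs))
            pos += gap
        cat = category_of(gene)
        if cat == "PCG":
            length = int(rng.choice(pcg_choices))
            sense = _random_cds(rng, length, probs, code)
        elif cat == "tRNA":
            length = int(rng.integers(spec.trna_length_range[0],
                                      spec.trna_length_range[1] + 1))
            sense = _random_bases(rng, length, probs)
        else:
            length = int(rng.integers(spec.rrna_length_range[0],
                                      spec.rrna_length_range[1] + 1))
            sense = _random_bases(rng, length, probs)
        strand = "H" if sign > 0 else "L"
        pieces.append(sense if strand == "H" else reverse_complement(sense))
        features.append(GeneFeature(
            name=gene, start=pos, end=pos + length - 1, strand=strand,
            start_codon=sense[:3] if cat == "PCG" else None,
            stop_codon=sense[-3:] if cat == "PCG" else None,
        ))
        pos += length
    if first_gap:
        pieces.append(_random_bases(rng, first_gap, probs))
        pos += first_gap
    genome_length = pos - 1
    annotation = MitoAnnotation(
        genome_length=genome_length, features=features, circular=True,
        organism=f"simulated mitogenome (seed {spec.seed})")
    return MitoGenome(annotation=annotation, sequence="".join(pieces))


# --------------------------------------------------------------------------
# Rearrangements

def apply_rearrangement(order: SignedGeneOrder, op: RearrangementOp
                        ) -> tuple[SignedGeneOrder, RearrangementOp]:
    """Apply a rearrangement; returns (new order, ground-truth record)."""
    return apply_op(order, op), op


def random_reversal(order: SignedGeneOrder,
                    rng: Union[int, np.random.Generator]) -> RearrangementOp:
    """A uniformly random segment reversal (never the full circle)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(order)
    while True:
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        i, j = min(i, j), max(i, j)
        if not (i == 0 and j == n - 1):
            return RearrangementOp("reversal", (i, j))


# --------------------------------------------------------------------------
# Sequence families for supermatrix recovery tests

def evolve_family(genome: MitoGenome, tree: str, rate: float = 0.01,
                  seed: int = 0) -> dict[str, dict[str, str]]:
    """Evolve the genome's translated PCGs along a Newick tree.

    Each protein is placed at the root and substituted site-wise along
    every branch: a site changes with probability min(1, rate x branch
    length) to a uniformly drawn different amino acid. No indels, so the
    per-gene blocks stay aligned and gap-free. Returns gene token ->
    {tip label: amino-acid row}.
    """
    if genome.sequence is None:
        raise ValueError("sequence required to evolve a family")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    root = TreeNode.read(io.StringIO(tree))
    tips = [t.name for t in root.tips()]
    if len(tips) != len(set(tips)) or any(t is None for t in tips):
        raise ValueError("tree tips must carry unique labels")

    code = default_code()
    roots = {}
    for f in genome.annotation.by_category("PCG"):
        roots[f.name] = translate(genome.feature_sequence(f), code)

    def _mutate(seq: str, blen: float) -> str:
        p = min(1.0, rate * blen)
        if p == 0:
            return seq
        arr = list(seq)
        hits = np.nonzero(rng.random(len(arr)) < p)[0]
        for idx in hits:
            choices = [a for a in AA20 if a != arr[idx]]
            arr[idx] = choices[int(rng.integers(len(choices)))]
        return "".join(arr)

    blocks: dict[str, dict[str, str]] = {g: {} for g in roots}
    for gene, root_seq in roots.items():
        stack = [(root, root_seq)]
        while stack:
            node, seq = stack.pop()
            for child in node.children:
                blen = child.length if child.length is not None else 1.0
                child_seq = _mutate(seq, blen)
                if child.is_tip():
                    blocks[gene][child.name] = child_seq
                else:
                    stack.append((child, child_seq))
    return blocks
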