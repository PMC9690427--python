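"""Genome-organization statistics for circular annotations.

The central object is the *gap ledger*: for every feature, the signed
intergenic distance to the preceding feature on the circle. A positive
gap is an intergenic spacer, zero means the genes abut, and a negative
gap is an overlap of adjacent features. The ledger closes the circle:

    sum(feature lengths) + sum(signed gaps) == genome length
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import GeneFeature, MitoAnnotation

__all__ = [
    "GapEntry", "GapLedger", "gap_ledger", "count_intergenic",
    "count_overlaps", "strand_tally", "length_extremes",
    "organization_report",
]


@dataclass(frozen=True)
class GapEntry:
    gene: str
    gap: Optional[int]        # signed bp preceding the gene; None if undefined
    preceded_by: Optional[str]


@dataclass
class GapLedger:
    entries: list[GapEntry]
    genome_length: int

    def gaps(self) -> list[int]:
        return [e.gap for e in self.entries if e.gap is not None]


def gap_ledger(annotation: MitoAnnotation) -> GapLedger:
    """Signed gap preceding every feature, with circular wrap.

    For feature i > 0 (genome order): gap = start(i) - end(i-1) - 1.
    For the first feature on a circular genome the gap wraps:
    (genome_length - end(last)) + (start(first) - 1). On a linear
    annotation the first feature's gap is undefined (None).
    """
    feats = annotation.features
    if not feats:
        raise ValueError("gap ledger needs at least one feature")
    n = annotation.genome_length
    entries = []
    for i, f in enumerate(feats):
        if i == 0:
            if annotation.circular:
                last = feats[-1]
                if last.wraps_origin():
                    # the last feature already crossed the origin: its end
                    # sits just before this feature on the circle
                    gap = f.start - last.end - 1
                else:
                    gap = (n - last.end) + (f.start - 1)
                prev = last.name if len(feats) > 1 else f.name
            else:
                gap, prev = None, None
        else:
            prev_f = feats[i - 1]
            gap = f.start - prev_f.end - 1
            prev = prev_f.name
        entries.append(GapEntry(gene=f.name, gap=gap, preceded_by=prev))
    return GapLedger(entries=entries, genome_length=n)


def count_intergenic(ledger: GapLedger) -> tuple[int, Optional[int], Optional[int]]:
    """(number of strictly positive gaps, min positive, max positive).

    Zero gaps are neither spacers nor overlaps; overlaps are the
    strictly negative entries.
    """
    positive = [g for g in ledger.gaps() if g > 0]
    if not positive:
        return 0, None, None
    return len(positive), min(positive), max(positive)


def count_overlaps(ledger: GapLedger) -> list[GapEntry]:
    """The strictly negative ledger entries (adjacent-feature overlaps)."""
    return [e for e in ledger.entries if e.gap is not None and e.gap < 0]


def strand_tally(annotation: MitoAnnotation) -> pd.DataFrame:
    """Feature counts by category x strand (rows PCG/tRNA/rRNA, cols H/L)."""
    table = pd.DataFrame(0, index=["PCG", "tRNA", "rRNA"], columns=["H", "L"])
    for f in annotation.features:
        table.loc[f.category, f.strand] += 1
    return table


def length_extremes(annotation: MitoAnnotation, category: str
                    ) -> Optional[tuple[GeneFeature, GeneFeature]]:
    """Shortest and longest feature of a category; length ties are broken
    by the lexicographically first gene token, so the result is
    deterministic. None when the category is absent."""
    feats = annotation.by_category(category)
    if not feats:
        return None
    n, circ = annotation.genome_length, annotation.circular
    lengths = {f.name: f.length(n, circ) for f in feats}
    lo, hi = min(lengths.values()), max(lengths.values())
    shortest = min(
        (f for f in feats if lengths[f.name] == lo), key=lambda f: f.name)
    longest = min(
        (f for f in feats if lengths[f.name] == hi), key=lambda f: f.name)
    return shortest, longest


def organization_report(annotation: MitoAnnotation) -> pd.DataFrame:
    """Feature table in genome order with recomputed Length and Intergenic.

    Column layout follows the standard mitogenome-organization table:
    Gene, From, To, Length, Start, Stop, Anticodon, Intergenic, Strand.
    """
    columns = ["Gene", "From", "To", "Length", "Start", "Stop",
               "Anticodon", "Intergenic", "Strand"]
    if not annotation.features:
        return pd.DataFrame(columns=columns)
    gaps = {e.gene: e.gap for e in gap_ledger(annotation).entries}
    rows = []
    for f in annotation.features:
        rows.append({
            "Gene": f.name, "From": f.start, "To": f.end,
            "Length": f.length(annotation.genome_length, annotation.circular),
            "Start": f.start_codon or "", "Stop": f.stop_codon or "",
            "Anticodon": f.anticodon or "",
            "Intergenic": gaps.get(f.name), "Strand": f.strand,
        })
    return pd.DataFrame(rows, columns=columns)
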