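"""Nucleotide composition, AT/GC content and strand-asymmetry skews.

AT skew = (A - T) / (A + T); GC skew = (G - C) / (G + C). Both are
dimensionless in [-1, 1] and antisymmetric under reverse complement.
AT content = A% + T% and is strand-invariant. IUPAC ambiguity codes are
excluded from counts and from every denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import MitoGenome

__all__ = [
    "CompositionStats", "base_composition", "skews_from_percentages",
    "regional_composition", "composition_report",
]

_AMBIGUOUS = set("RYSWKMBDHVN")


def _skew(x: float, y: float) -> Optional[float]:
    return (x - y) / (x + y) if (x + y) else None


@dataclass(frozen=True)
class CompositionStats:
    """Base counts and derived composition statistics for one region."""

    a: int
    c: int
    g: int
    t: int
    ambiguous: int = 0

    @property
    def total(self) -> int:
        """Unambiguous base count (the denominator for percentages)."""
        return self.a + self.c + self.g + self.t

    def pct(self, base: str) -> float:
        return 100.0 * getattr(self, base.lower()) / self.total

    @property
    def at_content(self) -> float:
        """A% + T%, in percent."""
        return self.pct("a") + self.pct("t")

    @property
    def at_skew(self) -> Optional[float]:
        return _skew(self.a, self.t)

    @property
    def gc_skew(self) -> Optional[float]:
        return _skew(self.g, self.c)


def base_composition(seq: str) -> CompositionStats:
    """Single-pass composition of a DNA string (case-insensitive).

    Ambiguity codes are tallied separately; anything outside the IUPAC
    alphabet raises. Empty input raises: every statistic would be
    undefined.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    ambiguous = 0
    for base, k in counts.items():
        if base in "ACGT":
            continue
        if base in _AMBIGUOUS:
            ambiguous += k
        else:
            raise ValueError(f"non-IUPAC character {base!r} in sequence")
    return CompositionStats(a=counts.get("A", 0), c=counts.get("C", 0),
                            g=counts.get("G", 0), t=counts.get("T", 0),
                            ambiguous=ambiguous)


def skews_from_percentages(a_pct: float, t_pct: float, g_pct: float,
                           c_pct: float
                           ) -> tuple[Optional[float], Optional[float], float]:
    """(AT skew, GC skew, AT content) from printed base percentages.

    Lets a published composition table be recomputed from its own
    percentage columns. Zero denominators yield None.
    """
    if min(a_pct, t_pct, g_pct, c_pct) < 0:
        raise ValueError("percentages must be non-negative")
    return _skew(a_pct, t_pct), _skew(g_pct, c_pct), a_pct + t_pct


def regional_composition(genome: MitoGenome,
                         selection: Union[str, Sequence[str]],
                         strand_policy: str = "sense") -> CompositionStats:
    """Composition over a set of features of one genome.

    ``selection`` is a category name ("PCG", "tRNA", "rRNA"), the string
    "all", or an iterable of gene tokens. Under the default
    ``strand_policy="sense"`` each feature contributes its sense-strand
    sequence (reverse complement for L-strand genes); under
    ``"reference"`` the deposited strand is used as-is. Features are
    concatenated in genome order.
    """
    if genome.sequence is None:
        raise ValueError("sequence required for regional composition")
    if strand_policy not in ("sense", "reference"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    ann = genome.annotation
    if isinstance(selection, str):
        if selection == "all":
            feats = list(ann.features)
        else:
            feats = ann.by_category(selection)
    else:
        wanted = set(selection)
        feats = [f for f in ann.features if f.name in wanted]
        missing = wanted - {f.name for f in feats}
        if missing:
            raise KeyError(f"genes not in annotation: {sorted(missing)}")
    if not feats:
        raise ValueError(f"selection {selection!r} matches no feature")
    pieces = []
    for f in feats:
        if strand_policy == "sense":
            pieces.append(genome.feature_sequence(f))
        else:
            pieces.append(genome.region(f.start, f.end))
    return base_composition("".join(pieces))


def composition_report(genomes: Iterable[MitoGenome]) -> pd.DataFrame:
    """One whole-genome composition row per genome, on the reference strand.

    Columns mirror the standard comparative table: Species, Length, A%,
    T%, G%, C%, AT_skew, GC_skew, AT_content. Percentages are rounded to
    2 decimals and skews to 6, the conventional printed precision.
    """
    rows = []
    for g in genomes:
        if g.sequence is None:
            raise ValueError(
                f"{g.annotation.organism or g.annotation.accession}: "
                "sequence required")
        s = base_composition(g.sequence)
        rows.append({
            "Species": g.annotation.organism or (g.annotation.accession or ""),
            "Length": g.annotation.genome_length,
            "A%": round(s.pct("a"), 2), "T%": round(s.pct("t"), 2),
            "G%": round(s.pct("g"), 2), "C%": round(s.pct("c"), 2),
            "AT_skew": round(s.at_skew, 6) if s.at_skew is not None else None,
            "GC_skew": round(s.gc_skew, 6) if s.gc_skew is not None else None,
            "AT_content": round(s.at_content, 2),
        })
    return pd.DataFrame(rows, columns=["Species", "Length", "A%", "T%", "G%",
                                       "C%", "AT_skew", "GC_skew",
                                       "AT_content"])
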