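"""CDS handling, genetic-code translation and codon-usage / RSCU analysis.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial), the standard for molluscan mitogenomes; under it AGA and
AGG encode serine, AUA methionine and UGA tryptophan.

Synonymous families follow the codon-box convention used in mitogenome
RSCU plots: codons are grouped by amino acid *and* by their first two
bases, so leucine splits into Leu1 (CUN, 4 codons) and Leu2 (UUR, 2),
and serine into Ser1 (UCN, 4) and Ser2 (AGN, 4 under table 5). RSCU of
a codon is its count divided by the mean count of its family:
RSCU(c) = count(c) * k / sum(family counts), k the family size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

import pandas as pd
from Bio.Data import CodonTable

from .model import GeneFeature, MitoGenome

__all__ = [
    "GeneticCode", "CodonUsageTable", "extract_cds", "identify_start_stop",
    "translate", "codon_counts", "rscu", "top_codons", "rscu_table",
]

_BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in product(_BASES, repeat=3))

# one-letter -> three-letter, for display
_AA_NAME = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with stop and start sets.

    ``table``: all 64 codons (DNA alphabet) to one-letter amino acids,
    stops mapped to ``*``. ``families`` partitions the sense codons into
    synonymous codon boxes keyed by family label (e.g. ``Leu1``).
    """

    id: int
    table: dict[str, str]
    start_codons: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(default=None, repr=False)

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        fam: dict[tuple[str, str], list[str]] = {}
        for codon in ALL_CODONS:
            aa = table[codon]
            if aa == "*":
                continue
            fam.setdefault((aa, codon[:2]), []).append(codon)
        # label families: plain amino-acid name, numbered when split.
        # Numbering matches the duplicated-tRNA convention (trnL1 reads
        # CUN, trnS1 reads UCN), hence the explicit prefix priority.
        split_rank = {("L", "CT"): 1, ("L", "TT"): 2,
                      ("S", "TC"): 1, ("S", "AG"): 2}
        by_aa: dict[str, list[tuple[str, str]]] = {}
        for aa, prefix in sorted(fam, key=lambda k: (k[0], split_rank.get(k, 0), k[1])):
            by_aa.setdefault(aa, []).append((aa, prefix))
        families = {}
        for aa, keys in by_aa.items():
            if len(keys) == 1:
                families[_AA_NAME[aa]] = tuple(fam[keys[0]])
            else:
                for i, key in enumerate(keys, start=1):
                    families[f"{_AA_NAME[aa]}{i}"] = tuple(fam[key])
        return cls(id=table_id, table=table,
                   start_codons=frozenset(ncbi.start_codons),
                   families=families)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    def family_of(self, codon: str) -> Optional[str]:
        for label, codons in self.families.items():
            if codon in codons:
                return label
        return None


def default_code() -> GeneticCode:
    """NCBI table 5, the invertebrate mitochondrial code."""
    return GeneticCode.from_ncbi(5)


def extract_cds(genome: MitoGenome, feature: GeneFeature) -> str:
    """Sense-strand CDS of a protein-coding gene (circular wrap allowed,
    reverse complement for L-strand genes)."""
    if feature.category != "PCG":
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    return genome.feature_sequence(feature)


def identify_start_stop(cds: str) -> tuple[str, str, bool]:
    """(start codon, stop codon, frame-ok) for a sense-strand CDS.

    The stop is the last three bases; a length not divisible by 3 sets
    frame-ok False (truncated stops are reported, never inferred).
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError("CDS shorter than two codons")
    return cds[:3], cds[-3:], len(cds) % 3 == 0


class InternalStopError(ValueError):
    def __init__(self, position: int, codon: str):
        self.position = position
        super().__init__(f"internal stop codon {codon} at codon position "
                         f"{position} (1-based)")


def translate(cds: str, code: Optional[GeneticCode] = None) -> str:
    """Translate an in-frame CDS; the terminal stop (if any) is dropped.

    An internal stop raises :class:`InternalStopError` naming the codon
    position; a codon containing a non-ACGT base translates to ``X``.
    """
    code = code or default_code()
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and code.table.get(codons[-1]) == "*":
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons, start=1):
        aa = code.table.get(codon, "X")
        if aa == "*":
            raise InternalStopError(i, codon)
        out.append(aa)
    return "".join(out)


@dataclass
class CodonUsageTable:
    """Codon counts grouped into synonymous families under a genetic code."""

    counts: Counter
    code: GeneticCode

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, label: str) -> int:
        return sum(self.counts.get(c, 0) for c in self.code.families[label])


def codon_counts(cds_list: Iterable[str], code: Optional[GeneticCode] = None,
                 include_start: bool = True,
                 include_stop: bool = False) -> CodonUsageTable:
    """Tally codon usage over a set of in-frame CDSs.

    Default policy: the start codon is counted, the terminal stop codon
    is not. Both switches are explicit so hand counts stay reproducible.
    """
    code = code or default_code()
    counts: Counter = Counter()
    for cds in cds_list:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and not include_stop and code.table.get(codons[-1]) == "*":
            codons = codons[:-1]
        if codons and not include_start:
            codons = codons[1:]
        counts.update(codons)
    return CodonUsageTable(counts=counts, code=code)


def rscu(table: CodonUsageTable) -> dict[str, Optional[float]]:
    """Relative synonymous codon usage per sense codon (DNA alphabet).

    RSCU(c) = count(c) * family_size / family_total; families with zero
    total yield None for all members. RSCU sums to the family size over
    every used family.
    """
    values: dict[str, Optional[float]] = {}
    for label, codons in table.code.families.items():
        total = table.family_total(label)
        k = len(codons)
        for c in codons:
            values[c] = (table.counts.get(c, 0) * k / total) if total else None
    return values


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


def top_codons(table: CodonUsageTable, n: int = 3
               ) -> list[tuple[str, str, int]]:
    """The n most used sense codons as (RNA codon, family label, count),
    descending by count with lexicographic codon tie-break."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sense = [(c, k) for c, k in table.counts.items()
             if table.code.table.get(c, "*") != "*"]
    sense.sort(key=lambda item: (-item[1], item[0]))
    return [(_rna(c), table.code.family_of(c), k) for c, k in sense[:n]]


def rscu_table(table: CodonUsageTable) -> pd.DataFrame:
    """Tidy per-codon report: codon (RNA), family, amino acid, count, RSCU."""
    values = rscu(table)
    rows = []
    for label, codons in table.code.families.items():
        for c in codons:
            rows.append({
                "Codon": _rna(c), "Family": label,
                "AA": table.code.table[c],
                "Count": table.counts.get(c, 0),
                "RSCU": round(values[c], 4) if values[c] is not None else None,
            })
    return pd.DataFrame(rows, columns=["Codon", "Family", "AA", "Count", "RSCU"])
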