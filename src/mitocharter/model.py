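"""Core domain model for annotated circular mitochondrial genomes.

The metazoan mitogenome carries a canonical complement of 37 genes:
13 protein-coding genes (PCGs), 2 ribosomal RNAs and 22 transfer RNAs.
This module defines the closed gene vocabulary, the feature/annotation
containers, circular coordinate arithmetic, and a synonym-driven gene-name
canonicalizer.

Coordinate convention: 1-based, fully inclusive, matching the feature
tables of GenBank-style mitogenome reports. A feature with ``end < start``
on a circular genome wraps across the origin.

Strand vocabulary: ``H`` (heavy) is the deposited reference strand,
``L`` (light) its complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "PCG_TOKENS",
    "RRNA_TOKENS",
    "TRNA_TOKENS",
    "ALL_TOKENS",
    "GeneFeature",
    "MitoAnnotation",
    "MitoGenome",
    "UnknownGeneError",
    "canonicalize_gene_name",
    "category_of",
    "feature_length",
    "reverse_complement",
]

# --------------------------------------------------------------------------
# Canonical vocabulary

PCG_TOKENS = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "atp6", "atp8",
)

RRNA_TOKENS = ("rrnS", "rrnL")

# trnL1/trnL2 and trnS1/trnS2 are distinguished by the codon family they
# serve: trnL1 reads CUN, trnL2 reads UUR; trnS1 reads UCN, trnS2 reads AGN.
TRNA_TOKENS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

ALL_TOKENS = PCG_TOKENS + RRNA_TOKENS + TRNA_TOKENS

_CATEGORY = {t: "PCG" for t in PCG_TOKENS}
_CATEGORY.update({t: "rRNA" for t in RRNA_TOKENS})
_CATEGORY.update({t: "tRNA" for t in TRNA_TOKENS})


def category_of(token: str) -> str:
    """Return the gene category (``PCG``, ``tRNA`` or ``rRNA``) of a token."""
    try:
        return _CATEGORY[token]
    except KeyError:
        raise UnknownGeneError(token) from None


class UnknownGeneError(ValueError):
    """A gene label that cannot be mapped onto the 37-token vocabulary."""

    def __init__(self, raw: str, detail: str = ""):
        self.raw = raw
        msg = f"unknown gene: {raw!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


# --------------------------------------------------------------------------
# Sequence helpers

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Gene-name canonicalization

_AA3_TO_LETTER = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# anticodon (written in either DNA or RNA alphabet) -> leucine/serine copy
_LS_BY_ANTICODON = {
    "TAG": "trnL1", "TAA": "trnL2",   # read CUN / UUR codons
    "TGA": "trnS1", "GCT": "trnS2",   # read UCN / AGN codons
    "TCT": "trnS2",                   # AGN-family alternative anticodon
}

_LS_BY_CODON_PREFIX = {
    ("L", "CT"): "trnL1", ("L", "TT"): "trnL2",
    ("S", "TC"): "trnS1", ("S", "AG"): "trnS2",
}


def _norm_label(raw: str) -> str:
    s = raw.strip().lower()
    s = s.replace("*", "").replace("_", " ")
    s = re.sub(r"\s+", " ", s)
    return s


def _norm_triplet(x: Optional[str]) -> Optional[str]:
    if not x:
        return None
    t = x.strip().upper().replace("U", "T")
    return t if re.fullmatch(r"[ACGT]{3}", t) else None


_SYNONYMS: Optional[dict] = None


def _synonym_map() -> dict:
    """Alias -> token map loaded from the packaged ``gene_synonyms.tsv``."""
    global _SYNONYMS
    if _SYNONYMS is None:
        table = {}
        text = (resources.files("mitocharter") / "data" / "gene_synonyms.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alias, token = line.split("\t")
            table[_norm_label(alias)] = token
        _SYNONYMS = table
    return _SYNONYMS


def canonicalize_gene_name(raw: str, anticodon: Optional[str] = None) -> str:
    """Map a free-text gene label onto one of the 37 canonical tokens.

    ``anticodon`` (DNA or RNA alphabet) disambiguates the duplicated
    leucine and serine tRNAs when the label itself does not. Labels such
    as ``tRNA-Ser(UCA)`` or ``tRNA-Ser^UCA^`` carry the codon family in
    the label and need no anticodon.

    Raises :class:`UnknownGeneError` for unmappable labels, including a
    bare ``trnL``/``trnS`` without any disambiguating information.
    """
    if not raw or not raw.strip():
        raise UnknownGeneError(raw, "empty label")
    s = _norm_label(raw)

    syn = _synonym_map()
    if s in syn:
        return syn[s]

    # tRNA forms: trnX, trnL1, tRNA-Ser(UCA), tRNA Ser, trna-ser^uca^ ...
    m = re.fullmatch(
        r"(?:trna|trn)[ -]?([a-z]{3}|[a-z])\s*(\d)?\s*(?:[\^(\[]\s*([acgtu]{3})\s*[\^)\]]?)?",
        s,
    )
    if m:
        aa_part, copy_no, codon = m.group(1), m.group(2), m.group(3)
        if len(aa_part) == 3:
            letter = _AA3_TO_LETTER.get(aa_part)
        else:
            letter = aa_part.upper() if aa_part.upper() in set(_AA3_TO_LETTER.values()) else None
        if letter is None:
            raise UnknownGeneError(raw, "unrecognized amino acid")
        if letter not in ("L", "S"):
            token = f"trn{letter}"
            if token in TRNA_TOKENS:
                return token
            raise UnknownGeneError(raw)
        # duplicated leucine/serine: need copy number, codon or anticodon
        if copy_no in ("1", "2"):
            return f"trn{letter}{copy_no}"
        if codon:
            codon_dna = codon.upper().replace("U", "T")
            key = (letter, codon_dna[:2])
            if key in _LS_BY_CODON_PREFIX:
                return _LS_BY_CODON_PREFIX[key]
        ac = _norm_triplet(anticodon)
        if ac and ac in _LS_BY_ANTICODON:
            token = _LS_BY_ANTICODON[ac]
            if token[3] == letter:
                return token
        raise UnknownGeneError(raw, "ambiguous leucine/serine tRNA: "
                                    "provide a codon suffix or anticodon")

    raise UnknownGeneError(raw)


# --------------------------------------------------------------------------
# Coordinates

def feature_length(start: int, end: int, genome_length: int,
                   circular: bool = True) -> int:
    """Length in bp of a 1-based inclusive interval, wrapping if circular.

    ``end >= start`` gives ``end - start + 1``; ``end < start`` on a
    circular genome gives ``(genome_length - start + 1) + end``.
    """
    if not (1 <= start <= genome_length and 1 <= end <= genome_length):
        raise ValueError(
            f"coordinates ({start}, {end}) outside [1, {genome_length}]")
    if end >= start:
        return end - start + 1
    if not circular:
        raise ValueError(f"end < start ({start}..{end}) on a linear genome")
    return (genome_length - start + 1) + end


# --------------------------------------------------------------------------
# Containers

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circle.

    ``start``/``end`` are 1-based inclusive; ``strand`` is ``H`` or ``L``.
    ``start_codon``/``stop_codon`` apply to PCGs, ``anticodon`` to tRNAs;
    all three are stored as DNA 3-mers.
    """

    name: str
    start: int
    end: int
    strand: str
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None

    def __post_init__(self):
        if self.name not in ALL_TOKENS:
            raise UnknownGeneError(self.name)
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        cat = self.category
        if cat == "PCG" and self.anticodon is not None:
            raise ValueError(f"{self.name}: a PCG carries no anticodon")
        if cat == "tRNA" and (self.start_codon or self.stop_codon):
            raise ValueError(f"{self.name}: a tRNA carries no start/stop codon")
        for attr in ("start_codon", "stop_codon", "anticodon"):
            v = getattr(self, attr)
            if v is not None and not re.fullmatch(r"[ACGT]{3}", v):
                raise ValueError(f"{self.name}: {attr} {v!r} is not a DNA 3-mer")

    @property
    def category(self) -> str:
        return category_of(self.name)

    def length(self, genome_length: int, circular: bool = True) -> int:
        return feature_length(self.start, self.end, genome_length, circular)

    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass
class MitoAnnotation:
    """An ordered, circular feature table for one mitogenome."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    organism: str = ""
    accession: Optional[str] = None

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen = set()
        for f in self.features:
            if not (1 <= f.start <= self.genome_length
                    and 1 <= f.end <= self.genome_length):
                raise ValueError(
                    f"{f.name}: coordinates ({f.start}, {f.end}) outside "
                    f"[1, {self.genome_length}]")
            if f.end < f.start and not self.circular:
                raise ValueError(f"{f.name}: wrap-around feature on a linear genome")
            if f.name in seen:
                raise ValueError(f"duplicate gene token: {f.name}")
            seen.add(f.name)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def category_counts(self) -> dict[str, int]:
        counts = {"PCG": 0, "tRNA": 0, "rRNA": 0}
        for f in self.features:
            counts[f.category] += 1
        return counts


@dataclass
class MitoGenome:
    """An annotation optionally bound to the deposited (H-strand) sequence."""

    annotation: MitoAnnotation
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.annotation.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != genome_length "
                    f"{self.annotation.genome_length}")

    def region(self, start: int, end: int) -> str:
        """Reference-strand sequence of a 1-based inclusive interval,
        wrapping across the origin when ``end < start``."""
        if self.sequence is None:
            raise ValueError("sequence required but absent")
        n = self.annotation.genome_length
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(f"coordinates ({start}, {end}) outside [1, {n}]")
        if end >= start:
            return self.sequence[start - 1:end]
        if not self.annotation.circular:
            raise ValueError("wrap-around region on a linear genome")
        return self.sequence[start - 1:] + self.sequence[:end]

    def feature_sequence(self, f: GeneFeature) -> str:
        """Sense-strand sequence of a feature (reverse complement for L)."""
        raw = self.region(f.start, f.end)
        return reverse_complement(raw) if f.strand == "L" else raw
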