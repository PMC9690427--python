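"""Readers and writers: feature-table TSV, GenBank flat files, FASTA.

The feature-table dialect is tab-separated with header columns
``Gene From To Length Start Stop Anticodon Intergenic Strand``.
``Length`` and ``Intergenic`` are derived quantities: they are
cross-checked (never trusted) on read and recomputed on write.
Thousands separators in coordinates ("11,196") are tolerated on read.
"""

from __future__ import annotations

import csv
import io
import logging
from typing import Optional, TextIO, Union

from Bio import SeqIO

from .model import (
    GeneFeature,
    MitoAnnotation,
    MitoGenome,
    UnknownGeneError,
    canonicalize_gene_name,
    category_of,
    feature_length,
)

logger = logging.getLogger("mitocharter")

COLUMNS = ["Gene", "From", "To", "Length", "Start", "Stop",
           "Anticodon", "Intergenic", "Strand"]


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "r", encoding="utf-8")


def _parse_int(text: str, context: str) -> int:
    t = text.strip().replace(",", "").replace("−", "-")
    try:
        return int(t)
    except ValueError:
        raise ValueError(f"unparsable integer {text!r} in {context}") from None


def _clean(text: Optional[str]) -> Optional[str]:
    if text is None:
        return None
    t = text.strip()
    return t.upper() if t else None


def read_feature_table(source: Union[str, TextIO], genome_length: int,
                       circular: bool = True, organism: str = "",
                       accession: Optional[str] = None) -> MitoAnnotation:
    """Parse a feature-table TSV into a :class:`MitoAnnotation`.

    Gene labels are canonicalized (anticodon column disambiguates the
    duplicated Leu/Ser tRNAs). A stored Length that disagrees with the
    coordinates is reported as a warning and ignored; the Intergenic
    column is never read.
    """
    stream = _as_stream(source)
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None:
        return MitoAnnotation(genome_length=genome_length, circular=circular,
                              organism=organism, accession=accession)
    missing = {"Gene", "From", "To", "Strand"} - set(reader.fieldnames)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")

    features = []
    for i, row in enumerate(reader, start=2):
        raw_name = (row.get("Gene") or "").strip()
        if not raw_name:
            continue
        context = f"row {i} ({raw_name})"
        anticodon = _clean(row.get("Anticodon"))
        try:
            name = canonicalize_gene_name(raw_name, anticodon)
        except UnknownGeneError as e:
            raise ValueError(f"{context}: {e}") from None
        start = _parse_int(row["From"], context)
        end = _parse_int(row["To"], context)
        for coord in (start, end):
            if not 1 <= coord <= genome_length:
                raise ValueError(
                    f"{context}: coordinate {coord} outside [1, {genome_length}]")
        strand = (row.get("Strand") or "").strip().upper()
        cat = category_of(name)
        feat = GeneFeature(
            name=name, start=start, end=end, strand=strand,
            start_codon=_clean(row.get("Start")) if cat == "PCG" else None,
            stop_codon=_clean(row.get("Stop")) if cat == "PCG" else None,
            anticodon=anticodon if cat == "tRNA" else None,
        )
        stored_length = (row.get("Length") or "").strip()
        if stored_length:
            stored = _parse_int(stored_length, context)
            actual = feature_length(start, end, genome_length, circular)
            if stored != actual:
                logger.warning("%s: stored length %d != computed %d",
                               context, stored, actual)
        features.append(feat)

    return MitoAnnotation(genome_length=genome_length, features=features,
                          circular=circular, organism=organism,
                          accession=accession)


def write_feature_table(annotation: MitoAnnotation,
                        dest: Optional[TextIO] = None) -> str:
    """Serialize an annotation to the feature-table TSV dialect.

    Length and Intergenic are recomputed from coordinates; thousands
    separators are never written. Returns the text (and writes it to
    ``dest`` when given).
    """
    from .organization import gap_ledger  # local import: avoid cycle

    gaps = {}
    if annotation.features and annotation.circular:
        gaps = {e.gene: e.gap for e in gap_ledger(annotation).entries}

    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(COLUMNS)
    for f in annotation.features:
        writer.writerow([
            f.name, f.start, f.end,
            f.length(annotation.genome_length, annotation.circular),
            f.start_codon or "", f.stop_codon or "", f.anticodon or "",
            gaps.get(f.name, ""), f.strand,
        ])
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text


# --------------------------------------------------------------------------
# GenBank

def _feature_label(feat) -> Optional[str]:
    for key in ("gene", "product", "label", "note"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _feature_anticodon(feat) -> Optional[str]:
    # /anticodon="(pos:...,aa:Ser,seq:tga)" or a bare triplet
    if "anticodon" in feat.qualifiers:
        q = feat.qualifiers["anticodon"][0]
        if "seq:" in q:
            seq = q.split("seq:")[1].strip(") ").upper()
            return seq[:3]
        q = q.strip("() ").upper()
        if len(q) == 3:
            return q
    return None


def read_genbank(source: Union[str, TextIO]) -> MitoGenome:
    """Read one GenBank flat file into a :class:`MitoGenome`.

    CDS/tRNA/rRNA features are mapped onto the canonical vocabulary;
    complement locations become strand L; a join() across the origin
    becomes a single wrap-around feature. Features with unmappable
    labels are skipped with a warning. The ORIGIN sequence, when
    present, is attached as the reference (heavy) strand.
    """
    stream = _as_stream(source)
    record = SeqIO.read(stream, "genbank")
    genome_length = len(record.seq) if record.seq is not None else None
    if not genome_length:
        genome_length = int(record.annotations.get("source_length", 0)) or None
    if genome_length is None:
        raise ValueError("GenBank record without a usable LOCUS length")
    circular = record.annotations.get("topology", "circular") == "circular"

    kind_map = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
    features = []
    for feat in record.features:
        if feat.type not in kind_map:
            continue
        label = _feature_label(feat)
        anticodon = _feature_anticodon(feat)
        if label is None:
            logger.warning("feature at %s has no gene/product label; skipped",
                           feat.location)
            continue
        try:
            name = canonicalize_gene_name(label, anticodon)
        except UnknownGeneError as e:
            logger.warning("skipping feature: %s", e)
            continue
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[-1].end) == genome_length and int(parts[0].start) == 0:
            start = int(parts[-1].start) + 1   # wrap across the origin
            end = int(parts[0].end)
        else:
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
        strand = "L" if feat.location.strand == -1 else "H"
        cat = category_of(name)
        features.append(GeneFeature(
            name=name, start=start, end=end, strand=strand,
            anticodon=anticodon if cat == "tRNA" else None,
        ))

    annotation = MitoAnnotation(
        genome_length=genome_length, features=features, circular=circular,
        organism=record.annotations.get("organism", ""), accession=record.id)
    sequence = str(record.seq) if record.seq and len(record.seq) else None
    return MitoGenome(annotation=annotation, sequence=sequence)


# --------------------------------------------------------------------------
# FASTA

def read_fasta(source: Union[str, TextIO]) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping."""
    stream = _as_stream(source)
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(stream, "fasta")}


def write_fasta(sequences: dict[str, str], dest: Union[str, TextIO],
                width: int = 70) -> None:
    """Write an {id: sequence} mapping as wrapped FASTA."""
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        for name, seq in sequences.items():
            dest.write(f">{name}\n")
            for i in range(0, len(seq), width):
                dest.write(seq[i:i + width] + "\n")
    finally:
        if close:
            dest.close()
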