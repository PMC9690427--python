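"""Packaged reference data.

``load_erumphii()`` returns the annotation of the Entemnotrochus rumphii
mitogenome (15,795 bp, circular, 37 features) transcribed from its
published feature table; no nucleotide sequence is bundled.

``load_vetigastropoda_composition()`` returns the published per-species
nucleotide-composition table for 20 vetigastropod mitogenomes (length,
base percentages, printed skews and AT content).
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .model import MitoAnnotation
from .tableio import read_feature_table

ERUMPHII_LENGTH = 15795


def _data_text(name: str) -> str:
    return (resources.files("mitocharter") / "data" / name).read_text()


def load_erumphii() -> MitoAnnotation:
    """The E. rumphii mitogenome annotation (37 features, circular)."""
    return read_feature_table(
        io.StringIO(_data_text("erumphii_features.tsv")),
        genome_length=ERUMPHII_LENGTH, circular=True,
        organism="Entemnotrochus rumphii", accession="OP354269")


def load_vetigastropoda_composition() -> pd.DataFrame:
    """Published composition table: one row per vetigastropod mitogenome.

    Columns: Species, Length, A%, T%, G%, C%, AT_skew, GC_skew,
    AT_content (percent). Skews and AT content are the values as
    printed, kept for cross-checking against recomputation.
    """
    return pd.read_csv(io.StringIO(_data_text("vetigastropoda_composition.tsv")),
                       sep="\t")
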