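"""Packaged reference fixtures: the two limpet annotation tables, the
published base-composition table, and an editable ancestral gene order.

The annotation fixtures carry the coordinates, strands, codons and
anticodons exactly as printed, plus the printed Length and Intergenic
columns (which the toolkit recomputes from coordinates).  A handful of
cells in the printed source are internally inconsistent; they are listed
in :data:`KNOWN_ERRATA` and excluded from exact regression checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gene_order import GeneOrderSignature, parse_order_string
from .io import parse_feature_table
from .records import MitogenomeRecord

__all__ = [
    "lottia_goshimai",
    "nipponacmea_fuscoviridis",
    "printed_annotation",
    "base_composition_table",
    "ancestral_gastropod_order",
    "KNOWN_ERRATA",
]

_FILES = {
    "Lg": "lottia_goshimai.tsv",
    "Nf": "nipponacmea_fuscoviridis.tsv",
}

#: Printed-source cells that disagree with the source's own coordinates or
#: prose.  Keys: (species, gene, column) -> (printed, coordinate-derived).
KNOWN_ERRATA = {
    ("Lg", "trnG", "Length"): (67, 60),
    ("Nf", "trnC", "Length"): (66, 60),
    ("Nf", "nad5", "Intergenic"): (1562, 1561),
    # skew cells that cannot be reproduced from the printed percentages
    ("Nf", "cox2", "ATskew"): (-0.090, None),
    ("Nf", "cox2", "GCskew"): (0.253, None),
    ("Nf", "cox3", "ATskew"): (-0.272, None),
    ("Nf", "cox3", "GCskew"): (0.265, None),
}


def _read_text(name: str) -> str:
    return resources.files("mitochar.data").joinpath(name).read_text()


def _load_record(species: str) -> MitogenomeRecord:
    return parse_feature_table(_read_text(_FILES[species]), canonicalize=False)


def lottia_goshimai() -> MitogenomeRecord:
    """Annotation of the Lottia goshimai mitogenome (18,192 bp, 13 PCGs,
    23 tRNAs, 2 rRNAs; control region left unannotated)."""
    return _load_record("Lg")


def nipponacmea_fuscoviridis() -> MitogenomeRecord:
    """Annotation of the Nipponacmea fuscoviridis mitogenome (18,720 bp,
    13 PCGs, 24 tRNAs, 2 rRNAs; control region left unannotated)."""
    return _load_record("Nf")


def printed_annotation(species: str) -> pd.DataFrame:
    """The annotation fixture as a DataFrame including the printed Length
    and Intergenic columns (``species`` is 'Lg' or 'Nf')."""
    import io as _io

    text = _read_text(_FILES[species])
    return pd.read_csv(_io.StringIO(text), sep="\t", comment="#")


def base_composition_table() -> pd.DataFrame:
    """Published per-region base-composition table for both species (long
    format; one row per region x species)."""
    import io as _io

    return pd.read_csv(
        _io.StringIO(_read_text("base_composition.tsv")), sep="\t", comment="#"
    )


def ancestral_gastropod_order() -> GeneOrderSignature:
    """The editable (synthetic stand-in) ancestral gastropod gene order."""
    text = _read_text("ancestral_gastropod_order.synthetic.txt")
    line = next(l for l in text.splitlines() if l.strip() and not l.startswith("#"))
    return parse_order_string(line)
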