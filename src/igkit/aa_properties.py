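"""Amino acid property classes and the four-type AA-change similarity scheme.

Each of the 20 standard residues is assigned one class on each of three axes:
hydropathy (3 classes), volume (5 classes) and chemical characteristics
(11 classes).  An amino acid replacement is then summarised by a three-sign
signature -- ``+`` where the two residues share a class, ``-`` where they do
not -- and mapped onto four similarity degrees:

==============  ==================
signature       similarity degree
==============  ==================
+++             very similar
++-, +-+        similar
--+, -+-, +--   dissimilar
---             very dissimilar
==============  ==================

The class table ships as a plain TSV fixture (``data/aa_classes.tsv``); only
the hydrophobic hydropathy set {I, V, L, F, C, M, A} is fixed by definition,
the remaining memberships are data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache

__all__ = [
    "AAClassError",
    "AAClassTable",
    "ChangeSignature",
    "HYDROPHOBIC_SET",
    "classify_aa",
    "classify_change",
    "load_class_table",
]

#: Residues with a positive hydropathy index; rendered blue (with W) in
#: Collier de Perles displays.
HYDROPHOBIC_SET = frozenset("IVLFCMA")

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class AAClassError(ValueError):
    """Raised for residues outside the 20 standard one-letter codes."""


@dataclass(frozen=True)
class AAClassTable:
    """Per-residue class assignments on the three property axes."""

    hydropathy: dict
    volume: dict
    chem: dict

    def classify(self, residue: str) -> tuple[str, str, str]:
        aa = _check_residue(residue)
        return self.hydropathy[aa], self.volume[aa], self.chem[aa]


@dataclass(frozen=True)
class ChangeSignature:
    """Signature of one amino acid replacement."""

    from_aa: str
    to_aa: str
    hydropathy_same: bool
    volume_same: bool
    chem_same: bool

    @property
    def signs(self) -> str:
        return "".join(
            "+" if same else "-"
            for same in (self.hydropathy_same, self.volume_same, self.chem_same)
        )

    @property
    def similarity_type(self) -> str:
        if self.from_aa == self.to_aa:
            return "identical"
        n_same = self.signs.count("+")
        return {
            3: "very similar",
            2: "similar",
            1: "dissimilar",
            0: "very dissimilar",
        }[n_same]


def _check_residue(residue: str) -> str:
    if not isinstance(residue, str) or len(residue) != 1:
        raise AAClassError(f"expected a one-letter residue, got {residue!r}")
    aa = residue.upper()
    if aa not in STANDARD_AA:
        raise AAClassError(f"non-standard residue {residue!r}")
    return aa


@lru_cache(maxsize=1)
def load_class_table() -> AAClassTable:
    """Load the packaged class table and validate its invariants."""
    hydropathy: dict = {}
    volume: dict = {}
    chem: dict = {}
    text = resources.files("igkit.data").joinpath("aa_classes.tsv").read_text()
    rows = [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    for row in csv.DictReader(rows, delimiter="\t"):
        aa = row["residue"]
        hydropathy[aa] = row["hydropathy"]
        volume[aa] = row["volume"]
        chem[aa] = row["chem"]
    missing = STANDARD_AA - hydropathy.keys()
    if missing:
        raise AAClassError(f"class table is missing residues {sorted(missing)}")
    hydrophobic = {aa for aa, cls in hydropathy.items() if cls == "hydrophobic"}
    if hydrophobic != set(HYDROPHOBIC_SET):
        raise AAClassError(
            "hydrophobic hydropathy class must be exactly "
            f"{sorted(HYDROPHOBIC_SET)}, fixture has {sorted(hydrophobic)}"
        )
    return AAClassTable(hydropathy=hydropathy, volume=volume, chem=chem)


def classify_aa(residue: str) -> tuple[str, str, str]:
    """Return (hydropathy class, volume class, chemical class) for a residue."""
    return load_class_table().classify(residue)


def classify_change(from_aa: str, to_aa: str) -> ChangeSignature:
    """Classify the replacement ``from_aa -> to_aa`` on the three axes."""
    h1, v1, c1 = classify_aa(from_aa)
    h2, v2, c2 = classify_aa(to_aa)
    return ChangeSignature(
        from_aa=from_aa.upper(),
        to_aa=to_aa.upper(),
        hydropathy_same=h1 == h2,
        volume_same=v1 == v2,
        chem_same=c1 == c2,
    )
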