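"""Allotype and isotype-marker inference, engineered-variant naming, and
Eu <-> IMGT constant-domain position mapping.

Allotypes (Gm, Km) are serologically detected polymorphic markers of the
IG constant regions; each corresponds to a small conjunction of residues
at fixed C-DOMAIN positions (IMGT unique numbering).  Isoallotypes (nGm)
are the markers of the alternative residue states; the lambda chain
isotypic markers Mcg/Ke/Oz distinguish the IGLC gene products.  The rule
tables ship as editable TSV fixtures.

Engineered Fc variants are named by comparison with allele *01 of the
gene; the catalogued variants (with their Eu correspondences) also ship
as a fixture, from which the Eu <-> IMGT position table is derived and
validated for per-domain bijectivity.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "MarkerRule",
    "MarkerCall",
    "VariantChange",
    "load_marker_rules",
    "load_km_alleles",
    "load_g1m_alleles",
    "load_variant_catalog",
    "load_eu_imgt_table",
    "call_markers",
    "map_eu_imgt",
    "name_variant",
]


def _read_fixture(name: str) -> list[dict]:
    text = resources.files("igkit.data").joinpath(name).read_text()
    rows = [ln for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


@dataclass(frozen=True)
class MarkerRule:
    marker: str
    gene: str
    kind: str                         # allotype | isoallotype | isotype_marker
    required: tuple                   # ((domain, position, aa), ...)
    corroborating: tuple = ()

    def satisfied_by(self, residues: dict) -> bool:
        return all(
            residues.get(dom, {}).get(pos) == aa
            for dom, pos, aa in self.required
        )


def _parse_conj(text: str) -> tuple:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        dom, pos, aa = part.split(":")
        out.append((dom, pos, aa))
    return tuple(out)


@lru_cache(maxsize=1)
def load_marker_rules() -> tuple:
    return tuple(
        MarkerRule(
            marker=row["marker"],
            gene=row["gene"],
            kind=row["kind"],
            required=_parse_conj(row["required"]),
            corroborating=_parse_conj(row.get("corroborating") or ""),
        )
        for row in _read_fixture("allotype_rules.tsv")
    )


@lru_cache(maxsize=1)
def load_km_alleles() -> list[dict]:
    rows = _read_fixture("km_alleles.tsv")
    for row in rows:
        row["igkc_alleles"] = row["igkc_alleles"].split(",")
    return rows


@lru_cache(maxsize=1)
def load_g1m_alleles() -> list[dict]:
    return _read_fixture("g1m_alleles.tsv")


_G1M_POSITIONS = (("CH1", "103"), ("CH1", "120"), ("CH3", "12"),
                  ("CH3", "14"), ("CH3", "101"), ("CH3", "110"),
                  ("CH3", "115"), ("CH3", "116"))


@dataclass(frozen=True)
class MarkerCall:
    """Result of marker inference on one chain."""

    gene: str
    markers: frozenset                # satisfied allotypes / isotype markers
    isoallotypes: frozenset
    allele: str | None = None         # combined allele label when resolved
    evidence: dict = field(default_factory=dict)
    corroborating: dict = field(default_factory=dict)
    unresolved: tuple = ()
    no_call: bool = False


def call_markers(residues: dict, gene: str) -> MarkerCall:
    """Infer allotype/isotype markers from numbered C-domain residues.

    ``residues`` maps domain labels (CH1, CH2, CH3, h, CL) to
    {position-string: one-letter AA}.  All satisfied rules for the gene
    context are reported; for IGKC the (45.1, 101) pair is mapped to a Km
    allele, for IGHG1 the allele table row is matched to a G1m allele.
    A residue combination matching no rule yields an explicit no-call with
    the positions that could not be matched.
    """
    rule_gene = "IGLC" if gene.startswith("IGLC") else gene
    rules = [r for r in load_marker_rules() if r.gene == rule_gene]
    markers = set()
    isoallotypes = set()
    evidence: dict = {}
    corroborating: dict = {}
    for rule in rules:
        if rule.satisfied_by(residues):
            if rule.kind == "isoallotype":
                isoallotypes.add(rule.marker)
            else:
                markers.add(rule.marker)
            evidence[rule.marker] = rule.required
            for dom, pos, aa in rule.corroborating:
                observed = residues.get(dom, {}).get(pos)
                corroborating[rule.marker] = (
                    (dom, pos, aa, observed))

    allele = None
    unresolved: tuple = ()
    if gene == "IGKC" or rule_gene == "IGKC":
        allele, unresolved = _km_allele(residues)
    elif gene == "IGHG1":
        allele, unresolved = _g1m_allele(residues)

    no_call = not markers and not isoallotypes and allele is None
    if no_call and not unresolved:
        unresolved = tuple(
            (dom, pos, residues[dom][pos])
            for dom in sorted(residues)
            for pos in sorted(residues[dom])
        )
    return MarkerCall(
        gene=gene, markers=frozenset(markers),
        isoallotypes=frozenset(isoallotypes), allele=allele,
        evidence=evidence, corroborating=corroborating,
        unresolved=unresolved, no_call=no_call)


def _km_allele(residues: dict):
    cl = residues.get("CL") or residues.get("C-KAPPA") or {}
    pair = (cl.get("45.1"), cl.get("101"))
    for row in load_km_alleles():
        if pair == (row["pos45_1"], row["pos101"]):
            return row["km_allele"], ()
    return None, (("CL", "45.1", pair[0]), ("CL", "101", pair[1]))


def _g1m_allele(residues: dict):
    observed = tuple(residues.get(dom, {}).get(pos)
                     for dom, pos in _G1M_POSITIONS)
    for row in load_g1m_alleles():
        expected = (row["ch1_103"], row["ch1_120"], row["ch3_12"],
                    row["ch3_14"], row["ch3_101"], row["ch3_110"],
                    row["ch3_115"], row["ch3_116"])
        if observed == expected:
            return row["g1m_allele"], ()
    unresolved = tuple((dom, pos, aa) for (dom, pos), aa
                       in zip(_G1M_POSITIONS, observed))
    return None, unresolved


# --------------------------------------------------------------------------
# engineered variants and Eu correspondence


@dataclass(frozen=True)
class VariantChange:
    domain: str
    position: str
    aa: str


@lru_cache(maxsize=1)
def load_variant_catalog() -> dict:
    """Catalogued variants: (gene, variant) -> frozenset of changes."""
    catalog: dict = {}
    for row in _read_fixture("engineered_variants.tsv"):
        key = (row["gene"], row["variant"])
        catalog.setdefault(key, set()).add(
            VariantChange(row["domain"], row["imgt_pos"], row["aa"]))
    return {k: frozenset(v) for k, v in catalog.items()}


@lru_cache(maxsize=1)
def load_eu_imgt_table() -> dict:
    """Per-domain bijective IMGT <-> Eu position pairs, derived from the
    variant catalog fixture (insertions excluded)."""
    imgt_to_eu: dict = {}
    eu_to_imgt: dict = {}
    for row in _read_fixture("engineered_variants.tsv"):
        if row["aa"].startswith("ins"):
            continue
        dom, imgt, eu = row["domain"], row["imgt_pos"], int(row["eu_pos"])
        if imgt_to_eu.get((dom, imgt), eu) != eu:
            raise ValueError(
                f"conflicting Eu numbers for {dom} {imgt}: "
                f"{imgt_to_eu[(dom, imgt)]} vs {eu}")
        if eu_to_imgt.get((dom, eu), imgt) != imgt:
            raise ValueError(
                f"conflicting IMGT positions for {dom} Eu {eu}: "
                f"{eu_to_imgt[(dom, eu)]} vs {imgt}")
        imgt_to_eu[(dom, imgt)] = eu
        eu_to_imgt[(dom, eu)] = imgt
    return {"imgt_to_eu": imgt_to_eu, "eu_to_imgt": eu_to_imgt}


def map_eu_imgt(domain: str, position, direction: str = "imgt_to_eu"):
    """Map one constant-domain position between IMGT and Eu numbering.

    ``direction`` is ``"imgt_to_eu"`` or ``"eu_to_imgt"``.  Unmapped
    positions raise KeyError listing the nearest mapped neighbours in the
    same domain.
    """
    table = load_eu_imgt_table()
    if direction not in table:
        raise ValueError(f"direction must be one of {sorted(table)}")
    mapping = table[direction]
    key = (domain, int(position) if direction == "eu_to_imgt"
           else str(position))
    if key in mapping:
        value = mapping[key]
        return value if direction == "imgt_to_eu" else value
    neighbours = sorted(
        (pos for dom, pos in mapping if dom == domain),
        key=lambda p: abs(float(str(p).replace("^", ".")) - float(
            str(position))) if str(position).replace(".", "").isdigit()
        else 0.0)
    raise KeyError(
        f"position {position} in {domain} is not in the correspondence "
        f"table; nearest mapped: {neighbours[:3]}")


def name_variant(gene: str, changes) -> dict:
    """Name an engineered variant from its change set.

    ``changes`` is an iterable of (domain, position, AA).  An exact set
    match against the catalog returns the catalogued id; an empty set is
    the reference allele; anything else receives a deterministic novel
    label ``vNEW-<hash>`` together with the nearest catalogued variant by
    change-set overlap.
    """
    change_set = frozenset(VariantChange(d, str(p), a) for d, p, a in changes)
    if not change_set:
        return {"variant": None, "reference": f"{gene}*01", "novel": False}
    catalog = load_variant_catalog()
    for (g, variant), cat_changes in catalog.items():
        if g == gene and cat_changes == change_set:
            return {"variant": variant, "reference": f"{gene}*01",
                    "novel": False}
    digest = hashlib.sha256(
        "|".join(sorted(f"{c.domain}:{c.position}:{c.aa}"
                        for c in change_set)).encode()).hexdigest()[:8]
    nearest = None
    best_overlap = -1
    for (g, variant), cat_changes in sorted(catalog.items()):
        if g != gene:
            continue
        overlap = len(cat_changes & change_set)
        if overlap > best_overlap:
            best_overlap = overlap
            nearest = variant
    return {"variant": f"vNEW-{digest}", "reference": f"{gene}*01",
            "novel": True, "nearest": nearest,
            "nearest_overlap": best_overlap}
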