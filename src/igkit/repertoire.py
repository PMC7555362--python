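"""Human IG locus gene tables, repertoire summaries and protein displays.

The three immunoglobulin loci (IGH on 14q32.33, IGK on 2p11.2, IGL on
22q11.2) carry the V, D, J and C genes whose somatic rearrangement builds
the expressed antibody repertoire.  This module loads the packaged locus
gene tables (group/subgroup classification, functionality, CDR lengths,
allele counts, gene order, CNV and cluster tags), reconciles them with
the per-group census, computes combinatorial-diversity products, and
renders IMGT-gapped protein display text blocks.

Gene names follow the standard classification: group (e.g. IGHV),
subgroup (IGHV3), gene (IGHV3-23, possibly with a D duplication suffix or
extra localization parts), allele (*01).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .numbering import NumberedDomain

__all__ = [
    "GeneRecord",
    "LocusTable",
    "GeneNameError",
    "parse_gene_name",
    "load_locus_tables",
    "load_locus_facts",
    "summarize_locus",
    "combinatorial_product",
    "render_protein_display",
    "find_glycosylation_sites",
]

_LOCI = ("IGH", "IGK", "IGL")


class GeneNameError(ValueError):
    """A gene name does not parse under the classification scheme."""


_NAME_RE = re.compile(
    r"^(?P<locus>IG[HKL])"
    r"(?P<gtype>V|D|J|C|M|G[1-4P]?|A[12]?|E(?:P[12])?|GP)"
    r"(?P<rest>.*)$"
)


def parse_gene_name(name: str) -> dict:
    """Split a gene name into locus, group, subgroup and localization.

    Examples: ``IGHV3-23D`` -> group IGHV, subgroup IGHV3, localization
    ``3-23D``; ``IGKV1D-8`` -> subgroup IGKV1 (distal); ``IGHG3`` ->
    group IGHC.  Raises :class:`GeneNameError` for unparseable names.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise GeneNameError(f"cannot parse gene name {name!r}")
    locus = m.group("locus")
    gtype = m.group("gtype")
    rest = m.group("rest")
    if gtype in ("V", "J") or (gtype == "D" and rest):
        group = locus + gtype
    else:
        # bare IGHD is the delta constant gene; M/G/A/E names are IGHC
        group = locus + "C"
    subgroup = None
    if gtype in ("V", "D") and rest:
        sub = re.match(r"^(\d+)", rest)
        if sub:
            subgroup = f"{group}{sub.group(1)}"
    return {
        "locus": locus,
        "group": group,
        "subgroup": subgroup,
        "localization": rest.lstrip("-") or None,
    }


@dataclass(frozen=True)
class GeneRecord:
    """One locus gene with classification and allele-count metadata."""

    locus: str
    group: str
    subgroup: str | None
    gene: str
    cdr_lengths: tuple | None
    alleles_f: int
    alleles_fp: int        # (F)/[F]: functional pending germline confirmation
    alleles_orf: int
    alleles_p: int
    cnv: str | None = None
    cluster: str | None = None
    gene_order: int | None = None

    @property
    def functional(self) -> bool:
        return self.alleles_f > 0

    @property
    def functionality(self) -> str:
        if self.alleles_f > 0:
            return "F"
        if self.alleles_fp > 0:
            return "(F)"
        if self.alleles_orf > 0:
            return "ORF"
        return "P"


@dataclass(frozen=True)
class LocusTable:
    """All packaged gene records of one locus plus its census row."""

    locus: str
    records: tuple
    group_counts: dict      # group -> {major_genes, orphon_genes, ...}
    facts: dict

    def genes(self, group: str | None = None, functional: bool = False):
        out = [r for r in self.records
               if group is None or r.group == group]
        if functional:
            out = [r for r in out if r.functional]
        return out


def _parse_cdr(text: str):
    if not text:
        return None
    m = re.fullmatch(r"\[(\d+)\.(\d+)\.(\d+)\]", text.strip())
    if not m:
        raise GeneNameError(f"bad CDR length notation {text!r}")
    return tuple(int(g) for g in m.groups())


def _read_fixture(name: str) -> list[dict]:
    text = resources.files("igkit.data").joinpath(name).read_text()
    rows = [ln for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


@lru_cache(maxsize=1)
def load_locus_facts() -> dict:
    return {row["key"]: int(row["value"])
            for row in _read_fixture("locus_facts.tsv")}


@lru_cache(maxsize=1)
def load_locus_tables() -> dict:
    """Load and validate the three locus tables.

    Every gene name is parse-checked; gene order indices must be unique
    within each locus (order 0 marks unmapped genes and is exempt).
    """
    counts: dict = {locus: {} for locus in _LOCI}
    for row in _read_fixture("locus_group_counts.tsv"):
        counts[row["locus"]][row["group"]] = {
            k: int(v) for k, v in row.items() if k not in ("locus", "group")
        }
    records: dict = {locus: [] for locus in _LOCI}
    for row in _read_fixture("locus_genes.tsv"):
        parsed = parse_gene_name(row["gene"])
        if parsed["locus"] != row["locus"] or parsed["group"] != row["group"]:
            raise GeneNameError(
                f"gene {row['gene']} classified as {row['group']} but "
                f"parses as {parsed['group']}")
        records[row["locus"]].append(GeneRecord(
            locus=row["locus"],
            group=row["group"],
            subgroup=row["subgroup"] or parsed["subgroup"],
            gene=row["gene"],
            cdr_lengths=_parse_cdr(row["cdr_lengths"]),
            alleles_f=int(row["alleles_f"]),
            alleles_fp=int(row["alleles_fp"]),
            alleles_orf=int(row["alleles_orf"]),
            alleles_p=int(row["alleles_p"]),
            cnv=row["cnv"] or None,
            cluster=row["cluster"] or None,
            gene_order=int(row["gene_order"]) if row["gene_order"] else None,
        ))
    facts = load_locus_facts()
    tables = {}
    for locus in _LOCI:
        recs = tuple(records[locus])
        orders = [r.gene_order for r in recs if r.gene_order]
        if len(orders) != len(set(orders)):
            raise GeneNameError(f"duplicate gene order indices in {locus}")
        tables[locus] = LocusTable(
            locus=locus, records=recs,
            group_counts=counts[locus], facts=facts)
    return tables


def summarize_locus(tables: dict, locus: str | None = None,
                    functional_only: bool = False) -> pd.DataFrame:
    """Counts per group: census gene counts plus fixture-derived
    functional gene counts.

    With ``functional_only`` the ``listed_genes`` column counts only genes
    holding at least one functional allele.
    """
    loci = [locus] if locus else list(_LOCI)
    for lc in loci:
        if lc not in tables:
            raise KeyError(f"unknown locus {lc!r}")
    rows = []
    for lc in loci:
        table = tables[lc]
        for group, census in table.group_counts.items():
            listed = table.genes(group, functional=functional_only)
            rows.append({
                "locus": lc,
                "group": group,
                "major_genes": census["major_genes"],
                "orphon_genes": census["orphon_genes"],
                "major_alleles": census["major_alleles"],
                "listed_genes": len(listed),
            })
    return pd.DataFrame(rows)


def combinatorial_product(tables: dict, locus: str) -> int:
    """Raw combinatorial diversity: product of functional V x D x J gene
    counts (V x J for the light-chain loci).  No junctional factor."""
    if locus not in tables:
        raise KeyError(f"unknown locus {locus!r}")
    table = tables[locus]
    n_v = len(table.genes(f"{locus}V", functional=True))
    n_j = len(table.genes(f"{locus}J", functional=True))
    if locus == "IGH":
        n_d = len(table.genes("IGHD", functional=True))
        return n_v * n_d * n_j
    return n_v * n_j


# --------------------------------------------------------------------------
# protein displays


_GLYCO_RE = re.compile(r"N(?=([^P.])[ST])")


def find_glycosylation_sites(gapped_seq: str) -> list[int]:
    """0-based indices of N in potential N-glycosylation motifs N-X-S/T,
    X != P, over an IMGT-gapped sequence (gaps '.' are transparent)."""
    compact = [(i, aa) for i, aa in enumerate(gapped_seq) if aa != "."]
    sites = []
    for k in range(len(compact) - 2):
        if (compact[k][1] == "N" and compact[k + 1][1] != "P"
                and compact[k + 2][1] in "ST"):
            sites.append(compact[k][0])
    return sites


def render_protein_display(entries, domain_kind: str = "V") -> str:
    """Render an IMGT-gapped protein display text block.

    ``entries`` is a list of (name, gapped_sequence) with '.' for gaps;
    all sequences must share one length (the canonical span).  The header
    has 7 lines for a V domain (regions, region spans, strands, strand
    spans, arrows, positions, pipes) and 5 for a C domain (no region
    lines).  Conserved positions 23, 41, 89 and 104 are marked and
    N-glycosylation motifs are flagged beneath each sequence.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("no sequences to display")
    width = len(entries[0][1])
    for name, seq in entries:
        if len(seq) != width:
            raise ValueError(f"{name}: length {len(seq)} != {width}")
        if "." not in seq and domain_kind == "V" and width < 100:
            raise ValueError(f"{name}: sequence does not look IMGT-gapped")
    header = _display_header(domain_kind, width)
    lines = list(header)
    name_pad = max(len(n) for n, _ in entries) + 2
    lines = [" " * name_pad + ln for ln in lines]
    for name, seq in entries:
        lines.append(name.ljust(name_pad) + seq)
        sites = find_glycosylation_sites(seq)
        if sites:
            marks = [" "] * width
            for i in sites:
                marks[i] = "*"
            lines.append(" " * name_pad + "".join(marks).rstrip())
    return "\n".join(lines) + "\n"


_V_REGIONS = [("FR1", 1, 26), ("CDR1", 27, 38), ("FR2", 39, 55),
              ("CDR2", 56, 65), ("FR3", 66, 104), ("CDR3", 105, 117),
              ("FR4", 118, 128)]
_V_STRANDS = [("A", 1, 15), ("B", 16, 26), ("BC", 27, 38), ("C", 39, 46),
              ("C'", 47, 55), ("C'C''", 56, 65), ("C''", 66, 74),
              ("D", 75, 84), ("E", 85, 96), ("F", 97, 104),
              ("FG", 105, 117), ("G", 118, 128)]
_C_STRANDS = [("A", 1, 15), ("AB", 15, 15), ("B", 16, 26), ("BC", 27, 38),
              ("C", 39, 45), ("CD", 45, 45), ("D", 77, 84), ("E", 85, 96),
              ("F", 97, 104), ("FG", 105, 117), ("G", 118, 128)]
_CONSERVED_BASES = (23, 41, 89, 104)


def _display_columns(domain_kind: str, width: int):
    """Map display columns to base positions for the canonical span."""
    if domain_kind == "V":
        bases = list(range(1, 129))
    else:
        bases = ([*range(1, 32), *range(34, 46), *range(77, 129)])
    # pad or trim to the requested width (CDR3 insertions extend the span)
    if width > len(bases):
        apex = bases.index(111) + 1
        bases = bases[:apex] + [111] * (width - len(bases)) + bases[apex:]
    return bases[:width]


def _span_line(spans, bases) -> str:
    out = [" "] * len(bases)
    for label, lo, hi in spans:
        cols = [i for i, b in enumerate(bases) if lo <= b <= hi]
        if not cols:
            continue
        start = cols[0]
        text = label[: len(cols)]
        for j, ch in enumerate(text):
            out[start + j] = ch
    return "".join(out).rstrip()


def _bound_line(spans, bases) -> str:
    out = [" "] * len(bases)
    for _label, lo, hi in spans:
        cols = [i for i, b in enumerate(bases) if lo <= b <= hi]
        if not cols:
            continue
        text = f"({lo}-{hi})"[: len(cols)]
        for j, ch in enumerate(text):
            out[cols[0] + j] = ch
    return "".join(out).rstrip()


def _position_line(bases) -> str:
    out = []
    last = None
    for b in bases:
        if b != last and b % 10 == 0:
            out.append(str(b // 10 % 10))
        else:
            out.append(" ")
        last = b
    return "".join(out).rstrip()


def _pipes_line(spans, bases) -> str:
    out = ["."] * len(bases)
    edges = set()
    for _label, lo, hi in spans:
        edges.add(lo)
        edges.add(hi)
    last = None
    for i, b in enumerate(bases):
        if b != last and (b in edges or b in _CONSERVED_BASES):
            out[i] = "|"
        last = b
    return "".join(out)


def _display_header(domain_kind: str, width: int) -> list[str]:
    bases = _display_columns(domain_kind, width)
    strands = _V_STRANDS if domain_kind == "V" else _C_STRANDS
    arrows = _span_line(
        [(">" * max(1, hi - lo), lo, hi) for label, lo, hi in strands
         if label not in ("BC", "FG", "AB", "CD", "C'C''")], bases)
    lines = []
    if domain_kind == "V":
        lines.append(_span_line(_V_REGIONS, bases))
        lines.append(_bound_line(_V_REGIONS, bases))
    lines.append(_span_line(strands, bases))
    lines.append(_bound_line(strands, bases))
    lines.append(arrows)
    lines.append(_position_line(bases))
    lines.append(_pipes_line(strands, bases))
    return lines
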