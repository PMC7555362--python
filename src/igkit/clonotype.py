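"""Clonotype identification and repertoire set comparison.

An amino-acid clonotype groups rearrangement records sharing one
V-(D)-J rearrangement (V and J gene/allele calls), one CDR3 amino acid
sequence, and the conserved junction anchors (C at position 104, W or F at
118).  Within each AA clonotype, records are further partitioned into
nucleotide clonotypes by their CDR3 nucleotide sequence.

:func:`compare_clonotype_sets` contrasts per-gene diversity (clonotype
counts) or expression (sequence counts) proportions between two
repertoires with a two-proportion z-test, adjusts the p-values by a
family of multiple-testing procedures, and classifies each gene by how
many procedures agree on significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RearrangementRecord",
    "ClonotypeNT",
    "ClonotypeAA",
    "ComparisonRow",
    "PROCEDURES",
    "call_clonotypes",
    "clonotype_tables",
    "compare_clonotype_sets",
]


#: Multiple-testing procedures applied by :func:`compare_clonotype_sets`,
#: keyed by short name -> statsmodels method id.
PROCEDURES = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "sidak": "sidak",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "bh": "fdr_bh",
    "by": "fdr_by",
}

_VALID_ANCHORS = {("C", "W"), ("C", "F")}


@dataclass(frozen=True)
class RearrangementRecord:
    """One annotated V-(D)-J rearrangement."""

    sequence_id: str
    v_call: str
    j_call: str
    cdr3_aa: str
    d_call: str | None = None
    cdr3_nt: str = ""
    junction_aa: str = ""
    anchor104: str = ""
    anchor118: str = ""
    v_identity_pct: float = float("nan")
    productive: bool = True
    sequence: str = ""

    @property
    def anchors(self) -> tuple[str, str]:
        a104 = self.anchor104 or (self.junction_aa[:1] if self.junction_aa
                                  else "")
        a118 = self.anchor118 or (self.junction_aa[-1:] if self.junction_aa
                                  else "")
        return (a104, a118)


def gene_of(call: str) -> str:
    """Gene-level name of a ``gene*allele`` call; multi-valued calls
    (comma separated) collapse to their first gene."""
    first = call.split(",")[0].strip()
    return first.split("*")[0]


@dataclass
class ClonotypeNT:
    cdr3_nt: str
    members: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class ClonotypeAA:
    """One AA clonotype with its nucleotide sub-clonotypes."""

    v_call: str
    j_call: str
    cdr3_aa: str
    anchors: tuple
    d_call: str | None = None
    members: list = field(default_factory=list)
    nt_children: list = field(default_factory=list)
    representative: str | None = None
    allele_metadata: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.v_call, self.j_call, self.cdr3_aa, self.anchors)

    @property
    def total(self) -> int:
        return len(self.members)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(one-copy, more-than-one, total) sequence counts."""
        multi = sum(c.count for c in self.nt_children if c.count > 1)
        return (self.total - multi, multi, self.total)

    @property
    def cdr3_length(self) -> int:
        return len(self.cdr3_aa)


def call_clonotypes(records, allele_level: bool = False
                    ) -> tuple[list, list]:
    """Group rearrangement records into AA clonotypes.

    Returns ``(clonotypes, excluded)`` where ``excluded`` collects
    (record, reason) pairs for records failing anchor conservation or
    lacking V/J calls.  By default V and J calls are collapsed to the gene
    level (allele ambiguity retained as metadata); pass
    ``allele_level=True`` to key on the full gene*allele strings.

    Grouping is permutation-invariant: output is sorted by
    (V, J, CDR3, anchors).
    """
    groups: dict = {}
    excluded = []
    for rec in records:
        if not rec.v_call or not rec.j_call:
            excluded.append((rec, "missing V or J call"))
            continue
        if not rec.cdr3_aa:
            excluded.append((rec, "missing CDR3"))
            continue
        anchors = rec.anchors
        if anchors not in _VALID_ANCHORS:
            excluded.append(
                (rec, f"anchors {anchors} not (C, W/F)"))
            continue
        v = rec.v_call if allele_level else gene_of(rec.v_call)
        j = rec.j_call if allele_level else gene_of(rec.j_call)
        key = (v, j, rec.cdr3_aa, anchors)
        groups.setdefault(key, []).append(rec)

    clonotypes = []
    for key in sorted(groups):
        members = groups[key]
        v, j, cdr3_aa, anchors = key
        d_calls = sorted({gene_of(m.d_call) for m in members if m.d_call})
        nt_groups: dict = {}
        for m in members:
            nt_groups.setdefault(m.cdr3_nt, []).append(m.sequence_id)
        nt_children = [ClonotypeNT(cdr3_nt=nt, members=ids)
                       for nt, ids in sorted(nt_groups.items())]
        rep = _representative(members)
        clonotypes.append(ClonotypeAA(
            v_call=v, j_call=j, cdr3_aa=cdr3_aa, anchors=anchors,
            d_call=d_calls[0] if d_calls else None,
            members=[m.sequence_id for m in members],
            nt_children=nt_children,
            representative=rep,
            allele_metadata={
                "v_alleles": sorted({m.v_call for m in members}),
                "j_alleles": sorted({m.j_call for m in members}),
            },
        ))
    return clonotypes, excluded


def _representative(members) -> str:
    # highest germline V identity, ties by longest sequence then id
    def score(m):
        ident = m.v_identity_pct
        if isinstance(ident, float) and math.isnan(ident):
            ident = -1.0
        return (-ident, -len(m.sequence), m.sequence_id)
    return min(members, key=score).sequence_id


def clonotype_tables(clonotypes) -> dict:
    """Diversity (clonotype counts) and expression (sequence counts)
    tables per V gene, per J gene and per CDR3 length."""
    rows = [
        {
            "v_gene": c.v_call,
            "j_gene": c.j_call,
            "cdr3_length": c.cdr3_length,
            "diversity": 1,
            "expression": c.total,
        }
        for c in clonotypes
    ]
    frame = pd.DataFrame(
        rows, columns=["v_gene", "j_gene", "cdr3_length",
                       "diversity", "expression"])
    out = {}
    for axis in ("v_gene", "j_gene", "cdr3_length"):
        out[axis] = (frame.groupby(axis)[["diversity", "expression"]]
                     .sum().sort_index())
    return out


@dataclass(frozen=True)
class ComparisonRow:
    gene: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    prop_a: float
    prop_b: float
    diff: float
    ci_low: float
    ci_high: float
    z: float
    raw_p: float
    significant: dict = field(default_factory=dict)
    significance_class: str = "non-significant"


def _two_proportion(count_a, total_a, count_b, total_b, alpha=0.05):
    """Pooled two-proportion z-test with an unpooled CI on the difference."""
    p_a = count_a / total_a
    p_b = count_b / total_b
    diff = p_a - p_b
    pooled = (count_a + count_b) / (total_a + total_b)
    se_pooled = math.sqrt(pooled * (1 - pooled)
                          * (1 / total_a + 1 / total_b))
    z = diff / se_pooled if se_pooled > 0 else 0.0
    p_value = 2 * norm.sf(abs(z)) if se_pooled > 0 else 1.0
    se_ci = math.sqrt(p_a * (1 - p_a) / total_a
                      + p_b * (1 - p_b) / total_b)
    crit = norm.ppf(1 - alpha / 2)
    return p_a, p_b, diff, z, p_value, diff - crit * se_ci, diff + crit * se_ci


def compare_clonotype_sets(tables_a, tables_b, axis: str = "v_gene",
                           measure: str = "diversity",
                           alpha: float = 0.05,
                           procedures=None) -> list:
    """Per-gene difference in proportions between two repertoires.

    ``tables_a``/``tables_b`` are outputs of :func:`clonotype_tables`.
    Each gene's count is tested against the set totals with a pooled
    two-proportion z-test; p-values are adjusted by every procedure in
    ``procedures`` (default: all seven).  The significance class records
    agreement: ``All_p`` when every procedure rejects, ``Min_2p`` when at
    least two do, ``Only_BH`` when only Benjamini-Hochberg does, ``rawp``
    when only the unadjusted test does, else ``non-significant``.
    """
    if procedures is None:
        procedures = dict(PROCEDURES)
    ta = tables_a[axis][measure]
    tb = tables_b[axis][measure]
    total_a = int(ta.sum())
    total_b = int(tb.sum())
    if total_a == 0 or total_b == 0:
        raise ValueError("cannot form proportions from a zero-total set")
    genes = sorted(set(ta.index) | set(tb.index), key=str)
    stats = []
    for g in genes:
        ca = int(ta.get(g, 0))
        cb = int(tb.get(g, 0))
        stats.append((g, ca, cb) + _two_proportion(ca, total_a, cb, total_b,
                                                   alpha))
    raw_p = [s[7] for s in stats]
    decisions = {}
    for name, method in procedures.items():
        reject, *_ = multipletests(raw_p, alpha=alpha, method=method)
        decisions[name] = reject
    rows = []
    for i, (g, ca, cb, p_a, p_b, diff, z, p, lo, hi) in enumerate(stats):
        sig = {name: bool(decisions[name][i]) for name in procedures}
        n_agree = sum(sig.values())
        if n_agree == len(procedures) and n_agree > 0:
            klass = "All_p"
        elif n_agree >= 2:
            klass = "Min_2p"
        elif n_agree == 1 and sig.get("bh"):
            klass = "Only_BH"
        elif n_agree == 1:
            klass = "rawp"
        elif p <= alpha:
            klass = "rawp"
        else:
            klass = "non-significant"
        rows.append(ComparisonRow(
            gene=str(g), count_a=ca, total_a=total_a,
            count_b=cb, total_b=total_b,
            prop_a=p_a, prop_b=p_b, diff=diff,
            ci_low=lo, ci_high=hi, z=z, raw_p=p,
            significant=sig, significance_class=klass))
    return rows
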