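"""Readers, writers and configuration for rearrangement tables.

Rearrangement records travel as AIRR-style tab- (or comma-) separated
text with at least ``sequence_id``, ``v_call``, ``j_call`` and a CDR3 or
junction column; column names are remappable through :class:`ToolConfig`
so differently-headed exports can be ingested unchanged.  Rows missing
mandatory fields are collected into a reject report, never dropped
silently.

All writers are deterministic: fixed column order, percentages formatted
to two decimals, IMGT positions as dotted strings, 1-based inclusive
sequence coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clonotype import RearrangementRecord

__all__ = [
    "ToolConfig",
    "ConfigError",
    "read_rearrangements",
    "write_rearrangements",
    "write_fasta",
    "read_fasta",
]

_DEFAULT_COLUMNS = {
    "sequence_id": "sequence_id",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "cdr3_aa": "cdr3_aa",
    "cdr3_nt": "cdr3_nt",
    "junction_aa": "junction_aa",
    "sequence": "sequence",
    "v_identity_pct": "v_identity_pct",
    "productive": "productive",
}

_MANDATORY = ("sequence_id", "v_call", "j_call")


class ConfigError(ValueError):
    """Invalid tool configuration."""


@dataclass(frozen=True)
class ToolConfig:
    """Validated run configuration.

    ``columns`` maps canonical field names to the column headers found in
    the input table; unknown canonical names are rejected.
    """

    columns: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    min_d_length: int = 5
    procedures: tuple = ("bonferroni", "holm", "sidak", "hochberg",
                         "hommel", "bh", "by")

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(_DEFAULT_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown column mappings: {sorted(unknown)}")

    def column(self, name: str) -> str:
        return self.columns.get(name, _DEFAULT_COLUMNS[name])


def read_rearrangements(path, config: ToolConfig | None = None,
                        sep: str | None = None):
    """Read an AIRR-style table into typed records.

    Returns ``(records, rejects)``; each reject is (row index, reason).
    """
    config = config or ToolConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    mapped = {name: config.column(name) for name in _DEFAULT_COLUMNS}
    present = {name: col for name, col in mapped.items()
               if col in frame.columns}
    if not present:
        raise ConfigError(
            f"no mappable columns in {path.name}; found {list(frame.columns)}")
    records = []
    rejects = []
    for idx, row in frame.iterrows():
        values = {name: row[col] for name, col in present.items()}
        missing = [name for name in _MANDATORY if not values.get(name)]
        if missing or not (values.get("cdr3_aa")
                           or values.get("junction_aa")):
            reason = (f"missing {', '.join(missing)}" if missing
                      else "missing cdr3_aa/junction_aa")
            rejects.append((int(idx), reason))
            continue
        ident = values.get("v_identity_pct", "")
        records.append(RearrangementRecord(
            sequence_id=values["sequence_id"],
            v_call=values["v_call"],
            d_call=values.get("d_call") or None,
            j_call=values["j_call"],
            cdr3_aa=values.get("cdr3_aa")
            or values.get("junction_aa", "")[1:-1],
            cdr3_nt=values.get("cdr3_nt", ""),
            junction_aa=values.get("junction_aa", ""),
            v_identity_pct=float(ident) if ident else float("nan"),
            productive=str(values.get("productive", "T")).lower()
            in ("t", "true", "1", "yes", ""),
            sequence=values.get("sequence", ""),
        ))
    return records, rejects


def write_rearrangements(records, path) -> None:
    """Write records back to a deterministic AIRR-style TSV."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        ident = d["v_identity_pct"]
        d["v_identity_pct"] = ("" if ident is None or math.isnan(ident)
                               else f"{ident:.2f}")
        d["d_call"] = d["d_call"] or ""
        d["productive"] = "T" if d["productive"] else "F"
        rows.append(d)
    frame = pd.DataFrame(rows, columns=list(_DEFAULT_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    """Minimal FASTA reader returning an ordered name -> sequence dict."""
    out: dict = {}
    name = None
    chunks: list = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    lines = []
    for name, seq in sequences.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")
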