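"""Tabular and FASTA readers/writers shared by the CLI and the library.

TSV is the canonical tabular format. Pair files carry the off-target task
(columns: sgrna, dna, then score and/or label); guide files carry the
on-target task (columns: seq, efficiency, and optional gene, cell_line,
copy_number, netexpress). Malformed rows raise :class:`ParseError` with the
1-based line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .encoding import AlignedPair, CasSystem, GuideRecord, TokenSequence
from .errors import CrisprAttnError, ParseError

__all__ = [
    "read_pairs",
    "write_pairs",
    "read_guides",
    "write_guides",
    "read_fasta",
    "write_tokens",
]


def read_pairs(path: str | Path, system: CasSystem = CasSystem.CAS9) -> list[AlignedPair]:
    df = pd.read_csv(path, sep="\t")
    required = {"sgrna", "dna"}
    if not required.issubset(df.columns):
        raise ParseError(f"pair file {path} must have columns {sorted(required)}")
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            pairs.append(
                AlignedPair(
                    sgrna_seq=str(row.sgrna),
                    dna_seq=str(row.dna),
                    score=float(row.score) if "score" in df.columns else None,
                    label=int(row.label) if "label" in df.columns else None,
                    system=system,
                )
            )
        except (CrisprAttnError, ValueError) as e:
            raise ParseError(str(e), line=i) from e
    return pairs


def write_pairs(pairs: list[AlignedPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        row = {"sgrna": p.sgrna_seq, "dna": p.dna_seq}
        if p.score is not None:
            row["score"] = p.score
        if p.label is not None:
            row["label"] = p.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_OPTIONAL_GUIDE_COLS = ("gene", "cell_line", "copy_number", "netexpress")


def read_guides(path: str | Path) -> list[GuideRecord]:
    df = pd.read_csv(path, sep="\t")
    if not {"seq", "efficiency"}.issubset(df.columns):
        raise ParseError(f"guide file {path} must have columns ['seq', 'efficiency']")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            records.append(
                GuideRecord(
                    seq=str(row["seq"]),
                    efficiency=float(row["efficiency"]),
                    gene_id=str(row["gene"]) if "gene" in df.columns else None,
                    cell_line=str(row["cell_line"]) if "cell_line" in df.columns else None,
                    copy_number=float(row["copy_number"]) if "copy_number" in df.columns else None,
                    netexpress=float(row["netexpress"]) if "netexpress" in df.columns else None,
                )
            )
        except (CrisprAttnError, ValueError) as e:
            raise ParseError(str(e), line=i) from e
    return records


def write_guides(records: list[GuideRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"seq": r.seq, "efficiency": r.efficiency}
        if r.gene_id is not None:
            row["gene"] = r.gene_id
        if r.cell_line is not None:
            row["cell_line"] = r.cell_line
        if r.copy_number is not None:
            row["copy_number"] = r.copy_number
        if r.netexpress is not None:
            row["netexpress"] = r.netexpress
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[str]:
    """Bare sequence list from a FASTA file."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_tokens(sequences: list[TokenSequence], path: str | Path,
                 ids: Optional[list[str]] = None) -> None:
    """Token TSV: one row per sequence, columns id, vocab, tokens (comma-joined)."""
    rows = []
    for i, ts in enumerate(sequences):
        rows.append(
            {
                "id": ids[i] if ids else f"seq{i}",
                "vocab": ts.vocab,
                "tokens": ",".join(map(str, ts.tokens.tolist())),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
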