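"""File-format helpers: FASTA with key=value header tokens, TSV tables, JSON.

All sequence input is normalized to uppercase RNA (T -> U).  TSV files are
tab-delimited UTF-8; lines starting with '#' are comments.  FASTA headers use
the convention ``>record_id key=value key=value ...`` so that structured
metadata (family labels, stop-codon offsets, species tags) travels with the
sequence without a sidecar file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised for malformed input files; message carries file and position."""


def normalize_rna(seq: str, *, context: str = "") -> str:
    """Uppercase a sequence and convert T to U; reject non-RNA characters.

    The position of the first offending character is reported so that bad
    FASTA records can be located.
    """
    s = seq.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            where = f" in {context}" if context else ""
            raise FormatError(f"non-RNA character {ch!r} at position {i}{where}")
    return s


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str
    attrs: dict

    def attr_int(self, key: str) -> int:
        return int(self.attrs[key])


def _parse_header_attrs(description: str) -> dict:
    attrs = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            attrs[key] = value
    return attrs


def read_fasta(path: str | Path, *, rna: bool = True) -> list[FastaRecord]:
    """Read FASTA into records, parsing ``key=value`` header tokens."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if rna:
            seq = normalize_rna(seq, context=f"{path}:{rec.id}")
        records.append(FastaRecord(rec.id, seq, _parse_header_attrs(rec.description)))
    return records


def write_fasta(path: str | Path, records: Iterable[FastaRecord]) -> None:
    out = []
    for r in records:
        desc = " ".join(f"{k}={v}" for k, v in r.attrs.items())
        out.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed TSV {path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a matrix TSV whose first column is the row index."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Read a species-gene -> reference-gene map.

    Columns: species, species_gene, ref_gene, confidence.  Malformed rows are
    reported with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "species":
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            conf = parts[3] if len(parts) > 3 else "1"
            rows.append((parts[0], parts[1], parts[2], conf))
    return pd.DataFrame(rows, columns=["species", "species_gene", "ref_gene", "confidence"])
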