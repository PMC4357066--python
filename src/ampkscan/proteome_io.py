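"""Reading, validating and normalizing protein FASTA collections.

Supports the ENSEMBL peptide and UniProt header dialects plus plain
headers, with per-record sniffing (``auto``).  Sequences are uppercased,
a trailing stop codon marker ``*`` is stripped, and an internal ``*``
truncates the sequence with a warning, mirroring how translated ENSEMBL
peptides are typically cleaned before motif scanning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ampkscan.motif import AMBIGUOUS_AA, STANDARD_AA

logger = logging.getLogger(__name__)

#: Residues accepted in input sequences: the 20 standard codes, the
#: ambiguity codes X/B/Z, and U/O (selenocysteine, pyrrolysine).
ALLOWED_RESIDUES = STANDARD_AA | AMBIGUOUS_AA | frozenset("UO")

DIALECTS = ("ensembl", "uniprot", "plain", "auto")

_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|\s]+)\|(?P<name>\S+)")
_GENE_SYMBOL_RE = re.compile(r"\bgene_symbol:(\S+)")
_GENE_RE = re.compile(r"\bgene:(\S+)")
_GN_RE = re.compile(r"\bGN=(\S+)")


@dataclass
class ProteinRecord:
    """One FASTA entry with a validated, normalized sequence."""

    protein_id: str
    sequence: str
    description: str = ""
    gene_symbol: str | None = None
    source: str = "plain"
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str) -> tuple[str, list[str]]:
    """Normalize a candidate amino-acid string.

    Uppercases, strips surrounding whitespace and a trailing ``*``;
    an internal ``*`` truncates the sequence with a warning.  Characters
    outside the accepted alphabet are rejected with their position.

    Returns
    -------
    (sequence, warnings)

    Raises
    ------
    ValueError
        On a disallowed character, or if nothing remains after
        normalization.
    """
    seq = raw.strip().upper()
    warnings: list[str] = []
    if seq.endswith("*"):
        seq = seq[:-1]
    star = seq.find("*")
    if star != -1:
        warnings.append(f"internal stop '*' at position {star + 1}; sequence truncated")
        seq = seq[:star]
    for i, ch in enumerate(seq):
        if ch not in ALLOWED_RESIDUES:
            raise ValueError(
                f"disallowed character {ch!r} at position {i + 1} of sequence"
            )
    if not seq:
        raise ValueError("sequence is empty after normalization")
    return seq, warnings


def _sniff_dialect(header: str) -> str:
    if _UNIPROT_RE.match(header):
        return "uniprot"
    first = header.split()[0] if header.split() else ""
    if first.startswith("ENS") or _GENE_SYMBOL_RE.search(header) or _GENE_RE.search(header):
        return "ensembl"
    return "plain"


def _parse_header(header: str, dialect: str) -> tuple[str, str, str | None, str]:
    """Return (protein_id, description, gene_symbol, source) for one header."""
    if dialect == "auto":
        dialect = _sniff_dialect(header)
    tokens = header.split(None, 1)
    first = tokens[0] if tokens else ""
    rest = tokens[1] if len(tokens) > 1 else ""
    if dialect == "uniprot":
        m = _UNIPROT_RE.match(header)
        if m:
            gm = _GN_RE.search(header)
            return m.group("acc"), rest, gm.group(1) if gm else None, "uniprot"
        # headerless accession: fall through to plain parsing, keep the label
        return first, rest, None, "uniprot"
    if dialect == "ensembl":
        gm = _GENE_SYMBOL_RE.search(header) or _GENE_RE.search(header)
        return first, rest, gm.group(1) if gm else None, "ensembl"
    return first, rest, None, "plain"


def read_fasta(path: str | Path, dialect: str = "auto") -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord` s.

    Parameters
    ----------
    path : path
        FASTA file; line-wrapped or single-line, CRLF tolerated.
    dialect : {"ensembl", "uniprot", "plain", "auto"}
        Header dialect; ``auto`` sniffs per record.

    Raises
    ------
    ValueError
        On an unknown dialect, an entry with an empty sequence, or a
        duplicate protein id (both entry numbers are reported).
    FileNotFoundError
        If the file does not exist.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for i, entry in enumerate(SeqIO.parse(handle, "fasta")):
            header = entry.description
            protein_id, description, gene_symbol, source = _parse_header(header, dialect)
            try:
                seq, warnings = validate_sequence(str(entry.seq))
            except ValueError as exc:
                raise ValueError(f"entry {i + 1} ({protein_id!r}): {exc}") from exc
            if protein_id in seen:
                raise ValueError(
                    f"duplicate protein id {protein_id!r}: entries "
                    f"{seen[protein_id] + 1} and {i + 1}"
                )
            seen[protein_id] = i
            for w in warnings:
                logger.warning("%s: %s", protein_id, w)
            records.append(
                ProteinRecord(protein_id, seq, description, gene_symbol, source, warnings)
            )
    if not records:
        logger.warning("no FASTA entries found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA (id + description headers, wrapped sequence)."""
    with open(path, "w") as out:
        for rec in records:
            header = rec.protein_id
            if rec.description:
                header += f" {rec.description}"
            out.write(f">{header}\n")
            for start in range(0, len(rec.sequence), width):
                out.write(rec.sequence[start : start + width] + "\n")


def dedup_by_sequence(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Collapse records with identical sequences.

    Keeps the first record of each distinct sequence as the representative.

    Returns
    -------
    (representatives, mapping)
        ``mapping`` maps every representative id to the list of ids it
        absorbed (empty for unique sequences).
    """
    kept: list[ProteinRecord] = []
    by_seq: dict[str, str] = {}
    mapping: dict[str, list[str]] = {}
    for rec in records:
        rep = by_seq.get(rec.sequence)
        if rep is None:
            by_seq[rec.sequence] = rec.protein_id
            mapping[rec.protein_id] = []
            kept.append(rec)
        else:
            mapping[rep].append(rec.protein_id)
    return kept, mapping


def manifest_frame(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """TSV-ready manifest of a loaded collection."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "length": [len(r) for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "source": [r.source for r in records],
            "n_warnings": [len(r.warnings) for r in records],
        }
    )
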