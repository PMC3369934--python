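"""Sequence and table I/O.

Reads FASTA/FASTQ through Biopython, normalising bases to the {A,C,G,T,N}
alphabet on ingest (ambiguity codes become N — they carry no information
for exact-prefix clustering), and writes the tab-separated error-profile
tables (raw-count and percent-scaled layouts).
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MAX_PHRED = 93

# every byte outside ACGTN (upper case) maps to 'N'
_CLEAN_TABLE = str.maketrans(
    {chr(c): "N" for c in range(256) if chr(c) not in "ACGTN"}
)


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


@dataclass
class SequenceRead:
    """One sequencing read: identifier, bases, optional Phred qualities."""

    id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        if self.quals is not None:
            if len(self.quals) != len(self.bases):
                raise ParseError(
                    f"read {self.id!r}: {len(self.quals)} quality values for "
                    f"{len(self.bases)} bases"
                )
            bad = [q for q in self.quals if q < 0 or q > MAX_PHRED]
            if bad:
                raise ParseError(
                    f"read {self.id!r}: Phred value {bad[0]} outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.bases)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _clean_bases(raw: str, read_id: str) -> str:
    up = raw.upper()
    cleaned = up.translate(_CLEAN_TABLE)
    if cleaned != up:
        n_mapped = sum(a != b for a, b in zip(up, cleaned))
        logger.warning(
            "read %s: %d non-ACGTN character(s) mapped to N", read_id, n_mapped
        )
    return cleaned


def read_fasta(path: str | Path) -> Iterator[SequenceRead]:
    """Stream reads from a (possibly gzipped, multi-line) FASTA file.

    Bases are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a logged warning. A sequence line before any ``>`` header is a
    :class:`ParseError` naming the offending line.
    """
    with _open_text(path) as handle:
        # Biopython silently skips leading junk; enforce a header first.
        pos = handle.tell()
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        handle.seek(pos)
        for record in SeqIO.parse(handle, "fasta"):
            yield SequenceRead(id=record.id, bases=_clean_bases(str(record.seq), record.id))


def detect_phred_offset(path: str | Path) -> int:
    """Guess the Phred ASCII offset (33 or 64) of a FASTQ file.

    Scans the quality lines of up to the first 10,000 records: any
    character code below 64 forces offset 33; otherwise 64 is assumed
    (codes in the overlap region are compatible with both encodings).
    A file with records but no quality characters defaults to 33.
    """
    n_records = 0
    min_code = 256
    with _open_text(path) as handle:
        while n_records < 10_000:
            header = handle.readline()
            if not header:
                break
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual and not seq.strip() and not plus.strip() and not header.strip():
                break
            n_records += 1
            q = qual.rstrip("\n")
            if q:
                min_code = min(min_code, min(ord(c) for c in q))
    if n_records == 0:
        raise ParseError(f"{path}: empty FASTQ file")
    if min_code == 256:  # records present but zero-length qualities
        return 33
    return 33 if min_code < 64 else 64


def read_fastq(path: str | Path, offset: int | str = "auto") -> Iterator[SequenceRead]:
    """Stream reads from a 4-line-per-record FASTQ file.

    Qualities are decoded as ``char_code - offset``; ``offset="auto"``
    runs :func:`detect_phred_offset` first. Length mismatches between
    sequence and quality strings, or decoded values outside [0, 93],
    raise :class:`ParseError`.
    """
    if offset == "auto":
        offset = detect_phred_offset(path)
    if offset not in (33, 64):
        raise ParseError(f"unsupported Phred offset {offset!r} (expected 33 or 64)")
    fmt = "fastq" if offset == 33 else "fastq-illumina"
    with _open_text(path) as handle:
        try:
            for record in SeqIO.parse(handle, fmt):
                quals = list(record.letter_annotations["phred_quality"])
                yield SequenceRead(
                    id=record.id,
                    bases=_clean_bases(str(record.seq), record.id),
                    quals=quals,
                )
        except ValueError as exc:  # Biopython's FASTQ validation
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(reads: Iterable[SequenceRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.id}\n{read.bases}\n")


def write_fastq(reads: Iterable[SequenceRead], path: str | Path, offset: int = 33) -> None:
    if offset not in (33, 64):
        raise ParseError(f"unsupported Phred offset {offset!r}")
    records = (
        SeqRecord(
            Seq(read.bases),
            id=read.id,
            description="",
            letter_annotations={"phred_quality": read.quals},
        )
        for read in reads
    )
    fmt = "fastq" if offset == 33 else "fastq-illumina"
    with open(path, "w") as handle:
        SeqIO.write(records, handle, fmt)


def phred_to_error_percent(q: float) -> float:
    """Convert a Phred quality score to percent error: 100 * 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"negative Phred score: {q}")
    return 100.0 * 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

# positional-block column order; InDel = Insertion + Deletion, Total = row sum
TABLE_COLUMNS = [
    "Consensus Position",
    "match_A",
    "match_T",
    "match_C",
    "match_G",
    "match_N",
    "A_subst",
    "T_subst",
    "C_subst",
    "G_subst",
    "Insertion",
    "Deletion",
    "InDel",
    "Total",
]

_SUMMARY_KEYS = ["A_subst", "T_subst", "C_subst", "G_subst", "InDel", "Total"]


def write_profile_table(profile, summary, path, mode: str = "raw", sample_id: str = "-") -> None:
    """Write an error profile plus its summary as a TSV table.

    The table has three blocks: ``ID`` (sample identifier), ``Summary``
    (the five per-type error percentages and their total, with the prefix
    length noted) and ``bp counts`` (one row per consensus position).
    ``mode="raw"`` writes event counts and the count-weighted summary
    (``Total_err``); ``mode="percent"`` writes per-position percentages
    and the position-averaged summary (``Total_avg_err``). Zero-coverage
    positions are written as blank rows — no data, not zero error.
    """
    from drisee.profile import normalize_profile  # deferred: avoids import cycle

    if mode not in ("raw", "percent"):
        raise ValueError(f"mode must be 'raw' or 'percent', got {mode!r}")
    if profile.counts.empty:
        raise ValueError("cannot write an empty profile")

    if mode == "raw":
        total_label = "Total_err"
        comp = summary.weighted
    else:
        total_label = "Total_avg_err"
        comp = summary.averaged

    ncol = len(TABLE_COLUMNS)
    lines: list[str] = []

    def row(cells: list[str]) -> None:
        cells = cells + [""] * (ncol - len(cells))
        lines.append("\t".join(cells))

    row(["ID:"])
    row([sample_id])
    row(["Summary:"])
    header = ["", "", "A_subst", "T_subst", "C_subst", "G_subst", "InDel", total_label,
              "", f"prefix_length = {profile.prefix_length}"]
    row(header)
    row(["", ""] + [f"{comp[k]:.4f}%" for k in _SUMMARY_KEYS])
    row(["bp counts:"])
    row(list(TABLE_COLUMNS))

    counts = profile.counts
    if mode == "raw":
        table = counts
    else:
        table = normalize_profile(profile)
    for pos in table.index:
        r = table.loc[pos]
        if mode == "percent" and r.isna().all():
            row([str(pos)])  # zero coverage: blank row
            continue
        ins = r["insertion"]
        dele = r["deletion"]
        cells = [
            r["match_A"], r["match_T"], r["match_C"], r["match_G"], r["match_N"],
            r["subst_A"], r["subst_T"], r["subst_C"], r["subst_G"],
            ins, dele, ins + dele,
        ]
        if mode == "raw":
            cells = [str(int(c)) for c in cells]
            cells.append(str(int(counts.loc[pos].sum())))
        else:
            cells = [f"{c:.3f}%" for c in cells]
            total = sum(
                r[k] for k in ("match_A", "match_T", "match_C", "match_G", "match_N",
                               "subst_A", "subst_T", "subst_C", "subst_G",
                               "insertion", "deletion")
            )
            cells.append(f"{total:.3f}%")
        row([str(pos)] + cells)

    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_table(path: str | Path):
    """Parse a raw-mode profile table written by :func:`write_profile_table`."""
    import pandas as pd

    from drisee.profile import EVENT_COLUMNS, ErrorProfile

    lines = Path(path).read_text().splitlines()
    prefix_length = None
    data_start = None
    for i, line in enumerate(lines):
        if "prefix_length" in line:
            for cell in line.split("\t"):
                if "prefix_length" in cell:
                    prefix_length = int(cell.split("=")[1])
        if line.split("\t")[0] == "Consensus Position":
            data_start = i + 1
            break
    if prefix_length is None or data_start is None:
        raise ParseError(f"{path}: not a recognisable profile table")

    positions = []
    rows = []
    for line in lines[data_start:]:
        cells = line.split("\t")
        if not cells[0].strip():
            continue
        positions.append(int(cells[0]))
        vals = cells[1:11]  # match_A..match_N, A..G_subst, Insertion
        dele = cells[11]
        rows.append([int(v.rstrip("%") or 0) for v in vals] + [int(dele or 0)])
    counts = pd.DataFrame(rows, index=positions, columns=EVENT_COLUMNS)
    return ErrorProfile(counts=counts, prefix_length=prefix_length)
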