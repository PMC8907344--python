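"""Readers, writers and record types for the tabular/sequence/gene-set formats.

Site and protein tables are UTF-8 tab-separated files with a header row;
lines starting with ``#`` are comments.  Intensities are arbitrary linear
LFQ units; an empty cell, ``NaN``, or ``0`` encodes a value that was never
quantified (the MaxQuant LFQ convention).  Parsing is strict: a cell that
does not parse as a plain non-negative float (no thousands separators, no
locale guessing) is a row-level error, because silent coercion corrupts
intensity ratios.

Site coordinates are 1-based positions on the protein sequence, matching
the "K147" convention of the PTM literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .design import StudyDesign
from .errors import FormatError, ValidationError

MISSING = None

SITE_COLUMNS = ("accession", "gene", "peptide", "sites")
PROTEIN_COLUMNS = ("accession", "gene")

_MISSING_TOKENS = {"", "nan", "na"}


@dataclass
class SiteRecord:
    """One quantified acetyl-peptide: sequence, its acetylated K position(s),
    and a per-sample intensity vector with imputation flags."""

    protein_accession: str
    gene_symbol: str
    peptide_sequence: str
    site_positions: tuple[int, ...]
    intensity: dict[str, float | None]
    imputed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_positions:
            raise ValidationError("site_positions must be non-empty")
        if any(p < 1 for p in self.site_positions):
            raise ValidationError("site positions are 1-based and must be >= 1")
        for s, v in self.intensity.items():
            if v is not None and v < 0:
                raise ValidationError(f"negative intensity in sample {s!r}")
        if not self.imputed:
            self.imputed = {s: False for s in self.intensity}

    @property
    def parent_accession(self) -> str:
        """First accession token; the normalization parent for shared peptides."""
        return self.protein_accession.split(";")[0].strip()

    @property
    def peptide_key(self) -> str:
        """Peptide identity: sequence plus acetyl-site set."""
        return f"{self.peptide_sequence}@{','.join(map(str, self.site_positions))}"


@dataclass
class ProteinRecord:
    """Global (whole-lysate) LFQ quantification of one protein."""

    protein_accession: str
    gene_symbol: str
    lfq: dict[str, float | None]
    imputed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, v in self.lfq.items():
            if v is not None and v < 0:
                raise ValidationError(f"negative LFQ in sample {s!r}")
        if not self.imputed:
            self.imputed = {s: False for s in self.lfq}


@dataclass(frozen=True)
class SequenceWindow:
    """A site-centered amino-acid context; out-of-protein positions are '-'."""

    accession: str
    center_position: int
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) % 2 != 1:
            raise ValidationError("window length must be odd")
        mid = len(self.residues) // 2
        if self.residues[mid] != "K":
            raise ValidationError("window center must be an acetylatable K")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Term -> gene-symbol sets (symbols uppercased, deduplicated)."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]


def _parse_intensity(cell: str, *, row: int, column: str) -> float | None:
    text = cell.strip()
    if text.lower() in _MISSING_TOKENS:
        return MISSING
    try:
        value = float(text)
    except ValueError:
        raise FormatError(
            f"row {row}: intensity {cell!r} in column {column!r} is not a plain number"
        ) from None
    if value != value:  # NaN literal such as "nan"
        return MISSING
    if value < 0:
        raise FormatError(f"row {row}: negative intensity {value} in column {column!r}")
    if value == 0.0:
        return MISSING  # LFQ 0 means "not quantified"
    return value


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    return frame


def read_site_table(path: str | Path, design: StudyDesign) -> list[SiteRecord]:
    """Read a tab-separated acetyl-site table (one acetyl-peptide per row)."""
    samples = design.sample_ids
    frame = _read_table(path, (*SITE_COLUMNS, *samples))
    records: list[SiteRecord] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        sites_cell = row_map["sites"].strip()
        try:
            positions = tuple(int(tok) for tok in sites_cell.split(";") if tok.strip())
        except ValueError:
            raise FormatError(
                f"row {row_index}: sites cell {sites_cell!r} is not ';'-separated integers"
            ) from None
        if not positions:
            raise FormatError(f"row {row_index}: empty sites cell")
        intensity = {
            s: _parse_intensity(row_map[s], row=row_index, column=s) for s in samples
        }
        records.append(
            SiteRecord(
                protein_accession=row_map["accession"].strip(),
                gene_symbol=row_map["gene"].strip().upper(),
                peptide_sequence=row_map["peptide"].strip().upper(),
                site_positions=positions,
                intensity=intensity,
            )
        )
    return records


def read_protein_table(path: str | Path, design: StudyDesign) -> list[ProteinRecord]:
    """Read a tab-separated global-protein LFQ table (one protein per row)."""
    samples = design.sample_ids
    frame = _read_table(path, (*PROTEIN_COLUMNS, *samples))
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for row_index, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        accession = row_map["accession"].strip()
        seen[accession] = seen.get(accession, 0) + 1
        lfq = {
            s: _parse_intensity(row_map[s], row=row_index, column=s) for s in samples
        }
        records.append(
            ProteinRecord(
                protein_accession=accession,
                gene_symbol=row_map["gene"].strip().upper(),
                lfq=lfq,
            )
        )
    duplicates = sorted(acc for acc, n in seen.items() if n > 1)
    if duplicates:
        raise FormatError(
            "duplicate protein accessions (one LFQ vector per protein): "
            + ", ".join(duplicates)
        )
    return records


def _format_value(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_site_table(
    records: Iterable[SiteRecord],
    design: StudyDesign,
    path: str | Path,
    comment: str | None = None,
) -> None:
    samples = design.sample_ids
    with open(path, "w", encoding="utf-8") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        handle.write("\t".join((*SITE_COLUMNS, *samples)) + "\n")
        for r in records:
            cells = [
                r.protein_accession,
                r.gene_symbol,
                r.peptide_sequence,
                ";".join(map(str, r.site_positions)),
                *(_format_value(r.intensity[s]) for s in samples),
            ]
            handle.write("\t".join(cells) + "\n")


def write_protein_table(
    records: Iterable[ProteinRecord],
    design: StudyDesign,
    path: str | Path,
    comment: str | None = None,
) -> None:
    samples = design.sample_ids
    with open(path, "w", encoding="utf-8") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        handle.write("\t".join((*PROTEIN_COLUMNS, *samples)) + "\n")
        for r in records:
            cells = [
                r.protein_accession,
                r.gene_symbol,
                *(_format_value(r.lfq[s]) for s in samples),
            ]
            handle.write("\t".join(cells) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a proteome FASTA into {accession: uppercase sequence}.

    The accession is the first whitespace-delimited token of the header.
    Duplicate accessions are an error.
    """
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise FormatError(f"duplicate FASTA accession {record.id!r}")
        proteome[record.id] = str(record.seq).upper()
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for accession, sequence in proteome.items():
            handle.write(f">{accession}\n")
            for start in range(0, len(sequence), width):
                handle.write(sequence[start : start + width] + "\n")


def window_at(sequence: str, position: int, half_width: int) -> str:
    """Half_width-residue context around a 1-based position, '-'-padded."""
    chars = []
    for offset in range(-half_width, half_width + 1):
        index = position - 1 + offset
        chars.append(sequence[index] if 0 <= index < len(sequence) else "-")
    return "".join(chars)


def extract_windows(
    records: Iterable[SiteRecord],
    proteome: Mapping[str, str],
    half_width: int = 15,
) -> list[SequenceWindow]:
    """One K-centered window per (record, site position).

    Sites whose protein residue is not K are skipped with a warning;
    an accession absent from the proteome is an error.
    """
    if half_width < 1:
        raise ValidationError("half_width must be a positive integer")
    windows: list[SequenceWindow] = []
    skipped = 0
    for record in records:
        accession = record.parent_accession
        if accession not in proteome:
            raise FormatError(f"accession {accession!r} not found in the proteome")
        sequence = proteome[accession]
        for position in record.site_positions:
            if position > len(sequence) or sequence[position - 1] != "K":
                skipped += 1
                continue
            windows.append(
                SequenceWindow(
                    accession=accession,
                    center_position=position,
                    residues=window_at(sequence, position, half_width),
                )
            )
    if skipped:
        warnings.warn(
            f"skipped {skipped} site(s) whose protein residue is not K",
            stacklevel=2,
        )
    return windows


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: term, description, then member symbols."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {line_number}: GMT lines need term, description and >=1 member"
                )
            term, description, *members = fields
            unique = tuple(dict.fromkeys(m.strip().upper() for m in members if m.strip()))
            if not unique:
                raise FormatError(f"line {line_number}: gene set {term!r} has no members")
            sets[term] = GeneSet(term_id=term, description=description, members=unique)
    return GeneSetCollection(sets=sets)


def copy_records(records: Iterable[SiteRecord | ProteinRecord]) -> list:
    """Shallow-copy records with fresh value/flag dicts (for non-mutating stages)."""
    out = []
    for r in records:
        if isinstance(r, SiteRecord):
            out.append(replace(r, intensity=dict(r.intensity), imputed=dict(r.imputed)))
        else:
            out.append(replace(r, lfq=dict(r.lfq), imputed=dict(r.imputed)))
    return out
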