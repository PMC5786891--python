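"""Sequence and metadata I/O.

Reads multi-FASTA nucleotide files and tabular group (taxonomy) metadata,
and writes cluster assignments and radial-layout coordinates as plain
TSV/CSV.  No binary formats.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from spectraclust.clustering import ClusterModel
    from spectraclust.radial_layout import RadialLayout

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted after uppercasing ('U' is normalized to 'T').
UNAMBIGUOUS = frozenset("ACGT")
AMBIGUOUS = frozenset("RYSWKMBDHVN")
VALID_CHARS = UNAMBIGUOUS | AMBIGUOUS | {"U"}

#: Placeholder group label for ids with no annotation at some level.
UNKNOWN_LABEL = "Unknown"

_STYLE_COLUMNS = ("color", "marker")


@dataclass(frozen=True)
class DnaSequence:
    """An identified nucleotide sequence.

    ``residues`` is stored uppercased with ``U`` replaced by ``T``; every
    character is a member of the IUPAC nucleotide alphabet.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        normalized = self.residues.upper().replace("U", "T")
        for pos, char in enumerate(normalized):
            if char not in UNAMBIGUOUS and char not in AMBIGUOUS:
                raise ValueError(
                    f"sequence {self.id!r}: illegal character {char!r} at position {pos + 1}"
                )
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)


class GroupTable:
    """Ordered group labels (e.g. kingdom, phylum, class) per sequence id.

    Levels are a fixed ordered list; a missing label at any level is stored
    as the explicit string ``"Unknown"``.  Optional per-id style attributes
    (color, marker) may ride along for plotting.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        levels: Sequence[str],
        styles: pd.DataFrame | None = None,
    ) -> None:
        levels = list(levels)
        missing = [lv for lv in levels if lv not in table.columns]
        if missing:
            raise ValueError(f"group table is missing level columns: {missing}")
        if table.index.has_duplicates:
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"duplicate sequence id in group table: {dup!r}")
        self._table = table[levels].fillna(UNKNOWN_LABEL).astype(str)
        self._table = self._table.replace("", UNKNOWN_LABEL)
        self.levels = levels
        self.styles = styles

    @property
    def ids(self) -> list[str]:
        return list(self._table.index)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._table.index

    def __len__(self) -> int:
        return len(self._table)

    def get(self, seq_id: str) -> list[str]:
        """Ordered labels for one id; KeyError if absent."""
        if seq_id not in self._table.index:
            raise KeyError(f"sequence id {seq_id!r} not present in group table")
        return list(self._table.loc[seq_id])

    def labels(self, level: str | None = None) -> pd.Series:
        """Label per id at ``level`` (default: first level)."""
        if level is None:
            level = self.levels[0]
        if level not in self.levels:
            raise KeyError(f"unknown group level {level!r}; available: {self.levels}")
        return self._table[level]

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()

    def check_ids(self, ids: Iterable[str]) -> None:
        """Log a warning for any referenced id absent from the table."""
        absent = [i for i in ids if i not in self._table.index]
        if absent:
            logger.warning(
                "%d sequence id(s) have no group annotation: %s",
                len(absent),
                ", ".join(absent[:10]),
            )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Sequence[str]], levels: Sequence[str]
    ) -> "GroupTable":
        frame = pd.DataFrame.from_dict(
            {k: list(v) for k, v in mapping.items()}, orient="index", columns=list(levels)
        )
        return cls(frame, levels)


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Parse a multi-FASTA file into a list of :class:`DnaSequence`.

    Record order is preserved; the id is the first whitespace-delimited
    header token.  Raises ``ValueError`` for an empty file, a duplicate id,
    or an illegal residue character (reported with its position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seqs: list[DnaSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        seqs.append(DnaSequence(id=rec.id, residues=str(rec.seq), description=rec.description))
    return seqs


def write_fasta(seqs: Sequence[DnaSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA (round-trips through :func:`read_fasta`)."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            header = seq.id
            if seq.description and seq.description != seq.id:
                header = seq.description
            fh.write(f">{header}\n")
            for start in range(0, len(seq.residues), width):
                fh.write(seq.residues[start : start + width] + "\n")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_groups(path: str | Path) -> GroupTable:
    """Read a tab- or comma-separated group table.

    The first column must be headed ``id`` (case-insensitive); remaining
    columns are ordered group levels, except the style columns ``color``
    and ``marker``.  Empty cells become ``"Unknown"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"group table not found: {path}")
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"group table {path} is empty")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        header = [h.strip() for h in header]
        if not header or header[0].lower() != "id":
            raise ValueError(
                f"group table {path} must have 'id' as its first header column, got {header[:1]}"
            )
        rows: list[list[str]] = []
        ids: list[str] = []
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"group table {path}: line {lineno} has {len(row)} fields, expected {len(header)}"
                )
            if not row[0].strip():
                raise ValueError(f"group table {path}: line {lineno} has an empty id")
            ids.append(row[0].strip())
            rows.append([c.strip() for c in row[1:]])
    frame = pd.DataFrame(rows, columns=header[1:], index=pd.Index(ids, name="id"))
    levels = [c for c in frame.columns if c.lower() not in _STYLE_COLUMNS]
    if not levels:
        raise ValueError(f"group table {path} has no group-level columns")
    style_cols = [c for c in frame.columns if c.lower() in _STYLE_COLUMNS]
    styles = frame[style_cols] if style_cols else None
    return GroupTable(frame, levels, styles=styles)


def cluster_name(label: int) -> str:
    """Human-readable 1-based cluster name for a 0-based internal label."""
    return f"C-{label + 1}"


def parse_cluster_name(name: str) -> int:
    if not name.startswith("C-"):
        raise ValueError(f"malformed cluster name {name!r}")
    return int(name[2:]) - 1


def write_assignments(model: "ClusterModel", ids: Sequence[str], path: str | Path) -> None:
    """Write per-sequence cluster assignments as TSV.

    Columns: ``id``, ``cluster`` (1-based ``C-j``), ``distance_to_centroid``.
    Row order follows the input order of ``ids``.
    """
    if len(ids) != len(model.labels):
        raise ValueError(
            f"ids ({len(ids)}) and model labels ({len(model.labels)}) differ in length"
        )
    frame = pd.DataFrame(
        {
            "id": list(ids),
            "cluster": [cluster_name(lbl) for lbl in model.labels],
            "distance_to_centroid": model.distances,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_assignments`; adds a 0-based ``label`` column."""
    frame = pd.read_csv(path, sep="\t", dtype={"id": str})
    if len(frame):
        frame["label"] = [parse_cluster_name(c) for c in frame["cluster"]]
    else:
        frame["label"] = pd.Series(dtype=int)
    return frame


def write_layout(
    layout: "RadialLayout", sequences_path: str | Path, clusters_path: str | Path | None = None
) -> None:
    """Export layout coordinates: per-sequence CSV and optional per-cluster CSV."""
    layout.sequences.to_csv(sequences_path, index=False)
    if clusters_path is not None:
        layout.clusters.to_csv(clusters_path, index=False)


def write_spectra_csv(spectra, path: str | Path) -> None:
    """Export a SpectrumSet as a plain CSV matrix (rows = ids, columns = bins)."""
    frame = pd.DataFrame(spectra.spectra, index=pd.Index(spectra.ids, name="id"))
    frame.columns = [f"bin_{q}" for q in range(spectra.n)]
    frame.to_csv(path)
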