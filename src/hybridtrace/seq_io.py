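"""Aligned-FASTA and sample-metadata I/O.

Alignments are pre-built upstream (the markers here — nuclear ITS and the
plastid spacers rpl32-trnL and petL-psbE — are short Sanger amplicons that
are aligned in a sequence editor); this module only reads, validates and
writes them.  Alignment coordinates are 1-based throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentGeometryError, AlphabetError, ValidationError

ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

MARKERS = ("ITS", "rpl32-trnL", "petL-psbE")


def normalize(seq: str) -> str:
    """Uppercase and map RNA 'U' to 'T'; no other rewriting."""
    return seq.upper().replace("U", "T")


@dataclass
class AlignedMatrix:
    """An alignment: named, equal-length rows over the IUPAC+gap alphabet.

    Invariants (enforced in ``__post_init__``): unique names, all rows the
    same length >= 1, only symbols from :data:`ALPHABET` after normalization.
    """

    names: list[str]
    rows: list[str]
    marker: str | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentGeometryError("names and rows differ in count")
        if not self.rows:
            raise AlignmentGeometryError("empty alignment")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValidationError(f"duplicate sequence names: {dupes}")
        self.rows = [normalize(r) for r in self.rows]
        width = len(self.rows[0])
        if width < 1:
            raise AlignmentGeometryError("alignment length must be >= 1")
        for name, row in zip(self.names, self.rows):
            if len(row) != width:
                raise AlignmentGeometryError(
                    f"ragged alignment: record {name!r} has length {len(row)}, expected {width}"
                )
            for col, sym in enumerate(row, start=1):
                if sym not in ALPHABET:
                    raise AlphabetError(
                        f"illegal symbol {sym!r} in record {name!r} at column {col}",
                        record=name,
                        column=col,
                    )

    @property
    def length(self) -> int:
        """Alignment width in columns (positions 1..length)."""
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def items(self):
        return zip(self.names, self.rows)


def read_alignment(path: str | Path, marker: str | None = None) -> AlignedMatrix:
    """Read a multi-FASTA alignment (wrapped or unwrapped) into an AlignedMatrix."""
    if marker is not None and marker not in MARKERS:
        raise ValidationError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentGeometryError(f"no FASTA records in {path}")
    return AlignedMatrix(
        names=[r.id for r in records],
        rows=[str(r.seq) for r in records],
        marker=marker,
    )


def write_alignment(matrix: AlignedMatrix, path: str | Path) -> None:
    """Write an AlignedMatrix as unwrapped multi-FASTA (stable, byte-reproducible)."""
    records = [SeqRecord(Seq(row), id=name, description="") for name, row in matrix.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


@dataclass
class SampleRecord:
    """One surveyed individual: where it was collected and its accessions."""

    sample_id: str
    region: str
    locality: str
    taxon_label: str | None = None
    fertile: bool | None = None
    accession_its: str | None = None
    accession_rpl32: str | None = None
    accession_petl: str | None = None


_REQUIRED_COLUMNS = ("sample_id", "region", "locality")
_OPTIONAL_COLUMNS = ("taxon_label", "fertile", "accession_its", "accession_rpl32", "accession_petl")


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def _opt_bool(value) -> bool | None:
    v = _opt(value)
    if v is None:
        return None
    low = v.strip().lower()
    if low in ("true", "1", "yes", "y"):
        return True
    if low in ("false", "0", "no", "n"):
        return False
    raise ValidationError(f"unparseable fertile flag: {value!r}")


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read the tab-separated sample-metadata table.

    Required columns: sample_id, region, locality.  Optional columns:
    taxon_label, fertile, accession_its, accession_rpl32, accession_petl.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"duplicate sample_id(s): {dupes}")
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        for col in _REQUIRED_COLUMNS:
            if str(row[col]).strip() == "":
                raise ValidationError(f"empty {col!r} in row {i + 1}")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                region=str(row["region"]),
                locality=str(row["locality"]),
                taxon_label=_opt(row.get("taxon_label")),
                fertile=_opt_bool(row.get("fertile")),
                accession_its=_opt(row.get("accession_its")),
                accession_rpl32=_opt(row.get("accession_rpl32")),
                accession_petl=_opt(row.get("accession_petl")),
            )
        )
    return records


def write_samples(records: list[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "region": r.region,
                "locality": r.locality,
                "taxon_label": r.taxon_label or "",
                "fertile": "" if r.fertile is None else str(r.fertile).lower(),
                "accession_its": r.accession_its or "",
                "accession_rpl32": r.accession_rpl32 or "",
                "accession_petl": r.accession_petl or "",
            }
        )
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
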