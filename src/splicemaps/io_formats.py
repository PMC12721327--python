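"""Readers and writers for the file formats the pipeline touches.

Coordinates are 0-based half-open throughout (BED convention). GTF output
(1-based closed) is converted at the boundary. ``upstream``/``downstream``
always refer to transcript orientation, so on the minus strand the
upstream exon lies genomically to the right of the cassette exon.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_VALID_BASES = frozenset("ACGTN")

NA = "NA"


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed or fails validation."""


class EventTableError(ValueError):
    """Raised when an event-table row violates its coordinate invariants."""


class GenomeStore:
    """In-memory genome: contig name -> uppercase A/C/G/T/N sequence.

    ``fetch`` is strand-aware: minus-strand requests return the reverse
    complement of the plus-strand slice, so sequences come back in
    transcript orientation.
    """

    def __init__(self, contigs: dict[str, str] | None = None):
        self._contigs: dict[str, str] = {}
        if contigs:
            for name, seq in contigs.items():
                self.add(name, seq)

    def add(self, name: str, sequence: str) -> None:
        if name in self._contigs:
            raise FastaParseError(f"duplicate contig name: {name!r}")
        seq = sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaParseError(
                f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        self._contigs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __len__(self) -> int:
        return len(self._contigs)

    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, name: str) -> int:
        return len(self._contigs[name])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        if contig not in self._contigs:
            raise KeyError(f"unknown contig: {contig!r}")
        seq = self._contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"request {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        if strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        sub = seq[start:end]
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


def read_fasta(path: str | Path) -> GenomeStore:
    """Load a (wrapped or unwrapped) multi-record FASTA into a GenomeStore."""
    path = Path(path)
    store = GenomeStore()
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
    for record in SeqIO.parse(str(path), "fasta"):
        store.add(record.id, str(record.seq))
    return store


def write_fasta(store: GenomeStore, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name in store.contig_names():
            out.write(f">{name}\n")
            seq = store.fetch(name, 0, store.contig_length(name))
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclasses.dataclass
class EventTableRow:
    """One skipped-exon event with per-replicate junction counts.

    ``ijc``/``sjc`` are inclusion/skipping junction counts; sample1 is the
    reference condition (differentiated control) throughout.
    """

    event_id: str
    gene_id: str
    contig: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_exon_start: int
    upstream_exon_end: int
    downstream_exon_start: int
    downstream_exon_end: int
    ijc_sample1: list[int]
    sjc_sample1: list[int]
    ijc_sample2: list[int]
    sjc_sample2: list[int]
    inc_form_len: int
    skip_form_len: int

    def validate(self) -> None:
        eid = self.event_id
        if self.strand not in {"+", "-"}:
            raise EventTableError(f"{eid}: strand must be + or -")
        if not self.exon_start < self.exon_end:
            raise EventTableError(f"{eid}: exon_end must exceed exon_start")
        if self.strand == "+":
            ordered = (
                self.upstream_exon_start < self.upstream_exon_end <= self.exon_start
                and self.exon_end <= self.downstream_exon_start < self.downstream_exon_end
            )
        else:
            ordered = (
                self.downstream_exon_start < self.downstream_exon_end <= self.exon_start
                and self.exon_end <= self.upstream_exon_start < self.upstream_exon_end
            )
        if not ordered:
            raise EventTableError(f"{eid}: exon coordinates out of order for strand {self.strand}")
        for name in ("ijc_sample1", "sjc_sample1", "ijc_sample2", "sjc_sample2"):
            counts = getattr(self, name)
            if any(c < 0 for c in counts):
                raise EventTableError(f"{eid}: negative count in {name}")
        if len(self.ijc_sample1) != len(self.sjc_sample1) or len(self.ijc_sample2) != len(
            self.sjc_sample2
        ):
            raise EventTableError(f"{eid}: replicate list lengths differ within a sample")
        if self.inc_form_len < 1 or self.skip_form_len < 1:
            raise EventTableError(f"{eid}: form lengths must be positive")

    # transcript-orientation intron coordinates, used by region extraction
    @property
    def upstream_intron(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.upstream_exon_end, self.exon_start)
        return (self.exon_end, self.upstream_exon_start)

    @property
    def downstream_intron(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.exon_end, self.downstream_exon_start)
        return (self.downstream_exon_end, self.exon_start)


_COUNT_COLS = ("ijc_sample1", "sjc_sample1", "ijc_sample2", "sjc_sample2")
_INT_COLS = (
    "exon_start",
    "exon_end",
    "upstream_exon_start",
    "upstream_exon_end",
    "downstream_exon_start",
    "downstream_exon_end",
    "inc_form_len",
    "skip_form_len",
)

EVENT_TABLE_COLUMNS = (
    "event_id",
    "gene_id",
    "contig",
    "strand",
    *_INT_COLS[:6],
    *_COUNT_COLS,
    "inc_form_len",
    "skip_form_len",
)


def _parse_counts(field: str) -> list[int]:
    return [int(tok) for tok in str(field).split(",")]


def read_event_table(path: str | Path) -> list[EventTableRow]:
    """Read a tab-separated skipped-exon event table and validate each row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(EVENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise EventTableError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        kwargs = {
            "event_id": rec["event_id"],
            "gene_id": rec["gene_id"],
            "contig": rec["contig"],
            "strand": rec["strand"],
        }
        for col in _INT_COLS:
            kwargs[col] = int(rec[col])
        for col in _COUNT_COLS:
            kwargs[col] = _parse_counts(rec[col])
        row = EventTableRow(**kwargs)
        row.validate()
        rows.append(row)
    return rows


def write_event_table(rows: Sequence[EventTableRow], path: str | Path) -> None:
    records = []
    for row in rows:
        rec = {
            "event_id": row.event_id,
            "gene_id": row.gene_id,
            "contig": row.contig,
            "strand": row.strand,
        }
        for col in _INT_COLS:
            rec[col] = getattr(row, col)
        for col in _COUNT_COLS:
            rec[col] = ",".join(str(c) for c in getattr(row, col))
        records.append(rec)
    pd.DataFrame(records, columns=list(EVENT_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_results(
    records: Iterable, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write dataclass records (or dicts) as a TSV with NA for missing values.

    Round-trips through :func:`read_results`: floats keep full precision and
    missing numeric values come back as NaN. An empty record list yields a
    header-only file (``columns`` may supply the header when no record is
    available to infer it from).
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rec = dataclasses.asdict(rec)
        rows.append(dict(rec))
    df = pd.DataFrame(rows, columns=list(columns) if columns else None)
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_gtf(rows: Sequence[EventTableRow], path: str | Path, source: str = "splicemaps") -> None:
    """Emit minimal GTF v2.2 exon lines (inclusion isoform) for each event."""
    with open(path, "w") as out:
        for row in rows:
            exons = sorted(
                [
                    (row.upstream_exon_start, row.upstream_exon_end),
                    (row.exon_start, row.exon_end),
                    (row.downstream_exon_start, row.downstream_exon_end),
                ]
            )
            for start, end in exons:
                attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.event_id}.inc";'
                out.write(
                    "\t".join(
                        [
                            row.contig,
                            source,
                            "exon",
                            str(start + 1),  # GTF is 1-based closed
                            str(end),
                            ".",
                            row.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_bed6(
    intervals: Sequence[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write BED6 lines (contig, start, end, name, score, strand)."""
    with open(path, "w") as out:
        for contig, start, end, name, score, strand in intervals:
            score_str = "0" if score is None or (isinstance(score, float) and math.isnan(score)) else f"{score:g}"
            out.write(f"{contig}\t{start}\t{end}\t{name}\t{score_str}\t{strand}\n")
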