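"""Readers and writers for FASTQ/FASTA streams and the three TSV sheets.

The toolkit's tabular inputs are three tab-separated sheets with header rows:

* barcodes: ``name  end  sequence`` — ``end`` is ``P5`` or ``P7``; sequences
  at one end must be unique and equal length.
* primers: ``target  genome  fwd  rev`` — target-specific primer parts only,
  with the conserved CS1/CS2 tails already stripped; ``genome`` is
  ``chloroplast`` or ``nuclear``.
* samples: ``sample  p5  p7  [project]`` — each sample is keyed by a unique
  (P5, P7) barcode-name pair.

All sequences are stored upper-case; comparison throughout the package is
case-insensitive by construction.
"""

from __future__ import annotations

import gzip
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "BarcodeEntry",
    "PrimerPair",
    "SampleRecord",
    "ReadPair",
    "BarcodeTable",
    "PrimerTable",
    "SampleTable",
    "SheetError",
    "FastqError",
    "read_fastq_pairs",
    "load_sheets",
    "load_barcode_sheet",
    "load_primer_sheet",
    "load_sample_sheet",
    "write_fasta",
    "write_fastq",
    "write_table",
]

_DNA = set("ACGT")


class SheetError(ValueError):
    """Raised when a TSV sheet is malformed or internally inconsistent."""


class FastqError(ValueError):
    """Raised on malformed or out-of-sync FASTQ input."""


@dataclass(frozen=True)
class BarcodeEntry:
    """One index barcode: a short label, its end (P5 or P7) and its sequence."""

    name: str
    end: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.end not in ("P5", "P7"):
            raise SheetError(f"barcode {self.name!r}: end must be P5 or P7, got {self.end!r}")
        if not self.sequence or set(self.sequence) - _DNA:
            raise SheetError(f"barcode {self.name!r}: sequence must be non-empty over ACGT")


@dataclass(frozen=True)
class PrimerPair:
    """A target with its forward/reverse target-specific primer sequences.

    The conserved CS1/CS2 universal tails are not part of ``fwd_seq`` /
    ``rev_seq``: matching against reads happens on the target-specific part
    only.
    """

    target_id: str
    genome: str
    fwd_seq: str
    rev_seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd_seq", self.fwd_seq.upper())
        object.__setattr__(self, "rev_seq", self.rev_seq.upper())
        if self.genome not in ("chloroplast", "nuclear"):
            raise SheetError(
                f"primer {self.target_id!r}: genome must be chloroplast or nuclear, got {self.genome!r}"
            )
        for label, seq in (("fwd", self.fwd_seq), ("rev", self.rev_seq)):
            if not seq or set(seq) - _DNA:
                raise SheetError(f"primer {self.target_id!r}: {label} sequence must be non-empty over ACGT")


@dataclass(frozen=True)
class SampleRecord:
    """A sample and the (P5, P7) barcode-name pair that identifies it."""

    sample_id: str
    p5_barcode: str
    p7_barcode: str
    project: str = ""


@dataclass
class ReadPair:
    """One paired-end record: headers, bases, Phred+33 qualities and the
    observed index sequences (from index reads or parsed from the header)."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str
    r1_bc: str = ""
    r2_bc: str = ""

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise FastqError(f"read {self.id!r}: sequence/quality length mismatch")


@dataclass
class BarcodeTable:
    """Barcodes grouped by end, with the multiplexing arithmetic attached."""

    entries: list[BarcodeEntry]
    by_end: dict[str, list[BarcodeEntry]] = field(init=False)

    def __post_init__(self) -> None:
        self.by_end = {"P5": [], "P7": []}
        for e in self.entries:
            self.by_end[e.end].append(e)
        for end, group in self.by_end.items():
            seqs = [e.sequence for e in group]
            names = [e.name for e in group]
            if len(set(names)) != len(names):
                raise SheetError(f"duplicate barcode names at end {end}")
            if len(set(seqs)) != len(seqs):
                raise SheetError(f"duplicate barcode sequences at end {end}")
            if len({len(s) for s in seqs}) > 1:
                raise SheetError(f"barcodes at end {end} are not equal-length")
            # design rule: same-end barcodes should differ at >2 positions;
            # user sets violating it still load, with a warning
            for a, b in itertools.combinations(group, 2):
                diff = sum(x != y for x, y in zip(a.sequence, b.sequence))
                if diff <= 2:
                    warnings.warn(
                        f"barcodes {a.name} and {b.name} ({end}) differ at only {diff} position(s); "
                        "the design rule asks for >2",
                        stacklevel=2,
                    )

    def get(self, end: str, name: str) -> BarcodeEntry:
        for e in self.by_end[end]:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def n_p5(self) -> int:
        return len(self.by_end["P5"])

    @property
    def n_p7(self) -> int:
        return len(self.by_end["P7"])

    @property
    def n_possible_pairs(self) -> int:
        """Number of distinct (P5, P7) combinations the set supports."""
        return self.n_p5 * self.n_p7


@dataclass
class PrimerTable:
    entries: list[PrimerPair]

    def __post_init__(self) -> None:
        ids = [p.target_id for p in self.entries]
        if len(set(ids)) != len(ids):
            raise SheetError("duplicate target ids in primer sheet")

    def __iter__(self) -> Iterator[PrimerPair]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, target_id: str) -> PrimerPair:
        for p in self.entries:
            if p.target_id == target_id:
                return p
        raise KeyError(target_id)


@dataclass
class SampleTable:
    entries: list[SampleRecord]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        ids = [s.sample_id for s in self.entries]
        if len(set(ids)) != len(ids):
            raise SheetError("duplicate sample ids in sample sheet")
        for s in self.entries:
            key = (s.p5_barcode, s.p7_barcode)
            if key in seen:
                raise SheetError(
                    f"barcode pair {key} reused by samples {seen[key]!r} and {s.sample_id!r}"
                )
            seen[key] = s.sample_id

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as handle:
        try:
            yield from FastqGeneralIterator(handle)
        except ValueError as exc:  # malformed FASTQ
            raise FastqError(f"{path}: {exc}") from exc


def _barcode_from_header(title: str) -> tuple[str, str]:
    """Parse ``...:<BC1>+<BC2>`` from a Casava-style header; empty if absent."""
    token = title.rsplit(":", 1)[-1].strip()
    if "+" in token:
        bc1, _, bc2 = token.partition("+")
        if bc1 and bc2 and not (set(bc1.upper()) - set("ACGTN")) and not (set(bc2.upper()) - set("ACGTN")):
            return bc1.upper(), bc2.upper()
    return "", ""


_SENTINEL = object()


def read_fastq_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    i1_path: str | Path | None = None,
    i2_path: str | Path | None = None,
) -> Iterator[ReadPair]:
    """Stream paired FASTQ records in lockstep as :class:`ReadPair` objects.

    Index sequences come from ``i1``/``i2`` index FASTQs when given, else are
    parsed from the read-1 header (the ``BC1+BC2`` token after the last
    colon). Mismatched record counts raise :class:`FastqError` naming the
    1-based record index at which one file ran out.
    """
    streams = [_fastq_records(r1_path), _fastq_records(r2_path)]
    if i1_path is not None:
        streams.append(_fastq_records(i1_path))
    if i2_path is not None:
        streams.append(_fastq_records(i2_path))
    idx = 0
    for recs in itertools.zip_longest(*streams, fillvalue=_SENTINEL):
        idx += 1
        if any(r is _SENTINEL for r in recs):
            raise FastqError(f"paired FASTQ files out of sync at record {idx}: unequal record counts")
        (t1, s1, q1), (t2, s2, q2) = recs[0], recs[1]
        id1, id2 = t1.split()[0], t2.split()[0]
        if id1.rstrip("/12") != id2.rstrip("/12"):
            raise FastqError(f"mate ids disagree at record {idx}: {id1!r} vs {id2!r}")
        if i1_path is not None:
            bc1 = recs[2][1].upper()
            bc2 = recs[3][1].upper() if i2_path is not None else ""
        else:
            bc1, bc2 = _barcode_from_header(t1)
        yield ReadPair(
            id=id1,
            r1_seq=s1.upper(),
            r2_seq=s2.upper(),
            r1_qual=q1,
            r2_qual=q2,
            r1_bc=bc1,
            r2_bc=bc2,
        )


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise SheetError(f"{path}: missing column(s) {missing}; header is {header}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < len(required):
                raise SheetError(f"{path}:{lineno}: expected >= {len(required)} columns")
            rows.append(dict(zip(header, cells)))
    return rows


def load_barcode_sheet(path: str | Path) -> BarcodeTable:
    rows = _read_tsv(path, ["name", "end", "sequence"])
    return BarcodeTable([BarcodeEntry(r["name"], r["end"], r["sequence"]) for r in rows])


def load_primer_sheet(path: str | Path) -> PrimerTable:
    rows = _read_tsv(path, ["target", "genome", "fwd", "rev"])
    return PrimerTable([PrimerPair(r["target"], r["genome"], r["fwd"], r["rev"]) for r in rows])


def load_sample_sheet(path: str | Path, barcodes: BarcodeTable | None = None) -> SampleTable:
    rows = _read_tsv(path, ["sample", "p5", "p7"])
    table = SampleTable(
        [SampleRecord(r["sample"], r["p5"], r["p7"], r.get("project", "")) for r in rows]
    )
    if barcodes is not None:
        p5_names = {e.name for e in barcodes.by_end["P5"]}
        p7_names = {e.name for e in barcodes.by_end["P7"]}
        for s in table:
            if s.p5_barcode not in p5_names:
                raise SheetError(f"sample {s.sample_id!r}: unknown P5 barcode {s.p5_barcode!r}")
            if s.p7_barcode not in p7_names:
                raise SheetError(f"sample {s.sample_id!r}: unknown P7 barcode {s.p7_barcode!r}")
    return table


def load_sheets(
    barcode_path: str | Path, primer_path: str | Path, sample_path: str | Path
) -> tuple[BarcodeTable, PrimerTable, SampleTable]:
    """Load and cross-validate the three sheets."""
    barcodes = load_barcode_sheet(barcode_path)
    primers = load_primer_sheet(primer_path)
    samples = load_sample_sheet(sample_path, barcodes)
    return barcodes, primers, samples


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> int:
    """Write ``(name, sequence)`` records as FASTA wrapped at ``width`` columns.

    Returns the number of records written; input order is preserved.
    """
    n = 0
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
            n += 1
    return n


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write ``(title, sequence, quality)`` records as 4-line FASTQ."""
    n = 0
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for title, seq, qual in records:
            out.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_table(rows: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None) -> int:
    """Write rows as TSV in input order; returns row count (excluding header)."""
    n = 0
    with open(path, "w") as out:
        if header is not None:
            out.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            out.write("\t".join(map(str, row)) + "\n")
            n += 1
    return n
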