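"""Genome/feature data model and readers/writers for the standard formats.

Coordinates are 1-based inclusive everywhere in this package; the BED writer
converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T, and map non-ACGTN IUPAC letters to N (logged)."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= DNA_ALPHABET:
        n_mapped = sum(1 for c in s if c not in DNA_ALPHABET)
        log.warning("mapped %d non-ACGTN letters to N", n_mapped)
        s = "".join(c if c in DNA_ALPHABET else "N" for c in s)
    return s


@dataclass
class GeneFeature:
    """One annotated gene with 1-based inclusive interval(s)."""

    name: str
    kind: str  # protein_coding | tRNA | rRNA | other
    intervals: list[tuple[int, int]]
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if not (1 <= s <= e):
                raise ValueError(f"feature {self.name!r}: bad interval {(s, e)}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)


@dataclass
class GenomeRecord:
    """One genome sequence with its annotated gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        for feat in self.features:
            if feat.end > len(self.sequence):
                raise ValueError(
                    f"feature {feat.name!r} extends past sequence end "
                    f"({feat.end} > {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


_KIND_BY_FEATURE_TYPE = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | os.PathLike) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Gene-level features are taken from CDS/tRNA/rRNA entries (falling back to
    ``gene`` features without a typed counterpart); joined locations are kept
    as interval lists. Features outside the sequence are dropped with a
    warning.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a parseable GenBank record ({exc})") from exc
    seq = normalize_sequence(str(record.seq))
    if not seq:
        raise FormatError(f"{path}: record has no sequence (missing ORIGIN block?)")

    features: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    # Typed features first so gene features don't shadow CDS/tRNA/rRNA kinds.
    ordered = [f for f in record.features if f.type in _KIND_BY_FEATURE_TYPE]
    ordered += [f for f in record.features if f.type == "gene"]
    for feat in ordered:
        kind = _KIND_BY_FEATURE_TYPE.get(feat.type, "other")
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        intervals, wraps = _feature_intervals(feat, len(seq))
        if not intervals:
            log.warning("dropping feature %r: outside sequence", name)
            continue
        key = (name, intervals[0][0], intervals[-1][1])
        if key in seen:
            continue
        seen.add(key)
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(name, kind, intervals, strand, wraps))
    features.sort(key=lambda f: f.start)
    return GenomeRecord(id=record.id or record.name, sequence=seq,
                        features=features, source=str(path))


def _feature_intervals(feat, genome_len: int):
    """1-based inclusive intervals from a Biopython feature location."""
    intervals = []
    wraps = False
    for part in feat.location.parts:
        start, end = int(part.start) + 1, int(part.end)
        if start > end:  # wrap-around part, split at the origin
            intervals += [(start, genome_len), (1, end)]
            wraps = True
            continue
        if end > genome_len or start < 1:
            return [], False
        intervals.append((start, end))
    return intervals, wraps


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA into an order-preserving list of ``(id, sequence)``.

    Ids are the first whitespace-delimited header token; duplicate ids and
    empty sequences are errors; non-ACGTN letters become N with a warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append((rec.id, seq))
    return records


def read_fasta_gapped(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Like :func:`read_fasta` but keeps ``-`` gap characters (aligned FASTA)."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        seq = "".join(
            c if c == "-" else (c if c in DNA_ALPHABET else "N")
            for c in raw.upper().replace("U", "T")
        )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | os.PathLike,
                width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA wrapped at ``width`` columns."""
    if not records:
        raise ValueError("no records to write")
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_tsv(rows: Iterable[Sequence], path: str | os.PathLike,
              header: Sequence[str] | None = None,
              metadata: Sequence[str] = ()) -> None:
    """Write rows as UTF-8 TSV with optional ``#``-prefixed metadata lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        if header is not None:
            fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]],
              path: str | os.PathLike) -> None:
    """Write named 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
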