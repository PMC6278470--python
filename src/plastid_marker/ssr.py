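"""Perfect-microsatellite scanner with region and genic-context assignment.

The scanner reports maximal runs of complete copies of a primitive 1-6 bp
unit, subject to per-unit-length minimum-unit thresholds (defaults 8, 4, 3,
3, 3, 3 for mono- through hexa-nucleotides). Only complete units count: a
trailing partial unit is excluded, so ``size == units * unit_length``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_genomes import GeneFeature, reverse_complement
from .structure import QuadripartitePartition

DEFAULT_THRESHOLDS: dict[int, int] = {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}

LENGTH_BINS = ((0, 9), (10, 19), (20, 29), (30, 10 ** 9))


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum complete-unit count per unit length (1..6)."""

    min_units: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        if set(self.min_units) != set(range(1, 7)):
            raise ValueError("thresholds must cover unit lengths 1..6")
        if any(v < 2 for v in self.min_units.values()):
            raise ValueError("all thresholds must be >= 2")

    @classmethod
    def from_csv(cls, text: str) -> "SSRThresholds":
        vals = [int(x) for x in text.split(",")]
        if len(vals) != 6:
            raise ValueError("expected 6 comma-separated thresholds")
        return cls({u: v for u, v in zip(range(1, 7), vals)})


@dataclass
class SSRRecord:
    """One perfect microsatellite (1-based inclusive coordinates)."""

    index: int
    unit_length: int
    motif: str
    units: int
    start: int
    end: int
    motif_class: str = ""
    region: str = ""
    context: str = ""
    spans_junction: bool = False

    @property
    def ssr_type(self) -> str:
        return f"p{self.unit_length}"

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def display(self) -> str:
        return f"({self.motif}){self.units}"

    def verify(self, sequence: str) -> None:
        assert self.size == self.units * self.unit_length
        assert is_primitive(self.motif)
        assert sequence[self.start - 1:self.end] == self.motif * self.units


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number repeat of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


def canonical_motif_class(motif: str) -> str:
    """Strand- and phase-invariant class label, e.g. ``A/T`` or ``AT/AT``.

    Takes the lexicographic minimum over cyclic rotations of the motif and
    of its reverse complement, printed in sorted order.
    """
    if not (1 <= len(motif) <= 6) or not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not a primitive 1-6 bp unit")
    x = min(motif[i:] + motif[:i] for i in range(len(motif)))
    rc = reverse_complement(motif)
    y = min(rc[i:] + rc[:i] for i in range(len(rc)))
    lo, hi = sorted((x, y))
    return f"{lo}/{hi}"


def scan_ssrs(sequence: str,
              thresholds: SSRThresholds | None = None) -> list[SSRRecord]:
    """All maximal perfect SSR runs meeting the thresholds, in scan order.

    For each unit length u the scan finds maximal stretches where
    ``seq[i] == seq[i+u]``; a stretch is reported if it holds >= threshold
    complete copies of a primitive u-mer. N breaks every run. Records are
    sorted by start, then unit length, and numbered from 1.
    """
    thr = (thresholds or SSRThresholds()).min_units
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    found: list[SSRRecord] = []
    for u in range(1, 7):
        min_len = thr[u] * u
        i = 0
        while i + u < n:
            if sequence[i] == "N" or sequence[i] != sequence[i + u]:
                i += 1
                continue
            # maximal phase-match run starting at i (N never matches N)
            j = i
            while j + u < n and sequence[j] != "N" and sequence[j] == sequence[j + u]:
                j += 1
            run_len = (j - i) + u  # full repeated region incl. partial unit
            units = run_len // u
            motif = sequence[i:i + u]
            if units * u >= min_len and units >= thr[u] and is_primitive(motif):
                start = i + 1
                end = i + units * u
                found.append(SSRRecord(0, u, motif, units, start, end,
                                       motif_class=canonical_motif_class(motif)))
            i = j + 1
    found.sort(key=lambda r: (r.start, r.unit_length))
    for idx, rec in enumerate(found, 1):
        rec.index = idx
        rec.verify(sequence)
    return found


def assign_region(ssrs: list[SSRRecord],
                  partition: QuadripartitePartition) -> list[SSRRecord]:
    """Fill ``region`` from the partition interval containing the SSR start;
    SSRs whose end falls in a different region are flagged as junction-spanning."""
    for rec in ssrs:
        rec.region = partition.region_of(rec.start)
        rec.spans_junction = partition.region_of(rec.end) != rec.region
    return ssrs


def annotate_context(ssrs: list[SSRRecord],
                     features: list[GeneFeature]) -> list[SSRRecord]:
    """Fill genic context: gene name, ``CNS``, or ``NAME-CNS`` when straddling."""
    for rec in ssrs:
        contained = None
        partial = None
        for feat in features:
            for s, e in feat.intervals:
                if s <= rec.start and rec.end <= e:
                    contained = contained or feat.name
                elif rec.start <= e and s <= rec.end:
                    partial = partial or feat.name
        # full containment outranks a partial overlap with another gene
        if contained:
            rec.context = contained
        elif partial:
            rec.context = f"{partial}-CNS"
        else:
            rec.context = "CNS"
    return ssrs


def summarize_ssrs(per_genome: dict[str, list[SSRRecord]]) -> dict:
    """Count tables across one or more genomes.

    Returns per-genome totals and per-type counts, pooled type / motif-class
    counts with percentages (2 decimals), per-region counts, and a length
    histogram (bins <10, 10-19, 20-29, >=30 bp).
    """
    if not per_genome:
        raise ValueError("no genomes supplied")
    by_type: dict[str, Counter] = {}
    totals: dict[str, int] = {}
    pooled_type: Counter = Counter()
    pooled_class: Counter = Counter()
    by_region: dict[str, Counter] = {}
    length_hist: Counter = Counter()
    for name, ssrs in per_genome.items():
        totals[name] = len(ssrs)
        by_type[name] = Counter(r.ssr_type for r in ssrs)
        by_region[name] = Counter(r.region or "?" for r in ssrs)
        pooled_type.update(r.ssr_type for r in ssrs)
        pooled_class.update(r.motif_class for r in ssrs)
        for r in ssrs:
            for lo, hi in LENGTH_BINS:
                if lo <= r.size <= hi:
                    label = f"{lo}-{hi}" if hi < 10 ** 9 else f">={lo}"
                    length_hist[label] += 1
                    break
    pooled_total = sum(pooled_type.values())

    def pct(c: int) -> float:
        return round(100 * c / pooled_total, 2) if pooled_total else 0.0

    return {
        "totals": totals,
        "by_type": {g: dict(c) for g, c in by_type.items()},
        "by_region": {g: dict(c) for g, c in by_region.items()},
        "pooled_type": {t: (c, pct(c)) for t, c in sorted(pooled_type.items())},
        "pooled_class": {m: (c, pct(c)) for m, c in sorted(pooled_class.items())},
        "length_hist": dict(length_hist),
        "pooled_total": pooled_total,
    }


def ssr_table_rows(ssrs: list[SSRRecord], min_size: int = 0):
    """Rows for the TSV report (optionally filtered by display min size)."""
    for rec in ssrs:
        if rec.size < min_size:
            continue
        yield (rec.index, rec.ssr_type, rec.display, rec.size, rec.start,
               rec.end, rec.region or ".", rec.context or ".")
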