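"""Inverted-repeat detection and LSC/IRb/SSC/IRa partitioning with GC stats."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .io_genomes import GenomeRecord, reverse_complement

log = logging.getLogger(__name__)

Interval = tuple[int, int]  # 1-based inclusive

DEFAULT_MIN_IR_LEN = 1000
SEED_K = 21  # reverse-complement anchoring k-mer; specific at ~160 kb scale


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the canonical (LSC-first) rotation.

    ``input_intervals`` maps each region to its interval(s) on the input
    linearization (two pieces when a region wraps the origin);
    ``rotation_offset`` is the input coordinate of canonical position 1.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    ir_length: int
    mismatches: int
    rotation_offset: int = 1
    input_intervals: dict[str, list[Interval]] = field(default_factory=dict)

    @property
    def genome_length(self) -> int:
        return self.ira[1]

    def regions(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def validate(self) -> None:
        ivs = [self.lsc, self.irb, self.ssc, self.ira]
        assert ivs[0][0] == 1
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 == e1 + 1, "regions must be contiguous"
            assert s1 <= e1 and s2 <= e2
        assert _ilen(self.irb) == _ilen(self.ira) == self.ir_length
        total = sum(_ilen(iv) for iv in ivs)
        assert total == self.genome_length, "partition must cover the genome"

    def region_of(self, pos: int) -> str:
        """Region containing an input-linearization position."""
        source = self.input_intervals or {
            name: [iv] for name, iv in self.regions().items()
        }
        for name, pieces in source.items():
            for s, e in pieces:
                if s <= pos <= e:
                    return name
        raise ValueError(f"position {pos} outside genome")


def _ilen(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


def find_longest_inverted_repeat(
    sequence: str,
    min_ir_len: int = DEFAULT_MIN_IR_LEN,
    max_mismatch_frac: float = 0.0,
) -> tuple[Interval, Interval, int] | None:
    """Locate the maximal inverted-repeat pair of a (linearized) genome.

    Seeds exact k-mer matches between the sequence and its reverse
    complement, extends each match diagonal, and returns the longest
    disjoint pair ``(A, B, mismatches)`` with A before B (1-based inclusive),
    or ``None`` if nothing reaches ``min_ir_len``. Ties break toward the
    smallest A start.
    """
    n = len(sequence)
    if n < 2 * min_ir_len:
        raise ValueError(f"sequence ({n} bp) shorter than 2*min_ir_len")
    if not 0 <= max_mismatch_frac < 0.05:
        raise ValueError("max_mismatch_frac must be in [0, 0.05)")
    k = min(SEED_K, min_ir_len)
    rc = reverse_complement(sequence)

    index: dict[str, list[int]] = defaultdict(list)
    for j in range(n - k + 1):
        index[rc[j:j + k]].append(j)

    # Seed hits grouped by diagonal (j - i constant along an exact match).
    diagonals: dict[int, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        for j in index.get(sequence[i:i + k], ()):
            diagonals[j - i].append(i)

    candidates: list[tuple[Interval, Interval, int]] = []
    for diag, hits in diagonals.items():
        hits.sort()
        runs = _exact_runs(sequence, rc, diag, hits, k)
        if max_mismatch_frac > 0:
            runs = _merge_runs(runs, max_mismatch_frac)
        for i0, i1, mism in runs:
            length = i1 - i0 + 1
            if length < min_ir_len:
                continue
            j0 = i0 + diag
            # rc position j maps back to sequence position n - 1 - j
            b = (n - 1 - (j0 + length - 1), n - 1 - j0)
            a = (i0, i1)
            if b[0] < a[0]:
                a, b = b, a
            if b[0] <= a[1]:
                continue  # overlapping / palindromic self-match
            candidates.append(((a[0] + 1, a[1] + 1), (b[0] + 1, b[1] + 1), mism))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (-(c[0][1] - c[0][0]), c[0][0], c[1][0]))
    best = candidates[0]
    # the pair is found twice (roles swapped land on a mirror diagonal)
    return best


def _exact_runs(seq: str, rc: str, diag: int, hits: list[int], k: int):
    """Maximal exact match runs (i0, i1, 0) on one diagonal, de-duplicated."""
    n = len(seq)
    runs = []
    covered_to = -1
    for i in hits:
        if i <= covered_to:
            continue
        lo, hi = i, i + k - 1
        while lo - 1 >= 0 and 0 <= lo - 1 + diag and seq[lo - 1] == rc[lo - 1 + diag] and seq[lo - 1] != "N":
            lo -= 1
        while hi + 1 < n and hi + 1 + diag < n and seq[hi + 1] == rc[hi + 1 + diag] and seq[hi + 1] != "N":
            hi += 1
        runs.append((lo, hi, 0))
        covered_to = hi
    return runs


def _merge_runs(runs, max_mismatch_frac):
    """Greedily bridge nearby runs on one diagonal within a mismatch budget."""
    if not runs:
        return runs
    merged = [runs[0]]
    for lo, hi, _ in runs[1:]:
        plo, phi, pm = merged[-1]
        gap = lo - phi - 1
        span = hi - plo + 1
        if gap >= 0 and pm + gap <= max_mismatch_frac * span:
            merged[-1] = (plo, hi, pm + gap)
        else:
            merged.append((lo, hi, 0))
    return merged


def partition_quadripartite(
    genome: GenomeRecord, ir: tuple[Interval, Interval, int]
) -> QuadripartitePartition:
    """Label the two single-copy gaps around an IR pair and canonicalize.

    The longer gap (on the circle) is the LSC, the shorter the SSC; the
    canonical rotation starts at LSC position 1, with IRb following the LSC
    and IRa following the SSC.
    """
    (a, b, mismatches) = ir
    n = genome.length
    if b[0] <= a[1]:
        raise ValueError("IR copies overlap: degenerate structure")
    ir_length = _ilen(a)

    mid_len = b[0] - a[1] - 1  # gap between the copies on the linearization
    wrap_len = (n - b[1]) + (a[0] - 1)  # gap crossing the origin
    if mid_len == 0 or wrap_len == 0:
        raise ValueError("zero-length single-copy gap: degenerate structure")

    def wrap_pieces(start: int, length: int) -> list[Interval]:
        if start + length - 1 <= n:
            return [(start, start + length - 1)]
        return [(start, n), (1, length - (n - start + 1))]

    if wrap_len >= mid_len:
        lsc_len, ssc_len = wrap_len, mid_len
        lsc_start = b[1] + 1 if b[1] < n else 1
        input_intervals = {
            "LSC": wrap_pieces(lsc_start, lsc_len),
            "IRb": [a],
            "SSC": [(a[1] + 1, b[0] - 1)],
            "IRa": [b],
        }
        rotation_offset = lsc_start
    else:
        lsc_len, ssc_len = mid_len, wrap_len
        ssc_start = b[1] + 1 if b[1] < n else 1
        input_intervals = {
            "LSC": [(a[1] + 1, b[0] - 1)],
            "IRb": [b],
            "SSC": wrap_pieces(ssc_start, ssc_len),
            "IRa": [a],
        }
        rotation_offset = a[1] + 1

    part = QuadripartitePartition(
        lsc=(1, lsc_len),
        irb=(lsc_len + 1, lsc_len + ir_length),
        ssc=(lsc_len + ir_length + 1, lsc_len + ir_length + ssc_len),
        ira=(lsc_len + ir_length + ssc_len + 1, n),
        ir_length=ir_length,
        mismatches=mismatches,
        rotation_offset=rotation_offset,
        input_intervals=input_intervals,
    )
    part.validate()
    if rotation_offset != 1:
        log.info("input linearization does not start at the LSC "
                 "(canonical rotation offset %d)", rotation_offset)
    return part


def gc_content(sequence: str, interval: Interval | None = None) -> float:
    """(G+C)/(A+C+G+T) of a (sub)sequence; N is excluded from both counts."""
    if interval is not None:
        s, e = interval
        if not (1 <= s <= e <= len(sequence)):
            raise ValueError(f"interval {interval} outside sequence")
        sequence = sequence[s - 1:e]
    if not sequence:
        raise ValueError("empty sequence")
    gc = sequence.count("G") + sequence.count("C")
    denom = gc + sequence.count("A") + sequence.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / denom


def region_gc(genome: GenomeRecord,
              partition: QuadripartitePartition) -> list[tuple[str, int, float]]:
    """Per-region (length, GC%) rows plus a whole-genome row.

    GC percentages are rounded to one decimal; regions are reported on the
    input linearization (wrapping regions are measured piecewise).
    """
    rows = []
    source = partition.input_intervals or {
        name: [iv] for name, iv in partition.regions().items()
    }
    for name in ("LSC", "IRb", "SSC", "IRa"):
        seq = "".join(genome.sequence[s - 1:e] for s, e in source[name])
        rows.append((name, len(seq), round(100 * gc_content(seq), 1)))
    rows.append(("genome", genome.length, round(100 * gc_content(genome.sequence), 1)))
    return rows
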