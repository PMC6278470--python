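"""Pairwise/progressive alignment and sliding-window identity profiling."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

NEG_INF = float("-inf")

# neutral defaults for closely related sequences; override per call
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -2.0
DEFAULT_GAP_EXTEND = -1.0

DEFAULT_WINDOW = 200
DEFAULT_STEP = 50


@dataclass
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.gapped_a) == len(self.gapped_b)

    @property
    def identity(self) -> float:
        cols = [(x, y) for x, y in zip(self.gapped_a, self.gapped_b)
                if not (x == "-" and y == "-")]
        if not cols:
            return 0.0
        return sum(x == y != "-" for x, y in cols) / len(cols)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows with optional per-sample species labels."""

    rows: list[tuple[str, str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (self.length,) = lengths

    def column(self, col: int) -> list[str]:
        """Characters of 1-based column ``col``."""
        return [seq[col - 1] for _, seq in self.rows]

    def row(self, sample_id: str) -> str:
        for name, seq in self.rows:
            if name == sample_id:
                return seq
        raise KeyError(f"sample {sample_id!r} not in alignment")

    def degapped(self, sample_id: str) -> str:
        return self.row(sample_id).replace("-", "")

    def species_of(self, sample_id: str) -> str:
        if sample_id not in self.labels:
            raise ValueError(f"sample {sample_id!r} has no species label")
        return self.labels[sample_id]

    def drop_all_gap_columns(self) -> "MultipleAlignment":
        keep = [c for c in range(self.length)
                if any(seq[c] != "-" for _, seq in self.rows)]
        rows = [(n, "".join(s[c] for c in keep)) for n, s in self.rows]
        return MultipleAlignment(rows, dict(self.labels))


def global_align(a: str, b: str,
                 match: float = DEFAULT_MATCH,
                 mismatch: float = DEFAULT_MISMATCH,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (Gotoh).

    A gap of length L costs ``gap_open + gap_extend*(L-1)``. Traceback ties
    prefer diagonal, then up (gap in ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)

    # traceback with the stated tie-break (diagonal > up > left)
    def close(x, y):
        return math.isclose(x, y, abs_tol=1e-9)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    score = max(M[n][m], X[n][m], Y[n][m])
    state = ("M" if close(M[n][m], score) else
             "X" if close(X[n][m], score) else "Y")
    while i > 0 or j > 0:
        if j == 0:
            state = "X"
        elif i == 0:
            state = "Y"
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = ("M" if close(M[i][j], prev) else
                     "X" if close(X[i][j], prev) else "Y")
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i][j]
            i -= 1
            if close(M[i][j] + gap_open, val):
                state = "M"
            elif close(X[i][j] + gap_extend, val):
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if close(M[i][j] + gap_open, val):
                state = "M"
            elif close(Y[i][j] + gap_extend, val):
                state = "Y"
            else:
                state = "X"
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


# ---------------------------------------------------------------------------
# progressive MSA

def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    ka = Counter(a[i:i + k] for i in range(max(0, len(a) - k + 1)))
    kb = Counter(b[i:i + k] for i in range(max(0, len(b) - k + 1)))
    shared = sum((ka & kb).values())
    total = min(sum(ka.values()), sum(kb.values())) or 1
    return 1.0 - shared / total


class _Profile:
    """A growing alignment block: list of (id, gapped sequence)."""

    def __init__(self, rows: list[tuple[str, str]]):
        self.rows = rows
        self.length = len(rows[0][1])

    def columns(self) -> list[Counter]:
        cols = []
        for c in range(self.length):
            cols.append(Counter(seq[c] for _, seq in self.rows))
        return cols


def _profile_align(p: _Profile, q: _Profile, match: float, mismatch: float,
                   gap_open: float, gap_extend: float) -> _Profile:
    """Affine-gap Gotoh on column profiles with sum-of-pairs column scores."""
    pc, qc = p.columns(), q.columns()
    n, m = len(pc), len(qc)
    np_, nq = len(p.rows), len(q.rows)

    def colscore(ci: Counter, cj: Counter) -> float:
        s = 0.0
        for x, cx in ci.items():
            for y, cy in cj.items():
                if x == "-" or y == "-":
                    continue
                s += cx * cy * (match if x == y else mismatch)
        return s / (np_ * nq)

    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = colscore(pc[i - 1], qc[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    ops: list[str] = []
    i, j = n, m
    score = max(M[n][m], X[n][m], Y[n][m])
    state = "M" if M[n][m] == score else ("X" if X[n][m] == score else "Y")
    while i > 0 or j > 0:
        if j == 0:
            state = "X"
        elif i == 0:
            state = "Y"
        if state == "M":
            s = colscore(pc[i - 1], qc[j - 1])
            prev = M[i][j] - s
            ops.append("M")
            i, j = i - 1, j - 1
            state = ("M" if math.isclose(M[i][j], prev, abs_tol=1e-9) else
                     "X" if math.isclose(X[i][j], prev, abs_tol=1e-9) else "Y")
        elif state == "X":
            val = X[i][j]
            ops.append("X")
            i -= 1
            if math.isclose(M[i][j] + gap_open, val, abs_tol=1e-9):
                state = "M"
            elif math.isclose(X[i][j] + gap_extend, val, abs_tol=1e-9):
                state = "X"
            else:
                state = "Y"
        else:
            val = Y[i][j]
            ops.append("Y")
            j -= 1
            if math.isclose(M[i][j] + gap_open, val, abs_tol=1e-9):
                state = "M"
            elif math.isclose(Y[i][j] + gap_extend, val, abs_tol=1e-9):
                state = "Y"
            else:
                state = "X"
    ops.reverse()
    new_rows: list[tuple[str, str]] = []
    for name, seq in p.rows:
        out, pos = [], 0
        for op in ops:
            if op in "MX":
                out.append(seq[pos])
                pos += 1
            else:
                out.append("-")
        new_rows.append((name, "".join(out)))
    for name, seq in q.rows:
        out, pos = [], 0
        for op in ops:
            if op in "MY":
                out.append(seq[pos])
                pos += 1
            else:
                out.append("-")
        new_rows.append((name, "".join(out)))
    return _Profile(new_rows)


def progressive_msa(seqs: list[tuple[str, str]],
                    labels: dict[str, str] | None = None,
                    match: float = DEFAULT_MATCH,
                    mismatch: float = DEFAULT_MISMATCH,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> MultipleAlignment:
    """Progressive multiple alignment along a k-mer-distance NJ guide tree.

    Intended scale is tens of sequences of a few kb (amplicon panels), not
    whole genomes; import an external aligned FASTA for anything larger.
    """
    from .phylo import DistanceMatrix, neighbor_joining

    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    profiles = {name: _Profile([(name, seq)]) for name, seq in seqs}
    if len(seqs) == 2:
        order = [(seqs[0][0], seqs[1][0])]
    else:
        names = [n for n, _ in seqs]
        d = [[_kmer_distance(a, b) for _, b in seqs] for _, a in seqs]
        for i in range(len(names)):
            d[i][i] = 0.0
        tree = neighbor_joining(DistanceMatrix(names, d))
        order = _merge_order(tree)
    merged = dict(profiles)
    for left, right in order:
        p, q = merged[left], merged[right]
        new = _profile_align(p, q, match, mismatch, gap_open, gap_extend)
        for name, _ in new.rows:
            merged[name] = new
    final = merged[seqs[0][0]]
    by_name = dict(final.rows)
    rows = [(name, by_name[name]) for name, _ in seqs]  # input order
    msa = MultipleAlignment(rows, labels or {})
    return msa.drop_all_gap_columns()


def _merge_order(tree) -> list[tuple[str, str]]:
    """Post-order list of (representative, representative) merge steps."""
    order: list[tuple[str, str]] = []

    def rep(node) -> str:
        if node.is_leaf():
            return node.name
        reps = [rep(c) for c in node.children]
        for a, b in zip(reps, reps[1:]):
            order.append((a, b))
        return reps[0]

    rep(tree.root)
    return order


# ---------------------------------------------------------------------------
# identity profiling

@dataclass(frozen=True)
class IdentityWindow:
    start: int  # 1-based alignment column
    end: int
    identity_pct: float
    partial: bool = False


def identity_profile(msa: MultipleAlignment, window: int = DEFAULT_WINDOW,
                     step: int = DEFAULT_STEP) -> list[IdentityWindow]:
    """Percent of fully conserved columns per sliding window.

    A column counts as identical only if it contains no gap, no N, and all
    characters agree. Windows tile from column 1 by ``step``; a final
    partial window is included and flagged.
    """
    if window > msa.length:
        raise ValueError("window larger than alignment")
    if step < 1:
        raise ValueError("step must be >= 1")
    ident = _column_identity(msa)
    out = []
    start = 0
    while start < msa.length:
        end = min(start + window, msa.length)
        frac = sum(ident[start:end]) / (end - start)
        out.append(IdentityWindow(start + 1, end, round(100 * frac, 4),
                                  partial=end - start < window))
        if end == msa.length:
            break
        start += step
    return out


def _column_identity(msa: MultipleAlignment) -> list[bool]:
    ident = []
    seqs = [s for _, s in msa.rows]
    for c in range(msa.length):
        chars = {s[c] for s in seqs}
        ident.append(len(chars) == 1 and "-" not in chars and "N" not in chars)
    return ident


@dataclass
class VariableRegion:
    start: int  # 1-based alignment columns
    end: int
    mean_identity_pct: float
    context: str = ""


def rank_variable_regions(profile: list[IdentityWindow],
                          threshold_pct: float = 90.0,
                          annotations: list | None = None) -> list[VariableRegion]:
    """Merge below-threshold windows into intervals, most divergent first."""
    lows = [w for w in profile if w.identity_pct < threshold_pct]
    if not lows:
        return []
    merged: list[list[IdentityWindow]] = [[lows[0]]]
    for w in lows[1:]:
        if w.start <= merged[-1][-1].end + 1:
            merged[-1].append(w)
        else:
            merged.append([w])
    regions = []
    for group in merged:
        mean = sum(w.identity_pct for w in group) / len(group)
        regions.append(VariableRegion(group[0].start, group[-1].end, round(mean, 4)))
    if annotations:
        for region in regions:
            names = sorted({f.name for f in annotations
                            if f.start <= region.end and region.start <= f.end})
            region.context = ",".join(names) if names else "intergenic"
    regions.sort(key=lambda r: (r.mean_identity_pct, r.start))
    return regions
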