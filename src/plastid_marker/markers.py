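"""Species-diagnostic substitution/indel calling and primer-pair design.

A site is diagnostic for species S when every S sample carries the same
state and no sample of any other species carries it. Substitution columns
additionally require every character involved to be an unambiguous base
(gap or N anywhere disqualifies the column). Indel events are maximal runs
of columns that are all-gap in S and all-base elsewhere (deletion in S) or
the converse (insertion in S).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import MultipleAlignment
from .io_genomes import reverse_complement

_BASES = frozenset("ACGT")


@dataclass
class DiagnosticEvent:
    event_type: str  # substitution | deletion | insertion
    species: str
    aln_start: int  # 1-based alignment columns; start == end for substitutions
    aln_end: int
    target_allele: str
    other_alleles: dict[str, str] = field(default_factory=dict)
    ref_start: int | None = None
    ref_end: int | None = None
    between_ref_positions: bool = False

    def verify(self, msa: MultipleAlignment) -> None:
        by_species: dict[str, list[str]] = {}
        for name, seq in msa.rows:
            by_species.setdefault(msa.species_of(name), []).append(seq)
        for col in range(self.aln_start, self.aln_end + 1):
            mine = {s[col - 1] for s in by_species[self.species]}
            assert len(mine) == 1, "diagnosed species must be fixed"
            others = {c for sp, seqs in by_species.items() if sp != self.species
                      for s in seqs for c in s[col - 1]}
            assert not (mine & others), "target state present in another species"


@dataclass
class PrimerParams:
    min_len: int = 18
    max_len: int = 24
    min_gc: float = 40.0
    max_gc: float = 60.0
    min_tm: float = 50.0
    max_tm: float = 62.0
    min_product: int = 150
    max_product: int = 900
    max_tm_diff: float = 5.0
    max_homopolymer: int = 4
    max_3prime_selfcomp: int = 4
    optimal_product: int = 400


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    fwd_interval: tuple[int, int]  # alignment columns, 1-based inclusive
    rev_interval: tuple[int, int]
    product_size: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float

    def verify(self, params: PrimerParams) -> None:
        for primer, tm, gc in ((self.forward, self.tm_f, self.gc_f),
                               (self.reverse, self.tm_r, self.gc_r)):
            assert params.min_len <= len(primer) <= params.max_len
            assert abs(primer_tm(primer) - tm) < 1e-9
            assert params.min_tm <= tm <= params.max_tm
            assert params.min_gc <= gc <= params.max_gc
            assert _max_homopolymer(primer) <= params.max_homopolymer
        assert self.fwd_interval[1] < self.rev_interval[0]
        assert abs(self.tm_f - self.tm_r) <= params.max_tm_diff
        assert params.min_product <= self.product_size <= params.max_product


@dataclass
class FilterReport:
    """Counts of candidates eliminated per filter (for empty-result triage)."""

    eliminated: Counter = field(default_factory=Counter)
    n_candidates: int = 0
    n_passed: int = 0

    def dominant_filter(self) -> str | None:
        if not self.eliminated:
            return None
        return self.eliminated.most_common(1)[0][0]


def _species_rows(msa: MultipleAlignment) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for name, seq in msa.rows:
        out.setdefault(msa.species_of(name), []).append(seq)
    return out


def call_diagnostic_events(msa: MultipleAlignment,
                           min_samples_per_species: int = 1) -> list[DiagnosticEvent]:
    """All species-diagnostic substitutions and merged indel runs, by column."""
    groups = _species_rows(msa)
    if len(groups) < 2:
        raise ValueError("need at least 2 species")
    for sp, seqs in groups.items():
        if len(seqs) < min_samples_per_species:
            raise ValueError(f"species {sp!r} has {len(seqs)} samples "
                             f"(< {min_samples_per_species})")
    species = sorted(groups)
    events: list[DiagnosticEvent] = []

    # per-column species states
    states: dict[str, list[set[str]]] = {
        sp: [set(seq[c] for seq in seqs) for c in range(msa.length)]
        for sp, seqs in ((s, groups[s]) for s in species)
    }

    open_indel: dict[tuple[str, str], int] = {}  # (species, kind) -> start col

    def close_indel(sp: str, kind: str, start: int, end: int) -> None:
        if kind == "deletion":
            allele = "-" * (end - start + 1)
        else:
            allele = "".join(next(iter(states[sp][c - 1])) for c in range(start, end + 1))
        others = {
            o: "".join(_summarize(states[o][c - 1]) for c in range(start, end + 1))
            for o in species if o != sp
        }
        events.append(DiagnosticEvent(kind, sp, start, end, allele, others))

    for col in range(1, msa.length + 1):
        col_states = {sp: states[sp][col - 1] for sp in species}
        for sp in species:
            mine = col_states[sp]
            fixed = len(mine) == 1
            x = next(iter(mine)) if fixed else None
            others_chars = set().union(*(col_states[o] for o in species if o != sp))

            # --- substitution: fixed base absent elsewhere, no gap/N anywhere
            if (fixed and x in _BASES and x not in others_chars
                    and others_chars <= _BASES):
                events.append(DiagnosticEvent(
                    "substitution", sp, col, col, x,
                    {o: _summarize(col_states[o]) for o in species if o != sp}))

            # --- indel runs
            del_here = mine == {"-"} and others_chars <= _BASES and others_chars
            ins_here = (fixed and x in _BASES and others_chars == {"-"})
            for kind, active in (("deletion", del_here), ("insertion", ins_here)):
                key = (sp, kind)
                if active and key not in open_indel:
                    open_indel[key] = col
                elif not active and key in open_indel:
                    close_indel(sp, kind, open_indel.pop(key), col - 1)
    for (sp, kind), start in sorted(open_indel.items()):
        close_indel(sp, kind, start, msa.length)
    events.sort(key=lambda e: (e.aln_start, e.event_type, e.species))
    for ev in events:
        ev.verify(msa)
    return events


def _summarize(chars: set[str]) -> str:
    return "/".join(sorted(chars)) if len(chars) > 1 else next(iter(chars))


def merge_haplotype_blocks(events: list[DiagnosticEvent]) -> list[DiagnosticEvent]:
    """Convenience rows merging runs of consecutive same-species substitutions."""
    subs = [e for e in events if e.event_type == "substitution"]
    blocks: list[DiagnosticEvent] = []
    run: list[DiagnosticEvent] = []

    def flush() -> None:
        if len(run) > 1:
            blocks.append(DiagnosticEvent(
                "substitution_block", run[0].species, run[0].aln_start,
                run[-1].aln_end, "".join(e.target_allele for e in run),
                {sp: "".join(e.other_alleles[sp] for e in run)
                 for sp in run[0].other_alleles}))
        run.clear()

    for ev in sorted(subs, key=lambda e: (e.species, e.aln_start)):
        if run and (ev.species != run[-1].species
                    or ev.aln_start != run[-1].aln_end + 1):
            flush()
        run.append(ev)
    flush()
    return blocks


def map_event_to_reference(event: DiagnosticEvent, msa: MultipleAlignment,
                           reference: str) -> tuple[int, int]:
    """Convert alignment columns to 1-based positions on the de-gapped reference.

    When the reference is gapped across the whole event (a deletion it
    shares), the event maps between the flanking positions
    ``(left, left + 1)`` and is flagged.
    """
    refseq = msa.row(reference)
    # ref position reached at or before each column
    pos = 0
    pos_at = [0] * (msa.length + 1)
    for col in range(1, msa.length + 1):
        if refseq[col - 1] != "-":
            pos += 1
        pos_at[col] = pos
    ref_chars = refseq[event.aln_start - 1:event.aln_end]
    if set(ref_chars) == {"-"}:
        left = pos_at[event.aln_start]
        event.ref_start, event.ref_end = left, left + 1
        event.between_ref_positions = True
    else:
        first = next(c for c in range(event.aln_start, event.aln_end + 1)
                     if refseq[c - 1] != "-")
        event.ref_start = pos_at[first]
        event.ref_end = pos_at[event.aln_end]
        event.between_ref_positions = False
    return event.ref_start, event.ref_end


def find_conserved_flanks(msa: MultipleAlignment, target: tuple[int, int],
                          flank_len: int = 20) -> tuple[list[tuple[int, int]],
                                                        list[tuple[int, int]]]:
    """Gap-free, 100%-identical windows of ``flank_len`` columns flanking
    ``target`` (1-based inclusive), each list ordered by distance to it."""
    t0, t1 = target
    if not (1 <= t0 <= t1 <= msa.length):
        raise ValueError(f"target {target} outside alignment")
    ident = _conserved_columns(msa)
    left, right = [], []
    for start in range(1, msa.length - flank_len + 2):
        end = start + flank_len - 1
        if end >= t0 and start <= t1:
            continue
        if all(ident[c - 1] for c in range(start, end + 1)):
            (left if end < t0 else right).append((start, end))
    left.sort(key=lambda iv: t0 - iv[1])
    right.sort(key=lambda iv: iv[0] - t1)
    return left, right


def _conserved_columns(msa: MultipleAlignment) -> list[bool]:
    seqs = [s for _, s in msa.rows]
    out = []
    for c in range(msa.length):
        chars = {s[c] for s in seqs}
        out.append(len(chars) == 1 and chars <= _BASES)
    return out


def primer_tm(primer: str, method: str = "wallace") -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C) degC."""
    if method != "wallace":
        raise ValueError(f"unknown Tm method {method!r}")
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 nt")
    if not set(primer) <= _BASES:
        raise ValueError("primer contains non-ACGT characters")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def _gc_pct(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _three_prime_selfcomp(primer: str, partner: str) -> int:
    """Longest ungapped complementary run between the primer's 3'-terminal
    8-mer and the partner (both 5'->3')."""
    tail = primer[-8:]
    comp_partner = reverse_complement(partner)
    best = 0
    for i in range(len(tail)):
        for j in range(len(comp_partner)):
            k = 0
            while (i + k < len(tail) and j + k < len(comp_partner)
                   and tail[i + k] == comp_partner[j + k]):
                k += 1
            best = max(best, k)
    return best


def design_primer_pairs(msa: MultipleAlignment, target: tuple[int, int],
                        params: PrimerParams | None = None,
                        reference: str | None = None,
                        max_pairs: int = 20,
                        return_report: bool = False):
    """Enumerate and rank primer pairs from conserved flanks around ``target``.

    Candidates are primer-length substrings of fully conserved gap-free
    flanking stretches, filtered on GC%, Wallace Tm, homopolymer length and
    3'-self/cross-complementarity, then paired under the product-size and
    Tm-difference constraints. Pairs are ranked by Tm balance, then product
    size closest to ``params.optimal_product``. Product size is measured on
    the de-gapped reference (first row by default), inclusive of primers.
    """
    params = params or PrimerParams()
    reference = reference or msa.rows[0][0]
    refseq = msa.row(reference)
    report = FilterReport()

    left, right = find_conserved_flanks(msa, target, params.min_len)
    fwd_cands = _enumerate_candidates(msa, left, params, report)
    rev_cands = _enumerate_candidates(msa, right, params, report)

    pos_at = []
    pos = 0
    for c in refseq:
        if c != "-":
            pos += 1
        pos_at.append(pos)

    pairs: list[PrimerPair] = []
    for f_iv, f_seq in fwd_cands:
        for r_iv, r_seq in rev_cands:
            if f_iv[1] >= r_iv[0]:
                continue
            product = pos_at[r_iv[1] - 1] - pos_at[f_iv[0] - 1] + 1
            if not params.min_product <= product <= params.max_product:
                report.eliminated["product_size"] += 1
                continue
            tm_f, tm_r = primer_tm(f_seq), primer_tm(r_seq)
            if abs(tm_f - tm_r) > params.max_tm_diff:
                report.eliminated["tm_difference"] += 1
                continue
            reverse = reverse_complement(r_seq)
            if (_three_prime_selfcomp(f_seq, reverse) > params.max_3prime_selfcomp
                    or _three_prime_selfcomp(reverse, f_seq) > params.max_3prime_selfcomp):
                report.eliminated["3prime_cross_complementarity"] += 1
                continue
            pairs.append(PrimerPair(f_seq, reverse, f_iv, r_iv, product,
                                    tm_f, tm_r, _gc_pct(f_seq), _gc_pct(reverse)))
    pairs.sort(key=lambda p: (abs(p.tm_f - p.tm_r),
                              abs(p.product_size - params.optimal_product),
                              p.fwd_interval, p.rev_interval))
    pairs = pairs[:max_pairs]
    report.n_passed = len(pairs)
    for p in pairs:
        p.verify(params)
    if return_report:
        return pairs, report
    return pairs


def _enumerate_candidates(msa, windows, params: PrimerParams,
                          report: FilterReport):
    """Primer-length substrings of conserved windows passing per-primer filters."""
    # conserved windows of min_len may abut; rebuild maximal stretches first
    cols = sorted({c for s, e in windows for c in range(s, e + 1)})
    stretches: list[tuple[int, int]] = []
    for c in cols:
        if stretches and c == stretches[-1][1] + 1:
            stretches[-1] = (stretches[-1][0], c)
        else:
            stretches.append((c, c))
    template = msa.rows[0][1]
    out = []
    seen: set[tuple[int, int]] = set()
    for s, e in stretches:
        for length in range(params.min_len, params.max_len + 1):
            for start in range(s, e - length + 2):
                iv = (start, start + length - 1)
                if iv in seen:
                    continue
                seen.add(iv)
                report.n_candidates += 1
                seq = template[start - 1:iv[1]]
                tm = 2.0 * (seq.count("A") + seq.count("T")) + \
                    4.0 * (seq.count("G") + seq.count("C"))
                if not params.min_gc <= _gc_pct(seq) <= params.max_gc:
                    report.eliminated["gc_content"] += 1
                    continue
                if not params.min_tm <= tm <= params.max_tm:
                    report.eliminated["tm_range"] += 1
                    continue
                if _max_homopolymer(seq) > params.max_homopolymer:
                    report.eliminated["homopolymer"] += 1
                    continue
                if _three_prime_selfcomp(seq, seq) > params.max_3prime_selfcomp:
                    report.eliminated["3prime_self_complementarity"] += 1
                    continue
                out.append((iv, seq))
    return out
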