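"""Seeded generators for plastome-like genomes and labeled species panels.

Every generator is deterministic given (config, seed) and returns a truth
table alongside the data, so downstream scanners and callers can be checked
against planted ground truth. Background sequence is i.i.d.: the consumers
are combinatorial algorithms that need controlled truth, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_genomes import GenomeRecord, reverse_complement
from .ssr import DEFAULT_THRESHOLDS, SSRRecord, canonical_motif_class, is_primitive

_ALPHABET = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    seed: int = 0
    lsc_len: int = 8000
    ir_len: int = 3000
    ssc_len: int = 1500
    gc: float = 0.37
    n_species: int = 3
    samples_per_species: int = 5
    n_diag_snps: int = 2
    diag_indel_lengths: list[int] = field(default_factory=list)
    intraspecific_rate: float = 0.0
    ssr_plants: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise ValueError("region lengths must be positive")
        if not 0 <= self.intraspecific_rate <= 0.05:
            raise ValueError("intraspecific_rate must be in [0, 0.05]")
        if any(l < 1 for l in self.diag_indel_lengths):
            raise ValueError("indel lengths must be >= 1")


@dataclass
class PlantedSSR:
    motif: str
    units: int
    region: str
    start: int  # 1-based on the generated genome
    end: int

    def as_record(self) -> SSRRecord:
        return SSRRecord(0, len(self.motif), self.motif, self.units,
                         self.start, self.end,
                         motif_class=canonical_motif_class(self.motif))


@dataclass
class PlantedEvent:
    event_type: str
    species: str
    aln_start: int
    aln_end: int
    target_allele: str


@dataclass
class TruthTable:
    ir_intervals: tuple[tuple[int, int], tuple[int, int]] | None = None
    region_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    ssrs: list[PlantedSSR] = field(default_factory=list)
    events: list[PlantedEvent] = field(default_factory=list)
    noise_positions: dict[str, list[int]] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_ALPHABET, size=n, p=p))


def simulate_plastome(config: SimulationConfig,
                      seed: int | None = None) -> tuple[GenomeRecord, TruthTable]:
    """Quadripartite genome ``LSC + IRb + SSC + revcomp(IRb)`` with planted SSRs.

    Planted SSRs are written at recorded coordinates with their immediate
    neighbourhood scrubbed so each planted run is maximal and no unplanned
    run meeting the default thresholds survives inside the planted window.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lsc = _random_dna(rng, config.lsc_len, config.gc)
    irb = _random_dna(rng, config.ir_len, config.gc)
    ssc = _random_dna(rng, config.ssc_len, config.gc)
    # stop chance IR extension across the SSC: first char must not pair
    # with the complement of the last one
    ssc[-1] = ssc[0]

    region_offsets = {
        "LSC": (0, lsc),
        "IRb": (config.lsc_len, irb),
        "SSC": (config.lsc_len + config.ir_len, ssc),
    }
    truth = TruthTable()
    used: list[tuple[int, int]] = []
    for motif, units, region in config.ssr_plants:
        motif = motif.upper()
        if not is_primitive(motif) or not 1 <= len(motif) <= 6:
            raise ValueError(f"planted motif {motif!r} must be primitive, 1-6 bp")
        if region not in region_offsets:
            raise ValueError(f"cannot plant into region {region!r}")
        offset, buf = region_offsets[region]
        size = units * len(motif)
        pad = 2 * len(motif) + 8  # scrub margin around the plant
        placed = False
        for _ in range(200):
            local = int(rng.integers(pad, len(buf) - size - pad))
            start = offset + local  # 0-based genome coordinate
            if all(start + size + pad <= s or start - pad >= e
                   for s, e in used):
                placed = True
                break
        if not placed:
            raise ValueError("planted SSRs overlap: no free space left")
        used.append((start - pad, start + size + pad))
        _scrub(buf, local, size, pad, motif, rng)
        buf[local:local + size] = list(motif * units)
        truth.ssrs.append(PlantedSSR(motif, units, region,
                                     start + 1, start + size))

    seq = "".join(lsc) + "".join(irb) + "".join(ssc)
    seq += reverse_complement("".join(irb))
    n = len(seq)
    L, I, S = config.lsc_len, config.ir_len, config.ssc_len
    truth.ir_intervals = ((L + 1, L + I), (L + I + S + 1, n))
    truth.region_intervals = {
        "LSC": (1, L), "IRb": (L + 1, L + I),
        "SSC": (L + I + 1, L + I + S), "IRa": (L + I + S + 1, n),
    }
    genome = GenomeRecord(id=f"synthetic-{config.seed if seed is None else seed}",
                          sequence=seq)
    return genome, truth


def _scrub(buf: list[str], local: int, size: int, pad: int, motif: str,
           rng: np.random.Generator) -> None:
    """Rewrite the plant neighbourhood with a repeat-free pattern and break
    the run phase at both ends so the planted SSR is exactly maximal."""
    lo = max(0, local - pad)
    hi = min(len(buf), local + size + pad)
    pattern = "ACGT" if motif[0] not in "AC" else "GTCA"
    filler = (pattern * (pad // 2 + 4))
    buf[lo:local] = list(filler[:local - lo])
    buf[local + size:hi] = list(filler[local - lo + size:local - lo + size + hi - local - size])
    u = len(motif)
    if local - 1 >= 0 and buf[local - 1] == motif[u - 1]:
        buf[local - 1] = _different(buf[local - 1], motif[u - 1])
    end = local + size
    if end < len(buf) and buf[end] == motif[0]:
        buf[end] = _different(buf[end], motif[0])


def _different(current: str, *avoid: str) -> str:
    for c in "ACGT":
        if c != current and c not in avoid:
            return c
    raise AssertionError


def simulate_species_panel(base: str, config: SimulationConfig,
                           seed: int | None = None,
                           reserved: list[tuple[int, int]] | None = None
                           ) -> tuple["object", TruthTable]:
    """Labeled multi-sample alignment with planted diagnostic events.

    Each species receives private substitutions and (optionally) one indel
    per entry of ``diag_indel_lengths`` (round-robin over species), placed
    outside ``reserved`` intervals (1-based, e.g. primer flanks or planted
    SSRs). Every sample then receives intraspecific substitution noise at
    positions disjoint from all diagnostic columns. Returns a
    :class:`~plastid_marker.align.MultipleAlignment` and the truth table.
    """
    from .align import MultipleAlignment

    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base = base.upper()
    n = len(base)
    species = [f"sp{chr(ord('A') + i)}" for i in range(config.n_species)]

    blocked = np.zeros(n, dtype=bool)
    for s, e in reserved or []:
        blocked[s - 1:e] = True

    # choose disjoint event footprints on the base sequence
    events_plan: list[tuple[str, str, int, int]] = []  # (kind, species, start0, end0)
    indel_kinds: list[tuple[str, int, str]] = []
    for idx, length in enumerate(config.diag_indel_lengths):
        sp = species[idx % len(species)]
        kind = "deletion" if idx % 2 == 0 else "insertion"
        indel_kinds.append((sp, length, kind))
    need_positions = config.n_diag_snps * len(species)

    def claim(length: int) -> int:
        for _ in range(500):
            start = int(rng.integers(0, n - length))
            if not blocked[start:start + length].any():
                blocked[max(0, start - 1):start + length + 1] = True
                return start
        raise ValueError("requested diagnostic events exceed available space")

    for sp, length, kind in indel_kinds:
        start = claim(length if kind == "deletion" else 1)
        events_plan.append((kind, sp, start, start + (length if kind == "deletion" else 1) - 1))
    snp_positions: list[tuple[str, int]] = []
    for sp in species:
        for _ in range(config.n_diag_snps):
            pos = claim(1)
            snp_positions.append((sp, pos))

    # species consensus sequences in a shared column space:
    # columns = base positions plus insertion slots after their anchor
    ins_by_pos: dict[int, tuple[str, str]] = {}
    del_by_species: dict[str, list[tuple[int, int]]] = {sp: [] for sp in species}
    for (kind, sp, s0, e0), (sp2, length, kind2) in zip(events_plan, indel_kinds):
        if kind == "insertion":
            ins_seq = "".join(_random_dna(rng, length, config.gc))
            ins_by_pos[s0] = (sp, ins_seq)
        else:
            del_by_species[sp].append((s0, e0))

    sub_by_species: dict[str, dict[int, str]] = {sp: {} for sp in species}
    for sp, pos in snp_positions:
        alt = _different(base[pos])
        sub_by_species[sp][pos] = alt

    truth = TruthTable()
    consensus: dict[str, list[str]] = {sp: [] for sp in species}
    colmap_base: list[int] = []  # alignment column (1-based) of base position i
    col = 0
    for i in range(n):
        col += 1
        colmap_base.append(col)
        for sp in species:
            if any(s <= i <= e for s, e in del_by_species[sp]):
                consensus[sp].append("-")
            else:
                consensus[sp].append(sub_by_species[sp].get(i, base[i]))
        if i in ins_by_pos:
            owner, ins_seq = ins_by_pos[i]
            for k, ch in enumerate(ins_seq):
                col += 1
                for sp in species:
                    consensus[sp].append(ch if sp == owner else "-")
            truth.events.append(PlantedEvent("insertion", owner,
                                             col - len(ins_seq) + 1, col, ins_seq))
    aln_len = col
    for sp in species:
        for s0, e0 in del_by_species[sp]:
            truth.events.append(PlantedEvent(
                "deletion", sp, colmap_base[s0], colmap_base[e0],
                "-" * (e0 - s0 + 1)))
        for pos, alt in sub_by_species[sp].items():
            truth.events.append(PlantedEvent("substitution", sp,
                                             colmap_base[pos], colmap_base[pos], alt))
    truth.events.sort(key=lambda e: (e.aln_start, e.event_type, e.species))

    diag_cols = np.zeros(aln_len, dtype=bool)
    for ev in truth.events:
        diag_cols[ev.aln_start - 1:ev.aln_end] = True

    rows: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for sp in species:
        cons = consensus[sp]
        noisable = [c for c in range(aln_len)
                    if not diag_cols[c] and cons[c] != "-"]
        for k in range(config.samples_per_species):
            sample_id = f"{sp}_{k + 1}"
            labels[sample_id] = sp
            seq = list(cons)
            if config.intraspecific_rate > 0 and noisable:
                hits = np.asarray(noisable)[
                    rng.random(len(noisable)) < config.intraspecific_rate]
                for c in hits:
                    seq[c] = _different(seq[c])
                truth.noise_positions[sample_id] = [int(c) + 1 for c in hits]
            else:
                truth.noise_positions[sample_id] = []
            rows.append((sample_id, "".join(seq)))
    return MultipleAlignment(rows, labels), truth
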