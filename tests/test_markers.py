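import numpy as np
import pytest

from plastid_marker.align import MultipleAlignment
from plastid_marker.io_genomes import reverse_complement
from plastid_marker.markers import (PrimerParams, call_diagnostic_events,
                                    design_primer_pairs, find_conserved_flanks,
                                    map_event_to_reference,
                                    merge_haplotype_blocks, primer_tm)
from plastid_marker.synthetic import SimulationConfig, simulate_species_panel


def _msa(rows, labels=None):
    if labels is None:
        labels = {name: name.split("_")[0] for name, _ in rows}
    return MultipleAlignment(rows, labels)


# ---------------------------------------------------------------------------
# diagnostic calling

def test_identical_alignment_no_events():
    rows = [(f"sp{s}_{i}", "ACGTACGT") for s in "ABC" for i in range(3)]
    assert call_diagnostic_events(_msa(rows), 3) == []


def test_planted_six_column_deletion_private_to_one_species():
    cfg = SimulationConfig(seed=5, n_species=3, samples_per_species=10,
                           n_diag_snps=0, diag_indel_lengths=[6],
                           intraspecific_rate=0.0)
    rng = np.random.default_rng(50)
    base = "".join(rng.choice(list("ACGT"), size=500))
    msa, truth = simulate_species_panel(base, cfg)
    events = call_diagnostic_events(msa, 10)
    assert len(events) == 1
    ev = events[0]
    t = truth.events[0]
    assert ev.event_type == "deletion"
    assert ev.species == t.species
    assert (ev.aln_start, ev.aln_end) == (t.aln_start, t.aln_end)
    assert ev.aln_end - ev.aln_start + 1 == 6
    assert ev.target_allele == "------"


def test_within_species_disagreement_blocks_call():
    # spC has G in 2/3 samples at the candidate column -> no event
    rows = [
        ("spA_1", "G"), ("spA_2", "G"),
        ("spB_1", "G"), ("spB_2", "G"),
        ("spC_1", "A"), ("spC_2", "A"), ("spC_3", "G"),
    ]
    assert call_diagnostic_events(_msa(rows), 2) == []


def test_other_species_need_not_agree_with_each_other():
    rows = [("spA_1", "A"), ("spA_2", "A"),
            ("spB_1", "C"), ("spB_2", "C"),
            ("spC_1", "G"), ("spC_2", "G")]
    events = call_diagnostic_events(_msa(rows), 2)
    # every species is fixed for a private base: three substitution events
    assert {(e.species, e.target_allele) for e in events} == \
        {("spA", "A"), ("spB", "C"), ("spC", "G")}
    a_event = next(e for e in events if e.species == "spA")
    assert a_event.other_alleles == {"spB": "C", "spC": "G"}


def test_gap_or_n_disqualifies_substitution_column():
    # col 1: gap in one spA sample; col 2: N in one spA sample.
    # spB is fixed for G at both columns but the gap/N disqualifies them.
    rows = [("spA_1", "-N"), ("spA_2", "AA"),
            ("spB_1", "GG"), ("spB_2", "GG")]
    assert call_diagnostic_events(_msa(rows), 2) == []
    # sanity: without the gap/N the substitution is called
    rows_ok = [("spA_1", "A"), ("spA_2", "A"), ("spB_1", "G"), ("spB_2", "G")]
    assert len(call_diagnostic_events(_msa(rows_ok), 2)) == 2


def test_min_samples_and_labels_enforced():
    rows = [("spA_1", "A"), ("spB_1", "G")]
    with pytest.raises(ValueError):
        call_diagnostic_events(_msa(rows), 2)
    msa = MultipleAlignment(rows, {"spA_1": "spA"})  # spB_1 unlabeled
    with pytest.raises(ValueError):
        call_diagnostic_events(msa, 1)


def test_insertion_event_called():
    rows = [("spA_1", "ACTTTGA"), ("spA_2", "ACTTTGA"),
            ("spB_1", "AC---GA"), ("spB_2", "AC---GA")]
    events = call_diagnostic_events(_msa(rows), 2)
    kinds = {(e.event_type, e.species, e.aln_start, e.aln_end) for e in events}
    assert ("insertion", "spA", 3, 5) in kinds
    assert ("deletion", "spB", 3, 5) in kinds


def test_merge_haplotype_blocks():
    rows = [("spA_1", "CCT"), ("spA_2", "CCT"),
            ("spB_1", "TAA"), ("spB_2", "TAA")]
    events = call_diagnostic_events(_msa(rows), 2)
    blocks = merge_haplotype_blocks(events)
    spa = next(b for b in blocks if b.species == "spA")
    assert (spa.aln_start, spa.aln_end, spa.target_allele) == (1, 3, "CCT")


@pytest.mark.parametrize("seed", range(100))
def test_precision_recall_one_on_noisy_panels(seed):
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        seed=seed, n_species=3,
        samples_per_species=int(rng.integers(5, 11)),
        n_diag_snps=int(rng.integers(1, 4)),
        diag_indel_lengths=[int(rng.integers(2, 8))],
        intraspecific_rate=float(rng.uniform(0, 0.005)))
    base = "".join(rng.choice(list("ACGT"), size=600))
    msa, truth = simulate_species_panel(base, cfg)
    events = call_diagnostic_events(msa, cfg.samples_per_species)
    called = {(e.event_type, e.species, e.aln_start, e.aln_end, e.target_allele)
              for e in events}
    expected = {(e.event_type, e.species, e.aln_start, e.aln_end, e.target_allele)
                for e in truth.events}
    assert called == expected  # precision == recall == 1.0


# ---------------------------------------------------------------------------
# reference mapping

def test_map_gap_free_reference_identity():
    rows = [("ref_1", "ACGTACGT"), ("spB_1", "ACGTTCGT")]
    msa = MultipleAlignment(rows, {"ref_1": "ref", "spB_1": "spB"})
    events = call_diagnostic_events(msa, 1)
    ev = events[0]
    assert map_event_to_reference(ev, msa, "ref_1") == (ev.aln_start, ev.aln_end)


def test_map_with_leading_reference_gaps():
    # reference has 2 gaps within columns 1-10; event at columns 11-16
    ref = "AC-GT-ACGT" + "ACGTAC"
    other = "ACAGTTACGT" + "GTACGT"
    msa = MultipleAlignment([("r_1", ref), ("o_1", other)],
                            {"r_1": "r", "o_1": "o"})
    from plastid_marker.markers import DiagnosticEvent
    ev = DiagnosticEvent("substitution", "o", 11, 16, "GTACGT", {"r": "ACGTAC"})
    assert map_event_to_reference(ev, msa, "r_1") == (9, 14)


def test_map_reference_deletion_flagged_between_positions():
    rows = [("spA_1", "AC---GA"), ("spA_2", "AC---GA"),
            ("spB_1", "ACTTTGA"), ("spB_2", "ACTTTGA")]
    msa = _msa(rows)
    ev = next(e for e in call_diagnostic_events(msa, 2)
              if e.event_type == "deletion")
    start, end = map_event_to_reference(ev, msa, "spA_1")
    assert (start, end) == (2, 3)
    assert ev.between_ref_positions


def test_map_missing_reference_errors():
    rows = [("spA_1", "A"), ("spB_1", "G")]
    msa = _msa(rows)
    ev = call_diagnostic_events(msa, 1)[0]
    with pytest.raises(KeyError):
        map_event_to_reference(ev, msa, "nope")


def test_map_roundtrip_allele_recovered():
    cfg = SimulationConfig(seed=3, n_species=3, samples_per_species=5,
                           n_diag_snps=2, diag_indel_lengths=[4],
                           intraspecific_rate=0.0)
    rng = np.random.default_rng(33)
    base = "".join(rng.choice(list("ACGT"), size=400))
    msa, _ = simulate_species_panel(base, cfg)
    events = call_diagnostic_events(msa, 5)
    for ev in events:
        ref_id = f"{ev.species}_1"
        start, end = map_event_to_reference(ev, msa, ref_id)
        if ev.event_type in ("substitution", "insertion"):
            refseq = msa.degapped(ref_id)
            assert refseq[start - 1:end] == ev.target_allele


# ---------------------------------------------------------------------------
# flanks and primers

def test_fully_conserved_alignment_all_windows():
    rows = [("a_1", "ACGT" * 20), ("b_1", "ACGT" * 20)]
    msa = _msa(rows)
    left, right = find_conserved_flanks(msa, (40, 45), flank_len=10)
    assert left and right
    assert all(e < 40 for _, e in left)
    assert all(s > 45 for s, _ in right)
    # ordered by distance to the target
    assert left[0][1] == 39
    assert right[0][0] == 46


def test_target_abutting_alignment_end():
    rows = [("a_1", "ACGT" * 10), ("b_1", "ACGT" * 10)]
    left, right = find_conserved_flanks(_msa(rows), (31, 40), flank_len=10)
    assert right == []
    assert left


def test_flanks_skip_gapped_or_variable_windows():
    a = "AAAAACCCCC" + "GGGG" + "TTTTTAAAAA"
    b = "AAAAACCCCC" + "CCCC" + "TTTTTA-AAA"
    left, right = find_conserved_flanks(_msa([("a_1", a), ("b_1", b)]),
                                        (11, 14), flank_len=5)
    assert (1, 5) in left and (6, 10) in left
    # no right window may touch the gap column (21) or the variable block
    assert right and all(not (s <= 21 <= e) for s, e in right)
    assert right[0] == (15, 19)  # closest to the target first


def test_primer_tm_wallace():
    assert primer_tm("GC" * 5 + "AT" * 5) == 60.0
    assert primer_tm("A" * 20) == 40.0
    with pytest.raises(ValueError):
        primer_tm("ACGTACG")  # 7-mer
    with pytest.raises(ValueError):
        primer_tm("ACGTACGN")
    with pytest.raises(ValueError):
        primer_tm("ACGTACGTACGT", method="nearest")


@pytest.fixture(scope="module")
def designed_panel():
    rng = np.random.default_rng(99)
    # balanced-GC random flanks, divergent center
    flank_l = "".join(rng.choice(list("ACGT"), size=220))
    flank_r = "".join(rng.choice(list("ACGT"), size=220))
    center_a = "".join(rng.choice(list("ACGT"), size=60))
    center_b = "".join(rng.choice(list("ACGT"), size=60))
    rows = []
    for s, center in (("spA", center_a), ("spB", center_b)):
        for i in (1, 2):
            rows.append((f"{s}_{i}", flank_l + center + flank_r))
    msa = _msa(rows)
    target = (221, 280)
    pairs = design_primer_pairs(msa, target, PrimerParams(), max_pairs=10)
    return msa, target, pairs


def test_design_finds_pairs_covering_target(designed_panel):
    msa, target, pairs = designed_panel
    assert pairs
    for p in pairs:
        assert p.fwd_interval[1] < target[0]
        assert p.rev_interval[0] > target[1]
        p.verify(PrimerParams())


def test_design_product_size_matches_reference_arithmetic(designed_panel):
    msa, _, pairs = designed_panel
    ref = msa.degapped(msa.rows[0][0])
    for p in pairs:
        # gap-free alignment: columns == reference positions
        expected = p.rev_interval[1] - p.fwd_interval[0] + 1
        assert p.product_size == expected
        # the reverse primer is the reverse complement of its template slice
        template = ref[p.rev_interval[0] - 1:p.rev_interval[1]]
        assert p.reverse == reverse_complement(template)
        assert p.forward == ref[p.fwd_interval[0] - 1:p.fwd_interval[1]]


def test_all_a_flanks_yield_empty_with_report():
    rows = [("a_1", "A" * 120 + "C" + "A" * 120),
            ("b_1", "A" * 120 + "G" + "A" * 120)]
    pairs, report = design_primer_pairs(_msa(rows), (121, 121),
                                        return_report=True)
    assert pairs == []
    assert report.dominant_filter() in ("gc_content", "homopolymer", "tm_range")
    assert report.eliminated


def test_design_respects_product_size_window():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=2500))
    rows = [("a_1", seq), ("b_1", seq)]
    params = PrimerParams(min_product=150, max_product=400)
    pairs = design_primer_pairs(_msa(rows), (1200, 1210), params)
    for p in pairs:
        assert 150 <= p.product_size <= 400
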