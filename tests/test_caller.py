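"""Pileup and heteroplasmy calling: gates, strand bias, indels, deletions."""
import numpy as np
import pytest

from mthet.align import index_reference, map_reads
from mthet.caller import (
    CallThresholds,
    Pileup,
    build_pileup,
    call_large_deletions,
    call_site_variants,
    error_p_value,
    left_align_insertion,
    mark_de_novo,
    progenitor_reference,
    realign_and_rebuild,
    strand_bias_filter,
    variant_frequency,
)
from mthet.mito_model import AnnotatedGenome
from mthet.preprocess import Read
from mthet.synthetic_data import SimVariant, n_fragments_for_coverage, simulate_fragments

TH = CallThresholds(error_rate=0.002)


def _pileup_with_site(genome, pos0, ref_base, alt_base, alt_n, cov, split=(0.5, 0.5)):
    """Construct a pileup with a single variant site by direct counts."""
    pile = Pileup(genome)
    bidx = {b: i for i, b in enumerate("ACGT")}
    L = genome.length
    for p in range(L):
        pile.base_counts[p, bidx[genome.sequence[p]], 0] = cov // 2
        pile.base_counts[p, bidx[genome.sequence[p]], 1] = cov - cov // 2
    r = bidx[ref_base]
    a = bidx[alt_base]
    fwd = int(round(alt_n * split[0]))
    rev = alt_n - fwd
    pile.base_counts[pos0, r, 0] -= fwd
    pile.base_counts[pos0, r, 1] -= rev
    pile.base_counts[pos0, a, 0] += fwd
    pile.base_counts[pos0, a, 1] += rev
    return pile


@pytest.fixture(scope="module")
def genome():
    from mthet import build_synthetic_genome, default_genome_spec

    return build_synthetic_genome(default_genome_spec(), seed=1)


class TestFrequencyArithmetic:
    @pytest.mark.parametrize(
        "support,coverage,expected",
        [(6, 402, 0.015), (54, 196, 0.276), (260, 260, 1.000), (116, 287, 0.404)],
    )
    def test_reported_frequency_is_support_over_coverage(self, support, coverage, expected):
        assert variant_frequency(support, coverage) == expected

    def test_support_cannot_exceed_coverage(self):
        with pytest.raises(ValueError):
            variant_frequency(10, 5)


class TestPileup:
    def test_single_perfect_read_covers_span(self, genome):
        idx = index_reference(genome, k=8)
        read = Read("r", genome.sequence[1000:1300], "I" * 300)
        alns, _ = map_reads([read], idx)
        pile = build_pileup(alns, genome)
        assert (pile.coverage[1000:1300] == 1).all()
        assert pile.coverage.sum() == 300

    def test_mismatch_counts_alt_base(self, genome):
        idx = index_reference(genome, k=8)
        s = list(genome.sequence[2000:2300])
        s[150] = "A" if s[150] != "A" else "C"
        alns, _ = map_reads([Read("r", "".join(s), "I" * 300)], idx)
        pile = build_pileup(alns, genome)
        bidx = "ACGT".index(s[150])
        assert pile.base_counts[2150, bidx].sum() == 1

    def test_reference_name_mismatch_rejected(self, genome):
        other = AnnotatedGenome(name="other", sequence="ACGT" * 10, circular=False)
        idx = index_reference(genome, k=8)
        alns, _ = map_reads([Read("r", genome.sequence[100:400], "I" * 300)], idx)
        with pytest.raises(ValueError):
            build_pileup(alns, other)

    def test_simulated_coverage_near_target(self, genome, rng):
        n = n_fragments_for_coverage(300, genome.length, 330)
        frags = simulate_fragments(genome, [], n, rng)
        idx = index_reference(genome, k=8)
        reads = [Read(f"r{i}", f.sequence, "I" * len(f.sequence)) for i, f in enumerate(frags)]
        alns, _ = map_reads(reads, idx)
        pile = build_pileup(alns, genome)
        assert abs(pile.coverage.mean() - 300) / 300 < 0.10


class TestProgenitorReference:
    def test_majority_base_wins(self, genome):
        pile = _pileup_with_site(genome, 3413, genome.sequence[3413], "T", 120, 300)
        ref, flagged = progenitor_reference(pile)
        assert "ACGT"[ref[3413]] == genome.sequence[3413]  # 60/40 keeps majority
        pile2 = _pileup_with_site(genome, 3413, genome.sequence[3413], "T", 200, 300)
        ref2, _ = progenitor_reference(pile2)
        assert "ACGT"[ref2[3413]] == "T"

    def test_tie_falls_back_to_fasta_and_flags(self, genome):
        pile = _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 150, 300)
        ref, flagged = progenitor_reference(pile)
        assert "ACGT"[ref[5000]] == genome.sequence[5000]
        assert 5001 in flagged

    def test_zero_coverage_falls_back_flagged(self, genome):
        pile = Pileup(genome)
        pile.base_counts[0, 0, 0] = 1  # cover only position 1
        ref, flagged = progenitor_reference(pile)
        assert 2 in flagged


class TestGates:
    def test_coverage_gate(self, genome):
        pile = _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 50, 99)
        assert call_site_variants(pile, TH, annotate=False) == []

    def test_support_gate(self, genome):
        pile = _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 3, 300)
        assert call_site_variants(pile, TH, annotate=False) == []

    def test_p_value_gate(self, genome):
        # support 4 of 3000 at error 0.002 is expected noise (p >> 1e-6)
        pile = _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 4, 3000)
        assert call_site_variants(pile, TH, annotate=False) == []

    def test_passing_site_called_with_frequency(self, genome):
        pile = _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 54, 196)
        (call,) = call_site_variants(pile, TH, annotate=False)
        assert (call.position, call.type, call.alt) == (5001, "SNP", "T")
        assert call.frequency == 0.276

    def test_permissive_mode_emits_single_read_observations(self, genome):
        pile = _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 2, 300)
        calls = call_site_variants(pile, TH, permissive=True, annotate=False)
        assert any(c.position == 5001 and c.support == 2 for c in calls)

    def test_at_rich_sites_excluded(self, genome):
        # position 400 lies inside the AT-rich feature (101..700)
        pile = _pileup_with_site(genome, 399, genome.sequence[399], "T", 100, 300)
        assert call_site_variants(pile, TH, annotate=False) == []


class TestStrandBias:
    def test_balanced_split_passes(self):
        assert strand_bias_filter((20, 20), (150, 150), TH)

    def test_extreme_one_sided_support_fails(self):
        # 40/0 on balanced coverage: exact binomial p = 2*0.5^40 << 1e-5
        assert not strand_bias_filter((40, 0), (150, 150), TH)

    def test_sixty_forty_passes_without_testing(self):
        assert strand_bias_filter((24, 16), (150, 150), TH)

    def test_skew_explained_by_coverage_passes(self):
        # 90% forward support when coverage itself is 90% forward
        assert strand_bias_filter((36, 4), (270, 30), TH)


class TestIndelCalls:
    def test_insertion_left_aligned_to_run_start(self, genome):
        # any placement inside the (A)10 run at 3567..3576 canonicalizes
        starts = {left_align_insertion(genome, p0, "A")[0] for p0 in range(3566, 3577)}
        assert starts == {3566}

    def test_non_repetitive_indel_unchanged(self, genome):
        pos0 = 6000
        assert genome.sequence[pos0 - 1] != genome.sequence[pos0]
        cpos, _ = left_align_insertion(genome, pos0, genome.sequence[pos0 - 1])
        assert cpos in (pos0 - 1, pos0)  # shifts at most one step in unique context

    def test_planted_insertion_called_with_run_notation(self, genome, rng):
        v = SimVariant("insertion", 3567, ref="A", alt="A")
        frags = simulate_fragments(genome, [(v, 0.15)], 6000, rng)
        idx = index_reference(genome, k=8)
        reads = [Read(f"r{i}", f.sequence, "I" * len(f.sequence)) for i, f in enumerate(frags)]
        alns, _ = map_reads(reads, idx)
        pile = build_pileup(alns, genome)
        calls = call_site_variants(pile, TH, annotate=False)
        ins = [c for c in calls if c.type == "insertion"]
        assert len(ins) == 1
        assert ins[0].position == 3567
        assert ins[0].homopolymer_run == 10
        assert ins[0].change == "(A)10 → (A)11"
        se = np.sqrt(0.15 * 0.85 / ins[0].coverage)
        assert abs(ins[0].frequency - 0.15) < 3 * se


@pytest.fixture(scope="module")
def deletion_pileup(genome):
    rng = np.random.default_rng(77)
    v = SimVariant("large_deletion", 12473, length=870)
    n = n_fragments_for_coverage(300, genome.length, 330)
    frags = simulate_fragments(genome, [(v, 0.85)], n, rng)
    idx = index_reference(genome, k=8)
    reads = [Read(f"r{i}", f.sequence, "I" * len(f.sequence)) for i, f in enumerate(frags)]
    alns, _ = map_reads(reads, idx)
    pile, _ = realign_and_rebuild(alns, genome)
    return pile


class TestLargeDeletion:
    def test_planted_deletion_recovered(self, genome, deletion_pileup):
        (call,) = call_large_deletions(deletion_pileup, genome, min_support=4)
        assert call.start == 12473
        assert call.length == 870
        lo, hi = call.frequency_range
        se = np.sqrt(0.85 * 0.15 / min(call.coverage_range))
        assert lo - 3 * se <= 0.85 <= hi + 3 * se
        assert call.repeat is not None and call.repeat.length == 36
        assert set(call.effect.kinds) == {"alternative_start", "truncation"}

    def test_ambiguity_interval_is_exact_repeat_extent(self, genome, deletion_pileup):
        (call,) = call_large_deletions(deletion_pileup, genome, min_support=4)
        # exact left subrepeat is 5 bp, so 6 equivalent start positions
        assert call.ambiguity_interval == (12473, 12478)

    def test_no_split_reads_empty(self, genome):
        assert call_large_deletions(Pileup(genome), genome) == []

    def test_alternative_boundaries_kept_distinct(self, genome):
        pile = Pileup(genome)
        # two clusters: canonical starts 6 apart (alternative repeat boundary)
        for _ in range(10):
            pile.split_events.append((12472, 870, "+", "a"))
            pile.split_events.append((12478 + 5, 864, "+", "b"))
        calls = call_large_deletions(pile, genome, min_support=4)
        assert len(calls) == 2
        assert calls[0].key != calls[1].key


class TestDeNovo:
    def _call(self, genome, pos0, alt, n, cov):
        pile = _pileup_with_site(genome, pos0, genome.sequence[pos0], alt, n, cov)
        return call_site_variants(pile, TH, annotate=False)

    def test_progenitor_trace_support_blocks_de_novo(self, genome):
        ma = self._call(genome, 5000, "T", 60, 300)
        prog_perm = self._call(genome, 5000, "T", 2, 300)  # below thresholds
        prog_perm = call_site_variants(
            _pileup_with_site(genome, 5000, genome.sequence[5000], "T", 2, 300),
            TH, permissive=True, annotate=False,
        )
        marked = mark_de_novo(ma, prog_perm)
        assert marked[0].de_novo is False

    def test_absent_from_progenitor_is_de_novo(self, genome):
        ma = self._call(genome, 5000, "T", 60, 300)
        marked = mark_de_novo(ma, [])
        assert marked[0].de_novo is True

    def test_progenitor_only_variant_not_in_ma_output(self, genome):
        ma = self._call(genome, 5000, "T", 60, 300)
        prog = self._call(genome, 7000, "A", 60, 300)
        marked = mark_de_novo(ma, prog)
        assert {c.position for c in marked} == {5001}


def test_error_p_value_is_binomial_tail():
    from scipy.stats import binom

    assert error_p_value(6, 402, 0.002) == pytest.approx(binom.sf(5, 402, 0.002))
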