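"""Genome model: census, direct repeats, protein effects, loading."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mthet.mito_model import (
    AnnotatedGenome,
    Feature,
    annotate_effect,
    census_homopolymers,
    find_direct_repeats,
    homopolymer_run_length,
    load_genome,
    revcomp,
)


def brute_force_census(seq: str, min_run: int, circular: bool = False) -> int:
    """Independent O(L) oracle: position-by-position scan for A/T runs."""
    if circular and len(set(seq)) > 1:
        # rotate so the sequence does not start mid-run
        i = 0
        while seq[i] == seq[-1]:
            i += 1
        seq = seq[i:] + seq[:i]
    total = 0
    run_base, run_len = None, 0
    for ch in seq + "$":
        if ch == run_base:
            run_len += 1
        else:
            if run_base in ("A", "T") and run_len >= min_run:
                total += run_len
            run_base, run_len = ch, 1
    return total


class TestCensus:
    def test_single_qualifying_run(self):
        g = AnnotatedGenome(name="t", sequence="CCAAAAAAAATTG", circular=False)
        c = census_homopolymers(g, min_run=8, exclude=None)
        assert c.n_sites == 8
        assert [(r.base, r.start, r.length) for r in c.runs] == [("A", 3, 8)]

    def test_threshold_just_above_run(self):
        g = AnnotatedGenome(name="t", sequence="CCAAAAAAAATTG", circular=False)
        assert census_homopolymers(g, min_run=9, exclude=None).n_sites == 0

    def test_runs_are_maximal(self):
        g = AnnotatedGenome(name="t", sequence="GAAAAAAAAG" + "C" * 10, circular=False)
        c = census_homopolymers(g, min_run=8, exclude=None)
        (run,) = c.runs
        assert (run.start, run.end, run.length) == (2, 9, 8)

    @given(st.text(alphabet="ACGT", min_size=50, max_size=400), st.integers(3, 9))
    def test_matches_brute_force_scan(self, seq, min_run):
        g = AnnotatedGenome(name="t", sequence=seq, circular=False)
        assert census_homopolymers(g, min_run=min_run, exclude=None).n_sites == brute_force_census(
            seq, min_run
        )

    def test_matches_brute_force_on_random_10kb(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000, p=[0.35, 0.1, 0.1, 0.45]))
        g = AnnotatedGenome(name="t", sequence=seq, circular=False)
        for k in (5, 8):
            assert census_homopolymers(g, min_run=k, exclude=None).n_sites == brute_force_census(seq, k)

    def test_monotone_in_min_run(self, genome):
        sizes = [census_homopolymers(genome, min_run=k, exclude=None).n_sites for k in range(2, 14)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_excluded_feature_bases_never_counted(self):
        seq = "G" + "A" * 10 + "G" + "C" * 8
        g = AnnotatedGenome(
            name="t", sequence=seq, circular=False,
            features=[Feature("ctrl", "AT-rich", 7, 20)],
        )
        # run spans 2..11; bases 7..11 fall inside the excluded feature
        c = census_homopolymers(g, min_run=8, exclude="AT-rich")
        assert c.n_sites == 5

    def test_wrapped_run_on_circular_genome(self):
        seq = "AAAA" + "G" + "C" * 5 + "G" + "AAAAA"
        g = AnnotatedGenome(name="t", sequence=seq, circular=True)
        c = census_homopolymers(g, min_run=8, exclude=None)
        assert c.n_sites == 9
        assert c.runs[0].wraps

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            AnnotatedGenome(name="t", sequence="")


class TestDirectRepeats:
    def _genome_with_planted(self, motif_a, motif_b, rng):
        left = "".join(rng.choice(list("ACGT"), size=200))
        mid = "".join(rng.choice(list("ACGT"), size=400))
        right = "".join(rng.choice(list("ACGT"), size=200))
        seq = left + motif_a + mid + motif_b + right
        return AnnotatedGenome(name="t", sequence=seq, circular=False), 201, 201 + len(motif_a) + 400

    def test_identical_planted_pair(self, rng):
        motif = "".join(rng.choice(list("ACGT"), size=36))
        g, a, b = self._genome_with_planted(motif, motif, rng)
        pairs = find_direct_repeats(g, (a - 50, a + 85), (b - 50, b + 85), min_len=10, max_mismatch=1)
        top = pairs[0]
        assert top.length >= 36
        assert top.left_interval[0] <= a <= top.left_interval[1]
        assert top.right_interval[0] - top.left_interval[0] == b - a

    def test_single_mismatch_decomposition(self, rng):
        motif = list("".join(rng.choice(list("ACGT"), size=36)))
        motif[5] = "C"
        right = motif.copy()
        right[5] = "T"
        g, a, b = self._genome_with_planted("".join(motif), "".join(right), rng)
        pairs = find_direct_repeats(g, (a, a + 35), (b, b + 35), min_len=5, max_mismatch=1)
        top = pairs[0]
        assert top.length == 36
        assert top.mismatch_positions == (5,)
        assert tuple(ln for _, ln in top.exact_subrepeats) == (5, 30)

    def test_no_shared_substring(self):
        g = AnnotatedGenome(name="t", sequence="A" * 50 + "C" * 50, circular=False)
        assert find_direct_repeats(g, (1, 50), (51, 100), min_len=5, max_mismatch=0) == []

    def test_overlapping_windows_rejected(self, genome):
        with pytest.raises(ValueError):
            find_direct_repeats(genome, (100, 300), (200, 400), min_len=5)

    def test_symmetry_under_window_swap(self, genome):
        a, b = (12400, 12560), (13300, 13440)
        fwd = find_direct_repeats(genome, a, b, min_len=10, max_mismatch=1)
        rev = find_direct_repeats(genome, b, a, min_len=10, max_mismatch=1)
        assert {(p.left_interval, p.right_interval) for p in fwd} == {
            (p.right_interval, p.left_interval) for p in rev
        }


class _Call:
    def __init__(self, position, vtype, ref="", alt="", length=1):
        self.position = position
        self.type = vtype
        self.ref = ref
        self.alt = alt
        self.length = length


class TestProteinEffect:
    @pytest.fixture()
    def coding_genome(self):
        # gene: ATG TCA AAA TAA then a trailing (A)9 run still inside the
        # annotated gene interval but after the stop codon
        seq = "GGGG" + "ATGTCAAAATAA" + "G" + "AAAAAAAAA" + "G" + "CCCCCC"
        gene = Feature("g1", "gene", 5, 27, "+", reading_frame_start=5)
        trna = Feature("tv", "tRNA", 30, 33, "+")
        return AnnotatedGenome(name="t", sequence=seq, circular=False, features=[gene, trna])

    def test_serine_to_leucine_substitution(self, coding_genome):
        # TCA (Ser) -> TTA (Leu) at the 2nd codon position
        eff = annotate_effect(_Call(9, "SNP", ref="C", alt="T"), coding_genome)
        assert eff.kinds == ("substitution",)
        assert (eff.aa_from, eff.aa_to) == ("S", "L")

    def test_insertion_after_stop_codon_is_none(self, coding_genome):
        eff = annotate_effect(_Call(19, "insertion", ref="A", alt="A"), coding_genome)
        assert eff.kinds == ("none",)

    def test_plus_one_insertion_in_gene_body_is_frameshift(self, coding_genome):
        eff = annotate_effect(_Call(8, "insertion", ref="T", alt="T"), coding_genome)
        assert eff.kinds == ("frameshift",)

    def test_inframe_indel_never_frameshift(self, coding_genome):
        eff = annotate_effect(_Call(8, "deletion", ref="TCA", alt="", length=3), coding_genome)
        assert "frameshift" not in eff.kinds

    def test_nonsense_snp_is_truncation(self, coding_genome):
        # AAA (Lys) -> TAA (stop) at codon 3 position 1
        eff = annotate_effect(_Call(11, "SNP", ref="A", alt="T"), coding_genome)
        assert eff.kinds == ("truncation",)

    def test_trna_variant_is_noncoding(self, coding_genome):
        eff = annotate_effect(_Call(31, "SNP", ref="C", alt="T"), coding_genome)
        assert eff.kinds == ("non-coding",)
        assert eff.feature_role == "tRNA"

    def test_large_deletion_removing_gene_start(self, coding_genome):
        eff = annotate_effect(_Call(3, "large_deletion", length=10), coding_genome)
        assert set(eff.kinds) == {"alternative_start", "truncation"}

    def test_out_of_bounds_rejected(self, coding_genome):
        with pytest.raises(ValueError):
            annotate_effect(_Call(999, "SNP", ref="A", alt="T"), coding_genome)


class TestLoadGenome:
    def test_roundtrip_with_features(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g1 test\nACGTACGTACGTACGTACGT\n")
        feats = tmp_path / "f.tsv"
        feats.write_text(
            "label\trole\tstart\tend\tstrand\ngeneA\tgene\t1\t9\t+\n"
        )
        g = load_genome(fasta, feats)
        assert g.length == 20
        assert len(g.features) == 1 and g.features[0].label == "geneA"

    def test_lowercase_normalized(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g1\nacgtacgtacgtacgtacgt\n")
        assert load_genome(fasta).sequence == "ACGTACGTACGTACGTACGT"

    def test_out_of_bounds_feature_names_offender(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g1\nACGTACGTACGTACGTACGT\n")
        feats = tmp_path / "f.tsv"
        feats.write_text("label\trole\tstart\tend\tstrand\nbad\tgene\t1\t25\t+\n")
        with pytest.raises(ValueError, match="bad"):
            load_genome(fasta, feats)

    def test_multi_record_fasta_rejected(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError):
            load_genome(fasta)


def test_homopolymer_run_length(genome):
    # the planted (A)10 run: every position inside reports length 10
    assert homopolymer_run_length(genome, 3566, "A") == 10
    assert homopolymer_run_length(genome, 3570, "A") == 10


def test_revcomp_involution(rng):
    s = "".join(rng.choice(list("ACGT"), size=100))
    assert revcomp(revcomp(s)) == s
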