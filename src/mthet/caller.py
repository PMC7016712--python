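"""Pileup construction and heteroplasmy calling.

Calls three variant classes against a small circular mtgenome:

* site-level SNPs and short (homopolymer) indels, gated on minimum
  coverage, raw supporting reads, an exact binomial error-model p-value
  and a strand-bias rule;
* large repeat-mediated deletions from split-read clusters, reported
  with canonical left-aligned breakpoints, a boundary-ambiguity interval
  (the flanking exact-repeat extent) and a per-breakpoint frequency
  range.

Variant frequency is simply supporting reads over coverage; because
exact PCR duplicates are removed upstream, each supporting read is
treated as an independent source molecule.  The binomial null is an
explicit replacement for proprietary callers' undocumented approximate
p-values, so printed p-values of other tools are not reproduced exactly.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .align import Alignment, left_align_gap
from .mito_model import (
    AnnotatedGenome,
    ProteinEffect,
    RepeatPair,
    annotate_effect,
    find_direct_repeats,
    homopolymer_run_length,
)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class CallThresholds:
    """Site-variant gates: coverage, raw support, error-model p, strand bias."""

    min_coverage: int = 100
    min_support: int = 4
    max_p: float = 1e-6
    strand_bias_trigger: float = 0.65
    strand_bias_min_p: float = 1e-5
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.min_support) <= 0 or self.max_p <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.5 < self.strand_bias_trigger <= 1:
            raise ValueError("strand_bias_trigger must be in (0.5, 1]")
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must be in (0, 1)")


class Pileup:
    """Per-site, per-strand base counts plus indel and split-read events."""

    def __init__(self, genome: AnnotatedGenome):
        self.genome = genome
        L = genome.length
        # [position, base, strand(0=+,1=-)]
        self.base_counts = np.zeros((L, 4, 2), dtype=np.int32)
        self.insertions: dict[int, Counter] = defaultdict(Counter)  # pos0 -> {(seq, strand): n}
        self.deletions: dict[int, Counter] = defaultdict(Counter)  # pos0 -> {(len, strand): n}
        self.split_events: list[tuple[int, int, str, str]] = []  # (start0, len, strand, read_id)
        self.ref = np.array([_BASE_IDX.get(b, -1) for b in genome.sequence], dtype=np.int8)
        self.n_reads = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.base_counts.sum(axis=(1, 2))

    def strand_coverage(self, pos0: int) -> tuple[int, int]:
        c = self.base_counts[pos0].sum(axis=0)
        return int(c[0]), int(c[1])

    def set_reference(self, ref_idx: np.ndarray) -> None:
        if len(ref_idx) != len(self.ref):
            raise ValueError("reference vector length mismatch")
        self.ref = ref_idx.astype(np.int8)


def build_pileup(alignments: list[Alignment], genome: AnnotatedGenome) -> Pileup:
    """Accumulate per-strand base counts and indel/split events."""
    pile = Pileup(genome)
    L = genome.length
    for aln in alignments:
        if aln.ref_name != genome.name:
            raise ValueError(f"alignment reference {aln.ref_name!r} does not match genome {genome.name!r}")
        sidx = 0 if aln.strand == "+" else 1
        pile.n_reads += 1
        for op, rs, qs, ln in aln.ops:
            if op == "M":
                pos = (rs + np.arange(ln)) % L
                cols = np.array([_BASE_IDX.get(c, -1) for c in aln.read_seq[qs : qs + ln]])
                keep = cols >= 0
                np.add.at(pile.base_counts, (pos[keep], cols[keep], sidx), 1)
            elif op == "I":
                pile.insertions[rs % L][(aln.read_seq[qs : qs + ln], aln.strand)] += 1
            elif op == "D":
                pile.deletions[rs % L][(ln, aln.strand)] += 1
        if aln.large_gap is not None:
            gs, gl = aln.large_gap
            pile.split_events.append((gs % L, gl, aln.strand, aln.read_id))
    return pile


def progenitor_reference(pileup: Pileup) -> tuple[np.ndarray, list[int]]:
    """Majority base per position, the calling reference for all lines.

    Zero-coverage positions and exact ties fall back to the FASTA base
    and are flagged (returned as a list of 1-based positions).
    """
    counts = pileup.base_counts.sum(axis=2)
    fasta_ref = np.array(
        [_BASE_IDX.get(b, 0) for b in pileup.genome.sequence], dtype=np.int8
    )
    ref = counts.argmax(axis=1).astype(np.int8)
    top = counts.max(axis=1)
    total = counts.sum(axis=1)
    flagged: list[int] = []
    for pos0 in np.flatnonzero(total == 0):
        ref[pos0] = fasta_ref[pos0]
        flagged.append(int(pos0) + 1)
    for pos0 in range(len(ref)):
        if total[pos0] > 0 and (counts[pos0] == top[pos0]).sum() > 1:
            ref[pos0] = fasta_ref[pos0]
            flagged.append(pos0 + 1)
    return ref, sorted(set(flagged))


@dataclass
class VariantCall:
    """One site-level SNP or short indel (frequencies to three decimals)."""

    position: int  # 1-based canonical (left-aligned for indels)
    type: str  # SNP | insertion | deletion
    ref: str
    alt: str
    coverage: int
    support: int
    frequency: float
    p_value: float
    strand_support: tuple[int, int]
    strand_coverage: tuple[int, int]
    homopolymer_run: int = 0
    feature: str = "-"
    effect: ProteinEffect | None = None
    de_novo: bool = False
    length: int = 1

    @property
    def change(self) -> str:
        if self.type == "SNP":
            return f"{self.ref} → {self.alt}"
        n = self.homopolymer_run
        base = self.alt if self.type == "insertion" else self.ref
        if n:
            delta = 1 if self.type == "insertion" else -1
            return f"({base}){n} → ({base}){n + delta}"
        sign = "+" if self.type == "insertion" else "-"
        return f"{sign}{base if self.type == 'insertion' else self.length}"

    @property
    def key(self) -> tuple:
        alt_key = self.alt if self.type in {"SNP", "insertion"} else self.length
        return (self.position, self.type, alt_key)


def variant_frequency(support: int, coverage: int) -> float:
    """Variant frequency as reported: support/coverage to three decimals."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if support > coverage:
        raise ValueError("support cannot exceed coverage")
    return round(support / coverage, 3)


def error_p_value(support: int, coverage: int, error_rate: float) -> float:
    """Upper-tail exact binomial probability of >= support errors."""
    return float(stats.binom.sf(support - 1, coverage, error_rate))


def strand_bias_filter(
    strand_support: tuple[int, int],
    strand_coverage: tuple[int, int],
    thresholds: CallThresholds,
) -> bool:
    """True (pass) unless support is strand-skewed beyond what coverage explains.

    If the larger strand fraction of supporting reads is within the
    trigger, pass outright; otherwise require a two-sided exact binomial
    test of the support split against the site's strand coverage split
    to give p above ``strand_bias_min_p``.
    """
    fwd, rev = strand_support
    total = fwd + rev
    if total == 0:
        return False
    frac = max(fwd, rev) / total
    if frac <= thresholds.strand_bias_trigger:
        return True
    cov_f, cov_r = strand_coverage
    if cov_f + cov_r == 0:
        return False
    p_fwd = cov_f / (cov_f + cov_r)
    p_fwd = min(max(p_fwd, 1e-12), 1 - 1e-12)
    res = stats.binomtest(fwd, total, p_fwd, alternative="two-sided")
    return res.pvalue > thresholds.strand_bias_min_p


def left_align_insertion(genome: AnnotatedGenome, pos0: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion (before ``pos0``) to its leftmost equivalent placement."""
    seq = genome.sequence
    s = pos0
    ins = inserted
    while s > 0 and seq[s - 1] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        s -= 1
    return s, ins


def left_align_deletion(genome: AnnotatedGenome, pos0: int, length: int) -> int:
    return left_align_gap(genome, pos0, length)


def call_site_variants(
    pileup: Pileup,
    thresholds: CallThresholds,
    permissive: bool = False,
    exclude_role: str | None = "AT-rich",
    annotate: bool = True,
) -> list[VariantCall]:
    """Call SNPs and short indels from a pileup.

    In permissive mode every non-reference observation is emitted with
    its statistics and no gates are applied — the screen used to decide
    whether a variant exists in a library "at any frequency".
    """
    genome = pileup.genome
    excluded = genome.excluded_positions(exclude_role)
    counts = pileup.base_counts
    total = pileup.coverage
    calls: list[VariantCall] = []

    min_support = 1 if permissive else thresholds.min_support
    alt_total = counts.sum(axis=2)
    candidate_pos = np.flatnonzero(total > 0)
    for pos0 in candidate_pos:
        if pos0 in excluded:
            continue
        ref_idx = int(pileup.ref[pos0])
        cov = int(total[pos0])
        for b in range(4):
            if b == ref_idx:
                continue
            support = int(alt_total[pos0, b])
            if support < min_support:
                continue
            strand_support = (int(counts[pos0, b, 0]), int(counts[pos0, b, 1]))
            call = _make_site_call(
                pileup, genome, pos0, "SNP",
                ref=_BASES[ref_idx] if ref_idx >= 0 else "N",
                alt=_BASES[b],
                support=support,
                cov=cov,
                strand_support=strand_support,
                thresholds=thresholds,
            )
            if _passes(call, strand_support, pileup.strand_coverage(pos0), thresholds, permissive):
                calls.append(call)

    # indels, aggregated after left-alignment
    agg_ins: dict[tuple[int, str], list] = defaultdict(lambda: [0, 0, 0])  # support, fwd, rev
    for pos0, ctr in pileup.insertions.items():
        for (seq, strand), n in ctr.items():
            cpos, cseq = left_align_insertion(genome, pos0, seq)
            rec = agg_ins[(cpos, cseq)]
            rec[0] += n
            rec[1 if strand == "+" else 2] += n
    agg_del: dict[tuple[int, int], list] = defaultdict(lambda: [0, 0, 0])
    for pos0, ctr in pileup.deletions.items():
        for (ln, strand), n in ctr.items():
            cpos = left_align_deletion(genome, pos0, ln)
            rec = agg_del[(cpos, ln)]
            rec[0] += n
            rec[1 if strand == "+" else 2] += n

    for (pos0, seq), (support, fwd, rev) in agg_ins.items():
        if pos0 in excluded or support < min_support:
            continue
        cov = int(total[pos0]) if total[pos0] > 0 else support
        call = _make_site_call(
            pileup, genome, pos0, "insertion",
            ref=genome.sequence[pos0], alt=seq, support=support, cov=max(cov, support),
            strand_support=(fwd, rev), thresholds=thresholds, length=len(seq),
        )
        if _passes(call, (fwd, rev), pileup.strand_coverage(pos0), thresholds, permissive):
            calls.append(call)
    for (pos0, ln), (support, fwd, rev) in agg_del.items():
        if pos0 in excluded or support < min_support:
            continue
        cov = int(total[pos0]) + support  # deleted bases contribute no base counts
        call = _make_site_call(
            pileup, genome, pos0, "deletion",
            ref=genome.sequence[pos0], alt="", support=support, cov=cov,
            strand_support=(fwd, rev), thresholds=thresholds, length=ln,
        )
        if _passes(call, (fwd, rev), pileup.strand_coverage(pos0), thresholds, permissive):
            calls.append(call)

    if annotate:
        calls = [_annotate(c, genome) for c in calls]
    calls.sort(key=lambda c: (c.position, c.type, c.alt))
    return calls


def _make_site_call(
    pileup, genome, pos0, vtype, ref, alt, support, cov, strand_support, thresholds, length=1
) -> VariantCall:
    base = alt if vtype == "insertion" else ref
    run = homopolymer_run_length(genome, pos0, base) if vtype in {"insertion", "deletion"} else 0
    return VariantCall(
        position=pos0 + 1,
        type=vtype,
        ref=ref,
        alt=alt,
        coverage=cov,
        support=support,
        frequency=variant_frequency(support, cov),
        p_value=error_p_value(support, cov, thresholds.error_rate),
        strand_support=strand_support,
        strand_coverage=pileup.strand_coverage(pos0),
        homopolymer_run=run,
        length=length,
    )


def _passes(call, strand_support, strand_cov, thresholds, permissive) -> bool:
    if permissive:
        return True
    if call.coverage < thresholds.min_coverage:
        return False
    if call.support < thresholds.min_support:
        return False
    if call.p_value >= thresholds.max_p:
        return False
    return strand_bias_filter(strand_support, strand_cov, thresholds)


def _annotate(call: VariantCall, genome: AnnotatedGenome) -> VariantCall:
    feat = genome.feature_at(call.position)
    effect = annotate_effect(call, genome)
    return replace(call, feature=(feat.label if feat else "-"), effect=effect)


# ---------------------------------------------------------------------------
# large deletions

@dataclass
class DeletionCall:
    """A split-read-supported long deletion with repeat-aware boundaries."""

    start: int  # 1-based canonical (left-aligned) first deleted base
    length: int
    ambiguity_interval: tuple[int, int]  # 1-based range of equivalent start positions
    support: int
    coverage_range: tuple[int, int]
    frequency_range: tuple[float, float]
    p_value: float
    repeat: RepeatPair | None = None
    effect: ProteinEffect | None = None
    feature: str = "-"
    de_novo: bool = False

    @property
    def type(self) -> str:
        return "large_deletion"

    @property
    def position(self) -> int:
        return self.start

    @property
    def key(self) -> tuple:
        return (self.start, "large_deletion", self.length)

    @property
    def change(self) -> str:
        return f"-N({self.length})"


def _repeat_extent(genome: AnnotatedGenome, start0: int, length: int, max_mismatch: int = 2) -> int:
    """How far the deleted prefix near-matches the sequence after the deletion.

    This is the flanking direct-repeat extent tolerating a few internal
    mismatches — the stretch over which a junction-crossing read aligns
    ungapped against the reference almost perfectly.
    """
    seq = genome.doubled() if genome.circular else genome.sequence
    mm = 0
    i = 0
    while start0 + length + i < len(seq) and i < length:
        if seq[start0 + i] != seq[start0 + length + i]:
            mm += 1
            if mm > max_mismatch:
                break
        i += 1
    return i


def _right_shift_extent(genome: AnnotatedGenome, start0: int, length: int) -> int:
    """How far the (left-aligned) deletion start can shift right equivalently."""
    seq = genome.doubled() if genome.circular else genome.sequence
    shift = 0
    while start0 + shift + length < len(seq) and seq[start0 + shift] == seq[start0 + shift + length]:
        shift += 1
    return shift


def call_large_deletions(
    pileup: Pileup,
    genome: AnnotatedGenome,
    min_support: int = 4,
    error_rate: float = 0.002,
    repeat_search_margin: int = 60,
    annotate: bool = True,
) -> list[DeletionCall]:
    """Cluster split reads into deletion calls.

    Events are canonicalized by left-aligning the gap; clusters meeting
    ``min_support`` are reported with the flanking exact-repeat extent
    as the boundary-ambiguity interval, and frequency computed at each
    breakpoint as split support over (split support + reads spanning
    that breakpoint without the deletion), reported as a range.
    """
    clusters: Counter = Counter()
    for start0, length, _strand, _rid in pileup.split_events:
        canon = left_align_gap(genome, start0, length)
        clusters[(canon % genome.length, length)] += 1

    total = pileup.coverage
    out: list[DeletionCall] = []
    for (start0, length), support in sorted(clusters.items()):
        if support < min_support:
            continue
        shift = _right_shift_extent(genome, start0, length)
        # Non-deleted molecules spanning each breakpoint: coverage probed just
        # inside the deletion but beyond the flanking-repeat extent, where
        # junction reads can no longer masquerade as reference-spanning.
        probe = min(shift + _repeat_extent(genome, start0, length), max(length // 2 - 1, 0))
        left_in = int(total[(start0 + probe) % genome.length])
        right_in = int(total[(start0 + length - 1 - probe) % genome.length])
        freqs = []
        covs = []
        for inside in (left_in, right_in):
            denom = support + inside
            covs.append(denom)
            freqs.append(variant_frequency(support, denom))
        lo, hi = min(freqs), max(freqs)
        p = error_p_value(support, max(covs), error_rate)
        repeat = None
        m = repeat_search_margin
        try:
            wa = (max(1, start0 + 1 - m), min(genome.length, start0 + m))
            wb = (max(1, start0 + length + 1 - m), min(genome.length, start0 + length + m))
            if wa[1] < wb[0]:
                pairs = find_direct_repeats(genome, wa, wb, min_len=5, max_mismatch=1)
                repeat = pairs[0] if pairs else None
        except ValueError:
            repeat = None
        call = DeletionCall(
            start=start0 + 1,
            length=length,
            ambiguity_interval=(start0 + 1, start0 + 1 + shift),
            support=support,
            coverage_range=(min(covs), max(covs)),
            frequency_range=(lo, hi),
            p_value=p,
            repeat=repeat,
        )
        if annotate:
            feat = genome.feature_at(call.start)
            call.feature = feat.label if feat else "-"
            call.effect = annotate_effect(call, genome)
        out.append(call)
    out.sort(key=lambda c: (c.start, c.length))
    return out


def realign_and_rebuild(
    alignments: list[Alignment],
    genome: AnnotatedGenome,
    min_candidate_support: int = 4,
    error_rate: float = 0.002,
) -> tuple[Pileup, list[Alignment]]:
    """Realign reads around candidate long deletions, then rebuild the pileup.

    Reads that end a little past a breakpoint initially align ungapped
    with a mismatching tail reaching into the deleted interval; rescoring
    them against the deletion haplotype converts them to split
    alignments and removes their spurious within-deletion coverage,
    which would otherwise deflate the deletion frequency.
    """
    from .align import realign_indels

    pile = build_pileup(alignments, genome)
    candidates = call_large_deletions(
        pile, genome, min_support=min_candidate_support, error_rate=error_rate, annotate=False
    )
    if not candidates:
        return pile, alignments
    for c in candidates:
        alignments = realign_indels(alignments, genome, (c.start - 1, c.length))
    return build_pileup(alignments, genome), alignments


# ---------------------------------------------------------------------------
# progenitor comparison

def mark_de_novo(ma_calls: list, progenitor_permissive_calls: list) -> list:
    """Flag MA-line calls absent from the progenitor's permissive screen.

    A variant observed in the progenitor at any read support — even one
    read below every threshold — is not de novo.
    """
    prog_keys = {c.key for c in progenitor_permissive_calls}
    out = []
    for c in ma_calls:
        flag = c.key not in prog_keys
        if isinstance(c, VariantCall):
            out.append(replace(c, de_novo=flag))
        else:
            c.de_novo = flag
            out.append(c)
    return out
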