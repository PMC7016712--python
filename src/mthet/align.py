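"""Seed-and-extend mapping of merged reads to a small circular reference.

The mapper targets the regime of this pipeline: a ~14 kb circular
mtgenome (plus a few short linear nuclear loci), merged single-end reads
of ~250-400 bp, and at most one long deletion (up to ``maxindel`` bp)
per read.  Strategy:

* exact k-mer seeds over the doubled circular sequence vote for
  diagonals (candidate start positions);
* a vectorized Hamming comparison scores each candidate placement;
* reads that score poorly ungapped are re-aligned with a banded
  edit-distance alignment (edlib) to pick up small indels, and a
  two-diagonal split alignment is attempted to capture long deletions
  (flat gap-open cost, length-free up to ``maxindel`` — a single
  biological deletion event);
* placements tying for best score are discarded as ambiguous, and
  placements below ``minratio`` identity are unmapped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .mito_model import AnnotatedGenome, revcomp, seq_to_array

GAP_OPEN = 6  # flat split-gap penalty, in score units (match=+1, mismatch=-2 relative)
_EDLIB_PAD = 24


@dataclass
class SeedIndex:
    """Exact k-mer index over the (doubled, for circular) reference."""

    genome: AnnotatedGenome
    k: int
    positions: dict[str, list[int]] = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.genome.length

    @property
    def circular(self) -> bool:
        return self.genome.circular


def index_reference(genome: AnnotatedGenome, k: int = 8) -> SeedIndex:
    """Index every reference k-mer start position (0-based, circular-unwrapped)."""
    if not 4 <= k <= 15:
        raise ValueError("k must be in [4, 15]")
    if genome.length < k:
        raise ValueError(f"genome of length {genome.length} shorter than k={k}")
    seq = genome.doubled() if genome.circular else genome.sequence
    n_start = genome.length if genome.circular else genome.length - k + 1
    positions: dict[str, list[int]] = {}
    for i in range(n_start):
        positions.setdefault(seq[i : i + k], []).append(i)
    return SeedIndex(genome=genome, k=k, positions=positions)


@dataclass
class Alignment:
    """A mapped read: ordered ops on the reference, optional long gap.

    ``ops`` entries are (op, ref_start0, read_start, length) with op in
    {M, I, D}; M spans include mismatches.  ``large_gap`` is
    (ref_start0, length) for a split alignment's deletion.  ``read_seq``
    is oriented to the reference strand.
    """

    read_id: str
    ref_name: str
    strand: str
    start0: int
    ops: list[tuple[str, int, int, int]]
    read_seq: str
    score: int
    mismatches: int
    identity: float
    large_gap: tuple[int, int] | None = None

    @property
    def start(self) -> int:  # 1-based
        return self.start0 + 1

    @property
    def ref_end0(self) -> int:
        last = self.ops[-1]
        return last[1] + (last[3] if last[0] != "I" else 0)

    def segments(self) -> list[tuple[int, int]]:
        """Reference intervals (0-based half-open) covered on either side of the gap."""
        if self.large_gap is None:
            return [(self.start0, self.ref_end0)]
        gs, gl = self.large_gap
        return [(self.start0, gs), (gs + gl, self.ref_end0)]


@dataclass
class MapResult:
    status: str  # mapped | unmapped | ambiguous
    alignment: Alignment | None = None


def _hamming(read_arr: np.ndarray, ref_arr: np.ndarray, d: int) -> int:
    n = len(read_arr)
    window = ref_arr[d : d + n]
    if len(window) < n:
        return n  # does not fit
    return int((read_arr != window).sum())


def _parse_ext_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _edlib_ops(read: str, ref_seq: str, w0: int, w1: int) -> tuple[list, int, int, int] | None:
    """Banded gapped alignment of the whole read inside ref window [w0, w1).

    Returns (ops, ref_start0, edit_distance, n_matches) or None.
    """
    window = ref_seq[w0:w1]
    res = edlib.align(read, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_start = res["locations"][0][0]
    ref_pos = w0 + loc_start
    read_pos = 0
    ops: list[tuple[str, int, int, int]] = []
    matches = 0
    for length, op in _parse_ext_cigar(res["cigar"]):
        if op in "=X":
            if ops and ops[-1][0] == "M" and ops[-1][1] + ops[-1][3] == ref_pos:
                prev = ops.pop()
                ops.append(("M", prev[1], prev[2], prev[3] + length))
            else:
                ops.append(("M", ref_pos, read_pos, length))
            if op == "=":
                matches += length
            ref_pos += length
            read_pos += length
        elif op == "I":  # extra bases in read
            ops.append(("I", ref_pos, read_pos, length))
            read_pos += length
        elif op == "D":  # bases missing from read
            ops.append(("D", ref_pos, read_pos, length))
            ref_pos += length
    return ops, w0 + loc_start, res["editDistance"], matches


@dataclass
class _Candidate:
    score: int
    strand: str
    d: int
    kind: str  # exact | gapped | split
    ops: list | None = None
    mismatches: int = 0
    matches: int = 0
    aln_len: int = 0
    gap: tuple[int, int] | None = None
    split_mism: tuple[int, int] = (0, 0)
    split_j: int = 0


def _diagonal_votes(seq: str, index: SeedIndex, n_seeds: int = 6) -> dict[int, int]:
    n = len(seq)
    k = index.k
    if n < k:
        return {}
    offsets = sorted({int(x) for x in np.linspace(0, n - k, n_seeds)})
    votes: dict[int, int] = {}
    L = index.L
    for off in offsets:
        for p in index.positions.get(seq[off : off + k], ()):
            d = (p - off) % L if index.circular else p - off
            votes[d] = votes.get(d, 0) + 1
    return votes


def map_read(
    read_id: str,
    seq: str,
    index: SeedIndex,
    minratio: float = 0.8,
    maxindel: int = 2000,
) -> MapResult:
    """Place one read on the reference; see module docstring for policy."""
    genome = index.genome
    L = index.L
    if len(seq) < index.k:
        return MapResult("unmapped")
    ref_seq = genome.doubled() if genome.circular else genome.sequence
    ref_arr = seq_to_array(ref_seq)
    n = len(seq)
    candidates: list[_Candidate] = []

    for strand, s in (("+", seq), ("-", revcomp(seq))):
        votes = _diagonal_votes(s, index)
        if not votes:
            continue
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])[:6]
        s_arr = seq_to_array(s)
        evaluated: dict[int, int] = {}
        for d, _v in ranked:
            if not index.circular and (d < 0 or d + n > L):
                continue
            mism = _hamming(s_arr, ref_arr, d)
            evaluated[d] = mism
            candidates.append(
                _Candidate(
                    score=n - 3 * mism,
                    strand=strand,
                    d=d,
                    kind="exact",
                    mismatches=mism,
                    matches=n - mism,
                    aln_len=n,
                )
            )
        best_mism = min(evaluated.values()) if evaluated else n
        if best_mism > max(2, int(0.02 * n)):
            # small-indel rescue on the best diagonals
            for d in sorted(evaluated, key=evaluated.get)[:2]:
                w0 = max(0, d - _EDLIB_PAD)
                w1 = min(len(ref_seq), d + n + _EDLIB_PAD)
                got = _edlib_ops(s, ref_seq, w0, w1)
                if got is None:
                    continue
                ops, start0, dist, matches = got
                candidates.append(
                    _Candidate(
                        score=n - 3 * dist,
                        strand=strand,
                        d=start0,
                        kind="gapped",
                        ops=ops,
                        mismatches=dist,
                        matches=matches,
                        aln_len=n,
                    )
                )
            # split (long-deletion) rescue: prefix vs suffix diagonals
            head = {}
            tail = {}
            k = index.k
            third = max(n // 3, k)
            for off in (0, third // 2, third - k):
                if off + k > n:
                    continue
                for p in index.positions.get(s[off : off + k], ()):
                    d = (p - off) % L if index.circular else p - off
                    head[d] = head.get(d, 0) + 1
            for off in (n - k, n - third // 2 - k, n - third):
                if off < 0:
                    continue
                for p in index.positions.get(s[off : off + k], ()):
                    d = (p - off) % L if index.circular else p - off
                    tail[d] = tail.get(d, 0) + 1
            if head and tail:
                d1 = max(head, key=head.get)
                d2 = max(tail, key=tail.get)
                gap = (d2 - d1) % L if index.circular else d2 - d1
                if d1 != d2 and 0 < gap <= maxindel:
                    m1 = (s_arr != ref_arr[d1 : d1 + n]) if d1 + n <= len(ref_arr) else None
                    m2 = (s_arr != ref_arr[d1 + gap : d1 + gap + n]) if d1 + gap + n <= len(ref_arr) else None
                    if m1 is not None and m2 is not None:
                        c1 = np.concatenate(([0], np.cumsum(m1)))
                        c2 = np.concatenate(([0], np.cumsum(m2)))
                        total2 = int(c2[-1])
                        costs = c1[:-1] + (total2 - c2[:-1])
                        j = int(np.argmin(costs))
                        mism = int(costs[j])
                        if j > 0 and j < n:
                            candidates.append(
                                _Candidate(
                                    score=n - 3 * mism - GAP_OPEN,
                                    strand=strand,
                                    d=d1,
                                    kind="split",
                                    mismatches=mism,
                                    matches=n - mism,
                                    aln_len=n,
                                    gap=((d1 + j) % L, gap),
                                    split_j=j,
                                )
                            )

    if not candidates:
        return MapResult("unmapped")
    candidates.sort(key=lambda c: -c.score)
    best = candidates[0]
    # ambiguity: a distinct placement with an equal score
    for c in candidates[1:]:
        if c.score < best.score:
            break
        if (c.strand, c.d % L if index.circular else c.d, c.gap) != (
            best.strand,
            best.d % L if index.circular else best.d,
            best.gap,
        ):
            return MapResult("ambiguous")
    identity = best.matches / best.aln_len if best.aln_len else 0.0
    if identity < minratio:
        return MapResult("unmapped")

    s = seq if best.strand == "+" else revcomp(seq)
    if best.kind == "exact":
        ops = [("M", best.d, 0, n)]
        start0 = best.d
        gap = None
    elif best.kind == "gapped":
        ops = best.ops
        start0 = best.d
        gap = None
    else:  # split
        j = best.split_j
        gs, gl = best.gap
        ops = [("M", best.d, 0, j), ("M", best.d + j + gl if not index.circular else best.d + j + gl, j, n - j)]
        start0 = best.d
        gap = best.gap
    aln = Alignment(
        read_id=read_id,
        ref_name=genome.name,
        strand=best.strand,
        start0=start0 % L if index.circular else start0,
        ops=[(op, (r % L if index.circular else r), q, ln) for op, r, q, ln in ops],
        read_seq=s,
        score=best.score,
        mismatches=best.mismatches,
        identity=identity,
        large_gap=((gap[0] % L, gap[1]) if gap else None),
    )
    return MapResult("mapped", aln)


def map_reads(reads, index: SeedIndex, minratio: float = 0.8, maxindel: int = 2000):
    """Map an iterable of Read objects; returns (alignments, stats dict)."""
    alignments = []
    stats = {"mapped": 0, "unmapped": 0, "ambiguous": 0}
    for r in reads:
        res = map_read(r.name, r.sequence, index, minratio=minratio, maxindel=maxindel)
        stats[res.status] += 1
        if res.status == "mapped":
            alignments.append(res.alignment)
    return alignments, stats


# ---------------------------------------------------------------------------
# indel realignment around a candidate long deletion

def left_align_gap(genome: AnnotatedGenome, start0: int, length: int) -> int:
    """Left-align a deletion's start within its flanking repeat context."""
    seq = genome.doubled() if genome.circular else genome.sequence
    s = start0
    while s > 0 and seq[s - 1] == seq[s + length - 1]:
        s -= 1
    return s


def realign_indels(
    alignments: list[Alignment],
    genome: AnnotatedGenome,
    deletion: tuple[int, int],
    gap_open: int = 2,
) -> list[Alignment]:
    """Rescore reads near a candidate deletion against the deleted haplotype.

    Reads that score strictly better with the deletion become split
    alignments with the canonical (left-aligned) breakpoint; all others
    are returned unchanged.  The gap cost here (``gap_open``) is lighter
    than the de-novo split search penalty: the deletion is a supplied
    hypothesis, so a read overhanging a flanking repeat copy converts on
    the strength of a single diagnostic mismatch.
    """
    dstart, dlen = deletion
    dstart = left_align_gap(genome, dstart, dlen)
    L = genome.length
    ref = genome.doubled() if genome.circular else genome.sequence
    ref_arr = seq_to_array(ref)
    out: list[Alignment] = []
    for aln in alignments:
        if aln.large_gap is not None:
            out.append(aln)
            continue
        n = len(aln.read_seq)
        end0 = aln.start0 + n
        covers = aln.start0 < dstart < end0 or aln.start0 < dstart + dlen < end0
        if not covers:
            out.append(aln)
            continue
        s_arr = seq_to_array(aln.read_seq)
        # the read may be anchored on the left flank (prefix at its current
        # start) or on the right flank (prefix at current start - deletion)
        best = None
        for d1 in (aln.start0, aln.start0 - dlen):
            if d1 < 0 or d1 + dlen + n > len(ref_arr):
                continue
            m1 = s_arr != ref_arr[d1 : d1 + n]
            m2 = s_arr != ref_arr[d1 + dlen : d1 + dlen + n]
            c1 = np.concatenate(([0], np.cumsum(m1)))
            c2 = np.concatenate(([0], np.cumsum(m2)))
            total2 = int(c2[-1])
            costs = c1[:-1] + (total2 - c2[:-1])
            j = int(np.argmin(costs))
            mism = int(costs[j])
            if best is None or mism < best[1]:
                best = (d1, mism, j)
        if best is None:
            out.append(aln)
            continue
        d1, mism, j = best
        split_score = n - 3 * mism - gap_open
        if split_score <= aln.score or j == 0 or j == n:
            out.append(aln)
            continue
        gap_start = left_align_gap(genome, (d1 + j) % L, dlen)
        j_canon = (gap_start - d1) % L if genome.circular else gap_start - d1
        if not 0 < j_canon < n:
            j_canon = j
            gap_start = (d1 + j) % L
        out.append(
            Alignment(
                read_id=aln.read_id,
                ref_name=aln.ref_name,
                strand=aln.strand,
                start0=d1 % L if genome.circular else d1,
                ops=[("M", d1 % L if genome.circular else d1, 0, j_canon),
                     ("M", (gap_start + dlen) % L, j_canon, n - j_canon)],
                read_seq=aln.read_seq,
                score=split_score,
                mismatches=mism,
                identity=(n - mism) / n,
                large_gap=(gap_start, dlen),
            )
        )
    return out


# ---------------------------------------------------------------------------
# iterative reference extension into low-coverage flanks

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _overhang_counts(
    seq: str, reads, k: int, max_mismatch_rate: float, min_anchor: int
) -> tuple[np.ndarray, int, bool]:
    """Ungapped-map reads onto ``seq`` allowing flank overhangs.

    Returns (base counts over a padded coordinate frame, pad, any_mapped);
    row ``pad + i`` corresponds to sequence position ``i``.
    """
    L = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    pad = max((len(r.sequence) for r in reads), default=0)
    counts = np.zeros((L + 2 * pad, 4), dtype=np.int32)
    ref_arr = seq_to_array(seq)
    any_mapped = False
    for r in reads:
        for s in (r.sequence, revcomp(r.sequence)):
            n = len(s)
            if n < k:
                continue
            votes: dict[int, int] = {}
            for off in sorted({0, max(n // 2 - k // 2, 0), n - k}):
                for p in index.get(s[off : off + k], ()):
                    d = p - off
                    votes[d] = votes.get(d, 0) + 1
            if not votes:
                continue
            d = max(votes, key=votes.get)
            o0 = max(0, -d)
            o1 = min(n, L - d)
            if o1 - o0 < min_anchor:
                continue
            s_arr = seq_to_array(s)
            mism = int((s_arr[o0:o1] != ref_arr[d + o0 : d + o1]).sum())
            if mism / (o1 - o0) > max_mismatch_rate:
                continue
            any_mapped = True
            rows = pad + d + np.arange(n)
            cols = np.array([_BASE_IDX.get(c, -1) for c in s])
            keep = (rows >= 0) & (rows < L + 2 * pad) & (cols >= 0)
            np.add.at(counts, (rows[keep], cols[keep]), 1)
            break  # a read maps on one strand only
    return counts, pad, any_mapped


def extend_reference(
    reads,
    genome: AnnotatedGenome,
    iterations: int = 10,
    low_cov_sd: float = 2.0,
    k: int = 13,
    max_mismatch_rate: float = 0.05,
    min_anchor: int = 25,
) -> AnnotatedGenome:
    """Iteratively extend a linear reference using read overhangs.

    Each iteration maps reads ungapped (<=``max_mismatch_rate`` in the
    overlapping part, anchor of at least ``min_anchor`` bases), takes a
    majority-rule consensus including bases overhanging the flanks, and
    grows the reference.  After the last iteration, extended positions
    whose coverage falls below mean - ``low_cov_sd``*SD (mean/SD over
    the whole final sequence) are trimmed back.  Circular genomes are
    returned unchanged (nothing to extend).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if genome.circular:
        return genome
    reads = list(reads)
    seq = genome.sequence
    orig_len = genome.length
    left_ext_total = 0

    for _ in range(iterations):
        if len(seq) < k:
            break
        counts, pad, any_mapped = _overhang_counts(seq, reads, k, max_mismatch_rate, min_anchor)
        if not any_mapped:
            import warnings

            warnings.warn("no reads mapped during reference extension; returning input genome")
            return genome
        L = len(seq)
        covered = counts.sum(axis=1)
        consensus = np.array(list("ACGT"))[counts.argmax(axis=1)]
        left = pad
        while left > 0 and covered[left - 1] >= 2:
            left -= 1
        right = pad + L
        while right < L + 2 * pad and covered[right] >= 2:
            right += 1
        new_left = "".join(consensus[left:pad])
        new_right = "".join(consensus[pad + L : right])
        if not new_left and not new_right:
            break
        left_ext_total += len(new_left)
        seq = new_left + seq + new_right

    # final coverage-based trim of the extended flanks only
    if len(seq) > orig_len:
        counts, pad, _ = _overhang_counts(seq, reads, k, max_mismatch_rate, min_anchor)
        cov_vec = counts.sum(axis=1)[pad : pad + len(seq)]
        mean, sd = float(cov_vec.mean()), float(cov_vec.std())
        cutoff = mean - low_cov_sd * sd
        right_ext = len(seq) - orig_len - left_ext_total
        lo, hi = 0, len(seq)
        while lo < left_ext_total and cov_vec[lo] < cutoff:
            lo += 1
        while hi > len(seq) - right_ext and cov_vec[hi - 1] < cutoff:
            hi -= 1
        seq = seq[lo:hi]
        left_ext_total -= lo

    shifted = [
        type(f)(
            label=f.label,
            role=f.role,
            start=f.start + left_ext_total,
            end=f.end + left_ext_total,
            strand=f.strand,
            reading_frame_start=(f.reading_frame_start + left_ext_total if f.reading_frame_start else None),
            wraps=f.wraps,
        )
        for f in genome.features
    ]
    return AnnotatedGenome(name=genome.name, sequence=seq, circular=False, features=shifted)
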