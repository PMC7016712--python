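"""Read preprocessing: adapter trimming, pair merging, exact deduplication.

The pipeline contract is trim -> merge -> dedupe.  Pairs that cannot be
merged are discarded by default, and duplicate removal is by exact
sequence equality only (no containment absorption), so that each
surviving read can be treated as an independent source molecule.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .mito_model import revcomp, seq_to_array

import numpy as np


@dataclass(frozen=True)
class Read:
    name: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.name}: sequence/quality length mismatch")


@dataclass
class MergeParams:
    min_overlap: int = 20
    max_mismatch_rate: float = 0.05
    adapter: str | None = None

    def __post_init__(self) -> None:
        if self.min_overlap < 10:
            raise ValueError("min_overlap must be >= 10")
        if not 0 <= self.max_mismatch_rate <= 0.2:
            raise ValueError("max_mismatch_rate must be in [0, 0.2]")


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(name=rec.id, sequence=str(rec.seq).upper(), qualities=quals)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.qualities}\n")


def trim_adapter(read: Read, adapter: str, min_overlap: int = 5) -> Read:
    """Remove the longest read suffix matching a prefix of the adapter.

    Up to one mismatch per 10 bases of overlap is tolerated.  Overlaps
    shorter than ``min_overlap`` are ignored (a single coincidental
    base match is not adapter evidence).  Never lengthens a read.
    """
    if len(adapter) < 5:
        raise ValueError("adapter must be at least 5 bases")
    seq = read.sequence
    best = 0
    max_ov = min(len(seq), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        suffix = seq[-ov:]
        prefix = adapter[:ov]
        mism = sum(1 for a, b in zip(suffix, prefix) if a != b)
        if mism <= ov // 10:
            best = ov
            break
    if best == 0:
        return read
    return Read(read.name, seq[:-best], read.qualities[:-best])


def merge_pairs(r1: Read, r2: Read, params: MergeParams) -> Read | None:
    """Merge an overlapping pair into the original fragment, or None.

    The mate is reverse-complemented, the best suffix(R1)/prefix(rc R2)
    overlap of at least ``min_overlap`` bases with mismatch rate at most
    ``max_mismatch_rate`` is taken, and overlap disagreements resolve to
    the higher-quality base.  ``None`` means the pair did not merge and
    is discarded by the pipeline.
    """
    s1 = r1.sequence
    s2 = revcomp(r2.sequence)
    q1 = r1.qualities
    q2 = r2.qualities[::-1]
    n1, n2 = len(s1), len(s2)
    if min(n1, n2) < params.min_overlap:
        return None

    a1 = seq_to_array(s1)
    a2 = seq_to_array(s2)

    def score_overlap(ov: int) -> tuple[int, int]:
        x = a1[n1 - ov :]
        y = a2[:ov]
        mism = int((x != y).sum())
        return ov - 2 * mism, mism

    # seed candidate overlaps with an exact 12-mer of the mate prefix
    candidates: set[int] = set()
    seed = s2[:12]
    start = 0
    while True:
        idx = s1.find(seed, start)
        if idx == -1:
            break
        candidates.add(n1 - idx)
        start = idx + 1
    if not candidates:
        candidates = set(range(params.min_overlap, min(n1, n2) + 1))
    best_ov, best_score, best_mism = 0, -(10**9), 0
    for ov in candidates:
        if ov < params.min_overlap or ov > min(n1, n2):
            continue
        score, mism = score_overlap(ov)
        if mism / ov > params.max_mismatch_rate:
            continue
        if score > best_score:
            best_ov, best_score, best_mism = ov, score, mism
    if best_ov == 0:
        return None

    ov = best_ov
    left = s1[: n1 - ov]
    right = s2[ov:]
    mid = []
    midq = []
    for i in range(ov):
        b1, b2 = s1[n1 - ov + i], s2[i]
        p1, p2 = q1[n1 - ov + i], q2[i]
        if b1 == b2 or p1 >= p2:
            mid.append(b1)
            midq.append(max(p1, p2) if b1 == b2 else p1)
        else:
            mid.append(b2)
            midq.append(p2)
    merged_seq = left + "".join(mid) + right
    merged_q = q1[: n1 - ov] + "".join(midq) + q2[ov:]
    return Read(r1.name, merged_seq, merged_q)


def dedupe_exact(reads: Iterable[Read]) -> list[Read]:
    """Keep the first occurrence of each exact sequence string."""
    seen: set[str] = set()
    out: list[Read] = []
    for r in reads:
        if r.sequence in seen:
            continue
        seen.add(r.sequence)
        out.append(r)
    return out


@dataclass
class PreprocessStats:
    n_pairs: int = 0
    n_merged: int = 0
    n_unmerged: int = 0
    n_after_dedupe: int = 0


def preprocess_pairs(
    pairs: Iterable[tuple[Read, Read]],
    params: MergeParams,
    keep_unmerged: bool = False,
) -> tuple[list[Read], PreprocessStats]:
    """trim -> merge -> dedupe over an iterable of read pairs."""
    stats = PreprocessStats()
    merged: list[Read] = []
    for r1, r2 in pairs:
        stats.n_pairs += 1
        if params.adapter:
            r1 = trim_adapter(r1, params.adapter)
            r2 = trim_adapter(r2, params.adapter)
        m = merge_pairs(r1, r2, params)
        if m is None:
            stats.n_unmerged += 1
            if keep_unmerged:
                merged.append(r1)
            continue
        stats.n_merged += 1
        merged.append(m)
    out = dedupe_exact(merged)
    stats.n_after_dedupe = len(out)
    return out, stats


def preprocess_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    params: MergeParams,
    keep_unmerged: bool = False,
) -> tuple[list[Read], PreprocessStats]:
    pairs = zip(read_fastq(r1_path), read_fastq(r2_path))
    return preprocess_pairs(pairs, params, keep_unmerged=keep_unmerged)
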