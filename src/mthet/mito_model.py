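"""Domain model for small annotated circular mitochondrial genomes.

The objects here carry everything the downstream stages need to reason
about a nematode mtgenome: the circular sequence itself, typed features
(genes, tRNAs, the low-complexity AT-rich control region, pseudogenes),
a census of A/T mononucleotide runs (replication-slippage hotspots),
direct-repeat discovery (the substrate of repeat-mediated large
deletions), and protein-level annotation of variants under the
invertebrate mitochondrial genetic code.

All user-visible coordinates are 1-based inclusive.  Internally 0-based
half-open indices are used freely but never serialized.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_ROLES = frozenset({"gene", "tRNA", "rRNA", "pseudogene", "AT-rich", "intergenic"})

#: NCBI translation table 5 (invertebrate mitochondrial) — appropriate for nematode mtDNA.
MITO_TABLE = 5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """DNA string as a uint8 byte array (for vectorized comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class Feature:
    """One annotated interval on a genome (1-based inclusive coordinates).

    ``wraps`` marks an origin-spanning feature on a circular genome, in
    which case ``end`` < ``start`` and the feature runs start..L,1..end.
    ``reading_frame_start`` applies to genes only and defaults to the
    strand-appropriate gene boundary.
    """

    label: str
    role: str
    start: int
    end: int
    strand: str = "+"
    reading_frame_start: int | None = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.role not in FEATURE_ROLES:
            raise ValueError(f"feature {self.label!r}: unknown role {self.role!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"feature {self.label!r}: coordinates are 1-based, got {self.start}..{self.end}")
        if not self.wraps and self.end < self.start:
            raise ValueError(
                f"feature {self.label!r}: end {self.end} < start {self.start} without wrap flag"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.label!r}: strand must be + or -")
        if self.reading_frame_start is not None and self.role != "gene":
            raise ValueError(f"feature {self.label!r}: reading_frame_start applies to genes only")

    def contains(self, pos: int, genome_length: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def positions0(self, genome_length: int) -> np.ndarray:
        """0-based positions covered by the feature, in genome order."""
        if self.wraps:
            return np.concatenate(
                [np.arange(self.start - 1, genome_length), np.arange(0, self.end)]
            )
        return np.arange(self.start - 1, self.end)


@dataclass
class AnnotatedGenome:
    """A (usually circular) reference sequence plus typed features."""

    name: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.name!r}: non-DNA characters {sorted(bad)}")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise ValueError(
                    f"feature {f.label!r} ({f.start}..{f.end}) outside genome "
                    f"{self.name!r} of length {self.length}"
                )
            if f.wraps and not self.circular:
                raise ValueError(f"feature {f.label!r} wraps origin of a linear genome")
        at_rich = [f for f in self.features if f.role == "AT-rich"]
        if len(at_rich) > 1:
            raise ValueError(f"genome {self.name!r}: more than one AT-rich feature")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def doubled(self) -> str:
        """Sequence concatenated with itself (circular unwrapping aid)."""
        return self.sequence + self.sequence

    def fetch(self, start: int, end: int) -> str:
        """Substring in 1-based inclusive coordinates; wraps when end < start."""
        if start < 1 or end < 1 or start > self.length or end > self.length:
            raise ValueError(f"interval {start}..{end} outside genome of length {self.length}")
        if end >= start:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError("wrapping fetch on a linear genome")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def features_of_role(self, role: str) -> list[Feature]:
        return [f for f in self.features if f.role == role]

    def feature_at(self, pos: int) -> Feature | None:
        """Highest-priority feature containing ``pos`` (gene first)."""
        priority = {"gene": 0, "pseudogene": 1, "tRNA": 2, "rRNA": 3, "AT-rich": 4, "intergenic": 5}
        hits = [f for f in self.features if f.contains(pos, self.length)]
        if not hits:
            return None
        return min(hits, key=lambda f: priority[f.role])

    def excluded_positions(self, role: str | None) -> frozenset[int]:
        """0-based positions covered by features of ``role`` (empty if None)."""
        if role is None:
            return frozenset()
        pos: set[int] = set()
        for f in self.features_of_role(role):
            pos.update(int(p) for p in f.positions0(self.length))
        return frozenset(pos)


# ---------------------------------------------------------------------------
# loading

def load_genome(fasta_path: str | Path, features_path: str | Path | None = None) -> AnnotatedGenome:
    """Load a single-record FASTA plus an optional tab-separated feature table.

    The feature table is the canonical annotation format: columns
    ``label  role  start  end  strand`` with optional ``reading_frame_start``
    and ``wraps`` columns.  Raises on multi-record FASTA or out-of-bounds
    features (naming the offending feature).
    """
    record = SeqIO.read(str(fasta_path), "fasta")  # raises if not exactly one record
    features: list[Feature] = []
    if features_path is not None:
        with open(features_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                rf = row.get("reading_frame_start") or None
                features.append(
                    Feature(
                        label=row["label"],
                        role=row["role"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=row.get("strand") or "+",
                        reading_frame_start=int(rf) if rf else None,
                        wraps=str(row.get("wraps", "")).lower() in {"1", "true", "yes"},
                    )
                )
    return AnnotatedGenome(name=record.id, sequence=str(record.seq), features=features)


def write_features(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["label", "role", "start", "end", "strand", "reading_frame_start", "wraps"])
        for f in features:
            w.writerow(
                [f.label, f.role, f.start, f.end, f.strand,
                 f.reading_frame_start if f.reading_frame_start is not None else "",
                 "true" if f.wraps else ""]
            )


# ---------------------------------------------------------------------------
# homopolymer census

@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int  # 1-based inclusive; for a wrapped run start > end
    end: int
    length: int
    wraps: bool = False


@dataclass
class HomopolymerCensus:
    """Maximal A/T mononucleotide runs of at least ``min_run`` bases.

    ``n_sites`` counts the bases of qualifying runs that fall outside the
    excluded feature (bases inside it never count, even for runs that
    straddle the boundary).
    """

    runs: list[HomopolymerRun]
    min_run: int
    excluded_role: str | None
    n_sites: int


def _maximal_runs(seq: str, circular: bool) -> list[tuple[str, int, int]]:
    """All maximal single-base runs as (base, start0, length); wrap-merged."""
    arr = seq_to_array(seq)
    n = len(arr)
    if n == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    runs = [(seq[s], int(s), int(e - s + 1)) for s, e in zip(starts, ends)]
    if circular and len(runs) > 1 and seq[0] == seq[-1]:
        b, s, l = runs[-1]
        _, _, l0 = runs[0]
        merged = (b, s, min(l + l0, n))
        runs = [merged] + runs[1:-1]
    return runs


def census_homopolymers(
    genome: AnnotatedGenome, min_run: int = 8, exclude: str | None = "AT-rich"
) -> HomopolymerCensus:
    """Census of A/T homopolymer runs >= min_run outside the excluded feature."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if not genome.sequence:
        raise ValueError("empty sequence")
    L = genome.length
    excluded = genome.excluded_positions(exclude)
    runs: list[HomopolymerRun] = []
    n_sites = 0
    for base, s0, length in _maximal_runs(genome.sequence, genome.circular):
        if base not in "AT" or length < min_run:
            continue
        positions = [(s0 + i) % L for i in range(length)]
        wraps = s0 + length > L
        runs.append(
            HomopolymerRun(
                base=base,
                start=s0 + 1,
                end=positions[-1] + 1,
                length=length,
                wraps=wraps,
            )
        )
        n_sites += sum(1 for p in positions if p not in excluded)
    runs.sort(key=lambda r: r.start)
    return HomopolymerCensus(runs=runs, min_run=min_run, excluded_role=exclude, n_sites=n_sites)


# ---------------------------------------------------------------------------
# direct repeats

@dataclass(frozen=True)
class RepeatPair:
    """Two near-identical genome intervals of equal length.

    ``mismatch_positions`` are 0-based offsets into the repeat;
    ``exact_subrepeats`` is the decomposition into exact pieces at the
    mismatches, as (offset, length) pairs.
    """

    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    length: int
    mismatch_positions: tuple[int, ...]
    exact_subrepeats: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        la = self.left_interval[1] - self.left_interval[0] + 1
        lb = self.right_interval[1] - self.right_interval[0] + 1
        if la != lb or la != self.length:
            raise ValueError("repeat intervals must have identical length")


def _subrepeat_decomposition(length: int, mismatches: Sequence[int]) -> tuple[tuple[int, int], ...]:
    pieces = []
    prev = 0
    for m in mismatches:
        if m > prev:
            pieces.append((prev, m - prev))
        prev = m + 1
    if length > prev:
        pieces.append((prev, length - prev))
    return tuple(pieces)


def find_direct_repeats(
    genome: AnnotatedGenome,
    window_a: tuple[int, int],
    window_b: tuple[int, int],
    min_len: int = 5,
    max_mismatch: int = 1,
) -> list[RepeatPair]:
    """All maximal direct-repeat pairs between two disjoint windows.

    A pair is maximal when it cannot be extended in either direction
    without exceeding ``max_mismatch`` internal mismatches or leaving a
    window; ends always fall on matching bases.  Sorted by length
    descending.
    """
    if min_len < 5:
        raise ValueError("min_len must be >= 5")
    (a0, a1), (b0, b1) = window_a, window_b
    if not (a1 < b0 or b1 < a0):
        raise ValueError("windows must be disjoint")
    A = seq_to_array(genome.fetch(a0, a1))
    B = seq_to_array(genome.fetch(b0, b1))
    la, lb = len(A), len(B)
    found: dict[tuple, RepeatPair] = {}
    for shift in range(-(lb - min_len), la - min_len + 1):
        i0 = max(0, shift)
        i1 = min(la, lb + shift)
        if i1 - i0 < min_len:
            continue
        eq = A[i0:i1] == B[i0 - shift : i1 - shift]
        n = len(eq)
        mism = np.flatnonzero(~eq).tolist()
        bounds = [-1] + mism + [n]
        for j0 in range(len(bounds) - max_mismatch - 1):
            left = bounds[j0] + 1
            right = bounds[j0 + max_mismatch + 1] - 1
            # trim to matching ends (relevant only at window edges)
            while left <= right and not eq[left]:
                left += 1
            while right >= left and not eq[right]:
                right -= 1
            if right - left + 1 < min_len:
                continue
            inner = tuple(m - left for m in mism if left < m < right)
            key = (i0 + left, i0 - shift + left, right - left + 1)
            if key in found:
                continue
            apos = a0 + i0 + left  # 1-based genome coords
            bpos = b0 + (i0 - shift) + left
            length = right - left + 1
            found[key] = RepeatPair(
                left_interval=(apos, apos + length - 1),
                right_interval=(bpos, bpos + length - 1),
                length=length,
                mismatch_positions=inner,
                exact_subrepeats=_subrepeat_decomposition(length, inner),
            )
    out = list(found.values())
    # drop pairs wholly contained in a longer reported pair on the same diagonal
    out.sort(key=lambda r: (-r.length, r.left_interval))
    return out


# ---------------------------------------------------------------------------
# protein effect annotation

@dataclass(frozen=True)
class ProteinEffect:
    """Predicted consequence of a variant on the encoded protein."""

    kinds: tuple[str, ...]
    aa_from: str | None = None
    aa_to: str | None = None
    feature_role: str | None = None

    def __str__(self) -> str:
        names = {
            "none": "None",
            "silent": "None",
            "substitution": f"{self.aa_from} → {self.aa_to} Sub",
            "frameshift": "Frame Shift",
            "truncation": "Truncation",
            "alternative_start": "Alternative Start Codon",
            "in_frame_indel": "In-Frame Indel",
            "non-coding": "-",
        }
        return ", ".join(names[k] for k in self.kinds)


def _translate(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate(table=MITO_TABLE))


def _gene_coding(genome: AnnotatedGenome, gene: Feature) -> tuple[str, int]:
    """Coding sequence of a gene and the genomic position of its first base."""
    if gene.strand == "+":
        rf = gene.reading_frame_start or gene.start
        if gene.wraps:
            coding = genome.fetch(rf, gene.end)
        else:
            coding = genome.fetch(rf, gene.end)
        return coding, rf
    rf = gene.reading_frame_start or gene.end
    coding = revcomp(genome.fetch(gene.start, rf))
    return coding, rf


def _coding_index(genome: AnnotatedGenome, gene: Feature, pos: int) -> int:
    """0-based offset of genomic position ``pos`` within the gene's coding sequence."""
    if gene.strand == "+":
        rf = gene.reading_frame_start or gene.start
        if gene.wraps and pos < rf:
            return genome.length - rf + pos
        return pos - rf
    rf = gene.reading_frame_start or gene.end
    return rf - pos


def annotate_effect(call, genome: AnnotatedGenome) -> ProteinEffect:
    """Predict the protein effect of a variant call.

    ``call`` is any object with attributes ``position`` (1-based),
    ``type`` (one of SNP/insertion/deletion/large_deletion), ``ref``,
    ``alt`` and for deletions a ``length``.  Genes are translated with
    the invertebrate mitochondrial code; indels of length not divisible
    by three inside a gene body are frameshifts, variants beyond the
    first stop codon have no effect, and a large deletion that removes a
    gene's start (but not its whole body) forces an alternative start
    codon plus truncation.
    """
    pos = int(call.position)
    if pos < 1 or pos > genome.length:
        raise ValueError(f"call position {pos} outside genome of length {genome.length}")
    vtype = call.type

    if vtype == "large_deletion":
        length = int(call.length)
        deleted = {((pos - 1 + i) % genome.length) + 1 for i in range(length)}
        kinds: list[str] = []
        for gene in genome.features_of_role("gene"):
            five_prime = gene.start if gene.strand == "+" else gene.end
            three_prime = gene.end if gene.strand == "+" else gene.start
            if five_prime in deleted and three_prime not in deleted:
                kinds = ["alternative_start", "truncation"]
                break
        if kinds:
            return ProteinEffect(kinds=tuple(kinds))
        return ProteinEffect(kinds=("non-coding",), feature_role="intergenic")

    feat = genome.feature_at(pos)
    if feat is None:
        return ProteinEffect(kinds=("non-coding",), feature_role="intergenic")
    if feat.role != "gene":
        return ProteinEffect(kinds=("non-coding",), feature_role=feat.role)

    coding, _ = _gene_coding(genome, feat)
    idx = _coding_index(genome, feat, pos)
    if idx < 0 or idx >= len(coding):
        return ProteinEffect(kinds=("non-coding",), feature_role="intergenic")
    protein = _translate(coding)
    stop_at = protein.find("*")
    codon_i = idx // 3
    if stop_at != -1 and codon_i > stop_at:
        return ProteinEffect(kinds=("none",))

    if vtype in {"insertion", "deletion"}:
        length = int(getattr(call, "length", None) or len(getattr(call, "alt", "") or "A"))
        if length % 3 == 0:
            return ProteinEffect(kinds=("in_frame_indel",))
        return ProteinEffect(kinds=("frameshift",))

    # SNP
    frame = idx % 3
    codon = coding[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return ProteinEffect(kinds=("none",))
    alt = str(call.alt).upper()
    alt_in_frame = alt if feat.strand == "+" else revcomp(alt)
    new_codon = codon[:frame] + alt_in_frame + codon[frame + 1 :]
    aa_from = _translate(codon)
    aa_to = _translate(new_codon)
    if aa_from == aa_to:
        return ProteinEffect(kinds=("silent",), aa_from=aa_from, aa_to=aa_to)
    if aa_to == "*":
        return ProteinEffect(kinds=("truncation",), aa_from=aa_from, aa_to=aa_to)
    return ProteinEffect(kinds=("substitution",), aa_from=aa_from, aa_to=aa_to)


def homopolymer_run_length(genome: AnnotatedGenome, pos0: int, base: str) -> int:
    """Length of the maximal run of ``base`` containing 0-based position ``pos0``.

    Returns 0 when the reference base at ``pos0`` differs from ``base``
    (the run is then the one the indel joins when inserted there).
    """
    seq = genome.sequence
    L = len(seq)
    if seq[pos0] != base:
        return 0
    left = pos0
    right = pos0
    for _ in range(L):
        nxt = (left - 1) % L if genome.circular else left - 1
        if nxt < 0 or seq[nxt] != base or nxt == right:
            break
        left = nxt
    for _ in range(L):
        nxt = (right + 1) % L if genome.circular else right + 1
        if nxt >= L or seq[nxt] != base or nxt == left:
            break
        right = nxt
    span = (right - left) % L if genome.circular else right - left
    return min(span + 1, L)
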