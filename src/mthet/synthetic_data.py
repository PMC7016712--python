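"""Synthetic mtgenomes, heteroplasmy drift across bottlenecks, and read simulation.

The generator emulates the architecture of a nematode mitochondrial
genome (~14 kb, circular, AT-biased) as sequenced in a
mutation-accumulation (MA) bottlenecking experiment: an AT-rich
low-complexity control region, planted A/T homopolymer runs of 5-13 bp,
a pseudogene sharing a near-exact 36 bp direct repeat with a downstream
gene (the substrate for an ~870 bp repeat-mediated deletion), 250 bp
paired-end reads at a few hundred-fold mtDNA coverage with single-digit
nuclear coverage, i.i.d. sequencing errors, and exact PCR duplicates.

Heteroplasmy dynamics are modeled as one Wright-Fisher resampling event
per host generation over ``n_eff`` effective mtDNA copies, with an
optional multiplicative transmission bias ``b`` (b=1 is neutral drift;
b>1 models a selfish element).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mito_model import (
    AnnotatedGenome,
    Feature,
    census_homopolymers,
    revcomp,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# genome construction

@dataclass(frozen=True)
class HomopolymerPlant:
    base: str
    length: int
    start: int  # 1-based


@dataclass(frozen=True)
class RepeatPlant:
    """A direct repeat: identical ``length``-mers at two positions, with an
    optional single mismatch at ``mismatch_offset`` (0-based) in the right copy."""

    left_start: int  # 1-based
    right_start: int
    length: int = 36
    mismatch_offset: int | None = 5


@dataclass
class GenomeSpec:
    """Blueprint for a synthetic annotated mtgenome."""

    length: int = 14420
    at_rich: tuple[int, int, float] = (101, 700, 0.94)  # start, end, AT fraction
    base_composition: tuple[float, float, float, float] = (0.32, 0.09, 0.14, 0.45)
    genes: list[Feature] = field(default_factory=list)
    homopolymers: list[HomopolymerPlant] = field(default_factory=list)
    repeat: RepeatPlant | None = None
    name: str = "synthetic-mt"

    def __post_init__(self) -> None:
        if not 0 < self.at_rich[2] <= 1:
            raise ValueError("AT fraction must be in (0, 1]")
        if abs(sum(self.base_composition) - 1) > 1e-9:
            raise ValueError("base composition must sum to 1")


def default_genome_spec() -> GenomeSpec:
    """AT-biased ~14.4 kb circular genome mirroring the AF16-style layout.

    The pseudogene shares a 36 bp direct repeat (one C/T mismatch at the
    sixth base) with the downstream NADH-dehydrogenase-5 gene; the two
    repeat copies start 870 bp apart, so the repeat-mediated deletion
    removes 870 bp.
    """
    genes = [
        Feature("trnV", "tRNA", 760, 820),
        Feature("nduo-6", "gene", 900, 1340, "+"),
        Feature("nduo-1", "gene", 1500, 2370, "+"),
        Feature("atp-6", "gene", 2900, 3560, "+"),
        Feature("nduo-2", "gene", 3700, 4540, "+"),
        Feature("ctc-3", "gene", 6100, 6900, "+"),
        Feature("nduo-4", "gene", 7600, 8290, "+"),
        Feature("ctc-1", "gene", 8400, 9980, "+"),
        Feature("l-rRNA", "rRNA", 10500, 11460, "+"),
        Feature("psi-nad5-2", "pseudogene", 12230, 12561),
        Feature("nduo-5", "gene", 12562, 14280, "+"),
    ]
    homopolymers = [
        HomopolymerPlant("A", 8, 950),
        HomopolymerPlant("A", 12, 2000),
        HomopolymerPlant("T", 6, 3582),
        HomopolymerPlant("A", 10, 3567),
        HomopolymerPlant("T", 13, 5050),
        HomopolymerPlant("T", 7, 6515),
        HomopolymerPlant("T", 9, 8305),
        HomopolymerPlant("T", 5, 12276),
        HomopolymerPlant("T", 8, 12601),
    ]
    return GenomeSpec(
        genes=genes,
        homopolymers=homopolymers,
        repeat=RepeatPlant(left_start=12473, right_start=13343, length=36, mismatch_offset=5),
    )


_STOPS = {"TAA", "TAG"}


def build_synthetic_genome(spec: GenomeSpec, seed: int) -> AnnotatedGenome:
    """Deterministically realize a :class:`GenomeSpec` as an AnnotatedGenome.

    Planted homopolymers are made maximal by forcing non-identical
    flanking bases; gene bodies are built from stop-free codons ending
    in TAA so that frame-aware effect annotation behaves sensibly.
    Raises when planted homopolymers overlap each other or the repeat.
    """
    rng = np.random.default_rng(seed)
    L = spec.length
    seq = rng.choice(list(BASES), size=L, p=spec.base_composition)

    # AT-rich control region
    a0, a1, at_frac = spec.at_rich
    n_at = a1 - a0 + 1
    p_at = at_frac / 2
    p_gc = (1 - at_frac) / 2
    seq[a0 - 1 : a1] = rng.choice(list(BASES), size=n_at, p=(p_at, p_gc, p_gc, p_at))

    # genes: random sense codons without internal stops, TAA-terminated
    codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    sense = [c for c in codons if c not in _STOPS and c != "TGA"]
    for g in spec.genes:
        if g.role != "gene":
            continue
        span = g.end - g.start + 1
        n_codons = span // 3
        body = "".join(rng.choice(sense) for _ in range(max(n_codons - 1, 0))) + "TAA"
        body = body[:span].ljust(span, "A")
        if g.strand == "-":
            body = revcomp(body)
        seq[g.start - 1 : g.end] = list(body)

    # direct repeat pair
    if spec.repeat is not None:
        r = spec.repeat
        motif = rng.choice(list(BASES), size=r.length, p=(0.3, 0.2, 0.2, 0.3))
        if r.mismatch_offset is not None:
            motif[r.mismatch_offset] = "C"
        right = motif.copy()
        if r.mismatch_offset is not None:
            right[r.mismatch_offset] = "T"
        seq[r.left_start - 1 : r.left_start - 1 + r.length] = motif
        seq[r.right_start - 1 : r.right_start - 1 + r.length] = right

    # homopolymers last, with distinct flanks for maximality
    occupied: set[int] = set()
    if spec.repeat is not None:
        occupied.update(range(spec.repeat.left_start - 1, spec.repeat.left_start - 1 + spec.repeat.length))
        occupied.update(range(spec.repeat.right_start - 1, spec.repeat.right_start - 1 + spec.repeat.length))
    for hp in spec.homopolymers:
        span = set(range(hp.start - 2, hp.start + hp.length))
        if span & occupied:
            raise ValueError(f"planted homopolymer at {hp.start} overlaps another planted element")
        occupied.update(span)
        seq[hp.start - 1 : hp.start - 1 + hp.length] = hp.base
        flank = "G" if hp.base in "AT" else "A"
        seq[hp.start - 2] = flank
        if hp.start - 1 + hp.length < L:
            seq[hp.start - 1 + hp.length] = flank

    features = list(spec.genes)
    features.append(Feature("AT-rich", "AT-rich", a0, a1))
    return AnnotatedGenome(name=spec.name, sequence="".join(seq), circular=True, features=features)


def make_nuclear_refs(seed: int, lengths: tuple[int, ...] = (1800, 1500, 1900)) -> list[AnnotatedGenome]:
    """Three linear single-copy nuclear loci (RNA-polymerase-II-like stand-ins)."""
    rng = np.random.default_rng(seed)
    names = ["ama-1", "efl-2", "ego-1"]
    refs = []
    for name, n in zip(names, lengths):
        s = "".join(rng.choice(list(BASES), size=n, p=(0.3, 0.2, 0.2, 0.3)))
        refs.append(AnnotatedGenome(name=name, sequence=s, circular=False))
    return refs


# ---------------------------------------------------------------------------
# lineage (drift) simulation

@dataclass(frozen=True)
class SimVariant:
    """A planted variant: SNP, single-base indel, or large deletion."""

    vtype: str  # SNP | insertion | deletion | large_deletion
    position: int  # 1-based
    ref: str = ""
    alt: str = ""
    length: int = 1
    bias: float = 1.0

    @property
    def key(self) -> tuple:
        return (self.vtype, self.position, self.alt, self.length)


@dataclass
class LineagePlan:
    """Conditions for one MA lineage: bottleneck size, rates, starting state.

    De-novo rates are per site per generation per mtDNA copy, so the
    Poisson mutational input per generation is ``rate * n_sites * n_eff``
    and each new variant is seeded at frequency ``1/n_eff``.
    """

    generations: int = 50
    n_eff: int = 100
    initial: list[tuple[SimVariant, float]] = field(default_factory=list)
    snp_rate: float = 0.0
    slippage_rate: float = 0.0
    deletion_rate: float = 0.0  # per genome per generation per copy
    deletion_template: SimVariant | None = None
    hp_min_run: int = 5

    def __post_init__(self) -> None:
        if self.generations < 0 or self.generations > 50:
            raise ValueError("generations must be in [0, 50]")
        if self.n_eff < 1:
            raise ValueError("n_eff must be >= 1")
        for v, f in self.initial:
            if not 0 <= f <= 1:
                raise ValueError(f"initial frequency {f} outside [0, 1]")


@dataclass
class VariantFate:
    variant: SimVariant
    frequency: float
    origin_generation: int
    fate: str  # fixed_variant | fixed_reference | heteroplasmic | lost


@dataclass
class LineageState:
    variants: list[VariantFate]
    generations: int
    n_eff: int

    def truth(self) -> list[tuple[SimVariant, float]]:
        return [(vf.variant, vf.frequency) for vf in self.variants if vf.frequency > 0]


def _resample(freq: float, bias: float, n_eff: int, rng: np.random.Generator) -> float:
    if freq in (0.0, 1.0):
        return freq
    p = freq * bias / (freq * bias + (1 - freq))
    return rng.binomial(n_eff, p) / n_eff


def simulate_ma_lineage(genome: AnnotatedGenome, plan: LineagePlan, seed: int) -> LineageState:
    """Evolve heteroplasmy frequencies through single-individual bottlenecks.

    Each generation every segregating variant is independently resampled
    binomially over ``n_eff`` transmitted copies with success probability
    p*b/(p*b + (1-p)); de-novo SNPs, homopolymer slippage indels and
    repeat-mediated deletions arrive as Poisson events at the plan's
    rates, seeded at frequency 1/n_eff.  Variants are unlinked.
    """
    rng = np.random.default_rng(seed)
    at_excluded = genome.excluded_positions("AT-rich")
    snp_positions = [p for p in range(1, genome.length + 1) if (p - 1) not in at_excluded]
    census = census_homopolymers(genome, min_run=plan.hp_min_run)
    hp_runs = census.runs
    hp_weights = np.array([r.length for r in hp_runs], dtype=float)
    if hp_weights.sum() > 0:
        hp_weights = hp_weights / hp_weights.sum()
    n_hp_sites = int(sum(r.length for r in hp_runs))

    state: dict[tuple, tuple[SimVariant, float, int]] = {}
    for v, f in plan.initial:
        state[v.key] = (v, f, 0)

    for gen in range(1, plan.generations + 1):
        # drift
        for key, (v, f, g0) in list(state.items()):
            state[key] = (v, _resample(f, v.bias, plan.n_eff, rng), g0)
        # de novo arrivals
        n_snp = rng.poisson(plan.snp_rate * len(snp_positions) * plan.n_eff)
        for _ in range(n_snp):
            pos = int(rng.choice(snp_positions))
            ref = genome.sequence[pos - 1]
            alt = rng.choice([b for b in BASES if b != ref])
            v = SimVariant("SNP", pos, ref=ref, alt=str(alt))
            if v.key not in state:
                state[v.key] = (v, 1.0 / plan.n_eff, gen)
        if hp_runs:
            n_slip = rng.poisson(plan.slippage_rate * n_hp_sites * plan.n_eff)
            for _ in range(n_slip):
                run = hp_runs[int(rng.choice(len(hp_runs), p=hp_weights))]
                vtype = "insertion" if rng.random() < 0.5 else "deletion"
                v = SimVariant(vtype, run.start, ref=run.base, alt=run.base)
                if v.key not in state:
                    state[v.key] = (v, 1.0 / plan.n_eff, gen)
        if plan.deletion_template is not None and plan.deletion_rate > 0:
            n_del = rng.poisson(plan.deletion_rate * plan.n_eff)
            if n_del > 0 and plan.deletion_template.key not in state:
                state[plan.deletion_template.key] = (
                    plan.deletion_template,
                    1.0 / plan.n_eff,
                    gen,
                )

    fates: list[VariantFate] = []
    for v, f, g0 in state.values():
        if f >= 1.0:
            fate = "fixed_variant"
        elif f <= 0.0:
            fate = "lost" if g0 > 0 else "fixed_reference"
        else:
            fate = "heteroplasmic"
        fates.append(VariantFate(variant=v, frequency=float(f), origin_generation=g0, fate=fate))
    fates.sort(key=lambda vf: vf.variant.position)
    return LineageState(variants=fates, generations=plan.generations, n_eff=plan.n_eff)


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class ReadSimParams:
    read_length: int = 250
    fragment_mean: float = 330.0
    fragment_sd: float = 30.0
    error_rate: float = 0.002
    mt_coverage: float = 300.0
    nuclear_coverage: float = 5.5
    duplicate_fraction: float = 0.05
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read length must not exceed mean fragment length")
        if self.mt_coverage <= 0 or self.nuclear_coverage < 0:
            raise ValueError("coverages must be positive")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate fraction must be in [0, 1)")


@dataclass(frozen=True)
class Fragment:
    sequence: str
    ref_name: str
    start0: int  # 0-based origin on the (non-deleted) reference
    from_deletion: bool = False


def _deletion_haplotype(genome: AnnotatedGenome, deletion: SimVariant) -> tuple[str, int]:
    s0 = deletion.position - 1
    hap = genome.sequence[:s0] + genome.sequence[s0 + deletion.length :]
    return hap, s0


def simulate_fragments(
    genome: AnnotatedGenome,
    variants: list[tuple[SimVariant, float]],
    n_fragments: int,
    rng: np.random.Generator,
    fragment_mean: float = 330.0,
    fragment_sd: float = 30.0,
    min_length: int = 250,
) -> list[Fragment]:
    """Draw fragments uniformly from the circular genome, sampling each
    variant independently with probability equal to its frequency."""
    L = genome.length
    dels = [(v, f) for v, f in variants if v.vtype == "large_deletion"]
    points = [(v, f) for v, f in variants if v.vtype != "large_deletion"]
    del_hap = None
    hap_doubled = None
    if dels:
        if len(dels) > 1:
            raise ValueError("at most one large deletion per simulated lineage")
        del_hap = _deletion_haplotype(genome, dels[0][0])
        hap_doubled = del_hap[0] + del_hap[0]
    ref_doubled = genome.doubled() if genome.circular else genome.sequence
    frags: list[Fragment] = []
    lengths = np.clip(
        np.rint(rng.normal(fragment_mean, fragment_sd, size=n_fragments)).astype(int),
        min_length,
        None,
    )
    use_del = (
        rng.random(n_fragments) < dels[0][1] if dels else np.zeros(n_fragments, dtype=bool)
    )
    point_draws = rng.random((n_fragments, len(points))) if points else None
    for i in range(n_fragments):
        flen = int(lengths[i])
        if use_del[i]:
            hap, _dstart = del_hap  # type: ignore[misc]
            hl = len(hap)
            if genome.circular:
                s = int(rng.integers(0, hl))
                raw = hap_doubled[s : s + flen]  # type: ignore[index]
            else:
                s = int(rng.integers(0, max(hl - flen, 1)))
                raw = hap[s : s + flen]
            frag_seq = raw
            from_del = True
            origin = s
        else:
            if genome.circular:
                s = int(rng.integers(0, L))
                raw = ref_doubled[s : s + flen]
            else:
                s = int(rng.integers(0, max(L - flen, 1)))
                raw = genome.sequence[s : s + flen]
            frag_seq = raw
            from_del = False
            origin = s
        if points:
            # apply point variants present on this molecule (unlinked sampling);
            # on the deletion haplotype, positions inside the deleted interval
            # do not exist and coordinates beyond it shift left
            edits = []
            for j, (v, f) in enumerate(points):
                if point_draws[i, j] >= f:
                    continue
                p0 = v.position - 1
                if from_del:
                    dv = dels[0][0]
                    ds0 = dv.position - 1
                    if ds0 <= p0 < ds0 + dv.length:
                        continue
                    hp0 = p0 if p0 < ds0 else p0 - dv.length
                    hap_len = len(del_hap[0])
                    off = (hp0 - origin) % hap_len if genome.circular else hp0 - origin
                else:
                    off = (p0 - origin) % L if genome.circular else p0 - origin
                if 0 <= off < len(frag_seq):
                    edits.append((off, v))
            for off, v in sorted(edits, key=lambda e: -e[0]):
                if v.vtype == "SNP":
                    frag_seq = frag_seq[:off] + v.alt + frag_seq[off + 1 :]
                elif v.vtype == "insertion":
                    frag_seq = frag_seq[: off + 1] + v.alt + frag_seq[off + 1 :]
                elif v.vtype == "deletion":
                    frag_seq = frag_seq[:off] + frag_seq[off + v.length :]
        frags.append(Fragment(sequence=frag_seq, ref_name=genome.name, start0=origin, from_deletion=from_del))
    return frags


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = str(rng.choice([b for b in BASES if b != out[p]]))
    return "".join(out)


def n_fragments_for_coverage(coverage: float, genome_length: int, fragment_mean: float) -> int:
    return max(1, int(round(coverage * genome_length / fragment_mean)))


def simulate_reads(
    genome: AnnotatedGenome,
    nuclear_refs: list[AnnotatedGenome],
    state: LineageState | list[tuple[SimVariant, float]],
    params: ReadSimParams,
    out_prefix: str | Path,
) -> dict:
    """Emit paired FASTQ (R1/R2) plus a truth TSV of planted variants.

    Fragments come from the circular mtgenome at ``mt_coverage`` and from
    each linear nuclear locus at ``nuclear_coverage``; each read is the
    appropriate end of its fragment with i.i.d. substitution errors, and
    ``duplicate_fraction`` of the emitted pairs are exact copies of
    other pairs.  All randomness flows from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    variants = state.truth() if isinstance(state, LineageState) else state
    frags: list[Fragment] = []
    n_mt = n_fragments_for_coverage(params.mt_coverage, genome.length, params.fragment_mean)
    frags += simulate_fragments(
        genome, variants, n_mt, rng, params.fragment_mean, params.fragment_sd, params.read_length
    )
    for ref in nuclear_refs:
        n_nuc = n_fragments_for_coverage(params.nuclear_coverage, ref.length, params.fragment_mean)
        frags += simulate_fragments(
            ref, [], n_nuc, rng, params.fragment_mean, params.fragment_sd, params.read_length
        )

    pairs: list[tuple[str, str, str]] = []
    for i, fr in enumerate(frags):
        r1 = fr.sequence[: params.read_length]
        r2 = revcomp(fr.sequence)[: params.read_length]
        r1 = _add_errors(r1, params.error_rate, rng)
        r2 = _add_errors(r2, params.error_rate, rng)
        name = f"{fr.ref_name}|{fr.start0}|{'D' if fr.from_deletion else 'R'}|{i}"
        pairs.append((name, r1, r2))

    f = params.duplicate_fraction
    n_dup = int(round(len(pairs) * f / (1 - f))) if f > 0 else 0
    if n_dup:
        src = rng.integers(0, len(pairs), size=n_dup)
        for j, s in enumerate(src):
            name, r1, r2 = pairs[int(s)]
            pairs.append((f"{name}|dup{j}", r1, r2))
    order = rng.permutation(len(pairs))
    pairs = [pairs[int(i)] for i in order]

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = out_prefix.with_suffix(".R1.fastq")
    r2_path = out_prefix.with_suffix(".R2.fastq")
    qual = "I"
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{qual * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{qual * len(r2)}\n")

    truth = pd.DataFrame(
        [
            {
                "variant_type": v.vtype,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "length": v.length,
                "frequency": freq,
            }
            for v, freq in variants
        ]
    )
    truth_path = out_prefix.with_suffix(".truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "r1": r1_path,
        "r2": r2_path,
        "truth": truth_path,
        "n_pairs": len(pairs),
        "n_duplicates": n_dup,
    }
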