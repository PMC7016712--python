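"""Writers for the pipeline's standard output formats (SAM, VCF 4.2, TSV)."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import Alignment
from .caller import DeletionCall, VariantCall
from .mito_model import AnnotatedGenome


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def _cigar(aln: Alignment) -> str:
    parts = []
    ops = aln.ops
    for i, (op, rs, qs, ln) in enumerate(ops):
        if op == "M":
            parts.append(f"{ln}M")
        elif op == "I":
            parts.append(f"{ln}I")
        elif op == "D":
            parts.append(f"{ln}D")
        if aln.large_gap is not None and i == 0 and len(ops) == 2:
            parts.append(f"{aln.large_gap[1]}D")
    return "".join(parts)


def write_sam(
    alignments: Iterable[Alignment],
    genome: AnnotatedGenome,
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Sorted single-end SAM; split reads carry the long gap as a D op."""
    alns = sorted(alignments, key=lambda a: a.start0)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{genome.name}\tLN:{genome.length}\n")
        for c in header_comments:
            fh.write(f"@CO\t{c}\n")
        for a in alns:
            flag = 0 if a.strand == "+" else 16
            fh.write(
                "\t".join(
                    [
                        a.read_id.replace(" ", "_"),
                        str(flag),
                        genome.name,
                        str(a.start),
                        "60",
                        _cigar(a),
                        "*",
                        "0",
                        "0",
                        a.read_seq,
                        "*",
                        f"NM:i:{a.mismatches}",
                    ]
                )
                + "\n"
            )


def write_vcf(
    calls: Sequence[VariantCall | DeletionCall],
    genome: AnnotatedGenome,
    path: str | Path,
    sample: str = "sample",
    header_comments: Sequence[str] = (),
) -> None:
    """VCF 4.2 with AF/DP/SB/HPRUN/DENOVO INFO fields.

    Indels are VCF-normalized (anchor base prepended); large deletions
    use symbolic <DEL> with END/SVLEN.
    """
    seq = genome.sequence
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.name},length={genome.length}>",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant read fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw coverage">',
        '##INFO=<ID=SB,Number=2,Type=Integer,Description="Supporting reads fwd,rev">',
        '##INFO=<ID=HPRUN,Number=1,Type=Integer,Description="Homopolymer run length at site">',
        '##INFO=<ID=DENOVO,Number=0,Type=Flag,Description="Absent from progenitor at any frequency">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Deletion end">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deletion length">',
    ]
    lines += [f"##{c}" for c in header_comments]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = []
    for c in calls:
        if isinstance(c, DeletionCall):
            pos = c.start - 1 if c.start > 1 else c.start
            ref = seq[pos - 1]
            info = (
                f"DP={max(c.coverage_range)};AF={c.frequency_range[1]};"
                f"END={c.start + c.length - 1};SVLEN=-{c.length}"
            )
            if c.de_novo:
                info += ";DENOVO"
            rows.append((pos, f"{genome.name}\t{pos}\t.\t{ref}\t<DEL>\t.\tPASS\t{info}"))
            continue
        sb = f"{c.strand_support[0]},{c.strand_support[1]}"
        info = f"AF={c.frequency};DP={c.coverage};SB={sb};HPRUN={c.homopolymer_run}"
        if c.de_novo:
            info += ";DENOVO"
        if c.type == "SNP":
            pos, ref, alt = c.position, c.ref, c.alt
        elif c.type == "insertion":
            pos = c.position - 1 if c.position > 1 else c.position
            anchor = seq[pos - 1]
            ref, alt = anchor, anchor + c.alt
        else:  # short deletion
            pos = c.position - 1 if c.position > 1 else c.position
            anchor = seq[pos - 1]
            ref = anchor + seq[c.position - 1 : c.position - 1 + c.length]
            alt = anchor
        rows.append((pos, f"{genome.name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}"))
    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, row in rows:
            fh.write(row + "\n")
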