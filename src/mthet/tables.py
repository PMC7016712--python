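"""Packaged worked-example tables.

Small TSVs transcribing the reported heteroplasmy survey of two
*C. briggsae* isolates (AF16 and ED3101) after up to 50 generations of
single-individual bottlenecking: site variants, the three large
repeat-mediated deletions, and per-library coverage summaries.  They
drive the worked examples and the bookkeeping/arithmetic checks without
any sequencing data.
"""
from __future__ import annotations

import re
from importlib import resources

import pandas as pd

_INDEL_RE = re.compile(r"\((?P<base>[ACGT])\)(?P<n_from>\d+) → \((?P=base)(\))(?P<n_to>\d+)")


def _classify_change(change: str) -> tuple[str, int]:
    """(variant type, homopolymer run length) from a printed change string."""
    change = change.strip()
    if change.startswith("-N("):
        return "large_deletion", 0
    m = re.match(r"\(([ACGT])\)(\d+) → \(([ACGT])\)(\d+)", change)
    if m:
        n_from, n_to = int(m.group(2)), int(m.group(4))
        return ("insertion" if n_to > n_from else "deletion"), n_from
    if "→" in change:
        return "SNP", 0
    raise ValueError(f"unrecognized change notation: {change!r}")


def _read(name: str) -> pd.DataFrame:
    with resources.files("mthet").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_variant_table() -> pd.DataFrame:
    """Site variants (homopolymer indels and SNPs) with a derived ``type``
    column and homopolymer run length."""
    df = _read("variant_table.tsv")
    types = df["change"].map(lambda c: _classify_change(c)[0])
    runs = df["change"].map(lambda c: _classify_change(c)[1])
    df = df.assign(type=types, homopolymer_run=runs)
    return df


def load_deletion_table() -> pd.DataFrame:
    df = _read("deletion_table.tsv")
    return df.assign(type="large_deletion")


def load_line_summary() -> pd.DataFrame:
    return _read("line_summary.tsv")
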