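"""Mutation-rate estimation for mutation-accumulation (MA) experiments.

The per-site per-generation rate for a variant class is

    mu = m / (L * n * T)

with standard error

    SE = sqrt(mu / (L * n * T))

where ``m`` sums, over MA lines and over the union of variant sites,
the absolute difference between the MA-line and progenitor heteroplasmy
frequencies (a variant absent from a library contributes frequency 0);
``L`` is the number of MA lines, ``n`` the number of scanned sites and
``T`` the average number of MA generations.

For base substitutions ``n`` is the genome length minus the AT-rich
region; for homopolymer indels ``n`` is the census of bases in A/T
mononucleotide runs of at least eight bases outside the AT-rich region
(shorter runs are reported by the caller but excluded here, as slippage
below that length is considered a different mutational regime).

Whether progenitor-only heteroplasmies (lost in an MA line) should
contribute |0 - f_prog| per line is a genuine bookkeeping choice; the
union rule above is the default, and ``include_progenitor_only=False``
restricts the sum to sites observed in the MA line.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

VARIANT_CLASSES = ("base_substitution", "homopolymer_indel")


@dataclass(frozen=True)
class RateInputs:
    m: float
    L: int
    n: int
    T: float

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.L < 1 or self.n < 1 or self.T <= 0:
            raise ValueError("need L >= 1, n >= 1, T > 0")


@dataclass(frozen=True)
class RateEstimate:
    variant_class: str
    mu: float
    se: float
    inputs: RateInputs


def average_generations(counts: Sequence[int]) -> float:
    """Arithmetic mean number of MA generations, T."""
    if not counts:
        raise ValueError("no generation counts supplied")
    if any(c <= 0 for c in counts):
        raise ValueError("generation counts must be positive")
    return sum(counts) / len(counts)


def _class_filter(call, variant_class: str, min_run: int) -> bool:
    if variant_class == "base_substitution":
        return call.type == "SNP"
    if variant_class == "homopolymer_indel":
        return call.type in {"insertion", "deletion"} and (call.homopolymer_run or 0) >= min_run
    raise ValueError(f"unknown variant class {variant_class!r}")


def _freq_map(calls: Iterable, variant_class: str, min_run: int) -> dict:
    out = {}
    for c in calls:
        if _class_filter(c, variant_class, min_run):
            out[c.key] = c.frequency
    return out


def estimate_m(
    progenitor_calls: Iterable,
    ma_calls: Mapping[str, Iterable],
    variant_class: str,
    min_run: int = 8,
    include_progenitor_only: bool = True,
) -> float:
    """Summed absolute frequency difference between MA lines and progenitor.

    For each MA line, sites are the union of that line's and the
    progenitor's variant sites of the class (absent = frequency 0);
    loss of a progenitor heteroplasmy contributes |0 - f_prog| and
    fixation contributes |1 - f_prog|.
    """
    prog = _freq_map(progenitor_calls, variant_class, min_run)
    m = 0.0
    for line, calls in ma_calls.items():
        line_map = _freq_map(calls, variant_class, min_run)
        keys = set(line_map)
        if include_progenitor_only:
            keys |= set(prog)
        for key in keys:
            m += abs(line_map.get(key, 0.0) - prog.get(key, 0.0))
    return m


def mutation_rate(inputs: RateInputs, variant_class: str = "base_substitution") -> RateEstimate:
    """Point estimate and SE from the closed forms above."""
    denom = inputs.L * inputs.n * inputs.T
    if denom <= 0:
        raise ValueError("zero denominator")
    mu = inputs.m / denom
    se = math.sqrt(mu / denom)
    return RateEstimate(variant_class=variant_class, mu=mu, se=se, inputs=inputs)


def rate_report(estimates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Tabular report: class, m, L, n, T, mu, SE."""
    rows = [
        {
            "variant_class": e.variant_class,
            "m": e.inputs.m,
            "L": e.inputs.L,
            "n": e.inputs.n,
            "T": e.inputs.T,
            "mu_per_site_per_generation": e.mu,
            "se": e.se,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
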