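"""Nuclear-normalized mtDNA copy-number estimation and comparisons.

Per-site mtgenome read depth (AT-rich region excluded) is divided by
the mean coverage of three single-copy nuclear loci, giving a per-site
proxy for the mtDNA:nDNA copy ratio.  Group comparisons follow the
standard nonparametric battery for such coverage tracks: a D'Agostino-
Pearson normality check, a Kruskal-Wallis test with Dunn's multiple-
comparison z-tests (Bonferroni-adjusted) for MA line versus progenitor,
and a two-sample Kolmogorov-Smirnov test for distribution equality
between isolates.  Positions are treated as exchangeable observations;
positional autocorrelation is ignored by design.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mito_model import AnnotatedGenome


@dataclass
class NormalizedCoverage:
    """Per-position normalized mtDNA coverage for one sample."""

    sample: str
    values: np.ndarray
    normalizer: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.normalizer <= 0:
            raise ValueError("nuclear normalizer must be positive")
        if (self.values < 0).any():
            raise ValueError("normalized values must be >= 0")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def normalize_coverage(
    mt_coverage: np.ndarray,
    nuclear_coverages: list[np.ndarray],
    genome: AnnotatedGenome,
    sample: str = "sample",
    exclude_role: str | None = "AT-rich",
) -> NormalizedCoverage:
    """Divide mtDNA depth by the mean of the nuclear loci's average depths.

    ``nuclear_coverages`` are the per-position depth tracks of the three
    nuclear reference loci; AT-rich mtgenome positions are dropped.
    """
    if len(nuclear_coverages) == 0:
        raise ValueError("need at least one nuclear locus")
    locus_means = [float(np.mean(c)) for c in nuclear_coverages]
    if any(m <= 0 for m in locus_means):
        raise ValueError("zero nuclear coverage")
    normalizer = float(np.mean(locus_means))
    mt = np.asarray(mt_coverage, dtype=float)
    if len(mt) != genome.length:
        raise ValueError("mt coverage track length does not match genome")
    excluded = genome.excluded_positions(exclude_role)
    keep = np.array([i not in excluded for i in range(genome.length)])
    return NormalizedCoverage(sample=sample, values=mt[keep] / normalizer, normalizer=normalizer)


def _dunn_z(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean ranks and the tie-corrected variance factor for Dunn's test."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    i = 0
    for g in groups:
        mean_ranks.append(ranks[i : i + len(g)].mean())
        i += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))
    return np.array(mean_ranks), np.array([var_factor, N])


def compare_to_progenitor(
    ma: list[NormalizedCoverage], progenitor: NormalizedCoverage
) -> dict:
    """Kruskal-Wallis over all groups plus Dunn's MA-vs-progenitor contrasts.

    Dunn's z uses pooled tie-corrected rank variance; adjusted p-values
    are Bonferroni over the MA-vs-progenitor contrasts (never smaller
    than the unadjusted p).  The report also carries each line's mean
    difference from the progenitor.
    """
    if not ma:
        raise ValueError("need at least one MA sample")
    groups = [progenitor.values] + [s.values for s in ma]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    H, p_kw = stats.kruskal(*groups)
    mean_ranks, (var_factor, N) = _dunn_z(groups)
    k = len(ma)
    rows = []
    n0 = len(progenitor.values)
    for i, s in enumerate(ma, start=1):
        ni = len(s.values)
        se = np.sqrt(var_factor * (1.0 / n0 + 1.0 / ni))
        z = (mean_ranks[0] - mean_ranks[i]) / se
        p_unadj = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "sample": s.sample,
                "z": float(z),
                "p_unadjusted": float(p_unadj),
                "p_adjusted": float(min(1.0, p_unadj * k)),
                "mean_difference": progenitor.mean - s.mean,
            }
        )
    return {
        "kruskal_H": float(H),
        "kruskal_p": float(p_kw),
        "contrasts": pd.DataFrame(rows),
    }


def compare_distributions(a: NormalizedCoverage, b: NormalizedCoverage) -> dict:
    """Two-sample Kolmogorov-Smirnov test between coverage distributions."""
    if len(a.values) == 0 or len(b.values) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a.values, b.values)
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def normality_check(values: np.ndarray) -> dict:
    """D'Agostino-Pearson K^2 omnibus normality test."""
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("normality check needs n >= 20")
    k2, p = stats.normaltest(values)
    return {"K2": float(k2), "p": float(p)}


def mean_reductions(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-isolate min/max drop of MA normalized coverage below the progenitor.

    Expects columns isolate, line, role (progenitor/MA), norm_mt_cov.
    Differences are on the printed means, rounded to the reported
    precision (one decimal at magnitude >= 10, two below).
    """
    rows = []
    for isolate, grp in summary.groupby("isolate"):
        prog = grp[grp["role"] == "progenitor"]
        if len(prog) != 1:
            raise ValueError(f"isolate {isolate}: expected exactly one progenitor")
        p = float(prog["norm_mt_cov"].iloc[0])
        ma = grp[grp["role"] == "MA"]
        diffs = p - ma["norm_mt_cov"].astype(float)
        lo, hi = float(diffs.min()), float(diffs.max())
        rnd = lambda x: round(x, 1) if abs(x) >= 10 else round(x, 2)
        rows.append(
            {
                "isolate": isolate,
                "min_reduction": rnd(lo),
                "max_reduction": rnd(hi),
                "progenitor_norm_cov": p,
            }
        )
    return pd.DataFrame(rows)
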