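"""CPM expression levels and gene-set temporal trend summaries.

CPM = count / library size x 1e6, with no further normalisation.  A gene-set
trend averages CPM over biological replicates per gene and week, then
summarises the set per week by the median and interquartile range over
genes.  The direction test is a two-sided exact binomial (sign) test on the
numbers of genes going up versus down between the first and last week, with
ties excluded and success probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, validate_counts


@dataclass
class TrendSummary:
    gene_set: str
    tissue: str
    weeks: list[int]
    median_cpm: list[float]   # per week, over genes
    iqr_cpm: list[float]      # per week
    n_up: int
    n_down: int
    n_tied: int

    @property
    def n_genes(self) -> int:
        return self.n_up + self.n_down + self.n_tied


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column; every column sums to 1e6."""
    counts = validate_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample {zero[0]!r}")
    return counts / totals * 1e6


def geneset_week_means(cpm_matrix: pd.DataFrame, meta: pd.DataFrame,
                       gene_set: list[str], tissue: str,
                       set_name: str = "") -> pd.DataFrame:
    """Gene x week matrix of CPM averaged over biological replicates."""
    genes = pd.Index(gene_set).intersection(cpm_matrix.index)
    if not len(genes):
        raise ValidationError(
            f"gene set {set_name or '<unnamed>'!r} shares no genes with the "
            "count matrix")
    sub_meta = meta[meta["tissue"] == tissue]
    if not len(sub_meta):
        raise ValidationError(f"no samples for tissue {tissue!r}")
    weeks = sorted(sub_meta["week"].unique())
    cols = {}
    for w in weeks:
        samples = sub_meta.index[sub_meta["week"] == w]
        cols[int(w)] = cpm_matrix.loc[genes, list(samples)].mean(axis=1)
    return pd.DataFrame(cols)


def geneset_trend(cpm_matrix: pd.DataFrame, meta: pd.DataFrame,
                  gene_set: list[str], tissue: str,
                  set_name: str = "") -> TrendSummary:
    """Per-week median/IQR over genes and up/down direction counts."""
    wm = geneset_week_means(cpm_matrix, meta, gene_set, tissue, set_name)
    weeks = list(wm.columns)
    med = [float(np.median(wm[w])) for w in weeks]
    iqr = [float(np.percentile(wm[w], 75) - np.percentile(wm[w], 25))
           for w in weeks]
    diff = wm[weeks[-1]] - wm[weeks[0]]
    return TrendSummary(
        gene_set=set_name, tissue=tissue, weeks=[int(w) for w in weeks],
        median_cpm=med, iqr_cpm=iqr,
        n_up=int((diff > 0).sum()), n_down=int((diff < 0).sum()),
        n_tied=int((diff == 0).sum()))


def direction_test(summary: TrendSummary) -> float:
    """Two-sided exact binomial p for up/down imbalance; NaN if all tied."""
    n = summary.n_up + summary.n_down
    if n == 0:
        return float("nan")
    return float(stats.binomtest(summary.n_up, n, 0.5,
                                 alternative="two-sided").pvalue)


def trend_table(summaries: list[TrendSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        p = direction_test(s)
        for w, m, q in zip(s.weeks, s.median_cpm, s.iqr_cpm):
            rows.append({"gene_set": s.gene_set, "tissue": s.tissue, "week": w,
                         "median_cpm": m, "iqr_cpm": q, "n_up": s.n_up,
                         "n_down": s.n_down, "n_tied": s.n_tied,
                         "direction_p": p})
    return pd.DataFrame(rows, columns=["gene_set", "tissue", "week",
                                       "median_cpm", "iqr_cpm", "n_up",
                                       "n_down", "n_tied", "direction_p"])
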