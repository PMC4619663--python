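"""Probe QC filtering and the two threshold callers.

Tissue-specific hypomethylation: a probe is called for a target tissue when,
at every gestational week, the mean beta of every other tissue exceeds the
target-tissue mean by at least ``delta`` (default 0.20), and the standard
deviation of the target tissue's samples (pooled over weeks) is below
``sd_max`` (default 0.10).

Dynamic methylation (gain/loss between the first and last week): a probe
gains methylation (GOM) when mean(W22) - mean(W9) >= delta with W18 lying in
between up to a 0.05 tolerance on either side; loss (LOM) is the mirror
image.  Probes with replicate SD >= ``sd_max`` in any (tissue, week) group
are treated as unstable estimates and discarded before calling.

All comparisons are made on replicate means per (tissue, week) and all
thresholds are inclusive (>=).  Sample SDs use the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import group_means
from .io import ValidationError, check_beta_meta_aligned

logger = logging.getLogger(__name__)


@dataclass
class CallSet:
    """Per-probe verdicts of one caller run for one tissue.

    ``stats`` is indexed by probe id and carries the per-week target-tissue
    means, the SD used for filtering, the achieved delta and the boolean
    ``called``; ``probes`` is the index of called probes.
    """

    kind: str  # tissue_hypo | gom | lom
    tissue: str
    probes: pd.Index
    stats: pd.DataFrame

    def __len__(self) -> int:
        return len(self.probes)


def filter_probes(detection_p: pd.DataFrame, bead_count: pd.DataFrame,
                  bead_min: int = 3, detp_max: float = 0.01,
                  success_min: float = 0.95,
                  exclude: pd.Index | None = None) -> pd.Index:
    """QC-retained probes: an observation fails on bead count < ``bead_min``
    or detection P > ``detp_max``; a probe is kept when its success rate is
    >= ``success_min`` and it is not on the exclusion list."""
    if not detection_p.shape == bead_count.shape or \
            not detection_p.index.equals(bead_count.index) or \
            not detection_p.columns.equals(bead_count.columns):
        raise ValidationError("detection_p and bead_count matrices are misaligned")
    fails = (bead_count.to_numpy() < bead_min) | \
            (detection_p.to_numpy() > detp_max) | \
            np.isnan(detection_p.to_numpy())
    success = 1.0 - fails.mean(axis=1)
    retained = detection_p.index[success >= success_min]
    if exclude is not None:
        retained = retained.difference(pd.Index(exclude), sort=False)
    return retained


def _check_cells(meta: pd.DataFrame) -> None:
    tissues = sorted(meta["tissue"].unique())
    weeks = sorted(meta["week"].unique())
    counts = meta.groupby(["tissue", "week"]).size()
    for t in tissues:
        for w in weeks:
            if (t, w) not in counts.index:
                raise ValidationError(f"empty design cell: tissue {t!r}, week {w}")


def call_tissue_hypomethylation(beta: pd.DataFrame, meta: pd.DataFrame,
                                target_tissue: str, sd_max: float = 0.10,
                                delta: float = 0.20,
                                comparison: str = "every") -> CallSet:
    """Probes consistently hypomethylated in ``target_tissue`` vs the others.

    ``comparison="every"`` (default) requires the margin against every other
    tissue at every week; ``"max"`` only against the most methylated other
    tissue at each week (a weaker reading).
    """
    check_beta_meta_aligned(beta, meta)
    _check_cells(meta)
    tissues = sorted(meta["tissue"].unique())
    if target_tissue not in tissues:
        raise ValidationError(f"unknown tissue {target_tissue!r}")
    if len(tissues) < 2:
        raise ValidationError("need at least two tissues")
    weeks = sorted(meta["week"].unique())
    gm = group_means(beta, meta)

    target_samples = meta.index[meta["tissue"] == target_tissue]
    target_block = beta[list(target_samples)]
    sd = target_block.std(axis=1, ddof=1)
    sd[target_block.isna().any(axis=1)] = np.nan

    others = [t for t in tissues if t != target_tissue]
    margins = []
    for w in weeks:
        diffs = pd.concat(
            [gm[(t, w)] - gm[(target_tissue, w)] for t in others], axis=1)
        margins.append(diffs.min(axis=1) if comparison == "every"
                       else diffs.max(axis=1))
    margin = pd.concat(margins, axis=1).min(axis=1)

    complete = margin.notna() & sd.notna()
    n_missing = int((~complete).sum())
    if n_missing:
        logger.warning("tissue_hypo %s: %d probes with missing data excluded",
                       target_tissue, n_missing)
    called = complete & (sd < sd_max) & (margin >= delta)
    stats = pd.DataFrame({
        **{f"mean_w{w}": gm[(target_tissue, w)] for w in weeks},
        "sd": sd, "delta": margin, "called": called})
    stats.index = beta.index.rename("probe_id")
    return CallSet("tissue_hypo", target_tissue, beta.index[called], stats)


def call_dynamic(beta: pd.DataFrame, meta: pd.DataFrame, tissue: str,
                 delta: float = 0.20, w18_tol: float = 0.05,
                 sd_max: float = 0.10) -> tuple[CallSet, CallSet]:
    """(GOM, LOM) call sets for one tissue across three gestational weeks."""
    check_beta_meta_aligned(beta, meta)
    sub = meta[meta["tissue"] == tissue]
    if not len(sub):
        raise ValidationError(f"unknown tissue {tissue!r}")
    weeks = sorted(sub["week"].unique())
    if len(weeks) != 3:
        raise ValidationError(
            f"dynamic calling needs exactly 3 weeks for {tissue!r}, got {weeks}")
    w_lo, w_mid, w_hi = weeks
    gm = group_means(beta, sub)
    m_lo, m_mid, m_hi = (gm[(tissue, w)] for w in weeks)

    sds = []
    for w in weeks:
        samples = sub.index[sub["week"] == w]
        if len(samples) < 2:
            logger.warning("dynamic %s W%d: fewer than 2 replicates, "
                           "SD undefined, probes excluded", tissue, w)
            sds.append(pd.Series(np.nan, index=beta.index))
            continue
        block = beta[list(samples)]
        s = block.std(axis=1, ddof=1)
        s[block.isna().any(axis=1)] = np.nan
        sds.append(s)
    sd_all = pd.concat(sds, axis=1)
    unstable = (sd_all >= sd_max).any(axis=1) | sd_all.isna().any(axis=1)

    complete = m_lo.notna() & m_mid.notna() & m_hi.notna()
    ok = complete & ~unstable
    gom = ok & (m_hi - m_lo >= delta) & \
        (m_mid >= m_lo - w18_tol) & (m_mid <= m_hi + w18_tol)
    lom = ok & (m_lo - m_hi >= delta) & \
        (m_mid <= m_lo + w18_tol) & (m_mid >= m_hi - w18_tol)

    def _stats(called: pd.Series, sign: float) -> pd.DataFrame:
        st = pd.DataFrame({
            f"mean_w{w_lo}": m_lo, f"mean_w{w_mid}": m_mid, f"mean_w{w_hi}": m_hi,
            "sd": sd_all.max(axis=1), "delta": sign * (m_hi - m_lo),
            "called": called})
        st.index = beta.index.rename("probe_id")
        return st

    return (CallSet("gom", tissue, beta.index[gom], _stats(gom, 1.0)),
            CallSet("lom", tissue, beta.index[lom], _stats(lom, -1.0)))


def callset_table(callsets: list[CallSet]) -> pd.DataFrame:
    """Called probes of several call sets as one tidy TSV-ready table."""
    rows = []
    for cs in callsets:
        st = cs.stats.loc[cs.probes]
        mean_cols = [c for c in st.columns if c.startswith("mean_")]
        for pid, row in st.iterrows():
            rows.append({"probe_id": pid, "tissue": cs.tissue, "kind": cs.kind,
                         **{c: row[c] for c in mean_cols},
                         "sd": row["sd"], "delta": row["delta"]})
    cols = ["probe_id", "tissue", "kind"]
    if rows:
        cols = list(rows[0].keys())
    return pd.DataFrame(rows, columns=cols)
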