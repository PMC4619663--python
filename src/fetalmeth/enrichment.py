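"""Enrichment odds ratios, nearest-gene mapping and signal metaprofiles.

Enrichment compares a called probe set against a background probe set (all
QC-passing probes on the array) per category with a 2x2 odds ratio
OR = (a*d)/(b*c) where a = called in the category, b = called outside it,
c = background in the category, d = background outside it.  When any cell is
zero the Haldane-Anscombe +0.5 correction is applied to all four cells for
the OR; significance comes from the Pearson chi-squared test on the raw
counts (1 df, no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntervalTrack, ValidationError, position_in_intervals, validate_manifest
from .regions import Region

UNSEGMENTED = "unsegmented"


@dataclass
class EnrichmentResult:
    category: str
    a: int  # called & in category
    b: int  # called & not
    c: int  # background & in category
    d: int  # background & not
    odds_ratio: float
    chi2_p: float


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with the Haldane-Anscombe +0.5 on all cells when any
    cell is zero.  A table with an all-zero column (the category covers the
    whole background, or none of it) carries no contrast and returns 1."""
    if (b == 0 and d == 0) or (a == 0 and c == 0):
        return 1.0
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float((a * d) / (b * c))


def chi2_p_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared p (1 df, no continuity correction) on raw counts;
    NaN for degenerate tables."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan")
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _or_and_p(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    return odds_ratio_2x2(a, b, c, d), chi2_p_2x2(a, b, c, d)


def enrichment_or(called: pd.Index, background: pd.Index,
                  labels: pd.Series) -> list[EnrichmentResult]:
    """One 2x2 enrichment per category of ``labels`` (a Series per probe)."""
    called = pd.Index(called)
    background = pd.Index(background)
    if len(called.difference(background)):
        raise ValidationError("called probes must be a subset of the background")
    missing = background.difference(labels.index)
    if len(missing):
        raise ValidationError(
            f"labels missing for {len(missing)} background probes")
    lab_bg = labels.loc[background]
    lab_called = labels.loc[called]
    n_called, n_bg = len(called), len(background)
    out = []
    for cat in sorted(lab_bg.unique()):
        a = int((lab_called == cat).sum())
        c = int((lab_bg == cat).sum())
        odds, p = _or_and_p(a, n_called - a, c, n_bg - c)
        out.append(EnrichmentResult(str(cat), a, n_called - a, c, n_bg - c,
                                    odds, p))
    return out


def probe_state_labels(manifest: pd.DataFrame,
                       segmentation: IntervalTrack) -> pd.Series:
    """Chromatin-state label per probe; probes outside any state are
    ``unsegmented``.  States are assumed to partition covered bases."""
    manifest = validate_manifest(manifest)
    out = np.full(len(manifest), UNSEGMENTED, dtype=object)
    per_chrom = {c: sub for c, sub in segmentation.intervals.groupby("chrom")}
    for chrom, sub in manifest.groupby("chrom", sort=False):
        seg = per_chrom.get(chrom)
        if seg is None:
            continue
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        labels = seg["label"].to_numpy()
        hit = position_in_intervals(sub["pos"].to_numpy(), starts, ends)
        rows = sub.index.to_numpy()
        ok = hit >= 0
        out[rows[ok]] = labels[hit[ok]]
    return pd.Series(out, index=pd.Index(manifest["probe_id"], name="probe_id"),
                     name="state")


def chromatin_state_enrichment(called: pd.Index, background: pd.Index,
                               manifest: pd.DataFrame,
                               segmentation: IntervalTrack,
                               ) -> list[EnrichmentResult]:
    return enrichment_or(called, background,
                         probe_state_labels(manifest, segmentation))


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.category, r.a, r.b, r.c, r.d, r.odds_ratio, r.chi2_p)
         for r in results],
        columns=["category", "a", "b", "c", "d", "odds_ratio", "chi2_p"])


# ---------------------------------------------------------------------------
# Nearest gene


def nearest_gene(items: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene (by TSS or TES distance) for each item.

    ``items`` needs columns item_id, chrom, pos — for regions use the
    midpoint (see :func:`regions_to_items`).  The distance is 0 for items
    inside a gene span; otherwise the minimum of the TSS and TES distances,
    signed negative when the item lies genomically left of the span.  Ties
    break by smaller |TSS distance|, then lexicographic gene id.
    """
    from .io import gene_tss_tes
    if not len(genes):
        raise ValidationError("genes must be nonempty")
    g = gene_tss_tes(genes)
    rows = []
    for chrom, sub in items.groupby("chrom", sort=False):
        gc = g[g["chrom"] == chrom]
        if not len(gc):
            for item in sub.itertuples(index=False):
                rows.append((item.item_id, "", np.nan))
            continue
        pos = sub["pos"].to_numpy()[:, None]
        tss = gc["tss"].to_numpy()[None, :]
        tes = gc["tes"].to_numpy()[None, :]
        lo = gc["tx_start"].to_numpy()[None, :]
        hi = gc["tx_end"].to_numpy()[None, :]
        d_tss = np.abs(pos - tss)
        d_tes = np.abs(pos - tes)
        inside = (pos >= lo) & (pos <= hi)
        dist = np.where(inside, 0, np.minimum(d_tss, d_tes))
        # minimise distance, tie-break on |TSS distance| then gene id
        choice = np.empty(len(pos), dtype=int)
        for r in range(len(pos)):
            cand = np.flatnonzero(dist[r] == dist[r].min())
            if len(cand) > 1:
                cand = cand[d_tss[r, cand] == d_tss[r, cand].min()]
            if len(cand) > 1:
                cand = cand[np.argsort(gc["gene_id"].to_numpy()[cand])[:1]]
            choice[r] = cand[0]
        ids = sub["item_id"].to_numpy()
        gids = gc["gene_id"].to_numpy()[choice]
        p = sub["pos"].to_numpy()
        sel_lo = gc["tx_start"].to_numpy()[choice]
        sel_hi = gc["tx_end"].to_numpy()[choice]
        signed = np.where(p < sel_lo, -(sel_lo - p),
                          np.where(p > sel_hi, p - sel_hi, 0))
        for item_id, gid, sd in zip(ids, gids, signed):
            rows.append((item_id, gid, int(sd)))
    return pd.DataFrame(rows, columns=["item_id", "gene_id", "distance"])


def regions_to_items(regions: list[Region]) -> pd.DataFrame:
    """Region midpoints as nearest-gene query items."""
    return pd.DataFrame(
        [(f"{r.chrom}:{r.start}-{r.end}", r.chrom, (r.start + r.end) // 2)
         for r in regions],
        columns=["item_id", "chrom", "pos"])


def probes_to_items(manifest: pd.DataFrame) -> pd.DataFrame:
    m = validate_manifest(manifest)
    return m.rename(columns={"probe_id": "item_id"})[["item_id", "chrom", "pos"]]


# ---------------------------------------------------------------------------
# Metaprofile


def region_metaprofile(signal: IntervalTrack, regions: list[Region],
                       flank: int = 5_000, n_bins: int = 50) -> np.ndarray:
    """Mean tag weight per bin across regions: ``n_bins`` bins over the
    upstream flank, the (length-scaled) region body, and the downstream
    flank — 3*n_bins values.  Each signal interval contributes its numeric
    label (weight 1 if the label is not numeric) at its midpoint."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    prof = np.zeros(3 * n_bins)
    if not regions:
        return prof
    sig = signal.intervals
    mids = (sig["start"].to_numpy() + sig["end"].to_numpy()) / 2.0
    weights = pd.to_numeric(sig["label"], errors="coerce").fillna(1.0).to_numpy()
    chroms = sig["chrom"].to_numpy()
    for r in regions:
        rs, re = r.start - 1, r.end  # half-open genomic span
        sel = (chroms == r.chrom) & (mids > rs - flank) & (mids <= re + flank)
        for m, w in zip(mids[sel], weights[sel]):
            if m <= rs:
                b = int((m - (rs - flank)) / flank * n_bins)
            elif m <= re:
                b = n_bins + int((m - rs) / (re - rs) * n_bins)
            else:
                b = 2 * n_bins + int((m - re) / flank * n_bins)
            prof[min(max(b, 0), 3 * n_bins - 1)] += w
    return prof / len(regions)
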