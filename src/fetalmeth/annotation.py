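"""CGI-centric and genic annotation of array probes, and per-feature summaries.

Each probe gets exactly one class on each of two axes:

* CGI axis — ``CGI`` (inside an island), ``SHO`` (shore, within 2 kb of an
  island edge), ``SHE`` (shelf, 2-4 kb), ``NC`` (non-CGI).  Outer boundaries
  are inclusive toward the nearer-island class: a probe exactly 2,000 bp from
  an edge is a shore, exactly 4,000 bp a shelf.
* genic axis — strand-aware windows around the TSS/TES: distal promoter
  ``DP`` (-10 kb..-1.5 kb), proximal promoter ``PP`` (-1.5 kb..+0.5 kb), gene
  body ``GB`` (+0.5 kb..TES), downstream ``DS`` (TES..+5 kb), else intergenic
  ``IG``.  A probe falling in windows of several genes or window types is
  resolved by the precedence PP > DP > GB > DS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import IntervalTrack, gene_tss_tes, position_in_intervals, validate_manifest

CGI_CLASSES = ("CGI", "SHO", "SHE", "NC")
GENIC_CLASSES = ("DP", "PP", "GB", "DS", "IG")
GENIC_PRECEDENCE = ("PP", "DP", "GB", "DS")


def classify_cgi(manifest: pd.DataFrame, cgi_track: IntervalTrack,
                 shore_bp: int = 2_000, shelf_bp: int = 2_000) -> pd.Series:
    """CGI/shore/shelf/non-CGI class per probe, from distance to the merged track."""
    manifest = validate_manifest(manifest)
    merged = cgi_track.merged().by_chrom() if len(cgi_track) else {}
    out = np.full(len(manifest), "NC", dtype=object)
    for chrom, sub in manifest.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos = sub["pos"].to_numpy()
        rows = sub.index.to_numpy()
        inside = position_in_intervals(pos, starts, ends) >= 0
        # distance to the nearest covered base for probes outside any island
        left = np.searchsorted(ends, pos, side="left") - 1  # nearest island to the left
        dist_left = np.where(left >= 0, pos - ends[np.clip(left, 0, None)], np.iinfo(np.int64).max)
        right = np.searchsorted(starts, pos, side="left")
        dist_right = np.where(right < len(starts),
                              starts[np.clip(right, None, len(starts) - 1)] + 1 - pos,
                              np.iinfo(np.int64).max)
        dist = np.minimum(dist_left, dist_right)
        cls = np.where(inside, "CGI",
                       np.where(dist <= shore_bp, "SHO",
                                np.where(dist <= shore_bp + shelf_bp, "SHE", "NC")))
        out[rows] = cls
    return pd.Series(out, index=pd.Index(manifest["probe_id"], name="probe_id"),
                     name="cgi_class")


def _genic_windows(genes: pd.DataFrame, distal=(10_000, 1_500),
                   proximal=(1_500, 500), body_offset=500, downstream=5_000,
                   ) -> dict[str, pd.DataFrame]:
    """1-based inclusive windows per class, strand-reflected for '-' genes."""
    g = gene_tss_tes(genes)
    plus = g["strand"].to_numpy() == "+"
    tss, tes = g["tss"].to_numpy(), g["tes"].to_numpy()
    win: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    win["PP"] = (np.where(plus, tss - proximal[0], tss - proximal[1]),
                 np.where(plus, tss + proximal[1], tss + proximal[0]))
    win["DP"] = (np.where(plus, tss - distal[0], tss + proximal[0] + 1),
                 np.where(plus, tss - proximal[0] - 1, tss + distal[0]))
    win["GB"] = (np.where(plus, tss + body_offset + 1, tes),
                 np.where(plus, tes, tss - body_offset - 1))
    win["DS"] = (np.where(plus, tes + 1, tes - downstream),
                 np.where(plus, tes + downstream, tes - 1))
    out = {}
    for cls, (lo, hi) in win.items():
        df = pd.DataFrame({"chrom": g["chrom"], "lo": np.maximum(lo, 1), "hi": hi})
        out[cls] = df[df["lo"] <= df["hi"]]
    return out


def classify_genic(manifest: pd.DataFrame, genes: pd.DataFrame,
                   precedence: tuple[str, ...] = GENIC_PRECEDENCE,
                   **window_kwargs) -> pd.Series:
    """DP/PP/GB/DS/IG class per probe with the configured precedence."""
    manifest = validate_manifest(manifest)
    out = np.full(len(manifest), "IG", dtype=object)
    assigned = np.zeros(len(manifest), dtype=bool)
    windows = _genic_windows(genes, **window_kwargs) if len(genes) else {}
    for cls in precedence:
        if cls not in windows or not len(windows[cls]):
            continue
        # merge the class windows (half-open start = lo-1, end = hi)
        track = IntervalTrack(cls, pd.DataFrame({
            "chrom": windows[cls]["chrom"],
            "start": windows[cls]["lo"] - 1,
            "end": windows[cls]["hi"]})).merged().by_chrom()
        for chrom, sub in manifest.groupby("chrom", sort=False):
            if chrom not in track:
                continue
            starts, ends = track[chrom]
            rows = sub.index.to_numpy()
            hit = position_in_intervals(sub["pos"].to_numpy(), starts, ends) >= 0
            take = hit & ~assigned[rows]
            out[rows[take]] = cls
            assigned[rows] |= hit
    return pd.Series(out, index=pd.Index(manifest["probe_id"], name="probe_id"),
                     name="genic_class")


def annotate(manifest: pd.DataFrame, cgi_track: IntervalTrack,
             genes: pd.DataFrame) -> pd.DataFrame:
    """Both annotation axes as one table (probe_id, cgi_class, genic_class)."""
    cgi = classify_cgi(manifest, cgi_track)
    genic = classify_genic(manifest, genes)
    return pd.DataFrame({"cgi_class": cgi, "genic_class": genic})


def group_means(beta: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean beta per (tissue, week) cell; NaN if any replicate missing."""
    cells = meta.groupby(["tissue", "week"], sort=True).groups
    cols = {}
    for (tissue, week), samples in cells.items():
        sub = beta[list(samples)]
        m = sub.mean(axis=1)
        m[sub.isna().any(axis=1)] = np.nan
        cols[(tissue, int(week))] = m
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["tissue", "week"])
    out.index = out.index.rename("probe_id")
    return out


def median_by_feature(beta: pd.DataFrame, meta: pd.DataFrame,
                      labels: pd.DataFrame) -> pd.DataFrame:
    """Median methylation per combined (CGI-class x genic-class) feature per
    (tissue, week); medians taken over the probe-level replicate means.
    Empty feature cells are emitted as missing (NaN), never zero."""
    if not beta.index.isin(labels.index).all():
        raise ValueError("labels must cover all probes in the beta matrix")
    gm = group_means(beta, meta)
    long = gm.stack(["tissue", "week"], future_stack=True).rename("beta").reset_index()
    lab = labels.copy()
    lab.index = lab.index.rename("probe_id")
    long = long.merge(lab.reset_index(), on="probe_id")
    med = (long.groupby(["cgi_class", "genic_class", "tissue", "week"])["beta"]
           .median().rename("median_beta").reset_index())
    full = pd.MultiIndex.from_product(
        [CGI_CLASSES, GENIC_CLASSES,
         sorted(meta["tissue"].unique()), sorted(meta["week"].unique())],
        names=["cgi_class", "genic_class", "tissue", "week"]).to_frame(index=False)
    return full.merge(med, how="left",
                      on=["cgi_class", "genic_class", "tissue", "week"])


def methylation_class_fractions(beta: pd.DataFrame, meta: pd.DataFrame,
                                thresholds: tuple[float, float] = (0.25, 0.75),
                                ) -> pd.DataFrame:
    """Fraction of probes hypo- (< t1), intermediately (t1..t2) and hyper-
    methylated (>= t2) per (tissue, week), on the replicate means."""
    t1, t2 = thresholds
    if not (0 < t1 < t2 < 1):
        raise ValueError(f"thresholds must be strictly increasing in (0,1): {thresholds}")
    gm = group_means(beta, meta)
    rows = []
    for (tissue, week) in gm.columns:
        v = gm[(tissue, week)].dropna().to_numpy()
        n = len(v)
        rows.append((tissue, week,
                     float((v < t1).sum()) / n,
                     float(((v >= t1) & (v < t2)).sum()) / n,
                     float((v >= t2).sum()) / n))
    return pd.DataFrame(rows, columns=["tissue", "week", "hypo",
                                       "intermediate", "hyper"])
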