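"""Empirical-null permutation test for region/peak overlap.

The observed statistic is the number of called regions whose genomic span
intersects (>= 1 bp) at least one peak.  The null distribution is built by
repeatedly sampling "DMR-like" regions from the probe manifest: runs of
consecutive array probes with inter-probe gaps below 1 kb and a shifted-
Poisson length (k = 3 + Poisson(2), mean 5 CpGs), matching the geometry of
called regions.  The two-sided empirical p doubles the smaller add-one-
corrected tail, capped at 1, so it can never be exactly zero.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalTrack, ValidationError, validate_manifest
from .regions import Region


@dataclass
class PermutationResult:
    observed_overlap: int
    null_overlaps: np.ndarray
    p_two_sided: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {"observed_overlap": int(self.observed_overlap),
                "p_two_sided": float(self.p_two_sided),
                "n_perm": int(self.n_perm), "seed": int(self.seed),
                "null_mean": float(np.mean(self.null_overlaps)),
                "null_sd": float(np.std(self.null_overlaps, ddof=1))}


class _ManifestRuns:
    """Precomputed run structure of a manifest for fast DMR-like sampling."""

    def __init__(self, manifest: pd.DataFrame, max_gap: int = 1_000):
        manifest = validate_manifest(manifest)
        self.manifest = manifest
        self.pos = manifest["pos"].to_numpy()
        self.chrom = manifest["chrom"].to_numpy()
        n = len(manifest)
        # chainable[i]: probe i+1 is on the same chromosome within max_gap
        chainable = np.zeros(n, dtype=bool)
        if n > 1:
            chainable[:-1] = (self.chrom[:-1] == self.chrom[1:]) & \
                (np.diff(self.pos) < max_gap)
        run_len = np.ones(n, dtype=np.int64)
        for i in range(n - 2, -1, -1):
            if chainable[i]:
                run_len[i] = run_len[i + 1] + 1
        self.run_len = run_len
        # eligible starts per k: indices ordered by run length descending
        self.order = np.argsort(-run_len, kind="stable")
        self.sorted_len = run_len[self.order]

    def n_eligible(self, k: int) -> int:
        return int(np.searchsorted(-self.sorted_len, -k, side="right"))


def _draw_lengths(rng: np.random.Generator, n: int, mean_cpgs: float,
                  min_cpgs: int) -> np.ndarray:
    return min_cpgs + rng.poisson(mean_cpgs - min_cpgs, size=n)


def _sample_draw(runs: _ManifestRuns, rng: np.random.Generator, n_regions: int,
                 mean_cpgs: float, min_cpgs: int, max_tries: int = 1_000,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One null draw: (start indices, lengths) of n_regions disjoint probe runs.

    Regions are placed sequentially: a length is drawn, a start is drawn
    uniformly over the probes eligible for that length, and the (length,
    start) pair is redrawn if the run would share probes with an
    already-placed region.  Lengths beyond the longest available run are
    simply redrawn as part of the same rejection.
    """
    if runs.n_eligible(min_cpgs) == 0:
        raise ValidationError(
            f"manifest has no probe run of length {min_cpgs}; cannot sample "
            "DMR-like regions")
    starts_out = np.empty(n_regions, dtype=np.int64)
    ks_out = np.empty(n_regions, dtype=np.int64)
    occ_s: list[int] = []
    occ_e: list[int] = []
    for r in range(n_regions):
        for _ in range(max_tries):
            k = int(min_cpgs + rng.poisson(mean_cpgs - min_cpgs))
            cnt = runs.n_eligible(k)
            if cnt == 0:
                continue
            s = int(runs.order[int(rng.random() * cnt)])
            e = s + k - 1
            i = bisect.bisect_left(occ_s, s)
            if (i > 0 and occ_e[i - 1] >= s) or \
                    (i < len(occ_s) and occ_s[i] <= e):
                continue
            occ_s.insert(i, s)
            occ_e.insert(i, e)
            starts_out[r], ks_out[r] = s, k
            break
        else:
            raise ValidationError(
                f"could not place {n_regions} non-overlapping DMR-like "
                "regions; try a smaller n_regions")
    order = np.argsort(starts_out)
    return starts_out[order], ks_out[order]


def sample_dmr_like(manifest: pd.DataFrame, n_regions: int,
                    rng: np.random.Generator, mean_cpgs: float = 5.0,
                    min_cpgs: int = 3, max_gap: int = 1_000) -> list[Region]:
    """Sample one set of disjoint DMR-like regions from the manifest."""
    runs = _ManifestRuns(manifest, max_gap)
    starts, ks = _sample_draw(runs, rng, n_regions, mean_cpgs, min_cpgs)
    regions = []
    ids = runs.manifest["probe_id"].to_numpy()
    for s, k in zip(starts, ks):
        j = s + k - 1
        regions.append(Region(
            chrom=str(runs.chrom[s]), start=int(runs.pos[s]),
            end=int(runs.pos[j]), probe_ids=ids[s:j + 1].tolist(),
            n_matching=int(k), n_nonmatching=0, kind="dmr_like"))
    return regions


def _peak_index(peaks: IntervalTrack) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return peaks.merged().by_chrom()


def _spans_overlap_any(chrom: np.ndarray, start: np.ndarray, end: np.ndarray,
                       peak_idx: dict) -> np.ndarray:
    """For 1-based spans [start, end], True where any peak intersects >= 1 bp."""
    out = np.zeros(len(start), dtype=bool)
    for c in np.unique(chrom):
        if c not in peak_idx:
            continue
        ps, pe = peak_idx[c]
        sel = chrom == c
        s, e = start[sel], end[sel]
        j = np.searchsorted(pe, s, side="left")  # first peak ending at/after s
        ok = j < len(ps)
        jj = np.clip(j, 0, len(ps) - 1)
        out[np.flatnonzero(sel)] = ok & (ps[jj] < e)
    return out


def count_overlapping_regions(regions: list[Region],
                              peaks: IntervalTrack) -> int:
    """Number of regions whose span intersects at least one peak."""
    if not regions:
        return 0
    chrom = np.array([r.chrom for r in regions])
    start = np.array([r.start for r in regions])
    end = np.array([r.end for r in regions])
    return int(_spans_overlap_any(chrom, start, end, _peak_index(peaks)).sum())


def empirical_p_two_sided(null: np.ndarray, observed: float) -> float:
    """Doubled, add-one-corrected smaller tail of the empirical null,
    capped at 1 (never exactly zero)."""
    null = np.asarray(null)
    n = len(null)
    upper = (int((null >= observed).sum()) + 1) / (n + 1)
    lower = (int((null <= observed).sum()) + 1) / (n + 1)
    return min(1.0, 2.0 * min(upper, lower))


def permutation_overlap_test(observed_regions: list[Region],
                             peaks: IntervalTrack, manifest: pd.DataFrame,
                             n_perm: int = 20_000, seed: int = 0,
                             mean_cpgs: float = 5.0, min_cpgs: int = 3,
                             max_gap: int = 1_000) -> PermutationResult:
    """Two-sided empirical test of region/peak overlap against DMR-like nulls."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not observed_regions:
        raise ValidationError("observed_regions must be nonempty")
    rng = np.random.default_rng(seed)
    peak_idx = _peak_index(peaks)
    observed = count_overlapping_regions(observed_regions, peaks)
    runs = _ManifestRuns(manifest, max_gap)
    n_regions = len(observed_regions)
    chrom_arr = runs.chrom
    null = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        starts, ks = _sample_draw(runs, rng, n_regions, mean_cpgs, min_cpgs)
        ends = starts + ks - 1
        null[p] = _spans_overlap_any(chrom_arr[starts], runs.pos[starts],
                                     runs.pos[ends], peak_idx).sum()
    return PermutationResult(observed_overlap=observed, null_overlaps=null,
                             p_two_sided=empirical_p_two_sided(null, observed),
                             n_perm=n_perm, seed=seed)
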