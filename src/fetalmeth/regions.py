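"""Clustering of called CpGs into regions (tHRs / dDMRs).

A region is a run of array probes on one chromosome that

* starts and ends with a probe matching the criterion,
* contains at least ``min_matching`` (default 3) matching probes,
* contains at most ``max_nonmatching`` (default 3) probes failing the
  criterion, counted over the whole region,
* has at most ``max_gap`` (default 1,000 bp) between consecutive member
  probes, matching or not.

The normative semantics are the *maximal* such intervals: enumerate every
probe interval, keep those satisfying all four constraints, drop intervals
contained in another surviving interval, and resolve any remaining overlaps
deterministically by repeatedly keeping the leftmost-starting candidate (the
longer one on equal starts) and discarding candidates that share probes with
it.  :func:`enumerate_regions_bruteforce` implements exactly that definition;
:func:`call_regions` is the equivalent linear-time scan used in production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalTrack, ValidationError


@dataclass
class Region:
    chrom: str
    start: int  # 1-based position of the first matching CpG
    end: int    # 1-based position of the last matching CpG
    probe_ids: list[str]
    n_matching: int
    n_nonmatching: int
    kind: str = ""
    tissue: str = ""

    def span(self) -> tuple[int, int]:
        return self.start, self.end


def _check_sorted(manifest: pd.DataFrame) -> None:
    got = list(zip(manifest["chrom"], manifest["pos"]))
    if got != sorted(got):
        raise ValidationError("manifest must be sorted by (chrom, pos)")


def _align_match(manifest: pd.DataFrame, match) -> np.ndarray:
    if isinstance(match, pd.Series):
        missing = pd.Index(manifest["probe_id"]).difference(match.index)
        if len(missing):
            raise ValidationError(
                f"match flags missing for {len(missing)} probes, "
                f"e.g. {sorted(missing)[:3]}")
        return match.reindex(manifest["probe_id"]).to_numpy(dtype=bool)
    arr = np.asarray(match, dtype=bool)
    if arr.shape != (len(manifest),):
        raise ValidationError("match vector length does not equal probe count")
    return arr


def _select_disjoint(candidates: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Leftmost-start (longer on ties) greedy selection of disjoint intervals."""
    out: list[tuple[int, int]] = []
    last_end = -1
    for i, j in sorted(candidates, key=lambda c: (c[0], -c[1])):
        if i > last_end:
            out.append((i, j))
            last_end = j
    return out


def _interval_valid(pos: np.ndarray, match: np.ndarray, i: int, j: int,
                    max_gap: int, min_matching: int, max_nonmatching: int) -> bool:
    if not (match[i] and match[j]):
        return False
    m = int(match[i:j + 1].sum())
    if m < min_matching or (j - i + 1 - m) > max_nonmatching:
        return False
    return bool((np.diff(pos[i:j + 1]) <= max_gap).all()) if j > i else True


def enumerate_regions_bruteforce(pos: np.ndarray, match: np.ndarray,
                                 max_gap: int = 1_000, min_matching: int = 3,
                                 max_nonmatching: int = 3) -> list[tuple[int, int]]:
    """Reference semantics on a single chromosome: all O(n^2) intervals,
    filtered, containment-pruned, then overlap-resolved.  Index pairs are
    inclusive probe indices."""
    n = len(pos)
    valid = [(i, j) for i in range(n) for j in range(i, n)
             if _interval_valid(pos, match, i, j, max_gap, min_matching,
                                max_nonmatching)]
    maximal = [(i, j) for (i, j) in valid
               if not any((a <= i and j <= b and (a, b) != (i, j))
                          for (a, b) in valid)]
    return _select_disjoint(maximal)


def _scan_chromosome(pos: np.ndarray, match: np.ndarray, max_gap: int,
                     min_matching: int, max_nonmatching: int,
                     ) -> list[tuple[int, int]]:
    """Linear-time scan equivalent to the brute-force semantics."""
    n = len(pos)
    if n == 0:
        return []
    # segments split at gaps > max_gap
    breaks = np.flatnonzero(np.diff(pos) > max_gap)
    seg_bounds = np.concatenate([[0], breaks + 1, [n]])
    mism = (~match).astype(np.int64)
    M = np.concatenate([[0], np.cumsum(mism)])      # prefix mismatches
    C = np.concatenate([[0], np.cumsum(match)])     # prefix matches
    # last matching index at or before t
    prev_match = np.full(n, -1, dtype=np.int64)
    last = -1
    for t in range(n):
        if match[t]:
            last = t
        prev_match[t] = last

    candidates: list[tuple[int, int]] = []
    for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
        prev_j = -2
        for i in range(s, e):
            if not match[i]:
                continue
            # furthest j in segment with mismatches(i..j) <= budget
            k = np.searchsorted(M, M[i] + max_nonmatching, side="right") - 1
            j_max = min(int(k) - 1, e - 1)
            j = int(prev_match[j_max]) if j_max >= i else -1
            if j < i or C[j + 1] - C[i] < min_matching:
                continue
            if j == prev_j:  # contained in the previous candidate
                continue
            candidates.append((i, j))
            prev_j = j
    return _select_disjoint(candidates)


def call_regions(manifest: pd.DataFrame, match, max_gap: int = 1_000,
                 min_matching: int = 3, max_nonmatching: int = 3,
                 kind: str = "", tissue: str = "") -> list[Region]:
    """Call maximal regions over a (chrom, pos)-sorted manifest.

    ``match`` is a boolean per probe (Series indexed by probe id, or an array
    aligned to the manifest rows): probes failing the criterion — including
    probes discarded by SD filters — count against the mismatch budget.
    """
    _check_sorted(manifest)
    manifest = manifest.reset_index(drop=True)
    flags = _align_match(manifest, match)
    regions: list[Region] = []
    for chrom, sub in manifest.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        sub_flags = flags[idx]
        for i, j in _scan_chromosome(pos, sub_flags, max_gap, min_matching,
                                     max_nonmatching):
            members = sub.iloc[i:j + 1]
            m = int(sub_flags[i:j + 1].sum())
            regions.append(Region(
                chrom=chrom, start=int(pos[i]), end=int(pos[j]),
                probe_ids=members["probe_id"].tolist(),
                n_matching=m, n_nonmatching=(j - i + 1) - m,
                kind=kind, tissue=tissue))
    return regions


def regions_to_bed(regions: list[Region], name: str = "regions") -> IntervalTrack:
    """Regions as a BED-convention track: half-open (start - 1, end)."""
    rows = [(r.chrom, r.start - 1, r.end,
             f"{r.kind}:{r.tissue}" if r.kind or r.tissue else name)
            for r in regions]
    return IntervalTrack(name, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label"]))


def regions_table(regions: list[Region]) -> pd.DataFrame:
    rows = [{"chrom": r.chrom, "start": r.start, "end": r.end,
             "kind": r.kind, "tissue": r.tissue, "n_matching": r.n_matching,
             "n_nonmatching": r.n_nonmatching,
             "probes": ",".join(r.probe_ids)} for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "tissue",
                                       "n_matching", "n_nonmatching", "probes"])
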