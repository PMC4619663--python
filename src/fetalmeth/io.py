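"""Readers and writers for the on-disk formats, plus the core in-memory containers.

Coordinate conventions
----------------------
Probe positions are 1-based (Illumina manifest convention).  Interval tracks
(CGIs, chromatin states, peaks, called regions exported to BED) are 0-based
half-open, the native BED convention.  The single conversion rule is: a
half-open interval ``[start, end)`` covers the 1-based positions
``start + 1 .. end``, so a 1-based position ``p`` lies inside it iff
``start < p <= end``.  :func:`position_in_intervals` implements that rule and
every membership query in the package goes through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A file or in-memory table violated a format contract."""


MANIFEST_COLUMNS = ["probe_id", "chrom", "pos"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tx_start", "tx_end"]
SAMPLE_COLUMNS = ["sample_id", "tissue", "week", "replicate", "sex"]


# ---------------------------------------------------------------------------
# Interval track


@dataclass
class IntervalTrack:
    """A named set of 0-based half-open genomic intervals with optional labels.

    ``intervals`` has columns chrom, start, end, label and is kept sorted by
    (chrom, start, end).
    """

    name: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals)
        if "label" not in df.columns:
            df["label"] = self.name
        df = df[["chrom", "start", "end", "label"]].copy()
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            bad = df["start"] >= df["end"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"track {self.name!r}: interval with start >= end at row {i}: "
                    f"{df.iloc[i].tolist()}")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "IntervalTrack":
        """Union of the intervals, per chromosome, labels dropped."""
        rows = []
        for chrom, sub in self.intervals.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e, self.name))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e, self.name))
        return IntervalTrack(self.name, pd.DataFrame(
            rows, columns=["chrom", "start", "end", "label"]))

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(starts, ends) arrays per chromosome, sorted by start."""
        return {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in self.intervals.groupby("chrom", sort=True)
        }


def position_in_intervals(pos: np.ndarray, starts: np.ndarray,
                          ends: np.ndarray) -> np.ndarray:
    """Membership of 1-based positions in sorted non-overlapping half-open intervals.

    A position ``p`` hits ``[s, e)`` iff ``s < p <= e``.  Returns the index of
    the containing interval, or -1.
    """
    pos = np.asarray(pos, dtype=np.int64)
    if len(starts) == 0:
        return np.full(pos.shape, -1, dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="left") - 1
    ok = idx >= 0
    hit = np.where(ok & (pos <= ends[np.clip(idx, 0, None)]), idx, -1)
    return hit


# ---------------------------------------------------------------------------
# Manifest / probes


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a probe manifest (probe_id, chrom, pos; pos 1-based)."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    df = manifest[MANIFEST_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValidationError("manifest positions must be >= 1")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id in manifest: {dup!r}")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Beta matrix


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    if beta.index.duplicated().any() or beta.columns.duplicated().any():
        raise ValidationError("beta matrix has duplicate row or column ids")
    vals = beta.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    bad &= ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value out of [0,1]: probe {beta.index[i]!r}, "
            f"sample {beta.columns[j]!r}, value {vals[i, j]!r}")
    return beta


def read_beta_matrix(path, manifest: pd.DataFrame) -> pd.DataFrame:
    """Read a probe x sample beta TSV, validate to [0,1], order rows by (chrom, pos)."""
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    validate_beta(beta)
    manifest = validate_manifest(manifest)
    known = pd.Index(manifest["probe_id"])
    unknown = beta.index.difference(known)
    if len(unknown):
        raise ValidationError(
            f"{len(unknown)} probes not in manifest, e.g. {sorted(unknown)[:5]}")
    order = [p for p in manifest["probe_id"] if p in set(beta.index)]
    return beta.loc[order]


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    validate_beta(beta)
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Sample sheet


def validate_sample_sheet(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.reset_index().columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    df = meta.reset_index() if meta.index.name == "sample_id" else meta.copy()
    df = df[SAMPLE_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    df["week"] = df["week"].astype(int)
    bad_sex = ~df["sex"].isin(["F", "M", "unknown"])
    if bad_sex.any():
        raise ValidationError(
            f"sex must be F/M/unknown, got {df.loc[bad_sex, 'sex'].iloc[0]!r}")
    return df.set_index("sample_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(meta: pd.DataFrame, path) -> None:
    validate_sample_sheet(meta).reset_index().to_csv(path, sep="\t", index=False)


def check_beta_meta_aligned(beta: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing = beta.columns.difference(meta.index)
    if len(missing):
        raise ValidationError(
            f"beta columns missing from sample sheet: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Gene models


def validate_gene_models(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene models missing columns: {missing}")
    df = genes[GENE_COLUMNS].copy()
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        g = df.loc[bad].iloc[0]
        raise ValidationError(
            f"gene {g['gene_id']!r}: strand must be '+' or '-', got {g['strand']!r}")
    df["tx_start"] = df["tx_start"].astype(np.int64)
    df["tx_end"] = df["tx_end"].astype(np.int64)
    bad = df["tx_start"] > df["tx_end"]
    if bad.any():
        g = df.loc[bad].iloc[0]
        raise ValidationError(f"gene {g['gene_id']!r}: tx_start > tx_end")
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in gene models")
    return df.sort_values(["chrom", "tx_start"], kind="mergesort").reset_index(drop=True)


def read_gene_models(path) -> pd.DataFrame:
    return validate_gene_models(pd.read_csv(path, sep="\t", dtype={"chrom": str,
                                                                   "strand": str}))


def write_gene_models(genes: pd.DataFrame, path) -> None:
    validate_gene_models(genes).to_csv(path, sep="\t", index=False)


def gene_tss_tes(genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware TSS/TES columns: TSS = tx_start on '+', tx_end on '-'."""
    genes = validate_gene_models(genes)
    plus = genes["strand"].to_numpy() == "+"
    out = genes.copy()
    out["tss"] = np.where(plus, genes["tx_start"], genes["tx_end"])
    out["tes"] = np.where(plus, genes["tx_end"], genes["tx_start"])
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path, name: str | None = None) -> IntervalTrack:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, label))
    track_name = name if name is not None else str(path)
    return IntervalTrack(track_name, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label"]))


def write_bed(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for row in track.intervals.itertuples(index=False):
            if row.label:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# Counts


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError("counts must be numeric")
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValidationError(
            f"negative count: gene {counts.index[i]!r}, sample {counts.columns[j]!r}")
    if not np.allclose(vals, np.round(vals)):
        raise ValidationError("counts must be integers")
    return counts.astype(np.int64)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path) -> None:
    validate_counts(counts).to_csv(path, sep="\t", index_label="gene_id")
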