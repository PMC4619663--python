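"""Synthetic 450k-style dataset generator with a machine-readable truth table.

The generator emulates the study design the callers target: four tissues
(amnion, muscle, adrenal, pancreas) sampled at gestational weeks 9, 18 and 22
with three biological replicates per cell.  CpG probes are laid out in
clusters (intra-cluster gaps < 1 kb, inter-cluster gaps > 4 kb) so that the
consecutive-CpG region caller has realistic geometry to work on; planted
blocks carry tissue-specific hypomethylation or gain/loss-of-methylation
trajectories, and every planted probe is recorded in a truth table.

Randomness: a single integer seed drives everything through
``numpy.random.SeedSequence(seed).spawn``; the spawned streams are consumed
in the fixed order manifest-layout (0), beta noise (1), expression (2),
chromatin states (3).  Peak simulation takes its own seed argument.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig, TruthTable
from .io import IntervalTrack, validate_manifest

_STREAMS = {"manifest": 0, "beta": 1, "expression": 2, "states": 3}


def _stream(config: SimulationConfig, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


# ---------------------------------------------------------------------------
# Layout: probe positions, blocks, CGIs, genes


def _layout(config: SimulationConfig) -> SimpleNamespace:
    """Deterministic genome layout derived from the config seed.

    Re-derivable at any time from the config alone, which is how
    :func:`simulate_beta` and :func:`simulate_expression` recover block and
    gene-link structure from just (manifest, config).
    """
    config.validate()
    rng = _stream(config, "manifest")

    # clusters: (size, planted-signal index or -1 for background)
    clusters: list[tuple[int, int]] = [
        (sig.n_cpgs_in_block, i) for i, sig in enumerate(config.planted)]
    n_background = config.n_cpgs - sum(s for s, _ in clusters)
    while n_background > 0:
        size = int(min(rng.integers(3, 13), n_background))
        clusters.append((size, -1))
        n_background -= size
    order = rng.permutation(len(clusters))
    clusters = [clusters[i] for i in order]

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 10_000 + int(rng.integers(0, 2_000)) for c in chroms}
    chrom_col: list[str] = []
    pos_col: list[int] = []
    block_col: list[int] = []
    cluster_records = []  # (chrom, first_pos, last_pos, size, signal_idx)
    for j, (size, sig_idx) in enumerate(clusters):
        chrom = chroms[j % len(chroms)]
        start = cursors[chrom]
        gaps = rng.integers(50, 401, size=size - 1) if size > 1 else np.empty(0, int)
        positions = start + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)
        chrom_col.extend([chrom] * size)
        pos_col.extend(positions.tolist())
        block_col.extend([sig_idx] * size)
        cluster_records.append((chrom, int(positions[0]), int(positions[-1]),
                                size, sig_idx))
        cursors[chrom] = int(positions[-1]) + int(rng.integers(5_000, 15_001))

    probes = pd.DataFrame({"chrom": chrom_col, "pos": pos_col,
                           "signal_idx": block_col})
    probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    probes.insert(0, "probe_id", [f"cg{i:07d}" for i in range(len(probes))])
    chrom_sizes = {c: cursors[c] + 20_000 for c in chroms}

    # probe positions per cluster, in emission order
    cluster_positions: list[list[int]] = []
    k = 0
    for size, _ in clusters:
        cluster_positions.append(pos_col[k:k + size])
        k += size

    # CGIs over clusters with >= 3 probes; each island covers a leading
    # sub-span of its cluster so the remaining probes fall in the
    # shore/shelf distance bands
    candidates = [ci for ci, (size, _) in enumerate(clusters) if size >= 3]
    if config.n_cgis > len(candidates):
        raise ConfigurationError(
            f"SimulationConfig.n_cgis: {config.n_cgis} CGIs requested but only "
            f"{len(candidates)} clusters with >= 3 probes")
    chosen = rng.choice(len(candidates), size=config.n_cgis, replace=False)
    cgi_rows = []
    for i in sorted(chosen.tolist()):
        ci = candidates[i]
        positions = cluster_positions[ci]
        chrom = cluster_records[ci][0]
        n_cover = int(rng.integers(3, len(positions) + 1))
        margin = int(rng.integers(50, 200))
        cgi_rows.append((chrom, positions[0] - 1 - margin,
                         positions[n_cover - 1] + margin, "CGI"))
    cgis = IntervalTrack("cgis", pd.DataFrame(
        cgi_rows, columns=["chrom", "start", "end", "label"]))

    # genes: one near each gom/lom block (up to n_genes), rest background
    dyn_blocks = [(i, sig) for i, sig in enumerate(config.planted)
                  if sig.kind in ("gom", "lom")]
    block_span = {r[4]: (r[0], r[1], r[2]) for r in cluster_records if r[4] >= 0}
    gene_rows = []  # chrom, strand, tx_start, tx_end, linked signal idx
    for i, sig in dyn_blocks[: config.n_genes]:
        chrom, first, last = block_span[i]
        length = int(rng.integers(3_000, 10_001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tx_start = last + int(rng.integers(200, 1_000))
            tx_end = tx_start + length
        else:
            tx_end = first - int(rng.integers(200, 1_000))
            tx_start = tx_end - length
            if tx_start < 1:
                strand, tx_start = "+", last + 500
                tx_end = tx_start + length
        gene_rows.append((chrom, strand, tx_start, tx_end, i))
    for _ in range(config.n_genes - len(gene_rows)):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(2_000, 20_001))
        tx_start = int(rng.integers(10_000, max(chrom_sizes[chrom] - length, 10_001)))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((chrom, strand, tx_start, tx_start + length, -1))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "strand", "tx_start",
                                             "tx_end", "signal_idx"])
    genes = genes.sort_values(["chrom", "tx_start"], kind="mergesort").reset_index(drop=True)
    genes.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(genes))])

    return SimpleNamespace(probes=probes, cgis=cgis, genes=genes,
                           chrom_sizes=chrom_sizes, config=config)


def _truth_from_layout(layout) -> TruthTable:
    config: SimulationConfig = layout.config
    probes = layout.probes
    kinds, targets = [], []
    for idx in probes["signal_idx"]:
        if idx < 0:
            kinds.append("neutral")
            targets.append("")
        else:
            sig = config.planted[idx]
            kinds.append(sig.kind)
            targets.append(sig.target_tissue or "")
    truth_probes = pd.DataFrame({
        "probe_id": probes["probe_id"], "kind": kinds,
        "target_tissue": targets, "block_id": probes["signal_idx"]})
    block_rows = []
    for idx, sub in probes[probes["signal_idx"] >= 0].groupby("signal_idx"):
        sig = config.planted[idx]
        block_rows.append((int(idx), sig.kind, sig.target_tissue or "",
                           sub["chrom"].iloc[0], int(sub["pos"].min()),
                           int(sub["pos"].max())))
    blocks = pd.DataFrame(block_rows, columns=[
        "block_id", "kind", "target_tissue", "chrom", "start", "end"])
    blocks = blocks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return TruthTable(probes=truth_probes, blocks=blocks,
                      chrom_sizes=dict(layout.chrom_sizes))


# ---------------------------------------------------------------------------
# Public operations


def simulate_manifest(config: SimulationConfig):
    """Generate (manifest, gene models, CGI track) for the configured genome."""
    layout = _layout(config)
    manifest = layout.probes[["probe_id", "chrom", "pos"]].copy()
    genes = layout.genes[["gene_id", "chrom", "strand", "tx_start", "tx_end"]].copy()
    return manifest, genes, layout.cgis


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for week in config.weeks:
            for rep in range(1, config.replicates_per_cell + 1):
                rows.append((f"{tissue}_W{week}_R{rep}", tissue, week, rep,
                             "F" if rep % 2 else "M"))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "week",
                                       "replicate", "sex"]).set_index("sample_id")


def _beta_draw(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Beta(mu*kappa, (1-mu)*kappa) draws; degenerate means 0/1 returned exactly."""
    interior = (mu > 0.0) & (mu < 1.0)
    a = np.where(interior, mu * kappa, 1.0)
    b = np.where(interior, (1.0 - mu) * kappa, 1.0)
    vals = rng.beta(a, b)
    return np.where(interior, vals, mu)


def simulate_beta(manifest: pd.DataFrame, config: SimulationConfig):
    """Draw the beta matrix for the design; returns (beta, meta, truth).

    Each observation is Beta-distributed around the planted (or background)
    mean with concentration ``noise_concentration``.
    """
    layout = _layout(config)
    manifest = validate_manifest(manifest)
    if not (manifest["probe_id"].to_numpy() == layout.probes["probe_id"].to_numpy()).all():
        raise ConfigurationError(
            "manifest does not match the layout generated by this config")
    n = len(manifest)
    tissues, weeks = list(config.tissues), list(config.weeks)
    t_index = {t: i for i, t in enumerate(tissues)}

    mu = np.full((n, len(tissues), len(weeks)), config.background_mean)
    sig_idx = layout.probes["signal_idx"].to_numpy()
    for i, sig in enumerate(config.planted):
        rows = np.flatnonzero(sig_idx == i)
        if not len(rows):
            continue
        mu[rows, :, :] = sig.background_mean
        if sig.kind != "neutral":
            traj = np.asarray(sig.mean_trajectory, dtype=float)
            mu[rows[:, None], t_index[sig.target_tissue], np.arange(len(weeks))] = traj

    meta = sample_sheet(config)
    rng = _stream(config, "beta")
    cols = {}
    for tissue in tissues:
        for wi, week in enumerate(weeks):
            cell_mu = mu[:, t_index[tissue], wi]
            for rep in range(1, config.replicates_per_cell + 1):
                cols[f"{tissue}_W{week}_R{rep}"] = _beta_draw(
                    rng, cell_mu, config.noise_concentration)
    beta = pd.DataFrame(cols, index=pd.Index(manifest["probe_id"], name="probe_id"))
    beta = beta[meta.index]
    return beta, meta, _truth_from_layout(layout)


def simulate_peaks(truth: TruthTable, frac_overlap_lom: float, n_decoys: int,
                   seed: int, peak_width: int = 600) -> IntervalTrack:
    """Binding-peak track: a configurable fraction of LOM blocks get a peak,
    decoy peaks land away from every planted block."""
    if not 0.0 <= frac_overlap_lom <= 1.0:
        raise ConfigurationError(
            f"frac_overlap_lom: {frac_overlap_lom} not in [0,1]")
    lom = truth.blocks[truth.blocks["kind"] == "lom"].reset_index(drop=True)
    if not len(lom):
        raise ConfigurationError("truth table contains no lom blocks")
    rng = np.random.default_rng(seed)
    n_overlap = int(round(frac_overlap_lom * len(lom)))
    chosen = np.sort(rng.choice(len(lom), size=n_overlap, replace=False))
    rows = []
    for i in chosen:
        blk = lom.iloc[int(i)]
        mid = (int(blk["start"]) + int(blk["end"])) // 2
        s0 = max(mid - peak_width // 2, 0)
        rows.append((blk["chrom"], s0, s0 + peak_width, "peak"))

    # block spans per chrom for decoy rejection (1-based inclusive spans)
    spans = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
             for c, sub in truth.blocks.groupby("chrom")}
    chrom_sizes = truth.chrom_sizes or {
        c: int(sub["end"].max()) + 20_000 for c, sub in truth.blocks.groupby("chrom")}
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed = 0
    attempts = 0
    while placed < n_decoys:
        attempts += 1
        if attempts > 1_000 * max(n_decoys, 1):
            raise ConfigurationError(
                "could not place decoy peaks clear of planted blocks")
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        s0 = int(rng.integers(0, chrom_sizes[chrom] - peak_width))
        if chrom in spans:
            bs, be = spans[chrom]
            # candidate covers 1-based s0+1 .. s0+peak_width
            if ((bs <= s0 + peak_width) & (be >= s0 + 1)).any():
                continue
        rows.append((chrom, s0, s0 + peak_width, "peak"))
        placed += 1
    return IntervalTrack("peaks", pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label"]))


def simulate_expression(genes: pd.DataFrame, truth: TruthTable,
                        config: SimulationConfig):
    """Negative-binomial count matrix with per-gene-set temporal trends.

    Genes linked to GOM blocks fall ``expression_fold_change``-fold from the
    first to the last week in the block's target tissue; LOM-linked genes rise
    by the same factor.  Library sizes vary at least two-fold across samples.
    Returns (counts, gene_sets) where gene_sets maps
    {gom_linked, lom_linked, background} to gene-id lists.
    """
    if not len(genes):
        raise ConfigurationError("genes: must be nonempty")
    layout = _layout(config)
    if not (genes["gene_id"].to_numpy() == layout.genes["gene_id"].to_numpy()).all():
        raise ConfigurationError(
            "gene models do not match the layout generated by this config")
    lg = layout.genes
    link_kind = np.array([
        config.planted[i].kind if i >= 0 else "" for i in lg["signal_idx"]])
    link_tissue = np.array([
        (config.planted[i].target_tissue or "") if i >= 0 else ""
        for i in lg["signal_idx"]])
    gene_sets = {
        "gom_linked": lg.loc[link_kind == "gom", "gene_id"].tolist(),
        "lom_linked": lg.loc[link_kind == "lom", "gene_id"].tolist(),
        "background": lg.loc[link_kind == "", "gene_id"].tolist(),
    }
    # per-tissue sets: a linked gene trends only in its block's target tissue
    for tissue in config.tissues:
        for kind in ("gom", "lom"):
            sel = (link_kind == kind) & (link_tissue == tissue)
            gene_sets[f"{kind}_linked_{tissue}"] = lg.loc[sel, "gene_id"].tolist()

    meta = sample_sheet(config)
    rng = _stream(config, "expression")
    n_genes, n_samples = len(lg), len(meta)
    base = rng.lognormal(mean=np.log(config.expression_base_mean), sigma=0.5,
                         size=n_genes)
    factors = 2.0 ** rng.uniform(-0.6, 0.6, size=n_samples)
    if factors.max() / factors.min() < 2.0:
        factors[int(np.argmax(factors))] = 2.0 * factors.min()

    weeks = list(config.weeks)
    fc = config.expression_fold_change
    week_frac = {w: (weeks.index(w) / (len(weeks) - 1) if len(weeks) > 1 else 1.0)
                 for w in weeks}
    cols = {}
    for si, (sample_id, row) in enumerate(meta.iterrows()):
        frac = week_frac[int(row["week"])]
        mult = np.ones(n_genes)
        in_tissue = link_tissue == row["tissue"]
        mult[in_tissue & (link_kind == "lom")] = fc ** frac
        mult[in_tissue & (link_kind == "gom")] = fc ** (-frac)
        mean = base * mult * factors[si]
        if config.expression_dispersion == 0:
            counts = np.round(mean).astype(np.int64)
        else:
            nb_n = 1.0 / config.expression_dispersion
            counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mean))
        cols[sample_id] = counts.astype(np.int64)
    counts = pd.DataFrame(cols, index=pd.Index(lg["gene_id"], name="gene_id"))
    return counts, gene_sets


_STATE_LABELS = ("TSS", "Enhancer", "Transcribed", "Repressed", "Quiescent")
_STATE_PROBS = (0.08, 0.17, 0.25, 0.15, 0.35)


def simulate_chromatin_states(truth: TruthTable, config: SimulationConfig,
                              ) -> IntervalTrack:
    """Chromatin-state partition of each chromosome.

    Random segments (2-10 kb) get background state labels; planted
    hypomethylated and LOM blocks are overwritten as Enhancer, GOM blocks as
    Repressed, so state enrichment of called CpGs is testable against truth.
    """
    rng = _stream(config, "states")
    block_state = {"tissue_hypo": "Enhancer", "lom": "Enhancer", "gom": "Repressed"}
    rows = []
    for chrom in sorted(truth.chrom_sizes):
        size = truth.chrom_sizes[chrom]
        blocks = truth.blocks[truth.blocks["kind"].isin(block_state)
                              & (truth.blocks["chrom"] == chrom)]
        # planted spans as half-open intervals, padded slightly
        spans = sorted((max(int(b.start) - 101, 0), int(b.end) + 100,
                        block_state[b.kind]) for b in blocks.itertuples())
        cuts = [0]
        labels = []
        pos = 0
        while pos < size:
            seg = int(rng.integers(2_000, 10_001))
            pos = min(pos + seg, size)
            cuts.append(pos)
            labels.append(str(rng.choice(_STATE_LABELS, p=_STATE_PROBS)))
        # flatten base segments minus planted spans, then add planted spans
        bounds = sorted({c for c in cuts}
                        | {s for s, _, _ in spans} | {e for _, e, _ in spans})
        span_starts = np.array([s for s, _, _ in spans], dtype=np.int64)
        span_ends = np.array([e for _, e, _ in spans], dtype=np.int64)
        span_labels = [lab for _, _, lab in spans]
        cuts_arr = np.array(cuts, dtype=np.int64)
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a >= size:
                break
            b = min(b, size)
            j = int(np.searchsorted(span_starts, a, side="right")) - 1
            if j >= 0 and a < span_ends[j]:
                label = span_labels[j]
            else:
                label = labels[int(np.searchsorted(cuts_arr, a, side="right")) - 1]
            if rows and rows[-1][0] == chrom and rows[-1][2] == a and rows[-1][3] == label:
                rows[-1] = (chrom, rows[-1][1], b, label)
            else:
                rows.append((chrom, a, b, label))
    return IntervalTrack("chromatin_states", pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label"]))


def simulate_dataset(config: SimulationConfig, frac_overlap_lom: float = 0.5,
                     n_decoys: int = 200, peaks_seed: int | None = None,
                     ) -> SimpleNamespace:
    """One-call convenience: the full synthetic dataset as a namespace."""
    manifest, genes, cgis = simulate_manifest(config)
    beta, meta, truth = simulate_beta(manifest, config)
    peaks = simulate_peaks(truth, frac_overlap_lom, n_decoys,
                           seed=peaks_seed if peaks_seed is not None
                           else config.seed + 10_007,
                           peak_width=config.peak_width)
    counts, gene_sets = simulate_expression(genes, truth, config)
    states = simulate_chromatin_states(truth, config)
    return SimpleNamespace(manifest=manifest, genes=genes, cgis=cgis,
                           beta=beta, meta=meta, truth=truth, peaks=peaks,
                           counts=counts, gene_sets=gene_sets, states=states,
                           config=config)
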