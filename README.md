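# fetalmeth

Analysis toolkit for DNA methylation dynamics across human fetal tissue
development on 450k-style arrays.  It answers two questions about a
tissue x gestational-week methylation matrix: *which CpGs mark a tissue*
(relative hypomethylation of one tissue against all others, stable across
weeks), and *which CpGs are remodelled during development* (gain or loss of
methylation between the first and last week).  Around those callers it
provides the supporting machinery a study of this kind needs: CpG-island /
genic annotation, clustering of called CpGs into regions, odds-ratio
enrichment against annotations and chromatin states, nearest-gene mapping,
an empirical permutation test for overlap with transcription-factor binding
peaks, and CPM expression-trend summaries — plus a synthetic-data generator
with planted truth that makes the whole pipeline testable end to end.

## The rules at the core

With β̄(t, w) the replicate-mean beta of a probe in tissue *t* at week *w*:

* **Tissue-specific hypomethylation** — probe called for tissue *t\** iff
  for every other tissue *t* and every week *w*:
  β̄(t, w) − β̄(t\*, w) ≥ 0.20, and SD of the *t\** samples (pooled over
  weeks) < 0.10.
* **Gain / loss of methylation (GOM/LOM)** — within one tissue with weeks
  9 < 18 < 22: GOM iff β̄(22) − β̄(9) ≥ 0.20 with β̄(18) ≥ β̄(9) − 0.05 and
  β̄(18) ≤ β̄(22) + 0.05; LOM is the mirror image.  Probes with replicate
  SD ≥ 0.10 in any (tissue, week) group are discarded first.
* **Regions (tHRs / dDMRs)** — maximal runs of probes that start and end
  with a calling probe, contain ≥ 3 calling probes and ≤ 3 non-calling
  probes, with ≤ 1 kb between consecutive members.  A brute-force
  maximal-interval enumeration is the normative reference; the production
  scan is linear-time and exactly equivalent.
* **Peak overlap** — observed: regions intersecting ≥ 1 peak; null: 20,000
  draws of "DMR-like" probe runs (mean 5 CpGs, gaps < 1 kb) from the
  manifest; two-sided empirical p = min(1, 2·(#{null ≥ obs}+1)/(n+1)).
* **Enrichment** — per category, OR = (a·d)/(b·c) of called vs all
  QC-passing probes, Haldane–Anscombe-corrected on zero cells, Pearson
  chi-squared significance.

Full definitions, boundary conventions and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the full synthetic study — simulate, annotate, call, cluster, enrich,
permute, summarise — from one command:

```python
from fetalmeth.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(outdir="demo_run", seed=3, n_perm=2000))
print(summary["calls"]["muscle"])
print(summary["regions"]["muscle"])
print(summary["permutation"]["observed_overlap"],
      summary["permutation"]["p_two_sided"])
```

prints (seed 3):

```
{'hypo': 170, 'gom': 165, 'lom': 165}
{'tHR': 34, 'dDMR_gom': 33, 'dDMR_lom': 33}
66 0.0009995002498750624
```

The default simulation plants, per tissue, 34 hypomethylated + 33 GOM + 33
LOM blocks of 5 CpGs each (planted effect 0.30 beta, replicate noise
κ = 200): the callers recover all 170/165/165 planted probes per tissue,
every 5-probe block is clustered into one region, and the binding-peak
track — built to overlap half of the 132 LOM blocks — yields an observed
overlap of 66 regions, beyond all 2,000 null draws, so the two-sided
empirical p is its minimum attainable value 2/2001 ≈ 0.001.

The same stages are available as CLI subcommands over files
(`fetalmeth simulate | annotate | call-hypo | call-dynamic | call-regions |
enrich | perm-overlap | expr-trends | run-all`):

```bash
fetalmeth simulate --outdir sim --seed 2
fetalmeth annotate --manifest sim/manifest.tsv --cgis sim/cgis.bed \
                   --genes sim/genes.tsv --out labels.tsv
```

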