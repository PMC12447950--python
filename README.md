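# regennet

Gene-regulatory network inference and promoter-motif analysis for
regenerating zebrafish lateral-line neuromasts.

After hair-cell (HC) ablation, neuromasts regenerate new HCs from their
central supporting cells (SCs) within hours, driven by the rapid
induction of fate genes such as *atoh1a*. Reconstructing the
gene-regulatory network (GRN) of this response from time-stamped
single-cell RNA-seq — and asking which transcription factor sits at its
top — requires a chain of analyses: pseudotime ordering of cells, scoring
of directed TF→target interactions from lagged expression, combination of
trajectory-specific predictions into one capped network, outdegree-based
hub ranking, and discovery and positional mapping of the hub's
DNA-binding motif in target promoters. `regennet` implements that chain
as a reusable, fully tested library, together with a synthetic-data
generator that plants known structure (a designated hub, per-edge lags,
promoter motif instances at known TSS offsets) so that every stage can be
validated end to end without any external download.

## What it computes

* **Edge scores.** For a pseudotime-ordered trajectory, cells are
  averaged into `n_bins` equal-occupancy bins and each directed pair is
  scored as

  `score(TF → g) = max over lag in 1..L of | rho(x_TF[t], x_g[t + lag]) |`

  where `rho` is the Spearman rank correlation of the binned,
  log-normalized series — a stand-in, with the same contract, for trained
  CNN predictors whose score tables can be loaded instead.
* **Combined network.** Per-pair maxima across trajectory tables
  (absence means unscored, not zero), then the top *k* = 20 regulators per
  gene; hubs ranked by outdegree; a zeta-distribution maximum-likelihood
  fit with bootstrap Kolmogorov–Smirnov goodness-of-fit provides an
  "approximately scale-free" diagnostic for the outdegree distribution.
* **Motifs.** TSS-centered ±50 kb windows, 100 bp fragments labeled
  target/control, discriminative word discovery ranked by one-sided
  Fisher enrichment (Bonferroni over all 4^w seeds), bipartite-motif
  scanning (forward CNNC half + spacer + reverse-complement GNNG half,
  both strands) and PWM scanning with *exact* p-values by dynamic
  programming over the achievable-score lattice; positional enrichment as
  the per-10 bp-bin ratio of mean-normalized, 50 bp-smoothed,
  min-max-scaled target vs control occurrence frequencies.
* **Promoter elements.** Progressive global alignment of orthologous
  promoter fragments (match +1, mismatch −1, gap −2), annotation of
  bipartite Ybx1 DNA sites, the DLE RNA element (AGCAC followed by a
  CCA-N6-TGG stem-loop), and per-species conservation calls.
* **Statistics.** Welch/pooled t-tests (one- and two-sided), Cohen's *d*
  with noncentral-*t* power, and the one-sided Fisher exact test, all
  from first principles and checked against enumeration/quadrature
  oracles.

## Worked example

```sh
python examples/01_hub_recovery.py
```

```
planted hub: tf000 (200 true targets)
   tf  outdegree  rank
tf000        262     1
tf023        243     2
tf037        195     3
tf020        187     4
tf014        183     5

top-ranked regulator: tf000 with outdegree 262 -> recovered the planted hub
```

The generator plants `tf000` as a master regulator driving 80 % of the
genome with lagged dynamics; the full pipeline (QC → normalization → PC1
pseudotime → lagged scoring → max-combination → top-20 capping) ranks it
first by outdegree. `examples/02_motif_enrichment.py` scans simulated
promoters for the bipartite motif and prints the TSS-relative enrichment
peak (`median ratio within 300 bp of the TSS: 1.47 vs beyond 1 kb:
0.18`); `examples/03_promoter_elements.py` annotates a DLE, its
stem-loop and bipartite sites in orthologue fragments and calls the site
conserved in the cyprinid sequences but not the mouse one;
`examples/04_group_statistics.py` runs the genotype comparison
statistics.

An end-to-end run with artifacts, manifest and checksums:

```sh
regennet demo-config demo.yaml --outdir demo_out
regennet run demo.yaml
```

## Layout

```
src/regennet/      simulate, preprocess, scoring, network, motif,
                   elements, stats, pipeline, cli
examples/          one short narrative script per capability
tests/             unit, property and acceptance suites
docs/methods.md    models, assumptions, parameter choices, limitations
```
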