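# Methods

This note documents the models behind `regennet`, the defaults that
matter, what the synthetic-data generator does and does not emulate, and
the design choices made where the design was genuinely open.

## Expression model and the planted study

`simulate_grn` plants a directed TF→target network over `n_tfs`
transcription factors and `n_targets` downstream genes. One designated
hub regulates `ceil(hub_out_fraction · (n_genes − 1))` genes — the
non-TF effector program first — with per-edge lags (1–2 pseudotime bins)
and signed weights (|w| ∈ [0.7, 1.2], half repressive). Every hub target
additionally receives one *secondary* co-regulator at 0.3–0.5 of the hub
edge's weight, assigned round-robin over the non-hub TFs, and a sparse
layer of strong extra edges with truncated-discrete-power-law counts
(exponent 2.5, inverse-CDF sampling) keeps the non-hub outdegree profile
heavy-tailed; four "anchor" TFs carry 6–10 such strong edges and play the
role of the curated, assay-derived regulators used for train/validation
splits. Genes are topologically ordered and edges point forward only, so
the network is a DAG. The curated ground truth holds primary edges only;
secondary co-regulation is sub-threshold modulation, not assay-grade
truth.

`simulate_expression` gives every root gene a latent log-expression
trace z(t) on the unit pseudotime interval and propagates it through the
network: a regulated gene's trace is the weight-normalized sum of its
regulators' *deviations from their own baselines*, evaluated `lag/n_bins`
earlier, added to a weighted baseline — so repression inverts dynamics
without collapsing expression levels, and a single unit-weight edge
copies its regulator's trace exactly (which the exactness tests rely
on). Gene- and bin-level Gaussian noise (sd `noise_sd`, default 0.5) is
added to the mean traces of regulated genes, making each downstream gene
an individual realization rather than a literal copy; counts are Poisson
draws of the exponentiated means. `noise_sd = 0` is the fully
deterministic regime: the matrix then carries continuous expected counts
so that noise-free recovery statements can be exact.

Trace families encode the study's qualitative biology:

* the **hub** is a monotone ramp (log-slope 2.5–3.5), the analogue of a
  master regulator climbing through early regeneration;
* **bystander TFs** are three-component sinusoid mixtures (3–10 cycles
  per trajectory) — transient programs whose rank correlation with any
  monotone series is near zero at every lag;
* a block of hub-independent **temporal-program genes** (monotone ramps
  of mixed sign) anchors the trajectory's principal axis to time, as the
  broad injury-response programs of real regenerating tissue do;
* flat, high-expression **housekeeping genes** pin per-cell library
  sizes. Without them, total-count normalization imprints a shared
  monotone drift on every gene and hands randomly chosen bystander TFs a
  stable spurious correlation with the hub's program. Likewise, noise is
  deliberately *not* added to bystander TF root traces: they are the
  scorer's regressors, and a frozen noise realization there again
  manufactures stable spurious correlations rather than modeling
  target-level variability.

True pseudotime is evenly spaced within and across the six sampled
timepoints (0, 0.5, 1, 3, 5, 10 hours post ablation). The generator does
not attempt to match real library-size, dropout or batch structure, nor
ambient RNA or doublets; what the passing tests show is that the
pipeline's inferential machinery is correct under a clean lagged-GRN
model, not that the model describes real neuromast data.

## Preprocessing and pseudotime

QC keeps cells with strictly more than 300 and strictly fewer than 6,000
expressed genes and a mitochondrial count fraction below 5 % (prefix
list, default `mt-`), applied globally. Normalization scales each cell
to 10,000 total counts and applies log1p; raw counts are kept alongside
and zeros are preserved exactly. The SC trajectory keeps central SCs
over 0–10 hpa; the HC trajectory keeps central SCs 0–3, HC progenitors
1–5, and young plus mature HCs 3–10 hpa, all endpoints inclusive.

Pseudotime is an explicit stand-in for principal-curve fitting: cells
are projected on the first principal axis of the trajectory's normalized
data, the axis is oriented so the earliest timepoint's mean projection
does not exceed the latest's, and projections are min-max scaled to
[0, 1]. The only property downstream stages use is a monotone cell
ordering, which this preserves whenever a dominant monotone axis of
variation exists (the generator guarantees one; real data may not).
Externally computed pseudotime can be supplied instead.

## Edge scoring and the number of bins

The built-in scorer bins cells into `n_bins` equal-occupancy pseudotime
bins and scores each directed pair by the maximum absolute Spearman
correlation between the TF's series and the target's series shifted
forward by 1..`max_lag` bins (default 5). Scores are treated as ranks
only; sign and best lag are kept as auxiliary columns.

`n_bins` defaults to 60. At 20 bins the null distribution of the
max-over-lags statistic is wide and heavy-tailed (correlations on ~18
points, maximized over five lags), and under top-20 capping a handful of
bystander TFs with lucky null correlations accumulate outdegrees
comparable to a genuine hub's; with 60 bins of ~9 cells each (540-cell
default study) the null tightens enough that the planted hub separates
with a comfortable margin (98/100 seeds in design-phase calibration,
median outdegree margin ≈ 29). Equal-occupancy (not equal-width) bins
keep the statistic robust to nonuniform cell density.

Held-out evaluation ranks each validation TF's candidates by score and
reports average precision (the step-function PR integral, via
scikit-learn) plus precision-at-k; training-split TFs are excluded. The
scorer's AUPRC exceeds its own permutation-null mean by ≈ 0.3 on average
across seeds; single-TF AUPRCs are high-variance because validation TFs
have only a handful of true targets among ~250 candidates.

## Network construction

`combine_max` merges score tables by per-pair maximum; a pair absent
from a table contributes nothing (absence means unscored, not zero, so
one trajectory's coverage gaps cannot drag maxima down).
`top_k_regulators` keeps each gene's 20 best-scoring regulators, ties at
the boundary broken by lexicographic TF id; self-edges are removed
before selection (re-enable with a flag — the hub's autoregulation is
biological context, not a construction rule). The scale-free diagnostic
fits a zeta distribution by maximum likelihood with `x_min = 1` (the
full distribution, since no tail cutoff is prescribed), measures the KS
distance with a closed-form Hurwitz-zeta CDF, and bootstraps the
distance under the fitted law; the flag is descriptive, true when the
bootstrap p-value exceeds 0.1.

## Motif analysis

Windows are `[TSS − 50 kb, TSS + 50 kb)` in 0-based half-open
coordinates, clipped at contig ends; minus-strand genes are
reverse-complemented with offsets negated so upstream is always
negative. Hits are located by motif start. Fragments tile each window
from its 5′ end in 100 bp pieces, the short remainder dropped, labeled
by gene membership.

Discriminative discovery is a deliberately simple procedure with the
same contract as heavier tools: exact words are counted per fragment,
ranked by the one-sided hypergeometric (Fisher) p-value of the
target/control × contains-word table, Bonferroni-corrected over all 4^w
candidate words, and the top seeds are extended to PWMs by averaging
base frequencies over their occurrences with ±2 bp of flank
(pseudocount 0.5).

Bipartite scanning matches forward half + spacer + reverse-complement
half (defaults CNNC/GNNG, spacer 0–10 bp — the spacer is configurable
because only the logo, not the spacing, is published) by exact
degenerate matching on both strands, with palindromic duplicates
collapsed by (start, span). PWM scanning computes log-odds in bits
against a 0-order background (estimable from control fragments,
uniform by default) and derives p-values *exactly*: the dynamic program
accumulates partial scores left-to-right exactly as a per-word scan
would, so the achievable-score lattice reproduces enumeration
bit-for-bit, with probabilities summed per score. Windows containing N
never match.

Positional enrichment bins hit-start offsets into 10 bp bins across the
window, divides each series by its mean, smooths with a centered 50 bp
(5-bin) rolling mean that shrinks at the edges, min-max scales to
[0, 1], and forms the per-bin ratio `(f_target + ε)/(f_control + ε)`
with ε = 10⁻⁶ guarding empty control bins.

**Resolution of the ratio's peak.** The argmax of the per-bin ratio is a
noisy location estimate: with 10,000 target hits at Normal(0, 500 bp)
against 10,000 uniform controls over ±50 kb, the target curve is nearly
flat across ±200 bp while the min-max-scaled control carries ~40 %
relative noise per smoothed bin, so the argmax concentrates on the peak
only at a resolution of several hundred bp (the unit tests assert
±1.5 kb; pinning it to ±50 bp would require roughly three orders of
magnitude more control hits). The identity property — identical target
and control multisets give a ratio of exactly 1 everywhere — is exact.

## Promoter elements

Pairwise alignment is global Needleman–Wunsch with linear gap costs
(match +1, mismatch −1, gap −2 — "simple alignment" defaults, exposed in
config) and a deterministic high-road traceback; multiple alignment is
progressive over a guide order of decreasing pairwise identity, scoring
a sequence against the running profile by sum-of-pairs. De-gapping any
row reproduces its input byte-for-byte.

Annotation reports all (possibly overlapping) occurrences of: bipartite
sites (CNNC then GNNG within the spacer range), the DLE (literal AGCAC
followed within 0–10 bp by a stem-loop) and the stem-loop itself
(CCA-N6-TGG, with the arm complementarity recorded as a structural
check). The element itself is not hard-coded — the module annotates the
described components on user-supplied orthologue sequences. Conservation
calls de-gap each species' segment under the reference feature's
alignment columns and re-test the pattern; an all-gap segment is absent.
Internal-ribosome-entry annotation is out of scope (no detection rule is
defined), and the Notch C-site check takes a user-supplied pattern
rather than a default. There is no RNA secondary-structure energy model;
the stem-loop check is pattern plus complementarity only.

## Statistics

The t-test defaults to the unequal-variance (Welch) statistic with
Welch–Satterthwaite degrees of freedom — the safer reading when the
variance assumption is unstated — with the pooled-variance classical
test available. One-sided tests are in the direction mean(a) > mean(b).
Cohen's d uses the standard pooled SD; power is post-hoc, from the
noncentral t distribution with noncentrality `d·sqrt(n_a n_b/(n_a+n_b))`
at the observed effect size and group sizes. The one-sided Fisher exact
test returns the hypergeometric tail P(X ≥ a) under fixed margins
(log-gamma arithmetic); a zero row or column margin leaves a single
achievable table and p = 1. Larva-level replicate ids are carried but
not modeled (data points are pooled, matching the quantification
design); there is no mixed-effects modeling.

## Pipeline and reproducibility

`RunConfig` holds every tunable with the study's printed values as
defaults where they exist (QC 300/6,000/5 %, scale 10,000, k = 20,
50 kb, 100 bp, 10 bp, 50 bp). One master seed derives per-stage seeds by
SHA-256 of `"{seed}:{stage}"` (mod 2³¹), so stages re-run independently
yet reproducibly. Stages communicate through files; the manifest records
the config hash and SHA-256 checksums of each stage's inputs and
outputs, giving byte-identical manifests for identical configs and a
checksum short-circuit that skips unchanged stages. The demo
configuration lowers only the QC gene-count floor, because the synthetic
panel has a few hundred genes rather than a transcriptome.

## Problem sizes used in the test suite

The acceptance suite runs 20 full studies at 50 TFs × 200 targets × 540
cells for hub recovery, 10 seeds each for pseudotime and discovery,
10,000 draws for the power-law fit, 10,000 replications for t-test
calibration, 100,000 simulated experiments for the power oracle, and 100
random pairs against the exhaustive alignment optimum; the whole suite
completes in well under a minute of compute beyond collection.

## Known limitations

* The generator's dynamics (ramps, sinusoid pulses, bin-level Gaussian
  noise, Poisson emission) are chosen for identifiability, not realism;
  absolute scores and AUPRCs on real data will differ.
* PC1 pseudotime assumes one dominant monotone axis; branching or
  cyclic trajectories need an external pseudotime.
* The lagged-correlation scorer cannot distinguish a regulator from a
  faster-responding sibling target on the same upstream signal; the
  planted benchmark avoids such degeneracies by construction.
* Exact PWM p-values enumerate the achievable-score lattice, which is
  exponential in the worst case; it is intended for motif widths up to
  ~12.
* The positional-enrichment argmax has a sampling resolution of
  hundreds of bp at realistic hit counts (see above).
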