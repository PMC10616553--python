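# Methods

`phosnet` implements the computational core of a TMT phosphoproteomics
study design: quantify reporter-ion intensities against in-plex reference
pools, test for treatment-induced changes with empirical-Bayes moderated
statistics, infer kinase signaling networks from significant phosphosite
changes and a signed site-specific prior, and score directional PTM
signatures. Because real deposited MS data are not required, a synthetic
generator produces data with known ground truth, and every stage is
validated by recovery and calibration experiments.

## Study design and the synthetic generator

The default design is three cell lines, each in its own TMT10 plex of
eight biological samples (four drug-treated, four vehicle) plus two
reference-pool channels, giving 24 non-reference samples. The reference
pool emulates a lysate mixture of all study samples: in the generator the
reference channels are the within-plex geometric mean of the eight sample
channels plus channel noise. The noise model for the reference channels is
not uniquely determined by the design; geometric mean + Gaussian log2
noise is a documented assumption.

The generator plants signal in three layers:

* **Prior network** — `n_kinases x targets_per_kinase` signed relations.
  Each relation carries a relation sign (phosphorylates +1 /
  dephosphorylates −1) and a site effect on the *target's* activity
  (activatory / inhibitory / unknown). Site positions are unique per
  substrate protein; residues are drawn from {S, T, Y}.
* **Ground truth** — a planted activity a(k) ∈ {+1, −1} per perturbed
  kinase propagates to target sites as an expected log2 fold change
  σ·a(k)·δ, where σ is the relation sign and δ the effect size in log2
  units. All other sites, including decoy background sites, expect 0.
* **Reporter tables** — one PSM-level table per plex. Feature baseline
  abundances are log-normal (log2 mean 20, sd 2 — a realistic reporter
  dynamic range); each peptide yields `psm_per_peptide` PSM rows with
  independent Gaussian channel noise on the log2 scale (default sd 0.2,
  a typical MS2 reporter-ion spread). Each substrate protein additionally
  yields unmodified peptides so protein-level quantification and
  phosphosite-to-protein adjustment are exercised. Localization
  probabilities are 90% in [0.9, 1.0] and 10% in [0.3, 0.75) to exercise
  the localization filter.

Gross outliers model isolated reporter-ion spikes: an affected PSM row
(probability `outlier_rate`) gets ±`outlier_shift` added to **one** random
sample channel. The reference channels are formed from the underlying
abundances before artifacts are planted, since the physical reference pool
predates any single-spectrum measurement error. Missing values erase
random intensity cells. Every planted effect, outlier, and missing cell is
recorded in a truth table so recovery is measurable.

What the generator does **not** emulate: isotope-impurity cross-talk,
co-isolation interference, ratio compression, retention-time structure,
peptide-specific ionization efficiency, and non-Gaussian heavy-tailed
noise. Passing recovery tests therefore demonstrates the correctness of
the analysis logic under its own assumptions, not performance on real
spectra.

## Reporter-ion quantification

PSM log2 ratios are taken against the geometric mean of the reference
channels within each row's plex; rows with no positive reference intensity
are dropped and counted. Within each sample, Dixon's Q test (r10
statistic, two-sided α = 0.05 critical values for n = 3–30) is applied
recursively to the PSMs of each peptide with at least three PSMs: the more
extreme end's gap/range ratio is tested and the extreme value removed
until no rejection remains or fewer than three values are left. For n > 30
the table runs out and 3×MAD trimming substitutes. Peptide values are
medians of retained PSMs; protein and phosphosite values are medians of
peptides. Dixon removal is applied at the PSM→peptide step only: the
rollup is described in terms of PSM counts, and peptide-level medians are
already robust.

Sample alignment fits a two-component Gaussian mixture to each sample's
log ratios (EM, initialized by a 25th/90th-percentile split, tolerance
1e-8, at most 500 iterations, variance floor) and subtracts the global
mode of the fitted density — the maximizer of the likelihood of a single
observation — locating it by a dense grid plus bounded scalar refinement.
Interpreting "centered at the maximum likelihood" as the mixture-density
mode (rather than the major component mean) is a deliberate choice: the
mode is the argmax of the fitted likelihood and is robust to an
asymmetric minor component. When a sample has fewer than 30 values, is
degenerate, or EM fails to converge, the median/MAD fallback is used and
logged. Scaling then standardizes spread jointly: each sample is divided
by its trimmed SD — computed over values inside the 5th–95th percentile
band of both log ratios and reporter intensities (the mean reference
intensity per feature serves as the intensity covariate) — and multiplied
by the geometric mean of all samples' trimmed SDs so the average scale is
preserved.

Sample relationships are visualized by classical (Torgerson) metric MDS on
complete-case features: double-centered squared Euclidean distances,
eigendecomposition, coordinates defined up to sign and rotation.

## Differential statistics

Each cell line is analyzed separately — with one plex per cell line there
is no cross-plex random effect to model, so the mixed-effects formulation
reduces to a per-feature two-group comparison within the plex. For each
feature with at least two non-missing replicates per condition:

    b  = mean(treated) − mean(vehicle)
    s² = pooled residual variance, d residual df
    s²_post = (d0·s0² + d·s²) / (d0 + d)
    t  = b / (s_post · sqrt(1/n_t + 1/n_v)),   df = d0 + d

The prior (d0, s0²) is estimated from the ensemble of sample variances by
moment matching on log s² using the digamma/trigamma relations of the
scaled-F hierarchy (features with zero residual df excluded; a
non-positive excess variance yields d0 = ∞). This reproduces the standard
empirical-Bayes moderated t; the implementation agrees with R/limma's
`eBayes` to machine precision on shared input (a cross-check in the test
suite). Missing values are not imputed by default; a per-plex
feature-minimum imputation is available but off, since model-based
imputation schemes are not reproducible from their name alone.

Benjamini–Hochberg step-up adjustment controls the FDR. Phosphosite
changes are normalized to the parent protein: adjusted b = b_site −
b_protein, SE combined in quadrature, df by Satterthwaite, p recomputed
and re-adjusted; sites whose parent protein lacks quantification are
removed and counted. A feature is significant iff adjusted p < 0.05 and
|b| > 0.58 (the log2 equivalent of ±50%, a threshold motivated by TMT
ratio compression), and at site level additionally localization
probability ≥ 0.75 and available protein quantification. Non-significant
features carry direction 0 and do not enter the causal analysis.

## Causal network inference

Significant sites at a chosen change-detection FDR cutoff form a change
set with directions ±1. A prior relation "A (de)phosphorylates B@s"
becomes a causal edge iff:

1. the detected site matches the prior site exactly (residue + position;
   no positional tolerance window);
2. A's activity direction a is evidenced — an activatory site change d on
   A gives a = d, an inhibitory one a = −d, A's total-protein change gives
   a = its sign; site evidence outranks protein evidence, and any
   contradiction among evidences excludes A (conflict handling is not
   specified by the matching rule itself, so exclusion is the conservative
   choice);
3. the target direction satisfies the consistency equation d = σ·a.

Protein activity significance uses label randomization: for each protein
with measured prior targets and each hypothesized activity, the statistic
is the number of measured target sites whose direction satisfies the
consistency equation. The null redistributes the direction labels over
**all measured sites** — preserving the global up/down/unchanged counts —
rather than per-protein counts; the dataset is the natural sampling frame
for "label randomization", and the choice is isolated behind one function.
p = (#null ≥ observed + 1)/(B + 1) with B = 10,000 by default; BH across
proteins within each hypothesis; activation and inactivation are tested
separately and a protein is reported once with the smaller adjusted p
(ties toward the larger consistent-target set), called at adjusted
p < 0.1. Because the statistic is a small integer count, the permutation
p-value is discrete; for calibration experiments the test exposes a
uniform tie-broken ("randomized") p-value, which is exactly U(0,1) under
the null for a calibrated test. Inference always uses the plain
conservative p.

The FDR sweep repeats matching and activity testing at change-detection
cutoffs 0.1, 0.01, 0.001, 0.0001 and assembles a heatmap matrix of
direction·log10(adjusted p) per called protein per cutoff. Call counts
need not be monotone in the cutoff: stricter change detection can remove
noise labels and *increase* the number of significant activity calls.
Subgraphs are induced by breadth-first search within a hop radius of genes
of interest; networks serialize to SIF plus an edge-attribute table and
round-trip bytewise.

## PTM signature enrichment

Signatures are GMT-dialect site sets with optional per-member direction
annotations ("u"/"d"). Members annotated "d" have their signed statistic
flipped before ranking. All measured sites are ranked by (flipped)
statistic descending; the running sum adds |stat|^w / Σ_hits|stat|^w at
members and subtracts 1/(N − N_hits) at non-members; the enrichment score
is the running-sum value of maximal absolute deviation, ties resolved
toward the positive extreme. The weight exponent defaults to w = 0.75 (the
PTM-SEA convention); the default ranking statistic is the moderated t of
the protein-adjusted site, both configurable and recorded in output
metadata. Significance is by site-label permutation (membership redrawn B
≥ 1000 times; for sets without direction annotations the ranking is fixed
and a fast hit-position path reproduces the full running sum exactly).
NES = ES / mean(|null ES| of the same sign); p compares |ES| with
same-sign null scores with the +1 correction; BH across signatures.
Site-label (rather than sample) permutation is used because per-sample
data may be unavailable at the enrichment stage.

## Pipeline

`run_pipeline` executes generate → quantify → test → infer → enrich as a
seeded, configured run: each cell line is an independent sub-run, overlap
sets of shared same-direction significant changes are computed across cell
lines, and all tables, network files, heatmap and volcano data, MDS
coordinates, and a manifest (verbatim config, config hash, seeds,
versions) are written to one artifact directory. Every output table
carries the config hash in a header comment; identical config + seed
reproduces identical bytes. The `phosnet` CLI exposes `simulate`, `quant`,
`diff`, `causal`, `enrich`, and `all`.

## Validation experiments and their problem sizes

The test suite and `scripts/acceptance.py` recompute, at modest problem
sizes chosen for quick iteration:

* **Oracle equivalence** — causal matching vs exhaustive truth-table
  enumeration on hundreds of ≤4-node networks; BH vs a hand-written
  step-up oracle on 1000 random vectors; the weighted-KS score vs a
  brute-force running sum on every hit pattern of lists up to length 8.
* **Calibration** — randomized activity-test p-values and enrichment
  p-values over 50 null seeds (KS against uniform); moderated-t raw p
  fraction below 0.05 on 2000 pure-noise features.
* **Recovery** — five kinases perturbed down (δ = 1, noise 0.2, ten
  measured targets each, B = 10,000) recovered as inactivated through the
  full chain with no wrong-direction calls; mixture alignment recovering a
  planted 0.2 shift within 0.05 at n = 5000.
* **Outlier removal** — with 4 PSMs per peptide and single-channel spikes
  planted at rate 0.05, recursive Dixon filtering removes ≈90% of planted
  ±4 log2 outliers. Its clean-cell loss is ≈1.3–1.4%: the α = 0.05
  critical table rejects ~5% of clean peptide groups by construction,
  which at 4 PSMs per group puts a ≥1.25% floor on clean loss. A stated
  1% target is therefore not attainable at this α and group size, and the
  corresponding check is expected to fail; it is kept at the stated bound
  rather than weakened.

## Known limitations

* The two-group moderated-t contrast approximates, but does not reproduce,
  mixed-effects implementations used with multi-plex designs.
* Exact site matching ignores positional ambiguity between neighboring
  residues; a tolerance window is out of scope.
* Multi-hop "chains of evidence" are represented implicitly as the union
  of consistent single edges; paths are not enumerated.
* Enrichment numerics follow the weighted-KS definition given above and
  are not intended to match any specific external implementation
  number-for-number.
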