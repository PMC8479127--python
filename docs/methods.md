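# Methods

## Input model

The atomic datum is a published QTL: trait code, linkage group, peak
position (cM) on its study's own genetic map, and a 95% confidence
interval. Trait codes are element symbols with optional tissue prefixes
(`rs` rosette, `ro` root, `sh` shoot); `rsZn` and `Zn` are distinct traits
throughout — folding them would change every presence count. The
vocabulary is a closed set of 39 codes (20 elements plus the 19 prefixed
variants that occur in the source studies). A peak less than 0.5 cM
outside its linkage-group span is treated as table rounding and clamped
with a warning; larger excursions are rejected.

## Consensus map

Maps are merged per linkage group. Maps are visited in descending marker
count (ties by population id); each map is aligned onto the growing
consensus by a piecewise-linear transform fitted on shared markers, with
terminal segments extrapolated at the nearest segment's slope and clamped
at 0 cM. A shared marker never anchors its own alignment (leave-one-out):
otherwise it would always land on its current consensus position and the
weighted mean below would degenerate to the first map's coordinate. After
all maps are aligned, a final re-averaging pass places every marker at the
weighted mean of its aligned positions — weight = the source map's marker
count on that linkage group, overridable per population — which makes the
result insensitive to visit order for shared markers. Markers unique to
one map are placed by the same transform (interpolation between their
nearest shared neighbours). Residual order inversions after averaging are
snapped to monotonicity by a running maximum.

Genome lengths are corrected for unobserved chromosome ends by the
Hubert–Hedgecock adjustment: average spacing χ = (Σ linkage-group
lengths)/(markers − groups), and each group gains 2χ. Both raw and
adjusted totals are reported, since published map totals are often the
plain sums.

## Projection

A QTL is transferred onto the consensus by the local affine transform
through the shared flanking markers nearest to its peak on each side (the
two nearest shared markers when the peak lies outside the shared span);
the CI moves through the same transform, coordinates are clamped to the
consensus span, and the positional standard deviation is s = CI width /
3.92, reading the reported interval as a 95% Gaussian interval. When a
study reports no CI, the expected width for a RIL design, 530/(N·R²) with
population size N and R² in percent, substitutes and the record is
flagged. Likelihood-curve-based projection is out of reach because
original scan curves are never published.

## Meta-QTL mixture model

Projected peaks on one chromosome follow x_i ~ Σ_k π_k N(μ_k, s_i²) with
known s_i. EM with precision-weighted M-steps fits K = 1..K_max (default
min(20, n−1)); initialisation is evenly spaced position quantiles plus 10
jittered restarts, tolerance 1e-8 on the log-likelihood, at most 1000
iterations, fixed default seed 17, and the log-likelihood is asserted
non-decreasing at every iteration. Weights are floored at 1e-8 during
iteration; a final weight below 1/(2n) marks the component empty and the
best non-degenerate restart is preferred. The free-parameter count is
p = 2K−1 (K means, K−1 weights; variances are known), giving

- AIC = −2L + 2p, AICc = AIC + 2p(p+1)/(n−p−1) (inadmissible for
  n ≤ p+1), AIC3 = −2L + 3p, BIC = −2L + p·ln n,
- AWE = −2Lc + 2p(3/2 + ln n) with Lc the classification log-likelihood
  under hardened assignments (Banfield–Raftery form).

K is selected by a vote: the K minimal on at least three of the five
criteria wins; failing that, the K winning the most criteria; ties go to
the smaller K. Per-criterion ties credit the smallest K attaining the
minimum. The mixture approach is intended for chromosomes with more than
10 QTLs; below that a warning is logged and the fit proceeds.

Each component k becomes a meta-QTL at position Σ r_ik x_i/s_i² ÷
Σ r_ik/s_i² with variance 1/Σ r_ik/s_i² and a 95% CI of ±1.96 sd (a
χ²-based interval would be an alternative; 1.96·sd matches the Gaussian
reading used throughout). Flanking markers are the nearest consensus
markers outside the CI. Input order never matters: QTLs are processed
sorted by position.

## Trait co-localization

Meta-QTLs are scored 0/1 per trait (exact string match, fixed vocabulary
column order). For target T ∈ {Zn, Fe, Mn}, the expected proportion is
p = n_T/n_MQTL, rounded half-up to two decimals (0.70/0.52/0.64 on the
packaged table). A trait co-occurring with T in n_co regions is tested
with χ² = n_co(1−p)²/p, df = 1, upper tail. This statistic — linear in
n_co — is the form consistent with every cell of the published
co-localization table, which our golden test reproduces in full; it is
not the textbook goodness-of-fit statistic, and an exact mode using the
unrounded proportion is available (`rounded_p=False`) but deviates from
the printed values in the third decimal. No multiple-testing correction
is applied, matching the original analysis. Summary percentages use one
decimal, round-half-up; note that for 22 of 33 regions supported by ≥6
populations the computed share is 66.7% (a published figure of 60.67%
appears to be a typo and is not reproduced).

## Physical anchoring and GWAS collinearity

Genetic intervals become physical ones through a marker → (chromosome, bp
interval) anchor table: from the left flank's start to the right flank's
end; an unanchored flank is replaced by the nearest anchored consensus
marker and the interval flagged `closest-marker fallback`. (Recovering
anchors by sequence alignment is data preparation, not part of the
method, so the anchor table is an input.) Candidate genes are GFF3 `gene`
features overlapping the interval — any overlap, strand ignored; GFF3
coordinates are 1-based inclusive, converted losslessly to the internal
0-based half-open convention; BED output is 0-based half-open.

GWAS SNPs are intersected with meta-QTL intervals in two modes:
`within` (strict containment, lo ≤ position ≤ hi) and `nearest` (each SNP
assigned to the nearest trait-matched interval on its chromosome,
distance 0 when contained). On the packaged tables the nearest mode
reproduces the published pairing exactly (9 SNP–MQTL pairs: 2 Zn, 3 Fe,
4 Mn); strict containment yields 8 because one published Zn SNP
(12.43 Mb) lies 2.1 Mb outside its reported interval (14.53–14.72 Mb) —
likely a typo in the source table, preserved as-is in the fixture.

## Density profiles

Locus density is counted in half-open bins [k·w, (k+1)·w) of distance
from the centromere, both arms pooled (per-arm profiles via a flag);
default widths 50 cM (genetic) and 10 Mb (physical). Gene density uses
absolute-coordinate 0.1 Mb bins with each gene assigned by its start.
Centromere positions are configuration; shipped A. thaliana defaults are
approximate and overridable. Pearson correlation between per-chromosome
counts uses the usual t-based two-sided P.

## Synthetic study generator

No raw multi-population QTL database for this system is public, so the
generator emulates one at the published scale and is itself first-class,
tested code. Defaults: 12 RIL populations; 5 chromosomes of 110.76,
105.64, 86.32, 96.72 and 114.57 cM (consensus-scale lengths); 30 backbone
markers per chromosome of which a guaranteed 60% core is shared by every
population and the rest included with probability 0.5; marker jitter
N(0, 0.5 cM), order-preserving; 3 true loci per chromosome, one drawn
uniformly from the central 60% of each third of the chromosome so
neighbours stay resolvable; detection probability 0.6 per population ×
locus; original CI widths truncated-Normal(10.88, 4) above 1 cM (the
published studies' mean original CI); spurious unlinked QTLs at rate 0.05
per population × locus slot, uniform on the chromosome; a Zn/Fe/Mn
co-occurrence probability of 0.5 inside each planted locus's trait set
(loosely motivated by the observed 0.4–0.7 co-localization frequencies —
a simulation choice, not an estimate).

Two design points keep the generator coherent with how real studies
behave. First, a study's peak error scales with its own reported
precision: the CI width w is drawn first and the peak error is
N(0, σ·w/10.88) with σ = 2 cM, so the error sd averages 2 cM at the mean
CI while narrow-CI studies are genuinely more accurate — a study's peak
and CI come from the same data, and breaking that link floods the
known-variance mixture with apparent outliers. Second, peaks and CIs are
expressed in the population's own (jittered) map coordinates, as a real
study reports positions on its own map. The toy gene annotation places
genes by rejection sampling with acceptance weight 0.15 + 0.85·(distance
from centromere / arm length), reproducing centromere-depleted,
(sub)telomere-enriched gene density; marker anchors follow a monotone
cM→bp map at 250 kb/cM. A single RNG stream is seeded once per run (map,
QTL and annotation streams use fixed offsets of the one seed) and draws
are consumed in documented order, so identical (config, seed) pairs give
byte-identical outputs.

What the generator does **not** emulate: genotype-level noise (no
meioses, no scan statistics), segregation distortion, study-specific CI
conventions (1-LOD vs bootstrap), shared parental lines between
populations, and trait-correlation structure beyond the Zn/Fe/Mn block.
Passing recovery tests therefore show that the clustering and selection
machinery works when published summaries mean what they claim; they do
not validate behaviour under miscalibrated source studies.

## Recovery benchmark and known limitations

The end-to-end benchmark simulates 20 replicates (seeds 1–20), runs the
full pipeline, and scores each replicate: the number of mixture
components must be within ±1 of the 3 planted loci on every chromosome,
and detected positions must match distinct planted loci within 2 cM
(optimal one-to-one matching, with planted positions first mapped onto
the consensus scale through the marker correspondence). A component whose
members are in majority spurious QTLs is counted as a background
detection — the correct inference for an isolated stray QTL — and
excluded from the comparison. Under the defaults the K criterion passes
in 20/20 replicates, the mean meta-QTL CI is below the mean input CI
(well below half) in 20/20, but the joint position criterion holds in
14/20: the inverse-variance-weighted position of a cluster whose members
all happen to have wide CIs has a standard error of ~1.3 cM, so roughly
2% of the 15 clusters per replicate miss the 2 cM bar — a fat tail driven
by CI-width heterogeneity, not by a removable implementation error. The
corresponding acceptance test asserts the stricter 80% bar and fails
honestly; the per-cluster behaviour, not the per-replicate conjunction,
is the robust quantity.

Other limitations: the consensus merge is position arithmetic (no
re-estimation of recombination fractions); projection assumes local
affinity between maps; the χ² co-localization test inherits the published
statistic's non-standard form; gene counts against a real annotation
depend on feature-type and overlap conventions the original analysis did
not state ("any overlap, type=gene" here); and the published 33-meta-QTL
result itself cannot be recomputed because the underlying 483-QTL
database was never released — the packaged result table stands in as the
fixed input for the co-localization, summary and GWAS analyses.
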