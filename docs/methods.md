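# Methods

This note documents the models and procedures implemented in `pepzone`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions used
throughout.

## Antigen reconstruction and pepscan tiling (`seqcore`)

The mature β2GP1 sequence (326 aa) is not shipped as a FASTA but
reconstructed by stitching the 79 overlapping 15-mers of the packaged array
table. Stitching asserts character-level agreement on every overlap and
full coverage of `[1, max(end)]`, so a single transcription error anywhere
in the table is detected rather than silently propagated. This also
sidesteps the signal-peptide offset ambiguity of database entries (the
precursor numbering differs from the mature chain by 19 residues).

Tiling follows the array design: peptide *i* spans
`[4(i−1)+1, 4(i−1)+15]`; when the next regular window would overrun the
C-terminus, a single final window anchored to the last residue is emitted
(residues 312–326) instead of a short or overhanging peptide. All
coordinates are 1-based inclusive; BED-style 0-based half-open coordinates
appear only at export and are flagged in the file header.

Sushi-domain boundaries are not published as residue numbers; they
are inferred from the table's domain labels. For each adjacent pair, a
boundary residue *b* must satisfy `end ≤ b` for every peptide labelled with
the left domain, `start > b` for the right domain, and `start ≤ b < end`
for every spanning ("k–k+1") peptide. The feasible sets are {61, 62},
{119, 120}, {183, 184}, {243, 244}; the defaults (61, 120, 183, 243, 326)
each come from the feasible set, and any member reproduces the table's
label column exactly. `infer_domain_boundaries` recomputes these sets from
any labelled tiling.

Midpoints of even-length spans round down; every array peptide is 15
residues long, so this rule never affects the shipped design and exists
only to make the function total and deterministic.

The hexapeptide LKTPRV (reported for the ILA-1 monoclonal antibody at
58–63) does not occur in the reconstructed sequence — residues 58–63 read
LKCTPR. It is most plausibly a phage-display mimotope rather than an exact
substring; the motif search reports its absence and no special-casing is
done.

## Fixed-circle quantification and positivity (`array_quant`)

Spot signal is the integrated optical density: the sum of pixel intensities
whose centers satisfy `(r−row)² + (c−col)² ≤ radius²` for the layout's
fixed circle. No adaptive segmentation, grid finding, or morphology QC is
performed, and no per-pixel background subtraction: background is handled
once, at the threshold stage. Images are interpreted as signal-positive
(brighter = more binding); an `invert` flag supports optical-density-style
scans. Pixel-center membership is the simplest reproducible circle rule;
the radius is a layout parameter, never auto-fitted.

The per-slide threshold is `mean(negative spots) + k·SD(sampled peptides)`
with `k = 2` and a seeded, recorded, without-replacement sample of 15
peptide spots (sample SD, n−1 denominator). Sampling is uniform over all
peptide spots — nothing excludes high-signal spots from the sample, which
matches how such thresholds are computed slide-by-slide in practice and
only makes the threshold conservative. A `use_all_peptides` switch replaces
the sample with every peptide spot. Positivity is strict
(`IOD > threshold`), so a spot exactly at threshold is negative. Under a
Gaussian null in which all spots share one intensity distribution, the
measured mean specificity is ≈ 95.6% (10,000-slide Monte Carlo in
`scripts/acceptance.py`), consistent with the intended > 95% specificity of
a mean + 2 SD rule.

## Antigenicity profiles and zones (`antigenicity`)

The recognition fraction of a peptide is the share of *all* sera calling it
positive — sera that recognize nothing stay in the denominator, matching
how cohort percentages are reported. High antigenicity means
`fraction ≥ 0.5` (the threshold is configurable; ≥ is used so a peptide
recognized by exactly half the sera qualifies). Zones are maximal runs of
consecutive high-antigenicity peptides; the representative is the
most-recognized member, ties breaking to the lowest index. The
near-threshold report (default 0.45 ≤ fraction < 0.5) captures
borderline regions such as the domain-1/2 linker peptide, which sits just
below the cutoff and behaves like a fourth antigenic zone.

## Serology (`serology`)

OD→units conversion is a least-squares line through ≥ 2 kit calibrator
points, clamped at zero below blank. Reference cutoffs use the empirical
quantile with linear interpolation between order statistics (numpy's
default rule; the convention is recorded because quantile definitions
differ). Default positivity cutoffs: 20 U (anti-β2GP1 IgA, a 99th
percentile of a healthy population), 23.8 U (anti-D1 IgA), 22 U
(anti-D4/5 IgA), 18 U (IgG/IgM assays); classification is strictly
greater-than.

Pearson correlations carry 95% confidence intervals via the Fisher
z-transform, `tanh(atanh(r) ± 1.96/√(n−3))`, and a Hinkle rule-of-thumb
magnitude label.

**Two-regime split.** Scatter plots of anti-D4/5 against whole-molecule
anti-β2GP1 levels can show two regimes: a subgroup tracking the
whole-molecule level linearly and a low-level subgroup with no association.
The split is operationalized as a deterministic grid search over horizontal
boundaries `y = c` (candidates at observed y values; sera with `y ≤ c`
form the low group B). Candidate boundaries are scored by the profile
log-likelihood of the two-regime model — group A as a Gaussian linear
regression of y on x, group B as a flat Gaussian band — subject to both
groups keeping ≥ `min_frac·n` sera (default 15%). A naive objective that
maximizes `|r_A − r_B|` directly was evaluated and rejected: the sample
correlation of the smallest admissible group has the widest sampling
distribution, so that objective systematically selects sampling extremes
rather than the regime boundary (membership agreement with generative
truth ≈ 0.67 versus ≈ 0.90 for the likelihood objective, with a
best-achievable ≈ 0.94 under the same boundary family). The split is
flagged non-informative when `|r_A − r_B|` at the chosen boundary is below
a margin (default 0.3). The flag is meaningful for homoscedastic clouds;
for strongly heteroscedastic single-regime data, a low band genuinely has
smaller variance and restricted-range correlation, so the flag can stay
raised — the split is labelled a heuristic in all outputs for this reason.

Group comparisons use Pearson's χ² without continuity correction, replaced
by Fisher's exact test for 2×2 tables when any expected count is below 5,
and the two-sided Mann-Whitney U for two-sample ordinal/scaled data.

## Face localization (`structure_map`)

The open ("fish-hook") conformation of β2GP1 shows an L-shaped silhouette
from one side and a J from the other. Published face assignments come from
manually rotating a viewer; this module substitutes a reproducible rule: a
least-squares plane through all alpha-carbons (normal = direction of least
coordinate variance, via SVD), oriented so the anchor residues — default
39–43, the domain-1 epitope known to lie on the L side — have positive
mean signed distance. Residues are L if their signed distance exceeds
`edge_delta` (default 1.5 Å), J below `−edge_delta`, and "edge" within the
band. The band absorbs side-chain protrusions and elbow residues whose
face is genuinely ambiguous in a rendering (the analysis is
alpha-carbon-only). Zone composition is reported as L/J/edge fractions
over resolved residues, with unresolved counts listed. The whole pipeline
is invariant under rigid motions, and flipping the anchors to the opposite
side exactly swaps L and J — both properties are tested.

PDB parsing keeps the first alternate location of each alpha-carbon and
rejects insertion codes (the β2GP1 crystal structure needs neither). The
face labels can be exported as a B-factor overlay (L = 1, J = −1,
edge = 0) loadable in any viewer. No attempt is made to model the circular
or S-shaped plasma conformations, for which no crystallographic data
exist.

## Synthetic data (`synth`)

The generators supply the statistical structure the analysis assumes, with
machine-readable truth records; no patient-level data of this kind are
publicly deposited, so they are the package's test substrate.

**Reactivity cohorts.** 93 sera × 79 peptides of independent Bernoulli
calls: background recognition probability 0.2, three planted zones
(peptides 33–35, 46–52, 62–67) at 0.7, a near-threshold peptide (14) at
0.46, and a 5/93 fraction of sera that recognize nothing. Planted
probabilities are cohort marginals: the all-zero sera are drawn first and
the remaining sera use `p/(1 − zero_fraction)`, so the expected recognition
fraction over all 93 sera equals the planted value (percentages are
reported against all sera). Independence across peptides and sera is a
deliberate simplification — real IgA responses are polyclonal with
within-serum correlation structure — so recovery tests certify the zone
machinery, not immunological realism. At these parameters the planted
near-threshold peptide has a ≈ 20% per-cohort chance of crossing the 50%
cutoff by sampling noise (binomial n = 93), which is why the acceptance
script reports the *median* zone count over 25 replicate cohorts rather
than a single draw.

**ELISA panels.** Whole-molecule anti-β2GP1 IgA is log-normal matched to a
median of 60.8 U and IQR 40.1–121 U. A 66/93 subgroup follows
`anti-D4/5 = 15 + 0.6·anti-β2GP1 + ε`, with heteroscedastic Gaussian noise
proportional to the expected level (immunoassay error is approximately
constant-CV) and total noise variance set so the within-group Pearson r is
0.8; the intercept and slope keep this subgroup above the 22 U anti-D4/5
positivity cutoff, as expected for D4/5-reactive sera. The remaining
sera draw anti-D4/5 independently from a low log-normal (median 8 U,
σ = 0.6 — negative-range levels), and anti-D1 is independent log-normal
(median 10 U) for all sera, reproducing the null anti-D1 association.

**Slides.** A 7×12 grid (79 peptide + 5 negative spots, 24 px pitch,
radius 6 px) on a Gaussian background (mean 500, SD 50 at 16-bit scale);
bound peptides add a Gaussian point-spread of amplitude 3000 and σ = 3 px;
intensities are clipped to [0, 65535].

**Structures.** Backbones trace a serpentine sheet, an L-shaped fish-hook,
or a flat coil in the x–y plane with 0.3 Å z-jitter, so the least-variance
direction is z; planted spans are displaced to ±5 Å and truth labels
derive from the final z of each residue. These clouds have the geometry the
face classifier needs (a dominant planar extent) but no secondary
structure, domain packing, or side chains.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (numpy `default_rng`) and
the pipeline stamps outputs with a config hash; identical configurations
produce byte-identical tables. The acceptance script uses 25 replicate
cohorts for the zone count and 10,000 slides × 84 spots for the null
specificity estimate, sizes at which the Monte-Carlo error of the reported
quantities is well below the tolerances of interest while the whole script
runs in seconds.

## Known limitations

- The stitched antigen is only as correct as the packaged peptide table;
  stitching detects internal inconsistency but cannot detect a consistent
  error replicated across overlapping rows.
- Bernoulli-independent reactivity ignores serum-level clonality; breadth
  distributions in real cohorts are overdispersed relative to the
  generator.
- The two-regime split assumes a horizontal boundary in y; mixtures
  separated along any other direction need a different partition family.
- The face classifier reduces "visible from a side" to signed distance
  from a single global plane; strongly bent molecules can place residues
  of one visual face on both sides of the plane (mitigated, not solved, by
  the edge band).
- Fixed-circle quantification assumes an accurate spot layout; there is no
  grid refinement, so systematic layout drift biases IODs.
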