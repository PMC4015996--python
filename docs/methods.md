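# Methods

This note records the models behind each stage of `factoscreen`, the
parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic tests can show.

## The screen and its design objects

The screen crosses five soluble chondrogenic factors — TGFB1, FGF2,
dexamethasone (DEX), IGF1 and BMP2 — in a two-level (present/absent)
full 2^5 factorial: 32 conditions, each run for three donors at days 1
and 7, with day-0 untreated cells as a reference state. Two auxiliary
arms extend the registry to 48 conditions: a ligand-isoform arm
(TGFB2/TGFB3 alone, +DEX, +DEX+BMP2; BMP4/BMP6 alone, +TGFB1,
+TGFB1+DEX) and a seeding-density arm (1.25, 2.5, 5, 20 ×10^6 cells/mL
under TGFB1+DEX+BMP2; the default density everywhere else is 10^7).

Conditions are numbered by
`id = 32 − (16·[TGFB1] + 8·[FGF2] + 4·[DEX] + 2·[IGF1] + 1·[BMP2])`,
so 32 is the factor-free basal medium and 1 the all-factor condition.
This weighting is the unique one consistent with every numbered
condition pair the screen's analyses refer to (12↔16 and 11↔15 differ
by DEX; 15↔16 and 11↔12 by BMP2; 9↔11, 2↔4 and 25↔27 by IGF1). Both
the weights and the composition of conditions 33–48 are conventions
exposed in the API (`condition_number(..., weights=...)`) so a user
with the authoritative plate layout can override them. Day-0 untreated
cells carry a reserved pseudo-condition id 0 rather than being folded
into condition 32, since they precede treatment.

Model matrices code each factor ±1 and form interaction columns as
element-wise products; over a complete replicate all effect columns are
mutually orthogonal and sum to zero, and donors enter as 0/1 block
indicator columns.

## Synthetic data generator

No public count-level dataset exists for this screen design, so the
package ships a generator whose defaults emulate the study conditions:
a 364-gene panel (14 wanted hyaline-cartilage markers, 11 unwanted
hypertrophy/bone/fat markers, 10 housekeeping candidates, named
response genes, synthetic `GENE#####` filler), 3 donors, days 0/1/7,
all 48 conditions, and a spike-in control series.

Counts are negative binomial (Poisson–gamma), `Var = μ + φμ²`, with
mean

    μ_gs = lane_s · 2^( b_g + donor_{g,d} + Σ planted effects active in s )

* `baseline_mean = 200` counts, with a per-gene log2 spread
  `gene_sd = 1.5` giving a realistic dynamic range (~10–10^4 counts).
* `dispersion φ = 0.05` for endogenous genes (≈22% CV above Poisson —
  counting plus residual biological noise). `φ = 0` degenerates to
  deterministic `round(μ)`, so the noise-free limit is exactly
  recoverable.
* Control probes carry a separate technical-only dispersion
  `ctrl_dispersion = 0.005` (≈7% CV): spike-ins and background probes
  have no biological variance. Positive controls follow the nominal
  geometric concentration series (ratio 4) at `pos_unit = 500` counts
  per unit, so the weakest spike-in still counts in the tens — the
  regime in which spike-in lane calibration is informative. Negative
  controls have constant mean 4.
* `lane_sd = 0.15` log2 units of per-sample scale variation, applied to
  every probe class, which makes lane factors identifiable from the
  positive controls alone.
* Donor effects are per-(gene, donor) log2 offsets (`donor_sd = 0.2`)
  constant across conditions and days — a donor identity, not a
  donor×condition response. They therefore cancel exactly in
  donor-blocked contrasts; replicate-level inference noise comes from
  counting noise. Donor-specific response magnitudes are a known
  omission (below).
* Of the 10 housekeeping candidates, the first 5 are truly stable
  (variance parameters scaled by 0.25, no day drift); the other 5
  receive a per-day wobble (`ref_instability_sd = 0.7`) so that
  reference-gene selection has something real to discriminate.

Planted effects attach log2 shifts to a gene or a whole marker set
whenever a factor term (a factor, an `A:B` interaction, or the density
profile) is active. The `paper_like` preset plants, on the wanted set
(day-7 magnitudes; day 1 at half strength): TGFB +0.8, DEX +0.3, BMP
+0.4, FGF2 −1.0, TGFB:DEX +1.2 (the synergy), TGFB:BMP −0.4 (the
damping), IGF1 absent; on the unwanted set: TGFB +0.4, BMP +0.6,
TGFB:BMP −0.5, TGFB:DEX −0.5, FGF2 −0.6 — i.e. TGFB or BMP alone raise
unwanted expression, the combination does not exceed either alone, and
DEX damps the gain in TGFB conditions; single-gene responses (COL10A1
+2.0 under TGFB1, BGLAP −2.5 and MMP1 −1.5 under DEX, MMP7 +1.5 under
DEX, NOG +1.5 under BMP, SOX9 +1.0 under TGFB:DEX); and a broad
TGFB-responsive program (15 genes +1.2, 3 genes −1.0) reflecting that
a chondrogenesis panel is dense in TGFB-superfamily targets — this
program is what makes the first principal component align with TGFB
exposure, as such screens observe. The density arm follows a unimodal
profile peaking at the default density.

What the generator does **not** emulate: per-gene dispersion
heterogeneity, donor×condition interaction noise, probe affinity or
cross-hybridization, background varying by probe GC content,
count saturation, or batch/cartridge structure beyond the lane factor.
Passing tests therefore demonstrate correctness of the machinery and
its calibration under a plausible generative model — not robustness to
every artifact of real screens.

## Normalization

1. **Lane scaling.** `factor_s = G / g_s`, with `g_s` the geometric
   mean of sample `s`'s positive controls and `G` the geometric mean of
   the `g_s`. After scaling, positive-control geometric means are equal
   across samples (to 1e-12). Note the grand-mean target makes the
   chain *relative*: multiplying one sample by α changes every
   normalized value by the same additive `log2(α)/n` on the log scale
   while leaving all profiles and contrasts untouched; the property
   test asserts exactly this form of equivariance.
2. **Reference-gene stability.** For candidates `i` in groups `g`
   (default grouping: day, the only grouping present in all arms;
   configurable): the within-group variance is estimated from the
   residuals of the additive gene+sample model,
   `σ̂²_ig = k/(k−2) · (MS_ig − M̄_g/(k−1))`, the multi-candidate bias
   correction that makes the estimate unbiased when every candidate
   carries noise (requires ≥3 candidates; clipped at 0). The
   between-group bias `d_ig` is the double-centered group mean, shrunk
   toward zero by its sampling variance via an empirical-Bayes weight
   `τ̂²/(τ̂² + σ̂²_ig/n_g)`. Stability is
   `ρ_i = mean_g(|d̂_ig| + σ̂_ig)`; the `n_refs = 5` lowest-ρ candidates
   are selected, ties broken lexicographically. With one group the bias
   term vanishes and ranking reduces to residual variance.
3. **Reference normalization** rescales each sample so the geometric
   mean of the references equals its across-sample grand geometric
   mean.
4. **glog.** `h(x) = log2((x + √(x²+c²))/2)`: strictly increasing,
   `h(x) → log2(x)` for `x ≫ c`, variance bounded near zero. The offset
   defaults to the mean negative-control count (`negctrl` policy);
   `quantile` and `fixed` policies are available. No background
   subtraction is performed; genes whose median count falls below the
   negative-control mean + 2 sd are flagged `below_background` only.

Zeros in any geometric mean raise an error unless a pseudo-count is
configured; the pipeline default is 0.5, applied only when zeros occur
and logged in the provenance record.

## Marker scoring

Replicates are collapsed to condition means first (one point per
condition, matching how such screens are plotted), then each gene is
studentized across conditions with the n−1 sd; sd-degenerate genes map
to all-zero rows with a flag, so set means stay defined. Wanted and
unwanted scores are set means of the studentized values; ranking is
descending by wanted score with ties broken by ascending unwanted
score, then condition id. Studentization is per day by default (day-1
and day-7 panels are standardized separately); pooling days is
available by passing `day=None`. Day-1 vs day-7 ranking agreement is
Spearman's rho with average-rank ties; the p-value uses the t
approximation, or the exact permutation distribution for n ≤ 9.

## Factorial inference

Responses are per-(condition, donor) marker-set means of per-gene
standardized expression. The effect of a term is the high-level mean
minus the low-level mean, computed both as twice the least-squares
coefficient of the coded column and as the Yates contrast divided by
2^(k−1)·replicates; the two routes must agree to 1e-10 and the fit
refuses incomplete designs. The analysis is univariate per response
(wanted and unwanted fitted separately) with donor blocks; four- and
five-way interactions are pooled into error, leaving 68 residual df at
3 donors. Standard errors come from the residual mean square
(`SE = 2σ̂/√N`), t statistics are effect/SE with two-sided p, α = 0.05
with no multiplicity correction across the 25 terms (deliberately — a
screening analysis reads the normal plot, whose quantiles use the
`(i − 0.375)/(n + 0.25)` convention). A Box-Cox transform with
profile-likelihood λ on the grid [−2, 2] (step 0.01, shift logged) is
available for responses with non-normal residuals.

## Differential expression

The engine fits one gene-wise linear model per day — expression ~
condition + donor over all conditions present — pooling the residual
variance per gene across the whole day (62 df at 3 donors/32
conditions), the standard linear-model practice for multi-condition
screens; the restricted two-condition fit is also exposed and coincides
with the pooled model when only those samples are present. Variances
are squeezed by empirical Bayes: with `s² ~ s0²·F(df, d0)`, the
moments of `log s²` give `Var = ψ'(df/2) + ψ'(d0/2)` and a mean with
digamma offsets; `d0` comes from trigamma inversion (Newton), with the
degenerate `d0 = ∞` branch when the observed spread does not exceed
`ψ'(df/2)`. The moderated t uses the posterior variance on `df + d0`
degrees of freedom. Calls require both `|log2FC| ≥ 1` (twofold on the
log2-asymptotic scale) and BH `q < 0.05`, with BH applied per contrast
across genes. The uniform single-factor analysis requires a gene to be
called, with one direction, in *all* 16 factorial conditions containing
the factor versus condition 32. Contrast overlaps are counted
same-direction only.

## Enrichment and PCA

Condition-level enrichment is a competitive mean-rank test: Wilcoxon
rank-sum of the marker set's moderated t statistics (condition vs
condition 32) against all other genes, directional, with the
tie-corrected normal approximation — deterministic and invariant to
monotone transforms of the statistics. FDR is BH across the 31
non-baseline factorial conditions within each set; a condition is
flagged when wanted FDR < 0.05 and unwanted FDR ≥ 0.05. A
self-contained rotation/permutation variant is a possible extension;
the competitive test is the documented default. PCA is a gene-centered
SVD (samples as observations); each component's sign is fixed by making
its largest-|loading| gene positive; variance fractions are
`s²_i / Σs²`.

## Numerical choices and degenerate inputs

* Geometric means: pseudo-count only on zeros, logged.
* Studentization and marker scores: zero-sd rows → 0 with a flag.
* `enumerate_factorial` uses standard order (first factor fastest).
* Effect/BH ties: stable mergesort everywhere a tie-break is
  documented.
* Wilcoxon with an empty complement (set = universe) returns p = 1.
* `d0 = ∞`: posterior variances collapse to s0², p-values go normal.
* Trigamma inversion: Newton from `x = 0.5 + 1/y`, tolerance 1e-10.
* Seeds: one global seed fans out to named per-stage substreams
  (`SeedSequence([seed, stage_index])`, reduced below 2^31), so stage
  reordering cannot perturb any stage's stream; end-to-end runs are
  byte-identical per seed.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the chain on reduced but
structurally complete screens — 60–120-gene panels for calibration
loops (400 null screens for the effect-test type-I rate, 200 for null
DE), the full 364-gene panel for the qualitative pattern battery
(10–20 seeds) — sizes chosen so the whole battery re-runs in minutes
while every estimate keeps its Monte-Carlo error well inside the
asserted bands.

## Known limitations

* The condition numbering beyond the factorial arm (33–48) is a
  documented convention, not a transcription of the original plate
  layout.
* The exact variance-stabilization and enrichment engines of published
  screens are named packages with unstated settings; this package
  implements the defining behavior (asinh-type glog; competitive
  mean-rank test) rather than binding to package internals, and treats
  their knobs as configuration.
* No probe-level QC (binding density, field of view), no fractional
  factorial generation, no response-surface optimization, no figure
  rendering beyond coordinate tables.
* Real gene counts per contrast (how many genes change when DEX is
  added to TGFB1, etc.) depend on the original raw data and are not
  reproducible from simulation; the package reproduces the machinery
  and the qualitative structure, not those integers.
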