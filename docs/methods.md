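# Methods

## Setting and scope

The package analyses feeding trials in which ruminants are fed a series
of diets along a concentrate:roughage gradient, indexed throughout by the
concentrate fraction x ∈ [0, 1] of dietary dry matter. The bundled
reference dataset is a five-diet buffalo trial (x = 0.20, 0.35, 0.50,
0.65, 0.80; three fistulated animals in an incomplete 3×5 Latin square)
whose group-level tables — diet nutrient composition, rumen VFA profile,
acetate proportion, apparent digestibility, and the fitted gradient
equations for NH₃-N, the acetate proportion and the core phyla — serve as
worked inputs and as generating truths for the simulator. Upstream
sequence processing (merging, QC, OTU clustering, taxonomy assignment),
beta diversity, and differential-abundance machinery are out of scope:
the package starts from tabular group or sample data.

## Digestibility

Apparent digestibility is the total-collection quantity
100·(intake − excretion)/intake per nutrient, with amounts computed as DM
mass × nutrient %DM / 100. DM digestibility always uses the DM masses
themselves rather than any DM% assay row. Values can legitimately exceed
the [0, 100] range at the low end (excretion above intake for ash or
minerals); they are reported unclipped with a warning, because silent
clipping hides collection errors. Per-animal-period results are averaged
with equal weights; the trial design is balanced so no variance weighting
is attempted.

Feed identities: NDFn = NDF − NDICP (protein-corrected fiber) and the
closure NFC = 100 − CP − EE − Ash − NDFn. When the identities are applied
to *printed* (2-decimal) component values, the result inherits up to
±0.01 of propagated rounding for the two-term difference and ±0.02 for
the four-term closure; tests assert within exactly those a-priori bounds
and exactly where the printed rows are exactly consistent. Intake is
scaled to metabolic body weight as 1000·DMI/BW^0.75 (g/kg W^0.75). The
reference trial's own printed intake-per-metabolic-weight row cannot be
reconciled with its printed total intakes and body weight under any DM
assumption, so the formula is defined explicitly and no test targets that
row.

## Trend fitting

Three response families, all unweighted OLS:

- linear: y = b₁x + b₀, with r² the squared Pearson correlation; a
  constant y (zero total sum of squares, zero residual) is reported as a
  horizontal line with r² = 1;
- quadratic: least squares via `numpy.polyfit`, r² = 1 − SSres/SStot;
- exponential: y = a·e^{kx} fitted as OLS of ln y on x, so k is the
  log-scale slope and a = exp(intercept). This is exactly the
  parameterisation under which the reference trial's printed exponential
  equation (rate 4.156, prefactor 0.0007) reproduces. Strictly positive
  y is required; compositional zeros are meaningful, so the caller must
  filter or substitute a pseudo-abundance explicitly.

Two coefficients of determination are carried for the exponential family:
`r2` on the fitting (log) scale and `r2_original` = 1 − SSres/SStot on
the raw scale. Family selection (`select_family`) always compares
`r2_original`, so the log fit gets no scale advantage; near-ties within
1e-12 go to the family with fewer coefficients. Note the reference
trial's printed R² for its exponential taxon fit (0.8175) is reproduced
by *neither* convention from the printed abundances (log-scale ≈ 0.685,
raw-scale ≈ 0.50); the slope and prefactor do reproduce, so the package
reports both conventions and treats the printed R² as unreproducible.

"Printed precision" comparisons in tests use Python's round-half-even at
the printed decimal count.

The NH₃-N colorimetric standard curve (absorbance = 0.0423·conc + 0.0157)
is inverted linearly; a zero slope is rejected.

## Alternation points (trend-line crossovers)

For two fitted trends, the crossover x\* solves f_a(x\*) = f_b(x\*).
Linear pairs use the closed form (b₀,b − b₀,a)/(b₁,a − b₁,b); parallel
distinct lines return no crossing, and coincident models are an error
(infinite intersection set). Any pair involving a non-linear family is
scanned for sign changes of the difference on 1000 equal subintervals of
the search range, each bracket refined by Brent's method to |Δx| < 1e-10.
Every returned root must satisfy |f_a(x\*) − f_b(x\*)| < 1e-9 (asserted at
run time); the two solver paths agree within 1e-8 on line pairs.

Crossings are searched on the data span extended by 0.05 on each side —
the biologically interesting core-phylum crossing sits near the upper
data edge — but flagged `in_range` only inside the span; extrapolated
crossings are logged as warnings. Three qualitative cases are reported:
opposite-signed line slopes (one taxon replacing another), same-signed
but unequal slopes, and any crossing involving a curved trend.

Per-taxon trends are fitted on group means at each gradient level by
default (five-point fits, matching how gradient equations are usually
derived from group summaries), switchable to per-sample fitting. A
minimum-prevalence filter (non-zero in ≥ 3 samples) excludes
uninformative taxa. The "core pair" for the warning point defaults to the
two taxa most abundant at the low-gradient end — in rumen data,
Bacteroidetes and Firmicutes — and the warning point is their smallest
in-range crossing.

The SARA assessment combines the chemistry thresholds — acute acidosis
pH < 5.0, subacute pH < 5.6, a caution band [5.6, 6.0) below which
fibrolytic activity is impaired, and the optimal NH₃-N band
5–27.5 mg/dL — with the alternation flags: every crossover at or below
the evaluated concentrate fraction is listed, since a diet at that
inclusion has already passed those community turning points. The
indicator is a screening statistic, not a clinical diagnosis.

## Abundance utilities

Counts are normalised per sample (columns sum to 1); rarefaction draws a
multivariate hypergeometric per sample (subsampling without replacement)
at a common depth, by default the shallowest sample, and is deterministic
per seed. Rank aggregation sums rows within the phylum or genus component
of prefixed, possibly pipe-joined identifiers (`p_…|g_…`); taxa without
the requested rank are pooled as `unclassified` to preserve column sums.
Shannon diversity uses the natural log (the base is a convention; ln is
declared so comparisons are internally consistent) and richness counts
non-zero taxa. Group summaries weight samples equally. A Kruskal–Wallis
diversity comparison is exposed as a thin utility.

## Synthetic-trial generator

The generator reproduces the statistical structure the analysis assumes,
with one master seed feeding named `SeedSequence` child streams
(fermentation / abundance / digestion), so outputs are reproducible per
stream.

- **Diets**: nutrient profiles linear in x between a pure-roughage and a
  pure-concentrate endpoint. Default endpoints are the x = 0 and x = 1
  evaluations of OLS lines fitted to the five reference diets, with NDFn
  and NFC re-imposed by the identities so every generated diet is
  internally consistent.
- **Fermentation**: NH₃-N = 2.0426·CP − 8.4155 (mg/dL) and acetate
  proportion = 0.0012·NDF + 0.641, the reference trial's fitted
  equations, plus Gaussian noise (defaults σ = 1.5 mg/dL and 0.015,
  roughly the within-group SDs of the reference tables). pH uses
  invented defaults 7.2 − 0.02·starch (σ = 0.08) — no fitted pH equation
  is available to copy — chosen to keep pH inside the observed 6.0–7.0
  band. TVFA is drawn around 110 mmol/L (σ = 10, reference grand mean);
  non-acetate acids split the remainder in the reference trial's mean
  shares, so every sample satisfies the VFA sum and acetate-proportion
  invariants by construction. Draws violating a physical range
  (proportions outside (0,1), non-positive TVFA) are redrawn (truncated
  resampling).
- **Abundance**: expected proportions are softmax(αₜ + βₜ·x) over taxa;
  per sample, a Dirichlet(θ·p) probability vector is drawn and counts
  are multinomial at fixed depth. Defaults: six taxa emulating a rumen
  phylum profile, two dominants whose expected curves cross at
  x = 0.7222 (inside 0.6–0.9, like the real core-phylum alternation),
  θ = 200 (moderate overdispersion) and depth 20 000 reads, typical of a
  16S library. `exact=True` skips sampling and returns the expected
  proportions — the zero-noise limit.
- **Digestion**: fecal amounts are intake × (1 − d/100) × (1 + ε) for a
  configured truth d per nutrient (relative σ default 0.02); at ε = 0 the
  pipeline recovers d exactly. Configuring all three of NDF, NDICP and
  NDFn is rejected as over-determined, since the NDFn identity fixes the
  third.

A deliberate property of the softmax model: the normaliser cancels in
log-differences, so the crossing of two taxa's *expected* curves is
exactly (α_b − α_a)/(β_a − β_b), and because OLS is linear in the
response, exponential-family (log-linear) fits recover that crossing to
machine precision at zero noise. Linear-family fits to the mildly curved
softmax proportions land within ~3×10⁻³ of it on five-point data. The
exactness of the exponential path is what the zero-noise recovery tests
exercise; stochastic recovery (bias < 3 SE over 100 replicates) holds for
the fermentation coefficients and the crossover location under the
default noise.

What the generator does **not** emulate: animal and period variance
components (a single residual σ per response; the Latin-square carryover
structure is ignored), richness-driven diversity (with six taxa the
Shannon index is dominated by the evenness of the two dominants and
*rises* toward the crossing, whereas a real hundreds-of-taxa rumen
community loses diversity at high concentrate), taxonomic depth below
phylum in the default set, and read-level sequencing error. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to real-data artefacts.

## Numerical and interface choices

- Tables are TSV (CSV by extension), first column = row label, UTF-8,
  decimal points. Concentrate fractions are always stored in [0, 1];
  "c:r" ratio labels are converted on read.
- Abundance mode is auto-detected on read (all columns ≈ 1 →
  proportions); negative values and samples missing metadata are hard
  errors naming the culprit.
- JSON reports carry a schema version and SHA-256 digests of their
  inputs; floats serialise at full repr precision, so a re-read
  reproduces every coefficient bit-exactly.
- Problem sizes in tests are the study's own scale (5 gradient levels ×
  3 animals; 100–200 replicate checks for unbiasedness), which keeps the
  full suite in a few seconds.

## Known limitations

- Trend fits are unweighted OLS on group means; no mixed-effects or
  repeated-measures structure, no confidence bands beyond what the
  coefficients imply.
- The alternation-point indicator is validated here only against the
  generator and the reference trial's printed equations; its clinical
  validity as a SARA definition is an open scientific question, not a
  claim of this package.
- The reference trial's printed crossover percentages (75.62% in one
  place, ~75.26% in another) are mutually inconsistent with its own
  printed equations, which give 77.11%; the package reports the
  equation-derived value.
- Exponential fits require positive abundances; zero-replacement policy
  is the caller's explicit choice.
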