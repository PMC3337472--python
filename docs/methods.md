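# Methods

## The model

An F1 mosaic screen passes chemically induced lethal mutations through a
chain of filters before a mutation can be counted as an allele of a locus:

1. **Mutagenesis.** EMS induces lethal point mutations at an approximately
   constant rate per mutagenized chromosome arm (default 0.65/arm, the
   standard feeding-protocol figure). With `A` arms screened the total is
   Poisson(`A·r`), and mutations distribute over the `G` essential genes of
   the screened fraction multinomially (equivalently, independent Poissons
   per gene). Hits per gene therefore have mean `λ_gene = A·r/G`, and the
   probability a gene is hit at least once — the *coverage* — is
   `1 − e^{−λ_gene}`.
2. **Detection and attrition.** Only mutations in the detectable *pathway*
   subset of genes can produce a scorable mosaic phenotype; a scored F1
   candidate must then survive to a balanced stock (`p_recover`) and pass a
   penetrance/expressivity filter (`p_penetrant`). Each step is modelled as
   independent Bernoulli thinning per mutation, so retained alleles per
   pathway gene are Poisson with the thinned mean
   `λ_eff = λ_gene · p_detect · p_recover · p_penetrant`.
3. **Observation.** A locus enters the data only if it retains ≥ 1 allele.
   The observed allele spectrum is therefore **zero-truncated Poisson**:
   the sufficient statistic for saturation is the mean observed alleles per
   locus, whose expectation is `λ_eff / (1 − e^{−λ_eff})`, not `λ_eff`.

### Estimators

*Plug-in*: `λ̂ = observed mean`; `saturation = 1 − e^{−λ̂}`;
`total loci = n_observed / saturation`. This is the convention screen
reports use. Because the observed mean overestimates `λ_eff` (truncation
inflates it), the plug-in rule overstates saturation and understates the
total locus count.

*ZTP MLE*: `λ̂` solves `λ/(1 − e^{−λ}) = observed mean`, the stationarity
condition of the zero-truncated Poisson log-likelihood
`Σ_i [k_i ln λ − λ − ln(1 − e^{−λ}) − ln k_i!]`. Always `λ̂ < mean`, so ZTP
saturation is strictly below and the total-locus estimate strictly above
the plug-in values — an ordering the test suite checks as a theorem. When
the observed mean is ≤ 1 (every locus a singleton) the equation has no
positive root and the package raises a degenerate-spectrum error rather
than report a meaningless boundary estimate.

*Uncertainty*: percentile bootstrap resampling **loci** with replacement.
Loci are the exchangeable units of the spectrum; resampling mutations would
destroy the truncation structure both estimators rely on. Degenerate ZTP
resamples (mean ≤ 1) are redrawn with a warning, capped at 10× the
requested replicates.

### Complementation grouping

Mutations are nodes; pairs that fail to complement (scored as an OR over
phenotype channels: lethality or reporter derepression) are edges; loci are
connected components. Three result states beyond `fails`:

- `untested` contributes no edge; the fraction of pairs actually tested is
  reported with every partition, since a sparse matrix over-splits
  silently.
- `partial` defaults to **flag, don't merge** (`partial_policy=
  "flag_only"`): the one biological pattern that produces partial
  complementation in these screens — an isoform-restricted hypomorph — is
  exactly what should be surfaced, not absorbed. `as_fail` (merge) and
  `as_complement` (ignore) are available; the `as_fail` partition is
  provably a coarsening of the others.
- Deficiency (deletion) tests anchor a deficiency to a group only on a
  **full** failure to complement, which is protein-null-like evidence. A
  mutation that fails or partially fails an anchored deficiency yet
  complements members of that group is flagged `hypomorph_candidate`;
  intransitive triangles (fails a–b, fails b–c, complements a–c) are
  enumerated and flagged; a mutation complementing a deficiency its
  groupmates fail is flagged `conflict_with_deficiency`. Flags carry the
  supporting pairwise results as evidence and never alter the partition.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `lethal_rate_per_arm` | 0.65 | EMS lethal hits per mutagenized arm (dimensionless rate) |
| `arms_screened` | 56,000 | mutagenized arms passed through the screen |
| `n_essential_genes` | 1,440 | essential genes in the screened genome fraction (≈ 40% of ~3,600) |
| `n_pathway_genes` | 30 | detectable subset; near the plug-in total-locus estimate for the packaged spectrum |
| `p_f1_detect` | 1.0 | P(pathway-gene mutation yields a scorable F1 phenotype) |
| `p_recover` | 73/950 | P(scored F1 candidate recovered as a balanced stock) |
| `p_penetrant` | 45/73 | P(recovered mutation passes the penetrance filter) |
| `p_hypomorph` | 0.0 | P(mutation is isoform-restricted, complementing same-gene full alleles) |
| `p_test_error` | 0.0 | P(a pairwise complementation call is flipped) |
| `gene_weights` | uniform | relative per-gene target sizes |

The attrition defaults are the observed screen fractions, so default
simulations land in the published regime. Gene target-size heterogeneity is
available through `gene_weights` but defaults to uniform, matching the
homogeneity assumption of both estimators; no claim of fidelity to EMS
sequence-context chemistry is made.

A screen design may carry an explicit `lethal_mutations_screened` override.
The published design this package ships as defaults quotes both 56,000
arms × 0.65/arm and a total of 29,900 lethals screened, which disagree
(56,000 × 0.65 = 36,400); the override is treated as authoritative so that
downstream ratios reproduce the published figures, and its use always
raises `InconsistentDesignWarning`, which the CLI carries into reports as
first-class output.

## What the simulator does and does not emulate

The generator reproduces the screen's *statistical* structure — Poisson
mutagenesis, multinomial gene assignment, independent Bernoulli attrition,
same-gene noncomplementation with hypomorph exceptions, symmetric scoring
noise — under one seeded `numpy` generator with a fixed draw order (total,
gene assignment, detect, recover, retain, hypomorph flags, pairwise error
flips over sorted pairs), so a seed reproduces a screen byte for byte.

It does **not** model FLP/FRT clone geometry, eye-disc development,
reporter fluorescence intensity, per-mutation differences in penetrance, or
correlated loss of sibling stocks; mosaicism-driven F1 loss enters only as
the `p_recover` thinning probability. Passing parameter-recovery tests
therefore shows the estimators are correct *under the Poisson-thinning
model*, not that real screens satisfy it — per-gene mutability
heterogeneity in real data biases any homogeneous-λ estimator toward
overcounting saturation, and is exposed only as a simulation knob
(`gene_weights`), not corrected for in inference.

## Numerical choices

- ZTP solve: Brent root finding on the strictly increasing mean map
  `λ ↦ λ/(1 − e^{−λ})`, bracketed on `(10⁻⁹, mean]` (the map's value at 0⁺
  is 1 and exceeds `mean` at `λ = mean`, so the bracket is guaranteed for
  any mean > 1); `xtol = 10⁻¹⁴`, verified post hoc against the requested
  tolerance (default 10⁻¹⁰). Chosen over Newton for unconditional
  convergence.
- `1 − e^{−λ}` is computed as `-expm1(-λ)` throughout; beyond λ ≈ 36 the
  result is exactly 1.0 in double precision, which is the correctly rounded
  value.
- Headline roundings use ties-away-from-zero (via `Decimal`), matching
  manuscript conventions: 1.875 → 1.9 at one decimal, 84.66% → 85%.
  Banker's rounding would report 1.875 → 1.8.
- `arms_needed` inverts coverage in closed form
  (`⌈G·(−ln(1−c))/r⌉`) and then adjusts by direct evaluation so the
  returned count is exactly minimal despite floating-point rounding of the
  closed form.
- Deterministic ordering everywhere: group members and groups sorted,
  triangle triples normalized `(a, b, c)` with `a < c`, matrix pairs stored
  canonically, JSON written with sorted keys — outputs are diffable.
- Replicate seeds in the recovery harness derive from a
  `numpy.random.SeedSequence` of the master seed (kept below 2³¹), so a
  study is reproducible without the replicates sharing streams.

## Study sizes used in the shipped validation

The parameter-recovery check simulates 200 screens at the published
attrition regime scaled to ~3,000 lethal mutations over a 100-gene
essential universe with 30 pathway genes. The scaling preserves the
quantity that drives estimator behaviour — the effective allele rate per
pathway gene (`λ_eff ≈ 1.42`, i.e. an expected observed mean of ≈ 1.87
alleles per locus, matching the packaged spectrum's 1.875) — while keeping
each replicate small. At these sizes the ZTP estimator recovers the true
locus count with a few percent upward relative bias (small-sample Jensen
effect of `n_obs/saturation`), and the plug-in estimator shows its
predicted downward bias.

## Known limitations

- Homogeneous per-locus λ is assumed by both estimators; richness-style
  estimators robust to heterogeneity (gamma-mixed Poisson, nonparametric
  coverage estimators) are out of scope.
- The bootstrap is percentile-only; small spectra (tens of loci) give
  asymmetric, upper-heavy intervals for the total locus count, and the
  interval should be read as descriptive rather than exactly calibrated.
- Complementation inference assumes recessive lethality scoring; dominant
  enhancers, second-site lethals, and map positions are not modelled.
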