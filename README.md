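# mosaicsat

Statistics for **F1 mosaic saturation mutagenesis screens** — the kind of
forward genetic screen that scores clones of homozygous mutant cells
(FLP/FRT mitotic recombination) in otherwise heterozygous animals, so that
organismal-lethal mutations can still be recovered and assigned to genes by
complementation testing.

The package answers the four quantitative questions such a screen raises:

1. **Design** — given `A` mutagenized chromosome arms at a lethal-mutation
   rate `r` per arm over `G` essential genes in the screened fraction, hits
   per gene are Poisson with mean `λ = A·r/G`, and the probability a gene
   is hit at least once is `1 − e^{−λ}`. (`mosaicsat.design`)
2. **Saturation** — from the observed *allele spectrum* (alleles per
   complementation group), estimate the fraction of detectable loci found
   and the total number of detectable loci. The plug-in rule uses
   `λ̂ = mean alleles/locus`; the statistically correct refinement notes
   that unhit loci are unobservable, so the counts are **zero-truncated
   Poisson (ZTP)** and the MLE solves `λ/(1 − e^{−λ}) = mean`. Either way,
   `saturation = 1 − e^{−λ̂}` and `total loci = observed loci / saturation`,
   with percentile bootstrap intervals from resampling loci.
   (`mosaicsat.saturation`)
3. **Grouping** — infer loci from a pairwise complementation-test matrix as
   connected components of the noncomplementation graph, and flag complex
   (intransitive) complementation — the signature of isoform-restricted
   hypomorphs — instead of silently merging or splitting on it.
   (`mosaicsat.complementation`)
4. **Validation** — a seeded stochastic simulator of the whole screen
   (Poisson mutagenesis → Bernoulli detection/recovery/penetrance attrition
   → complementation matrix with optional hypomorph and scoring noise) with
   full ground truth, plus a parameter-recovery harness for the estimators.
   (`mosaicsat.simulate`)

A packaged fixture carries the allele spectrum of a published *Drosophila*
miRNA-pathway screen: 45 retained mutations over 24 loci (Drosha 3,
Pasha 6, Dicer-1 8, Ago1 8, five identified singletons, and 15 unidentified
single-allele groups).

## Worked example

```sh
mosaicsat estimate --spectrum spectrum.tsv --method plug_in \
    --candidates 950 --recovered 73 --retained 45
```

with `spectrum.tsv` being the packaged 45/24 spectrum prints

```
n_loci: 24
n_mutations: 45
mean_alleles_per_locus: 1.875
mean_alleles_per_locus_rounded: 1.9
method: plug_in
lambda_hat: 1.875
saturation: 0.8466450331550716
saturation_percent: 85
total_loci: 28.3471810028373
total_loci_rounded: 28
total_loci_trivial_upper_bound: 45
f1_recovery_rate: 0.07684210526315789
f1_recovery_percent: 8
```

Reading: the screen averaged 1.9 alleles per locus, so under the plug-in
Poisson rule it found about **85%** of the detectable loci, implying about
**28** detectable loci in the screened genome fraction (45, one locus per
mutation, is the trivial upper bound); 8% of scored F1 candidates survived
to balanced stocks. The truncation-corrected estimate is more conservative:

```sh
mosaicsat estimate --spectrum spectrum.tsv --method ztp --bootstrap 1000 --seed 1
```

gives `lambda_hat: 1.4233`, `saturation: 0.759`, `total_loci: 31.6`
(95% bootstrap interval for the total: 26.0 – 74.1 — small spectra pin the
lower end much better than the upper).

The same arithmetic is available as a library:

```python
from mosaicsat import load_screen_spectrum, plug_in_saturation, ztp_mle

spectrum = load_screen_spectrum()        # 45 mutations, 24 loci
plug_in_saturation(spectrum).saturation_percent   # 85
ztp_mle(spectrum).total_loci_rounded              # 32
```

And the simulator validates the estimators by parameter recovery:

```sh
mosaicsat validate --seed 1 --reps 200 --boot 0 \
    --arms 4615 --essential-genes 100 --pathway-genes 30
```

simulates 200 screens at the published attrition regime (~3,000 lethal
mutations each) and reports that the ZTP estimator recovers the true
30 pathway genes with about +4% relative bias while the plug-in rule is
biased low, and that noise-free complementation grouping reconstructs the
true gene partition in every replicate.

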