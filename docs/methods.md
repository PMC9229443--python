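# Methods

## Scope and model

diallelkit analyses a half-diallel mating design: n inbred parents, all
n(n−1)/2 unordered F1 crosses, no selfs, no reciprocals. Parents and hybrids
are evaluated together in a randomized complete block design (RCBD), giving
the two-way additive model

    y_ij = mu + g_i + b_j + e_ij,   e_ij ~ N(0, sigma^2),

with genotype (entry) effects g_i, block effects b_j and independent plot
error. Entry means over blocks feed the heterosis formulas; the ANOVA error
mean square MSE = SS_error / ((g−1)(b−1)) feeds the LSD thresholds. All
entries (parents and F1s) are analysed in one ANOVA per trait, so one MSE is
shared by every cross of that trait.

Parental lines are treated as fully homozygous, which is the biologically
accurate description of advanced selfing-generation rice varieties. A
heterozygote cell dialect ("a/b") is parsed for generality and contributes
half a count to each allele in frequency estimation and dosage 0.5 in the
distance sum.

## Statistics

**Gene diversity and PIC.** At a locus with allele frequencies p_i among the
parents, gene diversity H = 1 − Σp_i² and Botstein PIC = H − Σ_{i<j} 2p_i²p_j².
Both are reported side by side because breeding papers often use the two
names interchangeably; PIC ≤ H ≤ 1 − 1/k always holds (k = allele count) and
is property-tested. The cross term is evaluated as (Σp²)² − Σp⁴, identical to
the double loop to 1e−12 (tested against an explicit double loop).

**Nei DA distance.** DA = 1 − (1/L) Σ_loci Σ_alleles sqrt(x_a y_a) with
within-line dosages x, y. For homozygous lines this is exactly the fraction
of compared loci with different alleles, and that mismatch-proportion
reduction is the documented default behaviour and the brute-force oracle in
the tests. Loci missing in either member of a pair are excluded pairwise
(per-pair denominator L), which is the only defensible choice when
missingness is sparse and non-systematic. Nei's standard distance −ln(I) is
provided as an option; the two orderings agree for homozygous lines but the
standard distance is unbounded and diverges for lines sharing no allele.

**UPGMA.** Implemented directly (not via a library) because the package
guarantees a deterministic tie-break — the closest pair with the lowest
(row, column) position wins — which generic nearest-neighbour-chain
implementations do not promise. The update is the size-weighted
Lance–Williams average, equivalent to re-averaging all member-pair distances
of the original matrix; node height is half the merge distance, so the tree
is ultrametric and cophenetic distances reproduce ultrametric inputs exactly.
Tests cross-check topology and heights against both a naive O(n³)
re-implementation and scipy's average linkage. Newick branch lengths are
parent height minus child height; round-trips are verified with dendropy.

**Heterosis and LSDs.** HMP% = 100(F1 − MP)/MP, HBP% = 100(F1 − BP)/BP. The
better parent is the larger-mean parent for every trait, including traits
where lower values are agronomically desirable (plant height, sterility):
with that convention HBP ≤ HMP holds identically for positive parent means,
which matches how published diallel tables behave cell by cell. Trait
desirability direction is carried as metadata for interpretation only.
Significance is assessed on the trait-unit difference scale: |F1 − MP|
against LSD_MP = t·sqrt(3·MSE/2r) and |F1 − BP| against
LSD_BP = t·sqrt(2·MSE/r) (two-sided t at the ANOVA error df), giving codes
** / * / ns at alpha 0.01/0.05. The 3/2 and 2 factors are the variances of
(F1 − (P1+P2)/2) and (F1 − BP) under equal plot variance, hence the exact
identity LSD_BP/LSD_MP = 2/√3. Comparing on the percent scale instead
(dividing the LSD by MP or BP) is available behind a flag; it changes star
patterns only when parent means differ strongly across crosses. Crosses with
a zero MP or BP mean get undefined (NaN) heterosis with a warning rather than
an infinite percentage.

Unbalanced data: entry means tolerate missing plots (with a warning); the
ANOVA refuses incomplete genotype × block tables because the LSD formulas
assume balance and silent imputation would fake precision.

**Distance–heterosis correlation.** Pearson r between the parents' distance
and the cross's heterosis percent, one record per trait × {MP, BP}; two-sided
p from the t transform on n−2 df. Zero variance raises instead of returning
NaN. Distances are looked up from the distance-matrix stage, never
recomputed. The default correlates distance; a similarity flag (1 − GD) only
flips signs. No multiple-testing correction is applied by default, matching
common practice in diallel marker studies.

## Synthetic-data generator

The generator emulates the study conditions, not an arbitrary population:

- 8 parents, 11 multi-allelic marker loci, 3 blocks by default — the scale of
  a small rice diallel drought trial (28 F1s, 36 entries).
- 4 alleles per locus by default (the modal count in the bundled rice panel,
  whose mean is 3.54), sampled uniformly; a Dirichlet skew parameter exists
  for stress-testing the diversity statistics.
- Trait model: parent value mu + Σ_l a_l(allele); F1 value = mid-parent value
  + Σ_{l het} d_l; observation = value + block effect + N(0, sigma). Additive
  allele values are drawn N(0, a_l) once per (locus, allele); dominance
  deviations d_l are fixed constants.
- Defaults: baseline mu 30 trait units (a grain-yield-per-plant scale under
  water deficit), residual sigma 1 trait unit, zero block effects, dominance
  1 per heterozygous locus. Drought is a label: an optional stress multiplier
  shrinks mu, but no genotype × environment interaction is modelled.
- One quantitative trait per run; a multi-trait study is emulated by several
  runs sharing the genotype table.

When `markers_are_trait_loci` is set (the default) the F1 heterozygosity
fraction at trait loci equals the parents' Nei DA distance, so with equal
parent values (additive effects 0) and constant dominance d,

    true HMP% = 100 · d · L · GD / mu

exactly — the closed form used in tests. Ground truth (MP, dominance
deviation D, HMP% = 100·D/MP, heterozygosity fraction) is emitted alongside
the data.

What the generator does **not** emulate: linkage and recombination,
epistasis, genotype × environment interaction, allele-size binning error, or
selection structure among parents. Passing tests therefore demonstrate that
the estimators recover the additive + dominance model's quantities under RCBD
noise — not that marker distance predicts heterosis in real germplasm, where
the correlation is typically weak precisely because those ignored factors
dominate.

## Numerical and design choices

- Allele labels are opaque pre-binned strings; no fragment-size tolerance
  matching. Missing calls are excluded per locus (frequencies) and per pair
  (distances).
- The RCBD sums of squares use the balanced closed forms; SS_error is clamped
  at zero against ~1e−14 floating cancellation. Partition exactness is
  asserted at 1e−8 relative and cross-checked against an OLS two-way fit.
- UPGMA closest-pair ties break deterministically (lowest row, then column);
  merge heights are monotone by construction and asserted.
- Every file format is delimited text (comma/tab autodetected); genotype
  parsing is strict — duplicate line ids and ragged rows are errors naming
  the offending row — because silently padded rows corrupt allele counts.
- Reproducibility: all simulation randomness flows from a single integer
  seed through numpy Generators; the CLI `simulate` manifest records seed,
  parameters and output checksums, and identical inputs give byte-identical
  reports.

## Validation problem sizes

The test suite and the acceptance script size their Monte Carlo loops as the
package's own defaults: 10,000 random triples for the HBP ≤ HMP identity;
1,000 random tables for the distance oracle; 100 random matrices (2–6 taxa)
for the UPGMA oracle; 300 simulated trials at sigma = 0.008, d = 0.02 for
per-cross HMP recovery (the band 3·sigma·sqrt(2/(3r))/MP·100 is ≈2 standard
errors of the HMP estimator, so ~95% of crosses fall inside); and 500
zero-dominance trials for type-I calibration at alpha 0.05 (accepted within
±2 binomial standard errors). The recovery/correlation configuration uses a
small dominance-to-mean ratio so that the percent-scale error band is
dominated by plot noise rather than by the curvature of the ratio estimator.

## Known limitations

- The ANOVA requires balance; genuinely unbalanced trials need a mixed-model
  extension out of scope here.
- Nei DA on a handful of inbred lines is a small-sample mismatch proportion;
  with 11 loci its resolution is 1/11, which bounds how finely distance can
  rank crosses.
- Star codes depend on the difference-scale convention; published tables do
  not always state theirs, so exact reproduction of third-party star patterns
  is not a goal.
- Griffing combining-ability (GCA/SCA) decomposition and heterosis over a
  commercial check are not implemented.
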