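# Methods

`abcoal` implements a complete, desk-scale pipeline for inferring the
divergence history of a pair of closely related populations (a native
lineage and a divergent lineage it may have exchanged genes with) from
multilocus haplotype data, together with the two companion analyses
used to screen for recent admixture: the three-population f3 test and
gene-tree topology weighting.

## The six divergence scenarios

All scenarios describe two populations (sizes `N1`, `N2` diploids)
that split from a panmictic ancestor (size `Nanc`) `Tdiv` generations
ago, and differ only in when bidirectional gene flow operates:

| scenario   | gene flow (backwards-time window)          |
|------------|--------------------------------------------|
| `pan`      | single panmictic deme, no split            |
| `div`      | none                                       |
| `im`       | `[0, Tdiv]` (ongoing)                      |
| `divAGF`   | `[Tnc, Tdiv]` (ancient only)               |
| `divSC`    | `[0, Tsc]` (recent contact only)           |
| `divAGFSC` | `[0, Tsc]` and `[Tnc, Tdiv]`               |

Two hard time constraints reflect the system's natural history at a
generation time of 2 years: recent contact is human-mediated and
begins at most 300 generations ago (`Tsc <= 300`, 600 years), while
ancient gene flow ended by the last glacial maximum
(`Tnc >= 10,000` generations, 20,000 years).

### Simulation kernel

The simulator is a standard two-deme structured coalescent with
piecewise-constant demography.  With time in coalescent units and
relative sizes `nu_d = N_d / Nref`:

- each pair of the `k_d` lineages in deme `d` coalesces at rate
  `k_d (k_d - 1) / 2 * 1 / nu_d`;
- each lineage in deme `d` migrates to the other deme at rate
  `M_into_d / 2` during migration epochs (`M = 4 Nref m`);
- at the scaled split time all lineages enter the ancestral deme;
- mutations fall on branches as Poisson events with rate
  `theta_locus / 2` per unit branch length, placed on [0, 1) under the
  infinite-sites model (`theta_locus = 4 Nref mu L`).

With this rate set the time unit is **2·Nref generations** while
`theta` and `M` keep their conventional `4 Nref` scaling; generations
convert to scaled time by `t / (2 Nref)`.  The unit checks
`E[S] = theta * a_{n-1}` and `E[pi] = theta` hold in a single
`Nref`-sized deme, and the full two-deme model was verified
distributionally against msprime (two-sample KS on S and dxy,
isolation-with-migration history, 5,000 loci).

The kernel tracks derived-allele sets as 64-bit masks (so at most 64
haplotypes per locus) and is JIT-compiled; a bulk path simulates an
entire reference table (parameter draws, loci, 16 per-locus
statistics, 39-vector aggregation) without leaving compiled code.

### Priors and the reference size

Priors are uniform and deliberately wide stand-ins bracketing the
system's plausible history (the posterior divergence-time scale is
~1e5 generations): `N1, N2, Nanc ~ U[1e3, 2e6]` diploids,
`Tdiv ~ U[1e4, 1e6]` generations, `Tnc ~ U[1e4, Tdiv]`,
`Tsc ~ U[1, 300]`, ancient/ongoing migration `M ~ U[0, 40]`.
Draws violating `Tsc < Tnc < Tdiv` are rejected and redrawn (capped at
10^4 attempts).  `Nref = 1e5` diploids — a typical effective size for
the system, near the log-midpoint of the N prior — fixes the
coalescent units and makes `M in [0, 40]` span none-to-strong physical
gene flow for populations of that size.

**Recent secondary contact is an invasion, not background migration.**
The recently admixed populations this scenario represents carry tens
of percent of introduced ancestry after at most a few hundred
generations of contact.  A per-generation migration prior tied to `M`
cannot produce that (at these sizes `m = M / 4 Nref <= 1e-4` replaces
at most a few percent in 300 generations), and it leaves the contact
window statistically invisible for much of the prior, collapsing
`divSC` onto `div` and `divAGFSC` onto `divAGF`.  The contact epoch is
therefore parameterized by its cumulative introgression proportion
`rho ~ U[0, 0.8]` per direction — the fraction of the recipient
population replaced since contact — with per-generation rate
`m = rho / Tsc`.  This matches the observed ancestry proportions of
recently invaded populations and makes the recent-contact scenarios
genuinely identifiable.

### Among-locus heterogeneity

Linked selection and introgression barriers make effective size and
migration vary across loci.  Three modes per parameter family
(`Ne`, `m`): `homo` (all loci share the genome-wide draw), `hetero1`
(affected loci get the draw multiplied by `U(0,1)`), `hetero2`
(multiplied by `U(0,2)`, i.e. below or above the draw).  Loci are
affected independently with probability `P_het`, itself drawn
`U(0,1)` per simulation and recorded as a parameter.

## Summary statistics

Per locus, 16 statistics: the biallelic site count and its partition
into fixed differences, private polymorphisms (per population) and
shared polymorphisms; Tajima's pi and Watterson's theta per
population; Tajima's D per population; dxy and net divergence
`Da = dxy - (piA + piB)/2`; the minimum and maximum cross-population
pairwise difference counts; Hudson's
`FST = 1 - mean-within / between`.  pi and dxy are per-locus sums (a
per-bp toggle exists for reporting).  Across loci: mean and SD of each
(32 values) plus 7 fixed Pearson correlations — 39 named values.
Undefined quantities (FST with `dxy = 0`, D with `S = 0`, correlations
with zero variance) are recorded as 0, identically for simulated and
observed data, so ABC distances stay comparable.  The exact 39-entry
composition is frozen as this package's contract; the ABC machinery is
agnostic to it.

## ABC model choice and validation

Statistics are centred and scaled by the pooled reference SD
(zero-variance columns dropped); the `ceil(eps * N)` rows nearest the
observation in Euclidean distance are accepted, ties broken by row
index.  Rejection probabilities are accepted-label fractions.  The
neural-net method fits a single-hidden-layer multinomial classifier
(4 logistic hidden units, softmax output, L2 penalty 1e-4, L-BFGS with
150 iterations — mirroring the conventions of R's `nnet`) to the
accepted rows, weighted by an Epanechnikov kernel of normalized
distance, and averages class probabilities over 10 random
initializations.  The classifier supports sample weights natively
(scikit-learn's MLP does not), which is why it is implemented here.
If the accepted set contains a single label the rejection proportions
are returned, flagged as a fallback.

Validation simulates PODs (pseudo-observed datasets) from each model's
prior and classifies each against shared reference tables, yielding a
confusion matrix, per-model precision, and per-POD posterior records.
The robustness threshold for a focal model scans probability cutoffs
on a 0.01 grid and returns the smallest cutoff at which PODs assigned
the focal model with at least that probability are truly from it at
the target rate (95% by default); `None` if unattainable.

Default validation scale (used by `scripts/acceptance.py` and the
acceptance tests): 10,000 simulations per model, 100 loci of 500 bp
per dataset, 16+16 haploid samples, 200 PODs per model, tolerance 0.01
of the pooled reference (600 accepted) with the neural-net method.
The tolerance keeps the categorical-regression regime of the
full-scale analysis, where thousands of simulations are accepted; a
literal 0.001 here would accept only 60 rows, far too few to fit a
six-class regression.  Full scale (10^6 sims, 1,000 PODs, >1,300
loci) is a configuration change.

## Parameter estimation

Posteriors are the accepted parameter draws under the chosen model
(tolerance 0.01 of the single-model table by default), optionally
adjusted by Epanechnikov-weighted local-linear regression on the
normalized statistics (on log scale for strictly positive parameters);
the adjustment is skipped, flagged, when the accepted count does not
exceed the statistic count (the regression would interpolate) or on
singularity.  Point estimate: mode of a Gaussian KDE (Silverman
bandwidth, 512-point grid over the accepted range); interval: [2.5%,
97.5%] quantiles.  Times are reported in generations and, at 2
years/generation, years.  The local-linear adjustment sharpens
intervals but, as is typical of regression-adjusted ABC, can fall
slightly below nominal coverage at 100-locus noise levels; the plain
rejection posterior is the conservative choice when interval
calibration matters, and is what the coverage test exercises.

## f3 admixture test

`f3(C; A, B) = mean over SNPs of (c - a)(c - b)` on sample
frequencies.  Standard errors come from a delete-one-block jackknife
over consecutive 100-SNP windows (a final partial window merges into
the previous one); admixture is called when `f3 < 0` and
`z = f3/SE <= -3.8` (p < 1e-4).  The finite-sample correction
(subtracting `c(1-c)/(n_c - 1)` per SNP) is off by default, matching
the common threepop convention, and available by flag.  The synthetic
admixture generator draws ancestral frequencies `U[0.05, 0.95]`,
drifts each source by a Balding–Nichols step with `F = 0.05`, mixes
them with fraction `alpha` and resamples binomially at 200 haplotypes
per population.  Those sizes keep the uncorrected statistic's
`+E[c(1-c)]/n` bias an order of magnitude below the admixture signal
`-alpha(1-alpha) E[(p1-p2)^2]`; with small panels use the corrected
flag.  Blocks are positional in file order; no genomic-distance logic.

## Locus trees and topology weighting

Locus trees are neighbour-joining trees on pairwise JC69 or F84
distances (F84 base frequencies pooled from the alignment; distances
validated against ape's `dist.dna`; saturated pairs raise).  Negative
NJ branch lengths are clamped to zero; three taxa solve the three-point
equations directly.  Topology weighting assigns each of four taxon
groups' one-tip-per-combination quartets to one of the three unrooted
topologies using the four-point condition on edge-count distances
(exact on binary trees) and reports matching fractions; enumeration is
exhaustive by default with a seeded sampling mode for very large
trees.  Trees shorter than 0.025 total substitutions (about 5 SNPs per
200 bp) are flagged as not retained.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the inference
machinery consumes: locus-level genealogical noise, among-locus
heterogeneity, known admixture fractions, missing-data conventions.
They do not emulate sequencing error, phasing error, codon structure
or selection at linked sites beyond the heterogeneity multipliers, and
loci are non-recombining and unlinked.  Passing tests therefore
demonstrate correctness of the methods under their own model
assumptions, not robustness to real-data artefacts.

## Numerical choices and limitations

- Reproducibility: one top-level seed; per-simulation substreams are
  drawn from it, and the bulk kernel seeds its internal RNG per
  simulation, so tables are bitwise reproducible.
- At most 64 haplotypes per locus (bitmask representation).
- No recombination within loci (`rho_locus` is accepted but the
  default pipeline treats transcriptome contigs as non-recombining);
  no selection; exactly two sampled demes.
- Model-choice probabilities are renormalized after averaging network
  replicates; probabilities always sum to 1.
- The robustness-threshold grid step (0.01) matches percent-level
  reporting granularity.
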