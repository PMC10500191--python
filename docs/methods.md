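# Methods

## Problem setting

A rare, presumably pathogenic variant is observed in several families from
the same region. If the families descend from one founder, the chromosomes
carrying the variant should still share an ancestral segment around it, and
the length of that segment shrinks with the number of meioses separating
the carriers from the founder. The package covers the four computations
such a study needs: shared-region delineation from unphased STR genotypes,
MRCA dating from haplotype decay, penetrance tabulation with 2×2 proportion
tests, and ACMG evidence combining.

## Sharing model and delineation

Genotypes are unordered allele pairs (PCR fragment sizes in bp) at ordered
STR markers, typically one genotyped carrier per family, so no phasing is
possible. A marker is **shared** when the intersection of the informative
carriers' allele sets is nonempty; **discordant** when it is empty;
**uninformative** when fewer than two carriers are informative there. For
unphased data this intersection criterion is exactly equivalent to asking
whether some haplotype assignment consistent with every genotype places one
common allele series across the carriers (each marker's phase can be chosen
freely), which is what the exhaustive test oracle enumerates.

The **minimal** region is the consecutive run of shared markers containing
the variant, reported by its outermost shared markers and measured
marker-to-marker; the **maximal** region is bounded by the first discordant
marker on each side, with the map end acting as an open sentinel (the span
is then only a lower bound). Uninformative markers inside a run do not
break it but can never anchor the minimal interval — missing data is
absence of evidence. If several alleles are shared at a marker, all are
retained; no arbitrary tie-break. If a variant-adjacent marker is
discordant, the minimal interval is reported empty with a warning rather
than raising.

Adding a carrier can only shrink or preserve both intervals **on fully
observed genotypes** (intersections only shrink). With missing data the
guarantee has a corner: an added carrier can lift a marker from one
informative carrier (uninformative) to two (possibly shared), extending a
run. The property test therefore runs on fully observed inputs.

## MRCA dating

**Closed form.** Survival of a founder-linked allele through one meiosis
has probability 1 − θ; after *n* generations (1 − θ)ⁿ. Solving
(1 − θ)ⁿ = p gives n = log(p)/log(1 − θ). The study constants are exposed
as parameters (`p_term = 2/5`, `theta = 0.04`), never hard-coded; with them
n = 22.446, rounded (nearest, half away from zero) to 22. Years are
reported as `generations_exact × generation_time` with a default of
20 y/generation — at that default, 22.45 generations is ≈ 449 years. θ
entered by a user is taken as a direct probability; distances in cM are
converted through the Haldane map function θ(d) = (1 − e^(−2d))/2.

**Monte-Carlo inversion.** For each candidate generation count g on a grid,
the forward model (below) is simulated `reps` times and scored by the
fraction of replicates whose minimal shared cM span falls within a ±25%
relative band of the observed span. The point estimate is the grid argmax
and the interval covers every candidate scoring within a factor e² of the
maximum — a likelihood-ratio-style interval, not a claim of optimality. An
observed span of zero returns the grid maximum flagged as a lower bound
(total decay is only boundable from below). The internal simulation is a
vectorised implementation of the same generative model used by the cohort
simulator (including chance allele sharing from population frequencies),
so observed and simulated statistics are identically distributed.

A single minimal-span observation carries limited information: the span is
approximately Gamma(2)-distributed with mean 2/(k·g) Morgans for k lineages,
so any point estimator of g from it has a relative spread near 1/√2. The
package's guarantee is therefore stated — and tested — for the interval:
simulating at g = 20 with 5 lineages and dating each replicate, the
interval covers the generating value in ≥ 90% of 20 seeded replicates
(measured 20/20 at reps = 300, grid 2–60). Point estimates scatter widely,
as the validation script's output shows; this is a property of the
statistic, not of the implementation.

## Forward simulator

`k` carrier chromosomes descend independently from one founder through `g`
meioses (star genealogy; the families' internal pedigrees are not
modelled). Per meiosis, crossovers fall as a Poisson process with rate
1/Morgan on each side of the variant (Haldane — no interference, matching
the map function used everywhere else). A marker keeps founder descent
through a meiosis iff an even number of crossovers falls between it and the
variant, so per-marker retention after g meioses is exactly
(1 − θ_Haldane(d))^g — the bridge that makes the Monte-Carlo dater
consistent with the closed-form formula — while the contiguous retained
segment around the variant is bounded by the nearest crossover over all
meioses, giving Exp(g)-distributed one-sided lengths (mean 1/g Morgans,
censored at the map ends). Both properties are verified against their
closed forms at 10,000 and 5,000 lineages within three Monte-Carlo
standard errors.

Non-founder positions and the entire non-transmitted homolog draw alleles
i.i.d. from per-marker population frequencies; background LD is not
modelled (panel markers sit ≳0.4 cM apart, where r² between dinucleotide
STRs is negligible for the tested properties). Population frequency
vectors are built from a target heterozygosity H as one major allele plus
equifrequent minors, solving 1 − Σp² = H exactly; the packaged panel
spreads H evenly over the published range [0.63, 0.83]. Optional stepwise
mutation moves a transmitted founder allele ±1 ladder position with a
per-meiosis probability (default 0; used only to probe robustness of the
delineation). RNG streams are split per (seed, lineage), so enlarging a
cohort never perturbs existing lineages, and fixed seeds give byte-identical
fixture files.

What the simulator does **not** emulate: genotyping error and allele
dropout, homoplasy between founder and population alleles beyond what the
frequency model implies, relatedness structure within families, population
growth or bottlenecks. Passing tests therefore validate the estimators
under the model's own assumptions, not against those real-data artefacts.

## Penetrance statistics

Category counts may overlap (a carrier can have both cardiovascular and
connective findings); "unaffected" means all four flags false. "Any
arterial involvement" is defined as TAAD OR other-arterial, which is how
the 5/27 and 38/82 counts arise. The 2×2 test uses the Yates-corrected
chi-square with the correction clamped at zero (identical proportions give
exactly p = 1) and the closed-form chi-square(1) tail p = erfc(√(chi2/2)),
verified against numerical integration to 1e−10 and against an independent
library implementation. Tests are two-sided; no multiple-testing adjustment
is applied across the three comparisons, matching the comparison design the
cohort analysis uses. The literature reference cohort is carried as
published category totals (n = 82), not as reconstructed individuals.

## ACMG combining

The published combining rules are applied over default strengths (no
upgrades/downgrades). Conflict handling: if both sides would classify, or a
classifying side is accompanied by any tag from the other side, the result
is VUS. The classifier is a pure function of the strength multiset and is
checked exhaustively against an independently coded rule table over all
1024 subsets of a 10-code vocabulary. PP5 is accepted (with a deprecation
warning) because legacy classifications use it.

## File formats and conventions

MAP dialect: whitespace-delimited `chromosome name cM [bp] [het]`, `#`
comments, focal variant flagged by a `*` suffix on the chromosome label;
rows must be strictly increasing in cM (ties and disorder are errors, not
silently repaired). PED dialect: `family individual carrier` plus two
allele columns per marker in map order; missing is 0 and half-missing
genotypes are rejected. Physical positions are 1-based points; a region's
bp size is the difference of its bound markers' positions. Cohort tables
are tab-delimited with a header. All writers round-trip bit-exactly for
integers and at fixed six-decimal precision for cM.

## Fixture provenance

The study's raw genotypes are not public. The packaged fixtures are
reconstructions constrained by every published total: marker coordinates
chosen so the minimal/maximal spans equal 2.13 cM/1.92 Mb and
6.54 cM/4.14 Mb; a genotype table reproducing the published per-marker
sharing pattern of six probands from five families; and a 27-carrier
phenotype table matching the published composition (17 M/10 F; TAAD 4,
any-arterial 5, other cardiovascular 9, connective 14, unaffected 11;
family sizes 10/6/1/7/3) with ages only where individually published.
Assertions against published values are restricted to those totals and to
the marker-pair identities — never to the invented coordinates or
per-individual details.

## Problem sizes and numerical choices

Validation problem sizes: retention check at 10,000 lineages; segment
lengths at 5,000; dater grid 2–60 with 300 replicates per candidate;
recovery experiment over 20 seeds. Monte-Carlo assertions use 3-standard-
error bands. Frequency-vector feasibility requires H ≤ 1 − 1/k with a
1e−12 slack; frequency sums are validated to 1e−9. The chi-square tail and
Haldane conversions are evaluated in double precision throughout.

## Known limitations

* Sharing is a necessary, not sufficient, condition for founder descent:
  population-frequency coincidences inflate apparent sharing, especially
  with few carriers; the dater accounts for this only through its matched
  generative model.
* The decay formula's two constants (p = 2/5, θ = 0.04) are inputs whose
  provenance the source study does not derive; neither published span
  converts to θ = 0.04 under any standard map function, so the package
  exposes them as parameters and attaches no interpretation.
* Star genealogy: shared internal pedigree structure between carriers
  would correlate their retained segments and is not modelled.
* The MC dater's point estimate is intrinsically noisy (see above); use
  the interval.
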