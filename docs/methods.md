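# Methods

This note documents the models, defaults, and design choices behind
`askit`, and what the simulation-based tests do and do not demonstrate.

## Haplotype construction

A locus is a single reference sequence plus ordered exon intervals
(internally 0-based half-open; VCF's 1-based and GFF3's 1-based-closed
conventions are converted at the I/O boundary).  The donor haplotype is
built by applying a table of fixed, non-overlapping variants in
VCF-anchored form (insertions/deletions carry one anchor base).  The
coordinate map is materialized as two integer arrays (haplotype→reference
and reference→haplotype); positions inside indel footprints map to a
sentinel.  This makes the round-trip identity outside indels, and length
conservation, exact by construction — both are asserted as properties.
Heterozygous (non-fixed) strain calls are excluded by default under the
inbred-strain assumption; variants overlapping N bases are rejected.

## Allele-specificity classification

A protospacer site found on the target haplotype is projected onto the
other allele through the coordinate maps.  Classes:

* `TARGET_ONLY_PAM` — the homologous window fails the PAM motif on the
  other allele.  Cleavage requires the PAM, so these guides cannot cut
  the other allele; this is the only class used for pair selection by
  default.
* `PROTOSPACER_VARIANT` — PAM present on both alleles, protospacer
  differs.  Reported but excluded from selection by default because
  discrimination through protospacer mismatches (especially outside the
  seed region) is unreliable; `allow_protospacer_variant=True` relaxes
  this.
* `SHARED` — window identical; `UNMAPPABLE` — window crosses an indel
  (excluded).

An N in the PAM motif matches any base (so a SNP at the N position never
changes a site's class), but an N in the *sequence* matches nothing:
an ambiguous base cannot guarantee a PAM.

Quality filters default to GC between 25–75% and no TTTT run (a Pol III
terminator for in vitro-transcribed guides); both are configurable, as
no single published standard exists.  Pair selection is deterministic:
the 5′-most qualifying site in the earliest coding exon, then the
farthest-downstream qualifying site in a different exon, maximizing the
expected deletion span; with fewer than two qualifying sites in two
exons the design is reported infeasible (with the best single sites)
rather than silently degraded.  Off-target counting is a plain Hamming
scan with a motif-matching PAM over both strands of a user-supplied
background; it is a coarse screen, not a substitute for dedicated
off-target scoring models.

## Founder genotyping

Fragment-length calls: peaks below 10% of the tallest peak in a
sample/assay are noise; each retained peak is matched to the nearest
per-allele expected amplicon length.  Within ±1 bp (default tolerance,
reflecting capillary sizing accuracy) the allele is wild-type; otherwise
the net indel is `round(observed − expected)`.  When the two alleles'
expected lengths differ by less than twice the tolerance, size alone
cannot assign the allele and calls are `ambiguous` — this is why
mistargeting is scored from clone sequences, which carry the
inter-strain diagnostic SNPs.

Clone calls: each Sanger clone is aligned globally (affine gaps, open
penalty ≫ extension, so one contiguous indel is preferred over
scattered gaps) against both alleles' amplicons; the allele of origin is
the majority vote over covered diagnostic SNPs, ties are `ambiguous`,
and clones under 90% alignment identity are rejected as cloning or
sequencing artifacts.  An indel is attributed to editing only within
±10 bp of a guide cut site (Cas9 cuts bluntly 3 bp 5′ of the PAM),
which separates edits from natural strain indels.

Frame classification: a net size not divisible by 3 inside the CDS is a
frameshift; in-frame indels are checked by translating the edited CDS —
a stop before 50% of the protein length counts as a premature stop.
ORF loss = frameshift or premature stop.  Indels with known size but
unknown position (fragment evidence) are classified on size alone.
A founder cohort summary counts animals, not clones: an animal is an
ORF-loss carrier with ≥1 target-allele ORF-loss call and mistargeted
with ≥1 non-target-allele indel call.

## Linkage mapping

The N2 design admits genotypes {heterozygous, homozygous-recurrent}
only.  Components:

* Segregation: 1-df χ² goodness of fit against 1:1.
* Map estimation: adjacent-marker recombination fraction over
  informative pairs, Haldane d = −50 ln(1 − 2r) cM, r̂ capped at 0.49
  (the distance diverges at ½).  Haldane (no interference) is used
  throughout and is isolated so another map function could be swapped
  in.
* Interval mapping: at each grid position (markers + pseudomarkers,
  default 1 cM) the heterozygosity probability is computed from the
  nearest informative flanking markers (missing flanks marginalized;
  individuals with no informative marker on a chromosome get the ½
  population prior).  The two-penetrance binomial likelihood
  (p₁ = P(phenotype|het), p₀ = P(phenotype|hom)) is maximized by EM
  over the latent genotype, vectorized across grid positions and
  permutation replicates.  EM runs from two symmetric starts
  (0.8, 0.2)/(0.2, 0.8) by default to avoid the mirrored local optimum;
  the null (p₁ = p₀) is a boundary point of the alternative, so LOD is
  clipped at 0.  Convergence is on the log-likelihood (10⁻¹⁰ for
  observed scans; permutations use a lighter 10⁻⁶ / 60 iterations since
  only the genome-wide maximum quantile matters).
* Permutation threshold: phenotype labels shuffled with a seeded
  generator; the threshold is the right-continuous empirical (1 − α)
  quantile of the per-permutation genome-wide maximum LOD (α = 1 gives
  the minimum of the maxima).
* Fine mapping: assuming full dominance, phenotypic individuals must be
  heterozygous and non-phenotypic homozygous at the causal position;
  each individual permits the region markers satisfying that, missing
  genotypes permit everything, and the interval is the tightest
  flanking-marker pair around the intersection (extending one marker
  into the adjacent gaps, since the causal position may lie between
  markers).  An individual permitting no position (phenocopy or
  genotyping error) empties the intersection; such individuals are
  reported and excluded from a recomputation only on request.  This
  logic assumes no double crossover between adjacent region markers —
  sound at the sub-cM marker spacing of dense STR fine mapping, which
  is where it is applied and tested; at multi-cM spacing rare double
  recombinants surface as reported inconsistencies rather than wrong
  intervals.
* Candidate filtering keeps interval genes whose expression in the
  relevant cell type reaches a user threshold; genes missing from the
  table are kept with an unknown-expression flag (conservative).

## Simulator

The generators define the study conditions; all are bit-reproducible
under a fixed seed.

* Strain pair: 8 kb locus, 19 evenly spaced 150-bp coding exons (CDS
  forced to a multiple of 3), background SNPs at 0.006/bp — the order
  of the genome-wide divergence between *domesticus*- and
  *musculus*-derived strains — plus planted PAM-gain SNPs (defaults in
  exons 5 and 12): the reference PAM triplet is written NGA and the SNP
  turns it into NGG on the donor haplotype, with the 23-nt window
  shielded from background SNPs so the planted site is provably
  target-only.  An optional strain indel exercises length-divergent
  amplicons.
* Backcross: one recombinant F1 gamete per chromosome per individual;
  recombination sampled independently per marker interval with Haldane
  probabilities (no interference, consistent with the mapping model).
  Phenotype is Bernoulli(penetrance = 1.0) for causal heterozygotes and
  Bernoulli(phenocopy rate = 0.0) otherwise.  Default panel: 559
  individuals; the default marker map is 19 autosomes × 5 markers at
  20 cM.
* Editing: per embryo, each allele × guide is cut independently
  (target 0.8 per guide, non-target 0.0 — the PAM is absent there);
  cut alleles draw one indel from a categorical size distribution over
  {−12..−1, +1..+6} weighted toward small deletions (the common NHEJ
  outcome; configurable, as no per-animal size table exists to fit).
  Readouts: per-allele peak sizes with Gaussian sizing noise
  (σ = 0.3 bp) and 10 TA clones per amplicon sampling the two alleles
  evenly.  Each embryo collapses to a single germline genotype per
  allele (founders are scored as single genotypes; clone-level
  mosaicism is not modeled).

What the simulations do not emulate: real chromatograms and their
artifacts, PCR amplification bias between length-divergent alleles,
crossover interference, population structure, incomplete penetrance of
real traits, or the real locus sequence (the published guide sequences
are only available as figure images).  Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
performance on any particular real dataset.

## Problem sizes in tests

The acceptance-style checks use: 100 replicate panels of 559 for
segregation; 200 simulated loci plus a 1000-embryo cohort for the
specificity guarantee; 100 replicate genome scans (n = 68, the size of
a typical initial scan cohort) with 200-permutation thresholds for
planted-locus recovery; 200 dense-marker pedigrees for fine-mapping
containment.  Permutation counts below the 1000 used for a final
published threshold are standard for calibration studies and keep the
Monte-Carlo error of the 95% quantile small relative to the LOD scale.

## Known limitations

* Only 3′-PAM (SpCas9-style) geometry is implemented, although the PAM
  motif itself is configurable IUPAC.
* Off-target counting is Hamming-distance only.
* F2/intercross designs, multi-QTL models, X-chromosome handling, and
  quantitative traits are out of scope; dominance of the donor allele
  is assumed in fine mapping.
* Fragment-length genotyping cannot see balanced (net-zero) indels and
  cannot assign alleles when amplicon lengths coincide; clone
  sequencing covers both gaps.
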