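# Methods

`adnasex` implements the computational core of an ancient-DNA authentication
and biological-sexing workflow for degraded skeletal samples: quality
filtering of aligned shotgun reads, quantification of post-mortem
deamination, damage-based read selection, the R_Y and R_X sex statistics,
mitochondrial consensus calling, and a mixture estimate of modern
contamination. Everything is exercised end-to-end against a truth-tagged
read simulator, so no external sequencing data are needed to validate the
pipeline.

## Read model and filtering

Reads are consumed already aligned (SAM/BAM via pysam, or a plain
tab-separated table) and stored with 0-based half-open coordinates; SAM's
1-based `POS` is converted on input. Minus-strand records are
reverse-complemented on demand so that damage offsets are always measured
from the original molecule's own 5′ end.

The filter chain retains reads with mapping quality ≥ 30 and fragment
length in the inclusive window [36, 70] bp (both bounds configurable —
different libraries have different length modes, and the 35 bp floor
additionally guards against spurious ultrashort alignments). Duplicate
molecules are collapsed on the key (chromosome, strand, 5′-most reference
coordinate of the molecule, fragment length), keeping the highest-mapq
representative with read-id tie-breaking; this emulates coordinate-based
duplicate marking without optical-duplicate logic, which is unnecessary at
this scale. Datasets are merged by concatenation followed by duplicate
collapse, so molecules sequenced in two libraries are counted once.

Reads containing indels are retained for per-chromosome counting but
excluded from damage profiling, where their terminal offsets would be
unreliable; the workflow otherwise never calls indels.

## Damage model

Terminal deamination is modelled as a geometric decay from each fragment
end:

    D(z) = δ · φ^z + ε

with `δ` the terminal amplitude (unitless, default 0.27 for an untreated
library and 0.084 after partial UDG treatment — roughly the three-fold
reduction expected of a successful partial-UDG protocol), `φ` the
per-position decay (default 0.5), and `ε` the background mismatch rate
absorbing sequencing error and polymorphism (default 0.01 for scoring real
alignments, 0.001 in the simulator where no sequencing error is drawn).
C→T substitutions are counted from the 5′ end and G→A from the 3′ end
only, i.e. double-stranded library geometry; single-stranded protocols are
out of scope. Offsets with zero opportunities are reported as undefined,
not zero.

`fit_damage_params` least-squares fits D(z) to the observed 5′ profile
(scipy `curve_fit`, parameters box-constrained to their valid ranges,
initialised from the profile head and tail). On noiseless analytic curves
the fit recovers parameters to ~1e-8; on 50k-read simulations the
amplitude is recovered well within 20 % relative error.

The per-read damage score is a log-likelihood ratio in nats: each matched
column with reference C (5′ frame) or G (3′ frame) contributes
`ln D(z)/ε` if the damage product is observed, `ln (1−D(z))/(1−ε)` if the
reference base is observed, and 0 otherwise (other substitutions are
equally likely under both models, and base qualities are ignored so the
score is computable from every supported input). Reads scoring at or above
the threshold — default 3, the conventional operating point for this kind
of score — are treated as authentically ancient. An undamaged modern read
can only accumulate non-positive contributions, so in the simulator's
contaminant model the damage filter excludes contaminants outright.

## Sexing statistics

With `nX`/`nY` unique reads on X/Y:

* **R_Y** = nY/(nX+nY), with the Wald interval R_Y ± 1.96·√(R_Y(1−R_Y)/(nX+nY)),
  clipped to [0, 1]. Call: female if the CI's upper bound < 0.016, male if
  its lower bound > 0.075, otherwise indeterminate.
* **R_X** = mean over the 22 autosomes of r_i = (nX/L_X)/(n_i/L_i), with the
  interval R_X ± 1.96·SD(r_i)/√22. Call: male if the upper bound < 0.60,
  female if the lower bound > 0.80. This CI is a reconstruction of the
  method's published normal-approximation form (per-autosome ratios, SD of
  their mean); the original appendix derivation was not available, so the
  interval should be read as "mean ± 1.96 standard errors across autosomes"
  rather than as a verbatim reimplementation. Note the r_i share the same
  numerator, so the interval reflects autosome-to-autosome scatter, not X
  sampling noise.

Autosomes with zero reads are excluded with a warning (fewer than two
usable autosomes is an error). Chromosome lengths default to the bundled
hg19 table and are fully overridable, which the simulated miniature genome
uses. Reported values are rounded half-up to 4 decimals; machine output
keeps full precision. When both statistics are computed the report states
each call and a combined verdict only when they agree — there is no
principled fusion rule for a conflict.

`sex_report` computes both statistics twice: on all quality-filtered reads
and on the damage-filtered subset, the standard guard against undamaged
modern contamination biasing the call.

## Mitochondrial consensus and coverage

The mito reference is circular; fragments may span the origin and every
aligned base is assigned to one position modulo the reference length. A
position is called to its majority base iff depth ≥ 5 and the majority
share is ≥ 0.80 (boundary inclusive, so 4-of-5 calls); failures are N with
the reason (`low_depth`/`low_frequency`), and a tie between top bases is
never called. Raising either threshold can only convert calls to N, never
the reverse. Coverage is summarised as min/max/mean depth with mean = total
aligned bases / reference length.

## Contamination mixture

Modern contamination of the mito data is estimated with a maximum-likelihood
mixture, a deliberately desk-scale replacement for the full Bayesian MCMC
machinery of the dedicated tools: one endogenous component (the called
consensus, scored with the damage-aware column model above) plus one
component per candidate contaminant haplotype in a user-supplied panel
(scored at the background rate only — modern molecules carry no post-mortem
damage). EM maximises all component weights to relative tolerance 1e-8
(log-likelihood asserted non-decreasing every iteration), and the reported
contamination proportion is 1 − w_endogenous, with a 95 % CI from a
non-parametric bootstrap over reads (default 200 replicates, seeded,
vectorised via multinomial read weights).

Two design points matter here. First, the likelihood is restricted to
reads overlapping at least one *diagnostic site* (a position where some
panel haplotype differs from the consensus); other reads carry no
divergence signal. Second, the contaminant side is a per-haplotype mixture
rather than a "best-matching panel sequence" score: with a best-match rule,
an endogenous read that mismatches the true contaminant haplotype simply
gets re-matched to a different, locally consensus-identical panel member,
destroying exactly the evidence that should count against contamination —
in simulation this inflated a true 10 % admixture to ~30 %, while the
mixture formulation (whose model family contains the generative truth)
recovers 0.099. Duplicating a panel sequence splits its weight but leaves
the total contamination estimate unchanged.

## The simulator

The simulator is the package's test bed and defines the conditions the
validation targets:

* **Genome**: 22 autosomes + X + Y at ~1/1000 of the hg19 chromosome
  proportions (i.i.d. uniform A/C/G/T; GC structure and mappability are
  explicitly not modelled), plus a full-length 16,569 bp circular mito
  genome — consensus and contamination need a realistic mito coordinate
  space, so it is not scaled down. Contaminant mito haplotypes differ from
  the endogenous sequence at exactly the configured number of sites
  (default 25, a plausible pairwise human mtDNA divergence).
* **Fragments**: lengths are log-normal parameterised by the mode (default
  38 bp; 47 bp is the other typical library mode), truncated to [20, 120]
  bp; origins are uniform over chromosome copies weighted by copy number ×
  length (XX: two X, no Y; XY: one each; autosomes two; mito copy number
  configurable — `mito_capture_config` sets it high enough to emulate
  hybridization capture, defaulting to 40,910 reads ≈ 108× mean coverage,
  the scale of the study data this workflow targets).
* **Damage**: endogenous reads are deaminated per D(z) with δ set by the
  UDG mode (none 0.27 / partial 0.084 / full 0.01, ε = 0.001); contaminant
  reads — mito from the first panel haplotype, nuclear from an undamaged
  genome of configurable karyotype — receive no damage at all.
* **Alignment**: reads are emitted pre-aligned at their true coordinates
  with the endogenous reference as mapping target, so contaminant mito
  divergence appears as mismatches. No mapper is run; consequently
  Y-mappability loss, which depresses real male R_Y to ~0.09 against hg19,
  is absent, and simulated male R_Y targets the idealized
  L_Y/(L_X+L_Y) ≈ 0.277 instead. Passing simulated-threshold tests
  therefore validates the statistics and their intervals, not real-data
  mapping artifacts.
* **Determinism and duplicates**: identical configs (including seed) give
  identical outputs; distinct reads are guaranteed distinct duplicate keys
  (collisions are resampled), so at duplication rate 0 duplicate removal
  is exactly the identity, and `duplicate_fraction` re-emits clones for
  dedup testing.

Fixtures are written as plain text: FASTA references, a SAM with MD/NM
tags (so parsing needs no reference), FASTQ, a lossless alignment TSV, and
the truth table. Origin-wrapping mito fragments cannot be expressed as a
single gapless SAM record and are written to the TSV only; the SAM always
validates against its header.

## Problem sizes and numerical choices

Validation runs use 50,000-read nuclear libraries (roughly 31–32 k after
filtering, of which ~3.6 % map to X/Y under the XY karyotype) and
40,910–75,000-read mito-capture sets; these sizes put every decision
statistic several standard errors clear of its threshold while keeping the
whole suite around one to two minutes. EM uses a 1e-8 relative tolerance,
the curve fit scipy defaults with bounded parameters, and report rounding
is decimal half-up (banker's rounding would disagree with published
4-decimal tables at ties).

## Known limitations

* No base-quality awareness anywhere; ε is a single pooled error rate.
* Double-stranded library geometry only; no single-strand protocols, no
  per-read Bayesian damage posteriors, no quality rescaling.
* The R_X interval is a reconstruction (see above).
* No mappability or GC modelling; thresholds tuned on real hg19 mapping
  (0.016/0.075, 0.60/0.80) are applied unchanged to the idealized
  simulated genome, where they are comfortably conservative.
* The contamination estimator assumes the panel spans the plausible
  contaminants and reads are independent; heteroplasmy appears only as
  uncalled (N) consensus positions.
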