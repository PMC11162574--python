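# Methods

This note records the models behind each stage, the tunable parameters and
their defaults, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the methodology left room.

## Expression preprocessing

Expression values (FPKM or TPM; the unit is treated as an opaque label) are
transformed as log₂(v + 1). Genes with transformed values below 1 in every
tissue are removed as likely transcriptional noise; the threshold is strict,
so a gene with exactly 1.0 in one tissue survives. Duplicate triples are
removed when either copy's synonymous divergence Ks is ≥ 3 (substitution
saturation) or missing; missing values are counted separately and never
imputed. Triples with any member removed by the expression filter are
dropped and logged. All filters report per-gene lists in a `FilterReport`,
and the tissue order (stem, leaf, flower, silique by default) is enforced
to be identical across matrices because the Euclidean distance is
order-sensitive.

## Fate classification

Distances are plain Euclidean on log₂(v+1) profiles. The combined
parent+child profile sums the two copies' transcript abundances on the raw
scale and re-log-transforms — log₂(2ᵖ + 2ᶜ − 1) — because abundance of a
merged two-copy unit is additive in transcripts, not in log space.

*E*<sub>div</sub> defaults to the 0.90 linear-interpolation quantile of the
single-copy ortholog distance distribution, overridable either as a
quantile or as an explicit value. A high quantile of between-species
divergence among genes that did not duplicate operationalizes "the
expression change expected from speciation alone"; with q = 0.90, ten
percent of genuinely conservation-like comparisons exceed the cutoff by
construction — this is an intrinsic property of the calibration, verified
by the null-calibration check below. Classification needs at least 30
single-copy distances, otherwise an explicit cutoff must be supplied.
Boundary ties (distance exactly *E*<sub>div</sub>) count as "within", i.e.
toward conservation. A degenerate all-zero distance distribution yields
*E*<sub>div</sub> = 0, which the ≤/> rules still classify correctly; the
cutoff is therefore validated as non-negative rather than strictly
positive. The four rules partition the distance space exhaustively, which
the suite proves by enumeration.

## Divergence statistics

τ = Σᵢ(1 − xᵢ/x_max)/(n − 1) on non-negative profiles (undefined when
all-zero); computed on the same log₂(v+1) profiles used for distances, so
the two statistics describe the same object. τ is scale-invariant and
bounded in [0, 1]. Correlations are Pearson product-moment with a two-sided
t-based p-value (n − 2 df), with pairwise-complete deletion per covariate
(a record missing Ka still contributes to the τ panel). Correlation records
are built per duplicate copy — each copy contributes its own distance to
the ancestor, its own τ and its own Ka/Ks entries.

## Cis/trans categories

Ratios use replicate-summed counts with a pseudocount (default 0.5 per
side) to avoid infinities; per-replicate log ratios are retained for the
replicate-level tests. An optional library-size rescaling (default on) puts
the progenitor-mix counts on the allopolyploid's total depth; within-sample
ratios are unaffected, only count magnitudes change. Pairs with all-zero
counts on either side of a ratio are untestable and routed to category VII
with a reason.

The category map is the McManus-style scheme: conserved (no significant
divergence anywhere), cis-only (A≠0, B≠0, A=B), trans-only (A≠0, B=0,
A≠B), enhancing vs opposing (all three significant, distinguished by
whether sign(B) = sign(A−B)), compensatory (A=0, B≠0, A≠B), ambiguous
(everything else). The map is a pure function of three flags and two signs
and partitions the full combination space (proved by enumeration).

Significance machinery is pluggable, with three built-in backends and a
callable hook for externally computed p-values (e.g. a negative-binomial
model fit from a differential-expression package):

- **pooled** (default): z-tests on per-replicate log ratios with the
  variance pooled across all pairs. With three replicates a per-pair
  variance estimate has 2 df, far too weak for FDR selection across
  thousands of tests; since overdispersion dominates counting noise, the
  log-ratio variance is nearly homogeneous across pairs and pooling it is
  the simplest form of the information sharing that moderated-t /
  dispersion-shrinkage methods perform. With thousands of pairs the pooled
  estimate is effectively exact, hence the normal reference.
- **t**: per-pair one-sample t (A, B) and Welch t (A vs B). Honest but
  underpowered at 3 replicates; provided for larger designs.
- **binomial**: exact binomial test on pooled counts against a 1:1 split.
  Appropriate only when counts are Poisson-like; under biological
  overdispersion it is severely anticonservative, which is why it is not
  the default.

All p-values are Benjamini–Hochberg adjusted; the significance threshold is
FDR < 0.05. Summaries report counts and proportions pooled and per tissue,
and two call sets are compared with a Pearson chi-squared test on the 2×7
contingency table (categories absent from both sets dropped).

## Methylation

Expression classes: non (< 0.001 FPKM), low (0.001–5), medium (5–50), high
(> 50); the "between" intervals are closed on the right. Region levels are
coverage-weighted — Σ methylated reads / Σ total reads over covered
cytosines — which makes levels additive across split call files and robust
to coverage variation; a region with fewer than `min_sites` (default 3)
covered cytosines is NA. The promoter is 2,000 bp upstream of the TSS and
the downstream region 2,000 bp past the TES, strand-aware, truncated at
position 1 with a log message when a gene sits near the chromosome start.

Meta-gene profiles use fixed 100-bp bins over each 2-kb flank (20 bins per
flank) and 40 proportional-position bins over the gene body; these defaults
follow common WGBS practice and are configurable. Genes shorter than the
body bin count (in bp) are excluded and counted. Minus-strand genes are
flipped so bin 0 is always the far 5′ end; the suite checks mirror-image
invariance under genome reversal. Contexts (CG/CHG/CHH) can be profiled
separately or combined. The methylation–expression association reuses the
Pearson machinery on (region level, log₂(FPKM+1)) pairs.

## Transmission

A bias state per generation is A>C, A=C or A<C: A=C whenever the
FDR-adjusted q-value is ≥ α (default 0.05), otherwise the direction sign
decides. The nine patterns are the fixed 3×3 enumeration — I: gt→gt, II:
eq→eq, III: lt→lt (group A, inherited); IV: gt→eq, V: lt→eq (group B, bias
lost); VI: eq→gt, VII: eq→lt, VIII: gt→lt, IX: lt→gt (group C, novel or
reversed bias) — and the enumeration is emitted in output headers so
results are self-describing. The maintenance rate is the fraction of
parental A=C pairs whose progeny state is also A=C. The same machinery
runs on expression q-values (in the pipeline, taken directly from the
cis/trans stage's A and B tests) and on methylation differences, tested
per pair with a chi-squared two-proportion test on pooled region counts
followed by BH adjustment (pluggable like the expression tests).

## Synthetic data

The generators emulate the study design — four tissues × three genomes,
three replicates — with standard generative assumptions: Gaussian noise on
log₂ expression, negative-binomial read counts (variance μ + φμ²),
binomial bisulfite calls. All randomness flows through one seeded
generator; identical seeds give bitwise-identical datasets, and every
generator returns a truth table aligned by id.

**Fate generator.** Ancestral log₂ profiles are uniform on (2, 8) per
tissue. Two stochastic components are deliberately distinct:
`noise_sd` (default 0.25) is technical/replicate noise on every observed
profile, while `species_sd` (default 0.35) is neutral between-species
drift that separates the members of a single-copy ortholog pair. Planted
conserved copies carry only technical noise — functional conservation
means selection holds the copy at the ancestral optimum while the
calibration set drifts. This separation is what makes planted fates
recoverable at all: if conserved copies drifted exactly like single-copy
genes, a q = 0.90 cutoff would misclassify ~18% of them by construction.
The special fate label `"null"` generates duplicates that *do* drift like
single-copy genes, for calibration checks: the fraction of null triples
with *E*<sub>P,A</sub> ≤ *E*<sub>div</sub> must match q. Diverging copies
are shifted upward by `divergence_offset` (default 1.5 log₂) in a random
subset of at least half the tissues — a 1.5-unit shift in a single tissue
produces a distance of ~1.5, indistinguishable from a typical
*E*<sub>div</sub> of ~1.4, so single-tissue shifts are not planted.
Subfunctionalized copies split the ancestral raw abundance over a
complementary tissue partition, so their raw sum reproduces the ancestor
exactly before noise. A Ka/Ks table is attached with a planted 5% of
saturated (Ks ≥ 3) entries to exercise the filter.

**Count generator.** Each pair draws a base mean from the per-pair share
of a 10⁶-read library (±1.5 log₂ uniform) and a planted category; cis and
trans effects are placed symmetrically on the A/C means so that the
progenitor-mix ratio is cis+trans and the allopolyploid ratio is cis.
Default effect magnitude is 2.0 log₂ with NB dispersion 0.05 and 3
replicates, set by power analysis: with three replicates the per-replicate
log-ratio SD is ≈ 0.47, and a 2.0-unit effect gives the pooled z-tests
comfortable margin over the FDR selection threshold, whereas 1.5 sits near
the recovery boundary.

**Methylome generator.** 500 genes (bodies ~0.8–1.2 kb, random strand) on
a 2-Mb single-chromosome genome, one gene per ~4-kb slot so that 2-kb
flanks never overlap a neighbouring gene body (flank–flank overlap is
harmless because the flank level, default 0.8, is gene-independent).
Cytosines every 10 bp cycle through the three contexts; calls are binomial
at coverage 20. Gene-body methylation is either class-specific (defaults
0.35/0.25/0.15/0.05 for non/low/medium/high — monotone decreasing with
expression) or, in correlated mode, drawn jointly with expression from a
bivariate normal at a requested Pearson r using clip-only margin
transforms so the correlation survives the mapping.

**Transmission generator.** Pattern frequencies default to a composition
in which parental legacy dominates (group A 86%), loss of parental bias is
the main change and reversals are rarest, yielding an eq-maintenance rate
of ~97%; significance inputs realize each planted state deterministically
(q = α/10 with the right sign, or q = 0.5).

What the generators do **not** emulate: mapping artefacts and positional
biases, expression correlation between neighbouring genes, library-size
imbalance between replicates, non-uniform cytosine density, DMRs, partial
methylation contexts with different baseline levels, and any linkage
between the fate, cis/trans and methylation datasets (they are generated
independently). Passing recovery tests therefore demonstrates correctness
of the algorithms under the stated generative models, not performance on
real sequencing data.

## Pipeline, determinism and problem sizes

The `run-all` pipeline reads only files, writes one TSV per stage plus a
JSON manifest (package version, resolved config, selected E_div, filter
counts), and is byte-identical across reruns with the same seed. Stage
outputs never overwrite another stage's files.

The shipped checks run at deliberately modest scales — 400 planted triples
(80 per fate) with 2,000 single-copy pairs, 5,000 null triples for
calibration, 1,000 count pairs, a 2-Mb methylome with 500 genes (4 Mb /
1,000 genes in correlated mode), and 10,000 transmission pairs — chosen so
every planted signal is estimated with sampling error well inside its
tolerance while the full suite and the acceptance script each finish in
tens of seconds on a single CPU.

## Known limitations

- The binomial backend is retained for Poisson-like data but is the wrong
  tool under biological overdispersion; the pooled backend assumes
  near-homogeneous log-ratio variance across pairs, which holds when a
  common dispersion dominates, and degrades gracefully (conservative for
  low-variance pairs, anticonservative for high-variance ones) when it
  does not.
- Welch's t-test on three replicates per side has ~2–4 effective df;
  trans-effect detection at that design is intrinsically weak unless
  variance is pooled.
- Region levels weight cytosines by coverage; an unweighted site-mean
  variant is not currently exposed.
- The fate classifier consumes duplication-type labels and parent/child
  roles as given; for WGD pairs without a positional parent the labels are
  taken from the input as-is.
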