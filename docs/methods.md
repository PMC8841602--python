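# Methods

This note records the models, parameter choices and numerical conventions
behind `polyload`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study system and data model

The pipeline assumes an allopolyploid clade with the structure of the cotton
genus: two diploid progenitor species (labelled A1 and D5), six allopolyploid
species (AD1 and AD3–AD7) descended from a single polyploidization and
carrying an At and a Dt subgenome, and three outgroup species (K1–K3) used
only for polarization. All variants are biallelic SNPs with diploid genotype
calls per sample; polyploid samples contribute one diploid genotype per
subgenome because reads map to subgenome-specific coordinates of the
polyploid reference (the reference species is AD1). Coordinates are 0-based
half-open internally, 1-based in VCF, converted once at the I/O boundary.

## Phylogenetic depth classes

Every polarized variant is assigned by parsimony to the stem branch of the
clade of carriers (tips with derived allele frequency > 0); patterns that are
not a single clade would need more than one gain and are reported AMBIGUOUS,
counted only at the deepest depth. Branch assignments map to three nested
depth classes: `clade_wide` (the branch lies inside either progenitor-side
subtree), `since_prog` (strictly below the split of a subgenome lineage from
its sampled diploid progenitor — for diploids, their own terminal branch),
and `within_poly` (strictly below the polyploid crown ancestor). Variants
shared across the two subgenome groups (pre-divergence mutations, gene
conversion, and outgroup-shared states that any outgroup-consensus
polarization necessarily mispolarizes) are removed by SNP retention
criterion 3 before depth statistics are computed, which is why the merged
stem path can safely be flagged clade-wide.

## Polarization

The ancestral allele is the allele carried homozygously and concordantly by
at least `min_outgroup_species` outgroup species (default 2 of 3).
Heterozygous or internally discordant outgroup species do not vote: a
"confident" ancestral call requires homozygosity. The default of 2 trades
resolution (one outgroup may be missing at any site) against robustness to
outgroup-private alleles; it is exposed as configuration.

## Conservation score

RS = E − O per site. E is the branch length of the neutral tree spanning the
species present (gapped species are excluded from both E and O); O is the
Fitch-parsimony minimum number of substitutions on that spanning subtree.
Fitch is a lower bound on the true substitution count, so RS is, if
anything, inflated for fast-evolving sites; this is adequate for ranking and
binning, and an externally computed per-site score track can be supplied in
its place (the pipeline's default path for synthetic data uses the
generator's score track). The focal genome's row is excluded from scoring so
derived alleles in the assayed lineage cannot depress their own scores.
The neutral tree is calibrated at 4-fold degenerate third-codon positions
(codon family 4-fold degenerate in every ungapped row): JC69-corrected
pairwise distances fit to the fixed topology by nonnegative least squares,
with saturated pairs (raw mismatch ≥ 0.75) rejected by name. Branch lengths
are clamped at zero by the NNLS fit. Scores above 6 are clamped into the
strong bin rather than silently discarded, since the bin definitions stop
at 6.

## Load statistics

Count load is Σ p over a class × depth × lineage cell; GERP load is Σ p×RS
restricted to RS > 0; proportion deleterious divides the externally flagged
deleterious load by the nonsynonymous load (flags must be a subset of
nonsynonymous variants — violated input is an error, not a warning).
Relative increase per bin divides a lineage's bin load by its diploid
progenitor's; a zero reference bin gives NA. π uses the unbiased sitewise
pairwise estimator 2j(n−j)/(n(n−1)) over nonmissing haplotypes, summed and
divided by the concatenated CDS length of retained pairs. Positions
nullified by the all-heterozygote filter are excluded from numerator and
denominator by default (`pi_exclude_nullified`); the alternative reading —
excluding positions with any missing call — is available behind the same
flag because the underlying definition is ambiguous in the field's usage.

## Synthetic clade generator

The generator emulates the statistical structure the analysis assumes, not
sequence evolution per se:

* **Tree and rates.** A fixed species tree with branch lengths in neutral
  substitutions/site, scaled at ≈0.003 per million years: outgroups split
  7 Mya, progenitor genomes 5 Mya, sampled progenitor lineages 2 Mya,
  polyploid crown 1.3 Mya with splits at 1.0/0.8/0.5/0.3 Mya. Mutation
  events per branch are Poisson with expectation μ × branch length × CDS
  sites; all events hit distinct ancestral sites, so every site is biallelic
  and multi-hits are excluded by construction.
* **Classes.** An event is synonymous with probability 0.3; 45 % of
  nonsynonymous events are deleterious with selection coefficient s drawn
  from a gamma DFE (shape 0.5, mean 10⁻³). With Ne = 25,000 this puts the
  bulk of deleterious mutations around 2·Ne·s·h ≈ 1–30, spanning the
  nearly-neutral boundary s ≈ 1/(2Ne) where drift and selection trade off.
  Dominance h = 0.25 (deleterious mutations partially recessive).
* **Retention.** Two paths. Fixation: a new mutation with heterozygous
  selection s·h_eff fixes with the diffusion probability relative to
  neutral, R = 2N(1−e^{2sh_eff})/(1−e^{4Nsh_eff}), evaluated with the
  branch's Ne; internal-branch events are fixation-path only. Segregating
  (terminal branches, 40 % of candidates): retained with probability
  1/(1 + 2·Ne_ref·s·h_eff), the mutation–selection-balance scaling of
  equilibrium frequency, with frequency drawn Beta(½, ½). The segregating
  path deliberately uses a fixed reference Ne: equilibrium frequency under
  mutation–selection balance is Ne-independent, so a bottleneck (smaller Ne
  on polyploid branches) moves only the fixation path, while masking —
  h_eff = h(1−m) on branches below the polyploid stem — rescales both.
  This is what lets the bin diagnostic separate the two scenarios: under a
  bottleneck the strong-s segregating load is unchanged (bin ratio ≈ 1)
  while mildly deleterious fixations inflate; under masking the strong bin
  inflates by ≈ 1/(1−m).
* **Conservation score truth.** Deleterious events score
  min(6, 1.2·ln(1+s·Ne_ref)) ± 0.25 uniform noise; non-deleterious events
  score in (−1, 0]. This encodes the monotone s→score relationship the bin
  analysis relies on without re-deriving an alignment-based score.
* **Artifacts.** Homoeologous exchanges: pairs (rate 0.05) get a copy state
  drawn from {0:4, 1:3, 3:1, 4:0} applied to all polyploid individuals'
  expected depths. Collapsed regions: extra all-heterozygote sites (rate
  0.001 per unused site) planted for one species group, with AD6+AD7 pooled
  exactly as the analysis merges them. Gene conversion (rate 0.01 per
  eligible event): the derived allele of a subgenome-side event is copied,
  fixed, into one carrier polyploid's other subgenome at the linked
  coordinate (the reference species is excluded as a target so reference
  haplotypes stay conversion-free). So that planted collapses are the only
  all-heterozygote signatures (and their recovery can be asserted exactly),
  genotype sampling never leaves a species all-heterozygous by chance: one
  individual is flipped to the nearer homozygote.
* **Depth.** Per-gene mean depth is a negative-binomial read total over the
  CDS divided by its length (variance m/L + d·m²); dispersion d = 0 is
  exactly deterministic, which the noiseless recovery tests use. The small
  default (5·10⁻⁴) reflects that a mean over hundreds of positions has far
  less variance than a single-site count.
* **Determinism.** One master seed feeds ten named substreams (layout,
  sequences, mutations, DFE, retention, frequencies, genotypes, artifacts,
  depths, scores); identical parameters give byte-identical files.

What the generator does **not** emulate: read-level errors and mapping bias,
recombination within genes, indels between homoeologs (CDS lengths are equal
by construction, so the CDS-length filter and gap-link criterion are
exercised on constructed fixtures rather than simulated data), codon-level
sequence evolution, shared standing variation across species boundaries, and
demographic trajectories richer than a per-branch Ne. Passing tests
demonstrate that the pipeline's logic is correct under its stated
assumptions, not that those assumptions hold for any particular dataset.

## Replicate experiment sizes

The replicate experiments (masking grid {0, 0.3, 0.6, 0.9} and the
bottleneck scenario) use 50 seeds per condition, 2,000 gene pairs of 300 bp,
and 3 individuals per species; the masking-only scenario sets m = 0.9
(strongly recessive mutations fully shielded, the regime the masking
hypothesis concerns) and the bottleneck-only scenario halves the polyploid
Ne with m = 0. Artifact rates are zero in these scenarios, since QC removal
of planted artifacts is validated separately and would only subtract
variants uniformly. A 300 bp gene keeps a grid of 250 simulations at
laptop/CI scale while leaving several thousand deleterious variants per run.

## Numerical conventions and edge cases

Alignment: global affine with match +2 / mismatch −3 / gap open −5 / gap
extend −2, end gaps penalized; the first alignment in the aligner's
deterministic traceback is used, so results are platform-stable. Alleles of
opposite-strand homoeologs are compared under A↔T / C↔G complement. Zero
total depth for a pair in one individual is missing evidence (the individual
is skipped), not grounds for removal. Boundary fractions exactly at
37.5/62.5 are retained (the removal condition is strict). SNP retention
criterion 4 (fixed-in-diploid versus segregating-in-subgenome contrast) is
implemented but off by default: read conjunctively with criterion 3 it would
exclude nearly all sites, and the two cannot simultaneously be satisfied by
most real patterns, so it is exposed as `criterion4` for users who want the
strict reading. Degenerate retention inputs clamp (s < 0 → 0, h and m into
[0, 1]) rather than raise, because the generator feeds it vectorized draws.

## Stage commands

The CLI's stage subcommands (`qc`, `link`, `polarize`, `load`) execute the
shared orchestrator from the same config and report their stage's artifact,
rather than re-implementing partial pipelines; stage outputs are therefore
always mutually consistent, and `run` remains the primary entry point.
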