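# Methods

## The codon substitution simulator

Orthologous CDS pairs are generated by evolving a common ancestor along two
independent lineages under a GY94-style continuous-time Markov chain on the
61 sense codons. The instantaneous rate of replacing codon *i* by codon *j*
is zero unless they differ at exactly one nucleotide, and otherwise
proportional to

&nbsp;&nbsp;π<sub>j</sub> · κ^[transition] · ω^[amino-acid change] · m^[transition at a CpG-context site]

with π the equilibrium codon frequencies (uniform over sense codons by
default), κ the transition/transversion rate ratio, ω the
nonsynonymous/synonymous rate ratio, and m ≥ 1 the CpG hypermutability
multiplier. Proposals that would create a stop codon carry rate zero, so the
process is a proper chain on sense codons and no simulated CDS ever contains
an internal stop. CpG context is evaluated dynamically on the current
sequence (a substitution can create or destroy context, including across
codon boundaries). The initiation codon is held fixed, mirroring the
absolute functional constraint on the start codon.

Simulation is by Gillespie exact simulation per sequence. Rates are
normalized so that one unit of the path length *t* equals one expected
substitution per codon at equilibrium; the normalizer is computed with the
CpG multiplier off, since CpG context is sequence-dependent. *t* is the
total ancestor→A plus ancestor→B path and is split equally between lineages
(pairwise estimators only see the total). `calibrate_time_for_ks` inverts
the model's equilibrium synonymous event fraction and κ-weighted synonymous
site count to find the *t* giving a target Ks; it ignores multiple-hit
effects and is accurate to a few percent at Ks ≈ 0.5.

Default generator conditions (used by the end-to-end pipeline unless
overridden): 100 pairs × 200 codons, κ = 2, ω = 0.2, t = 0.8, m = 4, UTRs of
50 nt. The validation regimes fix their own parameters: ω ∈ {0.02, 0.2, 1},
κ ∈ {1, 2, 5} with *t* calibrated for Ks ≈ 0.5 for estimator recovery, and
ω = 0.02 (the magnitude typical of strongly conserved between-species
ortholog sets) for the purifying-regime check.

What the generator does **not** emulate: indels (alignments of simulated
pairs are gap-free by construction — the aligner is exercised separately on
its own tests), assembly artifacts, read-level noise (counts are drawn
directly from the NB model), lineage-specific rates, and codon-usage
differences between species. Passing tests therefore demonstrate
correctness of the estimators and accounting under the model family they
assume, not robustness to misassembly or alignment error.

### Transcripts, hit tables, counts, annotations

Transcripts are UTR5 + CDS + stop + UTR3 with iid-uniform UTRs, re-drawn
until the planted ORF is the unique longest complete ORF (so CDS prediction
round-trips exactly on clean data). Hit tables are fabricated in BLAST
outfmt-6 with rank-consistent bitscores — the orthology stage consumes only
ordering, lengths and e-values. True pairs receive mutually best rows with
match length equal to the shorter transcript and agreeing reference
accessions; planted confounders exercise each filter (199 nt matches,
discordant reference accessions, 150 nt CDS, internal stop codons).

Internal-stop confounders deserve a note: a longest-complete-ORF finder can
never emit a CDS containing a stop, but trained gene predictors (the kind
used on real transcriptomes) can and do read through them on frameshifted or
chimeric transcripts. The generator therefore also writes an
external-predictor-style CDS call table (`orf_hints.tsv`) carrying its
intended coordinates — including deliberate read-through calls for corrupted
transcripts. The CDS stage uses such calls when supplied and its own ORF
finder otherwise; the internal-stop filter then catches exactly the
read-through miscalls, as it does in a real pipeline.

Counts are negative-binomial with gene mean = base mean × relative library
size × 2^(±log2FC/2) and variance μ + φμ²; φ = 0 degenerates to Poisson.
Defaults: 2 replicates per species, library sizes around 10⁶, φ = 0.05,
log-normal base means (log-mean 5, log-sd 1), fold change 2 on a 10%
background of genes, pathway annotation of 20 × 15 genes with 2 planted
enriched pathways at 80% DE membership.

## Ortholog identification

Hits shorter than 200 bp are discarded first; each query's best surviving
hit is the maximal bitscore, ties broken by lower e-value then
lexicographically smaller subject id, making the cascade deterministic and
input-order independent. A pair is kept iff the two best-hit maps are
mutually consistent. Each member's best reference-protein hit (same ranking,
no length filter — the 200 bp minimum belongs to the reciprocal step) must
exist at e-value ≤ 10⁻⁵ and both accessions must agree; a stricter mode
(`--strict-unambiguous`) additionally rejects members with more than one
distinct accession below the threshold.

## CDS processing

The ORF finder scans all six frames for complete ORFs (ATG…stop, no internal
stop, not spanning an ambiguous base) and returns the longest, preferring
forward frames then smaller start. "CDS longer than 150 bp" is read strictly
(≥ 151 nt excluding the terminal stop). Pairs are aligned in protein space
(global alignment, BLOSUM62, gap open 10 / extend 1, first optimal traceback
— deterministic) and back-translated, which guarantees frame-preserving
whole-codon gaps. The standard nuclear genetic code (translation table 1) is
used throughout. Columns containing a gap or N in either row are excluded
from all downstream site accounting, whole codons at a time (degeneracy is a
property of the complete codon).

## Site-class divergence

A codon position is nondegenerate (nd) if every single-nucleotide change
alters the amino acid and fourfold-degenerate (4d) if none does; variants
creating stop codons are excluded from the denominator (so TTA position 2,
whose only non-stop variant is nonsynonymous, is nd). A column enters the
nd or 4d tally only when **both** species' codons assign it that class;
discordant columns are "mixed" and count in the CDS region only. Means and
standard errors are across pairs, unweighted, matching the loci-based
structure of classic divergence tables; "compared kb" pools sites.

CpG context is annotated on the **first species only** (default
`--cpg-mode first`). This is a measured design decision: flagging a column
when *either* sequence shows a CG (a common reading) is ascertainment-biased
— a mismatched column has two chances to carry a CG — and inflates the
CpG-cell divergence by ~19 standard errors under a simulator with the CpG
effect switched off; requiring *both* sequences deflates it symmetrically.
Single-genome annotation is the only variant that is calibrated under the
CpG-neutral model; the alternatives remain available behind the flag. The
price is that the CpG/non-CpG split of the divergence table depends on which
species carries the annotation (context-free cells remain exactly invariant
under swapping the species).

A second, genuinely biological confound is documented rather than removed:
CG-containing codons are enriched for degenerate positions (arginine's CGN
box is 4d at position 3), so under purifying selection CpG-context sites
diverge more than non-CpG sites even with no CpG rate effect. The
CpG-calibration validation therefore runs at neutral ω = 1, isolating the
rate effect; at multiplier 4 it is detected at ≈ +16 SE. Real divergence
tables' CpG/non-CpG contrasts mix both causes.

## Ka/Ks estimation

Both estimators share conventions: mutations to/from stop codons are
excluded from site and difference counting, with per-position renormalization
so every compared codon contributes exactly 3 sites (S + N = 3 × codons,
exactly); multi-difference codons are resolved by enumerating substitution
pathways that avoid stop codons (all orderings are used as a fallback in the
rare case every ordering is blocked); pairs with Ks = 0 report ω as
undefined rather than infinite, and the batch summary reports the number of
pairs for which both rates were estimable.

**NG86**: equal-weight site fractions and pathway averaging, Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3) applied to pS and pN independently
(one may saturate while the other is estimable); saturation at p ≥ 3/4.

**YN00**: F3×4 codon frequencies from the pooled position-specific
nucleotide frequencies of both sequences; κ estimated from
transition/transversion proportions at nd and 4d columns (classes agreeing
in both sequences), each corrected under K80 and combined weighted by site
counts; site counting weighted by target-codon frequency × κ; difference
counting weighted per pathway by ∏ π(target)·κ^ts·ω^nonsyn, summed over both
traversal directions so estimates are exactly symmetric under sequence swap;
dS and dN corrected with the two-parameter (K80) formula on their ts/tv
components; ω iterated from 0.5 to relative tolerance 10⁻⁶ (max 100
iterations; non-convergence is flagged and the last iterate reported).

The closed-form K80 κ estimator uses the transition distance a =
−½ln(1−2P−Q) + ¼ln(1−2Q) (= αt) and transversion distance b = −½ln(1−2Q)
(= 2βt), giving κ̂ = α/β = 2a/b; it inverts exact K80 probabilities to
machine precision and matches numerical ML to 10⁻⁴. Per-pair κ̂ is a convex
function of noisy proportions, so batch summaries quote its median rather
than its mean.

Validated behaviour: across κ ∈ {1,2,5} × ω ∈ {0.02,0.2,1} (100 replicate
500-codon pairs at Ks ≈ 0.5), YN00's median ω̂ is within 15% of truth in
every cell. NG86 is within 25% except the (κ=5, ω=1) corner, where its
structural blindness to transition/transversion bias gives ≈ −29%; an
independent reference implementation of the same counting method is biased
further on identical alignments, so this is the method, not the code. At
ω = 0.02 the batch mean YN00 ω̂ over 200 pairs is ≈ 0.018.

## Differential expression

TMM factors follow the trimmed-mean-of-M-values recipe: reference = sample
whose upper-quartile count rate is closest to the mean of upper quartiles;
log2 ratios trimmed 30% per tail by M and 5% per tail by A, weighted by
inverse asymptotic variance; factors scaled to geometric mean 1. Counts are
then scaled to a common effective library size and rounded; a single common
NB dispersion is estimated by pooled method of moments,
φ̂ = Σ(v−m)/Σm² over within-group means/variances, floored at 10⁻⁴ (a
`--dispersion` override supports sensitivity checks). Each gene's two group
sums are compared by a two-sided exact NB test conditioned on their total
(p = probability mass of outcomes no more likely than the observed split);
log2 fold changes use a pseudo-count of 0.5 — for reporting only, never for
testing. BH step-up adjustment is applied across all tested genes, and a
gene is called when |log2FC| > 1 (strict) and FDR < 0.05 (strict).

This is a deliberately simple, fully specified pipeline rather than a
re-implementation of any particular package's dispersion machinery; its
acceptance surface is calibration: the null false-positive rate at p < 0.05
lands in [0.03, 0.07] on 2000-gene NB simulations, and planted
|log2FC| = 3 genes at mean ≥ 200 are called with power > 95%.

## Enrichment

Over-representation is the one-sided upper-tail hypergeometric test, exact
by pmf summation (verified against full enumeration for every configuration
with ≤ 20 elements). The high-divergence set is the genes strictly below the
lower quartile (linear interpolation) of amino-acid identity; the quantile
is a parameter. The universe defaults to the annotated tested genes and can
be widened to all tested orthologs. No gene-length bias correction is
applied; both raw and adjusted p-values are reported because pathway-level
results routinely show nominal enrichment that does not survive adjustment.

## Determinism and problem sizes

All randomness flows through explicitly seeded numpy generators; pipeline
outputs are plain text with fixed float formatting, so identical seeds give
byte-identical runs (this is itself under test). The validation suite uses
60–200 pairs of 100–500 codons per scenario and 400–2000 genes for the
count models — sizes at which every systematic effect checked is several
standard errors wide while the whole suite stays quick on one CPU.

## Known limitations

- Gap-free simulation means alignment robustness is tested only on
  synthetic gap cases, not on evolved indels.
- NG86 is provided as the classical baseline; its κ-blindness makes it
  unreliable beyond κ ≈ 5 at high ω (see above). YN00 is the default.
- The common-dispersion NB test is anti-conservative if counts carry strong
  gene-wise dispersion heterogeneity; with 2 replicates per group a tagwise
  treatment is not identifiable, which is why the calibration test pins the
  realized false-positive rate instead.
- Cross-species count comparability assumes reads were counted over the
  shared orthologous regions; no transcript-length correction is applied.
- The CpG/degeneracy compositional confound means observed CpG vs non-CpG
  contrasts on real data overstate pure hypermutability under selection.
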