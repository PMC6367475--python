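# Methods

`mirarray` reimplements, as a tested library plus CLI, a common insect
epigenomics workflow: profiling mature miRNAs on a spotted oligonucleotide
microarray across four host cohorts — a fungus-resistant and a susceptible
*Galleria mellonella* line, each infected or uninfected (R+, R−, S+, S−) —
in two tissues (cuticle, fat body), then predicting the targets of the
differentially expressed miRNAs in an unannotated transcriptome assembly.
Because no raw arrays or assemblies ship with the package, a synthetic-data
generator with machine-readable planted ground truth stands in for the
bench data, and every pipeline stage is validated by recovery of that
truth or by equivalence with an independent brute-force oracle.

## Synthetic data model

`simulate.SimConfig` fixes the study conditions. Defaults: 300 miRNAs of
18–24 nt (mature-miRNA length range), 400 contigs of 600–1,200 nt, four
cohorts × two tissues × three replicates (24 arrays), probe triplicates per
miRNA (900 probe rows), planted log2 fold change ±2, replicate noise
SD 0.25 (log2), intensity-bias amplitude 0.8 (log2), additive background
with mean 60 fluorescence units. The miRNA and transcriptome scale is a
deliberate desk-scale emulation of a multi-thousand-probe array rather than
a reproduction of any particular platform; all counts are configurable.

Each contig is `5' pad + ORF + 3' tail`. The ORF is ATG, 38–148 random
non-stop codons, and a stop; the tail may carry a planted target site for
one designated miRNA. Two site styles exist: `site_context="full"`
(default) plants the reverse complement of the whole miRNA — so the site
both contains the exact 7-mer seed complement and supports a stable
full-length hybrid — while `"seed"` plants the bare 7-mer.

Two deterministic scrubbing passes give the fixture its recovery
guarantees. First, every spurious ATG outside the planted start loses its G
by a G→C substitution; because no stop codon and no ATG contains C, this
can neither create a stop in the planted frame nor a new start anywhere.
Second, ATGs whose G cannot be touched (inside the planted stop codon or a
planted site) keep it, and if their reading frame would otherwise run to a
stop ≥ 30 codons away, a TAA is placed just past the protected span
(insertion positions are reserved so fixes in different frames cannot undo
each other). The result is that the 3'-most-complete-ORF rule provably
recovers the planted ORF, and therefore the planted UTR, on every contig.
This makes the tails slightly poorer in ATGs than random sequence — a
trade accepted so that UTR recovery is exact rather than statistical. With
`scrub_background_seeds=True` the tails are additionally cleared of chance
seed matches for any configured miRNA, which the no-false-positive scan
test uses.

Microarray signal on the log2 scale is per-miRNA baseline (uniform on
8–13) + planted cohort×tissue effect + bias + Gaussian noise, emitted
linearly with the background added to the foreground channel. The bias term
is `amplitude × c_k × g(baseline)` with per-sample coefficients `c_k`
spread evenly over [−1, 1] and `g` a linear ramp over the baseline range
scaled to [−1, 1]. The ramp is the classic intensity-dependent channel
bias as seen in MA space; a curved (sine) shape was evaluated and rejected
because a locally-linear smoother at span 0.3 leaves a ~0.06 log2
curvature residual, defeating the point of a fixture whose bias the
normalization stage is supposed to remove essentially completely.
Replicates are modeled independent (no replicate correlation structure is
asserted for the emulated platform). A single `numpy` Generator seeded
once drives all draws in a documented order (miRNAs → contigs in order →
baselines → DE assignment → background → noise), so all outputs are
byte-stable for a given configuration.

Planted differential expression: for each tissue and each test cohort
(S+, R+, R−), `n_de_per_comparison` miRNAs (default 20) receive a ±2 log2
offset on that cohort×tissue cell relative to the S− reference. Draws are
independent across the six contrasts, so overlaps (the same miRNA planted
in two cohorts) occur and exercise the Venn intersection cells and the
R+/S+ exclusion rule.

## Preprocessing and differential expression

Background subtraction is `max(F − B, 1.0)` per spot; the 1.0-unit floor
keeps log2 defined and is an artifact choice (no floor is standard across
scanners). Normalization forms, per sample, M = log2(sample) −
log2(reference) and A = their mean against a pseudo-reference array (the
per-probe median of all samples' log2 intensities — the single-channel
analogue of two-channel MA normalization), fits a robust locally-weighted
linear regression of M on A (statsmodels LOWESS, span 0.3, 3 reweighting
iterations), and subtracts the fit. Fewer than 10 probes is refused as
insufficient support. The residual-trend diagnostic (`ma_trend`) reports
the maximum absolute fitted trend over the central 90% of the A range.

Probe triplicates are collapsed to one value per miRNA per sample by their
mean. The mean rather than the median is deliberate: with three spots and
independent spot noise the median forfeits roughly a third of the
information (SD factor ≈ 0.67σ vs 0.58σ), which at n = 3 arrays and a
±2 log2 effect over 0.25 noise drops paired-t recovery from ~97% to ~88% —
below what the pipeline's own recovery tests require of it.

Each two-group contrast uses a paired Student's t across replicate pairs
(samples paired by replicate index; the pairing key is an artifact choice),
log2 fold change = mean(A) − mean(B), and Benjamini–Hochberg adjustment
across all miRNAs of the contrast. One-way ANOVA is provided for >2-group
questions; two-group contrasts always use the paired t. The significance
call is gated on raw p < α with α = 0.01 for miRNA differential
expression (0.05 elsewhere), with the BH-adjusted p reported alongside:
this reproduces the headline-threshold convention of miRNA array studies
without discarding the correction. Zero-variance differences are flagged
degenerate (p reported as 1 for a zero mean difference, as the smallest
positive float otherwise); these arise only in noise-free fixtures.

qPCR-style relative quantification uses the Livak ΔΔCt model against a
housekeeping reference (e.g. 18S rRNA): ΔCt = Ct_target − Ct_ref per
condition, fold change = 2^(−ΔΔCt), with per-replicate folds retained for
paired testing.

## Cohort bookkeeping

All six cohort pairs within each tissue plus the fat-body-vs-cuticle
contrast within each cohort give 16 comparisons, reported uniformly. A
miRNA is "upregulated in X vs S−" iff significant and log2FC > 0 strictly;
no fold-change floor is applied. Before Venn partitioning, miRNAs present
in both infected cohorts' DE sets (R+ ∩ S+, per tissue and direction) are
excluded from both sets, then the three DE-vs-S− sets are partitioned into
the seven disjoint cells (singletons = "specifically" regulated, pairwise
and triple intersections). Partition recovery is scored on the
element-of-set membership indicators (miRNA × three groups, over the union
of both partitions): the cells are derived from exactly these indicators,
and an indicator metric degrades gracefully — a single false positive at
α = 0.01 perturbs one indicator, not an entire cell assignment.

## ORF and 3'UTR annotation

ORFs are forward-strand only (contigs are assembled mRNA-sense
transcripts): every ATG is walked codon by codon to the first in-frame
stop (TAA/TAG/TGA); candidates shorter than `min_len_codons` (default 30,
a common de facto threshold — configurable) or containing N are dropped,
ATG-less or stop-less walks are reported incomplete. The reference ORF of
a contig is the complete ORF with the 3'-most stop (ties: longer, then
more 5'), because the putative 3'UTR is defined as the contig suffix
outside all confirmed coding sequence. Contigs without a complete ORF
yield no UTR. UTRs shorter than 7 nt (the seed length) are discarded.

## Seed matching and hybridization energy

The seed is miRNA nt 2–8 (1-based from the 5' end); a candidate target
site is an exact Watson–Crick reverse complement of the seed in the UTR,
found by exhaustive overlapping substring scan. A `literal_revcomp` variant
(taking nt 2–8 of the reverse-complemented miRNA instead) is available
behind a flag for comparison; the default follows the canonical seed
definition. G:U wobbles never count toward seed matching.

Each seed match is confirmed by the minimum free energy of the miRNA:site
hybrid over a window of the match ± 30 nt of UTR context (truncated at UTR
bounds; the window size is an artifact choice). The energy model is
intermolecular-only nearest-neighbor: allowed pairs are Watson–Crick plus
G:U; energy = helix initiation (+4.09 kcal/mol) + stacking terms for
adjacent pairs + an affine penalty (open 3.0, extend 0.5 kcal/mol per
unpaired nt, both strands pooled — so asymmetric loops pay per unpaired
base) for every interior loop or bulge; no intramolecular pairs, no
pseudoknots, no dangling-end or tandem-mismatch tables. Watson–Crick
stack doublets carry the standard Turner/Xia ΔG°37 values; the 20
wobble-containing doublets use a compact class approximation (wobble
stacked on C:G −1.40, on A:U −0.80, wobble-on-wobble +0.50). The table
ships as editable TSV (`mirarray/data/energy_model.tsv`) and is validated
on load (WC stacks ≤ 0, penalties ≥ 0). Absolute MFEs are therefore
model-dependent; nothing in the package compares them to any external
tool's numbers.

The optimum is computed by an O(n·s) dynamic program over "last pair"
states with running prefix minima implementing the affine loop transition;
an exhaustive enumeration of all hybrids is kept in the test suite as its
oracle. With the seed constraint on, only structures pairing every miRNA
position 2–8 are admissible (any allowed pair type; within the seed block
only target-side bulges are possible since every seed position must pair),
implemented by restricting the first-pair position, the loop transitions
across the seed block, and the final-state minimization. The reported MFE
is the re-summation of the traced-back structure's terms, which the DP
value must match to 1e-6 (asserted); the empty structure is not
admissible, so a lone pair scores exactly the initiation penalty. Sites
are retained when MFE ≤ −20 kcal/mol, the common literature convention;
under this model an AU-rich miRNA's *perfect* full-length duplex can
legitimately sit above −20 (an all-AU 18-mer helix reaches only about
−11.7), so the threshold is prominently configurable and recovery
guarantees in the tests are stated with the filter off.

Seed matches are searched in UTRs only (not whole contigs), and the
pipeline's target stage restricts the scan to the significantly DE miRNAs
when DE results are present, mirroring the screen-then-confirm order of
the underlying workflow.

## Pipeline

`mirarray <stage>` with stages `simulate, normalize, de, sets,
annotate-utr, targets, report, all`; one YAML config (CLI flags `--seed`,
`--out` win over the file). Every TSV artifact carries `#` metadata
headers (package version, hash of the analysis-relevant config, RNG seed);
no artifact embeds a timestamp, and stages never mutate other stages'
outputs, so a rerun is byte-identical. Missing upstream artifacts raise an
error naming the stage to run first.

## What the tests do and do not show

Oracle-equivalence tests (duplex DP vs exhaustive enumeration, seed scan
vs naive search, ORF finder vs every-ATG walk, BH vs the literal step-up
formula) establish algorithmic correctness exactly, independent of the
data model. The statistical tests — type-I fraction within 3 binomial SDs
of 0.01 on a 2,000-miRNA null, ≥90% signed recovery of planted ±2 log2
effects at n = 3, ≥90% Venn membership agreement, bias removal to <0.05
residual trend and 1e-3 idempotence — hold under the generator's
assumptions: independent Gaussian log2 noise, exactly additive effects, a
linear-in-log-intensity bias, clean backgrounds, balanced complete
designs. Real arrays violate all of these to some degree (heteroscedastic
and correlated spots, saturation, spatial artifacts, dye chemistry), so
passing tests certify the implementation, not platform-level performance
on bench data. The normalization-efficacy fixture is noise-free by design
to isolate bias removal; the type-I and power fixtures carry the full
noise model and exercise normalization in passing.

## Numerical choices and degenerate inputs

Background floor 1.0 unit; LOWESS uses a small interpolation delta
(0.003 × A-range) above 200 probes for speed; BH validates p ∈ (0, 1];
ANOVA and paired t flag zero-variance inputs rather than dividing by zero;
`duplex_mfe` returns +inf with an empty structure when no pair is possible
(e.g. poly-A vs poly-A) and errors on empty sequences, on seed-constrained
miRNAs shorter than 8 nt, and on seed-constrained windows shorter than
7 nt. Venn partitioning is order-invariant by construction (cells are
keyed by frozensets). All coordinates are 0-based half-open internally;
miRNA positions are quoted 1-based in user-facing text, matching the
"nt 2–8" convention.

## Known limitations

No dye-swap or multi-channel model; no empirical-Bayes variance
moderation (deliberately classical paired t at n = 3); no target-site
conservation, context scores, or target accessibility; no reverse-strand
or splice-aware ORFs; wobble stack energies are approximate by design;
the MFE threshold and site window are conventions, not fitted quantities;
UniProt-style functional annotation is consumed from a user-supplied
transcript→process TSV rather than fetched.
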