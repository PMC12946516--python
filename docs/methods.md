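# Methods

`homeobias` analyses homoeolog-level expression and chromatin bias in an
allotetraploid genome with two subgenomes, here labelled M and U (seven
chromosome pairs, `1M`–`7M` and `1U`–`7U`). This note documents the models
and procedures, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (the BED convention); GFF3's
1-based closed coordinates are converted at the I/O boundary in both
directions. The strand-aware coding start of a gene is the leftmost CDS base
on `+` and the rightmost on `-`; genes without CDS children fall back to the
gene span. Alignment hits are consumed as 14-column BLAST-style tabular
files (the 12 standard fields plus query and subject length), which is what
`-outfmt "6 std qlen slen"` produces. Fold-enrichment (FE) signal is a
per-chromosome step function read from bedGraph; overlapping intervals are
rejected. All readers and writers are gzip-transparent.

## Homoeolog pairing (iterative reciprocal best hits)

Hits are filtered on three inclusive thresholds: target coverage
(`aln_length / subject_length`) ≥ 0.90, percent identity ≥ 90, e-value
≤ 1e-5. Coverage is evaluated per hit with no HSP chaining. Each query's
best subject is chosen by bit score; ties break by lower e-value, then
higher identity, then lexicographically smallest subject id — the chain is
arbitrary but fixed, so the procedure is deterministic. Mutual best pairs
become dyads; all hits touching paired genes are removed and the cycle
repeats until a round yields nothing. Iterating rescues pairs masked early
by a stronger competing match (a duplicated paralog can absorb the best-hit
slot in round 1). Termination is guaranteed: every productive round removes
at least two genes. Genes never paired are reported as genome-unique.

Collinear blocks from an external collinearity tool are merged into
structural-rearrangement (SRA) regions when same-chromosome gaps are
≤ `max_gap_bp` (default 10 Mb, conservative relative to the 50 Mb analysis
windows). A gene is *rearranged* iff its midpoint falls inside a region; a
dyad is rearranged iff either member is.

## Expression metrics

A gene is *expressed* in a tissue at TPM ≥ 1 and *retained* for analysis at
cumulative TPM ≥ 10 across tissues (both inclusive). Global TPM is the mean
over expressed tissues, 0 for never-expressed genes. The coefficient of
variation uses the sample (n−1) standard deviation over all tissues, zeros
included; classes are conserved (CV < 0.35), intermediate, highly variable
(CV > 1), with exact boundary values closing onto the middle class (the
printed inequalities are strict on both sides, which would otherwise leave
gaps).

For a dyad in a tissue where at least one copy is expressed:

- `HEB = log2(TPM_M / TPM_U)`, with a copy below the expression threshold
  replaced by the pseudocount 1e-6 so the ratio stays finite. Positive
  values mean M-biased expression. Both copies silenced ⇒ undefined, dyad
  excluded. The same 1e-6 constant is used in the chromatin bias formula;
  both are configurable.
- `normTPM_M = TPM_M / (TPM_M + TPM_U)` and its complement — scale-free
  within-dyad proportions.
- Dominance is the nearest of the expected proportion vectors (0.5, 0.5),
  (1, 0), (0, 1) in Euclidean distance, which reduces to thresholds at
  normTPM_M = 0.25 and 0.75 (equivalently |HEB| = log2 3 ≈ 1.585). Exact
  ties go to `balanced`.

## Dyad dynamics (CMD deciles)

Per expressed tissue, the distance between the tissue's proportion vector
and the dyad's global proportion vector (from global TPMs) is the Euclidean
distance of the two 2-vectors, i.e. √2·|Δp|, ranging 0 to √2. The
coefficient of mean distance (CMD) is the mean over expressed tissues.
Dyads are ranked by CMD ascending (stable = closest to the global ratio),
ties broken by dyad id, and cut into deciles `floor(10·(rank−1)/n)`:
deciles 0–1 stable, 8–9 dynamic, the middle six intermediate — a fixed
20/60/20 split when n is divisible by 10. Proportion vectors (not raw TPM)
are used so the classification is invariant to absolute expression level; a
dyad with the same split in every tissue has CMD 0 regardless of magnitude.

## Chromatin bias

The per-gene H3K4me3 signal is the area under the FE step function over the
gene body plus 2 kb flanks (FE·bp, computed exactly from the step function,
not from binned values). The dyad-level bias is
`HPHB = log2((Area_M + 1e-6) / (Area_U + 1e-6))`, antisymmetric under
swapping the subgenomes. Binned gene profiles (upstream flank in fixed
20 bp bins, body rescaled to 100 bins, downstream flank) are length-weighted
mean FE per bin, read in transcription order; genes shorter than the bin
count get one bin per bp, and flanks truncated at chromosome ends keep
reduced weights. Peak presence is any reproducible-peak interval
overlapping a symmetric ±500 bp window around the coding start (a
downstream-only window is available via configuration, since H3K4me3 mass
sits mostly downstream of initiation sites). Peak calling itself is
upstream of this package: reproducible peak BED files and FE bedGraphs are
inputs. The "summit" metric is the maximum FE value over the flanked gene
window — a definition chosen here because the quantity is otherwise
unspecified.

## Rearranged-vs-control comparisons

Seven metrics are tested between SRA and control groups: HEB, HPHB and
dominance-category bias (DCB) at the dyad level; global TPM, summit FE,
expressed proportion and peak status at the gene level. The gene universe
is the dyad members; genes carry their own midpoint-based label. Continuous
metrics use the Kruskal–Wallis rank test (global) or the two-sided
Mann–Whitney rank-sum test (per region vs pooled control); categorical
metrics use the chi-square contingency test without continuity correction
(2×2 for proportions, 2×3 for DCB). Kruskal–Wallis on category codes is
ill-posed, so the contingency test is the default for categorical rows even
where a rank test is named for the whole table. The per-region comparison
is between two independent gene sets, so the unpaired rank-sum test is used
(a signed-rank test would require a pairing that does not exist).

The asymptotic Mann–Whitney p-value is computed with tie correction and
*without* continuity correction, so the two-group Kruskal–Wallis decision
and the rank-sum decision coincide exactly (z² = H); exact enumeration is
used when both groups have ≤ 8 observations and no ties. Benjamini–Hochberg
adjustment runs across the seven metrics for the global table and across
regions within each metric for the per-region table (the family choice is
configurable; the direction of adjustment is the step-up procedure with
cumulative minimum from the largest p). Significance stars: * ≤ 0.05,
** ≤ 0.01. Regions with fewer than 5 dyads are flagged `low_n` but still
tested. Degenerate inputs are defined rather than fatal: identical groups
give H = 0, p = 1; a contingency table with an empty row or column gives
p = 1; expected cells below 1 warn.

## Window-coverage analyses

Depth tables (chrom, bin start, depth) are averaged in fixed windows tiled
from 0, the last window truncated. Normalisation divides by the genome-wide
median of window means and is idempotent. A disomic-addition line is
assigned to the chromosome with the highest median normalised depth when it
reaches `fold_threshold` (default 1.5; an added disomic pair roughly
doubles coverage against the shared background, but skim coverage is
noisy); otherwise no call, with a warning.

Centromeres are local maxima of the 1 Mb-window CENH3 profile. A window
qualifies when its normalised depth reaches the chromosome median + 5
robust standard deviations (MAD × 1.4826) and its prominence reaches 3
robust SDs. Two floors are needed: height alone rejects background noise
excursions (pure prominence thresholds admit noise maxima, whose
peak-to-valley span easily exceeds a few MADs over hundreds of windows),
while prominence alone is what separates two closely spaced centromere
summits into distinct calls. On noiseless profiles the MAD collapses to 0;
both floors then fall back to 10% of the profile's dynamic range. Flat
profiles yield no call and are flagged; terminal windows are never peaks.
The reported midpoint is the summit window's center (a depth-weighted
centroid is available by option, for peaks spanning several windows).

## Synthetic data generator

The generator emulates the structure the pipeline consumes, with a truth
table for every planted feature. One global seed drives independent
per-stage substreams, so regenerating one layer never perturbs another;
outputs are byte-identical given the seed.

- **Genome**: `n_dyads` homoeologous pairs placed collinearly on 7 M/U
  chromosome pairs (default length 350 Mb), plus genome-unique genes per
  subgenome. Dyad partners share a gene length so that equal planted
  chromatin signal implies equal FE area. SRA blocks are contiguous runs of
  U-genome dyad genes relocated to the distal end of the next U chromosome;
  the intervals they land in define the SRA region set (13 blocks by
  default).
- **Hits**: reciprocal true hits per dyad (identity ~ N(98, 1.5) truncated
  to [90, 100], target coverage ≥ 0.92, e ≤ 1e-20), decoy paralog hits at
  rate 0.1 with identity 90–97 and a bit score strictly below the query's
  true hit, and one-directional dropout of true hits at rate 0.01.
- **Expression**: per dyad, a lognormal base abundance (log-mean 2.0,
  log-sd 1.2, i.e. median ≈ 7.4 TPM), a dominance class from the mixture
  (0.78, 0.12, 0.10 balanced/M/U, close to the proportions reported for
  natural allopolyploid tissues), an M:U split Beta-jittered around 0.5 or
  0.95 (concentration 60), a shared per-tissue multiplier (log-sd 0.4) and
  a per-copy ratio wobble (log-sd 0.25) that makes tissue-level bias
  fluctuate around the global bias (without it every dyad would have
  CMD = 0). Each copy is silenced (zeroed) with probability 0.08. Tissues
  are the seven sampled organs (seedling leaf/root, flag leaf, leaf sheath,
  whole spike, pre-anthesis spike, stem).
- **SRA perturbation** (off by default; the null genome carries regions but
  no effect): both copies of a rearranged dyad are scaled by
  `sra_tpm_factor` and silenced with extra probability
  `sra_extra_silencing` per copy, independently but at the same rate in M
  and U. The symmetry is the point: absolute expression and peak presence
  shift, while within-dyad ratios (HEB, HPHB) remain null — the qualitative
  contrast the comparison framework is designed to resolve. No effect-size
  estimates exist for real rearrangements; these are free parameters.
- **Chromatin**: background FE 1 everywhere; each expressed gene adds a
  body plateau of height log1p(global TPM) and, with probability 0.9, a
  peak interval within 500 bp of its coding start. Silenced genes stay at
  background.
- **Coverage**: 13 DA-line depth tables (every chromosome except 6U, for
  which no addition line exists) at baseline 1× with the added chromosome
  at 2×, Gaussian noise sd 0.1; one CENH3 table with a Gaussian bump per
  chromosome (height 6, sd 2 windows, noise sd 0.5), two bumps 8 windows
  apart on 5M.

What the generator does **not** emulate: sequence content, read-level
noise, mapping bias, tissue-correlated expression programs, TE landscapes,
copy-number variation, and chromatin signal unrelated to expression.
Passing tests therefore demonstrate that the pipeline's logic and
statistics behave as documented under controlled conditions, not that the
biological conclusions transfer to any particular real dataset.

## Verification strategy and problem sizes

The test suite checks each operation against hand-computed values and
independent brute-force oracles (an all-pairs RBH enumeration, per-bp step
function integration), property tests for the invariants (antisymmetry of
the log-ratio biases, scale invariance of proportions, monotone-transform
invariance of decile classes, permutation invariance), and statistical
calibration: with no planted effect, each of the seven comparison metrics
rejects at the nominal 5% level (600 simulated genomes of 2000 dyads);
with the symmetric perturbation (factor 0.5, extra silencing 0.05),
absolute metrics fire while relative metrics stay quiet in ≥ 90% of 100
replicates. Simulation studies use 2000 dyads — large enough for stable
rank tests and decile counts, small enough that a replicate takes a
fraction of a second. Replicate seeds are spawned from one master seed via
`numpy.random.SeedSequence`.

## Known limitations

- Dominance is a hard nearest-centroid classification; dyads near the
  log2 3 boundary flip between classes under small noise. The paper-style
  three-class summary hides that uncertainty.
- The decile split forces 20/60/20 regardless of the CMD distribution;
  class labels are relative to the cohort, not absolute.
- Chi-square contingency tests assume independent genes; homoeologous
  partners have correlated expression, so gene-level categorical tests are
  mildly miscalibrated when both members share a group.
- The per-region rank-sum tests reuse one pooled control, so region results
  are mutually dependent; BH within metric controls FDR only approximately
  under that dependence.
- `fold_threshold` for DA assignment and the peak height/prominence floors
  are heuristics chosen for well-behaved synthetic profiles; very noisy or
  very short chromosomes may need tuning.
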