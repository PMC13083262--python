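# Methods

## Read processing and isoform tabulation

Reads are processed per sample in three stages. Adapter trimming removes the
leftmost occurrence of the 3′ adapter, allowing the adapter to overlap the
read's 3′ end by as few as `min_overlap` bases (default 4) with a
configurable mismatch rate (default 0, i.e. exact matching); reads without a
detectable adapter are discarded and counted. Quality filtering keeps a read
iff its mean Phred quality strictly exceeds 30. The commonly used
alternatives — a percent-of-bases rule, or per-base trimming — behave
differently on mixed-quality reads; the mean rule was chosen because it is
deterministic and single-parameter, and the threshold semantics ("30 or
below is filtered") are preserved by the strict inequality. Assignment
string-matches the first 13 nt of the trimmed insert against the dictionary;
species sharing a 13-nt prefix (including processing variants of the same
guide) are collapsed into one entry named by joining the member names with
"/" in dictionary order. The isoform length is the full trimmed read length;
inserts below 13 nt or above 31 nt fall outside the tabulated range and are
counted separately. U and T are equivalent throughout.

Every rejection class is counted per sample, and the invariant
`assigned + adapter_rejected + quality_rejected + too_short + too_long +
unassigned = total` is enforced and tested. Mapping is order-independent and
collapsing is idempotent.

## Differential stability

The miRNA-level analysis compares 3 knockout against 3 control libraries.
After summing isoforms and applying the expression filter (strictly more
than 5 reads in at least 2 knockout libraries, and at least 30 reads across
all six — the first cutoff strict, the second inclusive, as the thresholds
are phrased), size factors are estimated by median-of-ratios: references
are miRNAs positive in every library, and each library's factor is the
median ratio of its counts to the per-miRNA geometric means (the median is
taken in ratio space, which matters when the reference count is even).

Fold changes use a deliberately transparent two-group negative-binomial
estimator rather than a GLM: `lfc = log2((mean normalized KO + 0.5) /
(mean normalized control + 0.5))`, with the pseudocount (0.5 in normalized
space) stabilizing miRNAs with zero counts in one group. The standard error
comes from the delta method with a per-miRNA method-of-moments dispersion
`alpha = (var − mean) / mean²`, averaged over the two groups and floored at
1e-8; the variance of a group mean is `(mean + alpha·mean²) / n`. The Wald
statistic `lfc / se` is referred to a Student-t distribution with
`n_KO + n_control − 2 = 4` degrees of freedom: the moment-based variance
estimate carries roughly that many degrees of freedom at this design size,
and a normal reference would be anti-conservative. This choice is validated
by simulation, not assumed: under a global null the empirical type-I error
at the 5% level is required (and tested) to fall in 0.05 ± 0.02 over more
than 1,000 simulated miRNAs. Multiple testing uses Benjamini–Hochberg;
any alternative adjuster with the same signature can be plugged into the
classification step.

Potentially ZSWIM8-sensitive miRNAs are flagged by three approaches:
(1) adjusted p < 0.05 with positive fold change; (2) the miRNA's fold
change separated from that of its passenger strand beyond their respective
standard errors — passengers are production-rate controls, so a mature
strand rising above its passenger implicates degradation; multiple
passengers are summed before estimation, and passengers are exempt from the
expression cutoff since many are lowly expressed; (3) membership in an
externally supplied list of previously called sensitive miRNAs. The
passenger rule is directional by default (mature above passenger),
matching the degradation rationale; an absolute-separation variant is
available via `directional=False`. The union of the three flags and the
significant set is excluded from isoform-level analysis.

Isoform-level fold changes reuse the size factors computed from the summed
counts — the `SizeFactors` object carries provenance and the isoform stage
refuses factors not derived from summed counts. Centering subtracts the
median fold change of all 22-nt species from every isoform, pinning the
22-nt distribution at exactly zero (22 nt is the dominant, presumptively
ZSWIM8-insensitive length). The short-isoform signal is assessed by a
one-sided Wilcoxon signed-rank test of the centered fold changes of
isoforms shorter than 19 nt against zero (alternative: greater, i.e. short
species accumulate after knockout), with the median centered fold change
reported as the effect size. The signed-rank test is this package's choice
of test — a robust, distribution-free default for a median-shift question —
not a claim about how the original observation was tested; zeros are
rank-split so a degenerate all-null input returns p ≈ 0.5. Isoform-level
p-values play no role in the exclusion logic, which operates at the summed
level only.

## Binding models

`eval_quadratic` implements the ligand-depletion isotherm for a titration
in which the active-complex concentration `DF·[stock]` is comparable to the
target concentration, so free and total ligand cannot be equated. It is
evaluated as `2·DF·stock / (b + √(b² − 4·DF·stock·target_T)) · F_max` with
`b = DF·stock + target_T + K_D`, which avoids the catastrophic cancellation
of the textbook `(b − √disc)` form near the stoichiometric limit; the
discriminant is clamped at zero against round-off. Equivalence with a
numerical mass-action equilibrium solver is enforced to 1e-10 over a broad
random parameter sweep.

`fit_quadratic_titration` estimates `(stock, K_D, F_max)` by bounded
least squares with K_D optimized in log space and F_max confined to (0, 1),
from a 3×3×3 grid of starts: stock at {0.1, 1, 10}× a nominal value (the
target concentration divided by the dilution factor nearest half-plateau),
K_D at {0.01, 1, 100} nM, F_max at {0.3, 0.6, 0.9}. The best-residual
solution is returned with diagnostics (residual norm, convergence, grid).
At least 4 points spanning a decade of dilution are required; a flat
response is rejected as unidentifiable. Requirements validated by test:
noise-free round trips recover all three parameters to 0.1%, and at 2%
Gaussian noise the median stock error over 50 replicates stays below 10%.

Gel quantification normalizes each band as
`(band − blank − (band_0nM − blank)) / (band_T6B − blank − (band_0nM − blank))`,
where `blank` is the mean of empty-region rectangles, the 0 nM lane removes
bait-independent background, and the T6B lane (a TNRC6-derived peptide that
binds AGO–miRNA regardless of the bound target) normalizes for complex
amounts, mapping to 1 by construction. Only the blank-rectangle background
model is implemented; lane-profile background estimation is out of scope.
Negative normalized values are clipped at zero with a warning. The
normalization is invariant to global intensity rescaling, so cross-gel
gain/exposure differences cancel within a gel but comparisons across gels
are outside the contract.

Fold enrichment divides normalized trigger by reference binding per shared
concentration; reference values at or below a floor (default 1e-3, roughly
the reproducibility of background subtraction on faint bands) censor the
fold into a lower bound, so "greater than N-fold" statements are
representable rather than silently divided by noise. `conc_at_pulldown`
interpolates linearly in log concentration between the two observed points
bracketing the requested level — appropriate for dose curves sampled on
log-spaced grids — and refuses to extrapolate. Single-site fits
(`R = R_max·c/(K_D + c)`) assume the titrated species is in excess; the
double-filter convention takes bound RNA on nitrocellulose and free RNA on
nylon, `fraction = nitro/(nitro + nylon)` after per-membrane background
subtraction.

## Duplex annotation

Pairing is Watson–Crick–Franklin by default; G:U wobbles are available
behind a flag but excluded from the defaults because the reference duplex
diagrams this package formalizes depict WCF pairs only. Guide nucleotide 1
is never paired (it is anchored inside AGO). A seed site is an exact
7-mer match of the reverse complement of guide nt 2–8; all occurrences are
reported. The 3′ register search enumerates every combination of unpaired
guide nucleotides (0–8 by default) and unpaired target nucleotides (0–16)
between the seed and the 3′ block, scoring the number of contiguous pairs
between guide nt ≥ 9 and the target upstream of the seed match; ties prefer
the smaller target loop, then the smaller guide loop. The loop bounds are
operational defaults reflecting the observation that triggers tolerate only
a limited range of internal-loop lengths; both are parameters. The search
is exhaustive within its bounds, and equivalence with an independent
enumeration oracle is enforced on random inputs up to 60 nt.

Classification thresholds are likewise operational, not measured constants:
`full` requires no internal loop and total pairing within 2 nt of the guide
length; `tdmd_like` requires at least 8 contiguous 3′ pairs reaching within
3 nt of the guide 3′ end plus a non-empty loop; `seed_only` allows at most
2 incidental 3′ pairs; everything else (including 3′ pairing that stops
short of the guide 3′ end) is `supplementary`. All four numbers are exposed
as keyword arguments. Flank lengths are measured from the outermost paired
target nucleotide to each target end and are invariant, like the
classification itself, to appending non-pairing flanking sequence.

## Synthetic-data generators

The simulators define the conditions under which the analysis is validated.

**Dictionaries.** `make_mirna_dictionary` emits one 22-nt mature and one
22-nt passenger per hairpin with distinct 13-nt prefixes, plus 12 nt of
templated 3′ hairpin context per species so isoforms up to 31 nt remain
prefix-consistent (real longer isoforms are templated or tailed). A
requested fraction of mature species is arranged into deliberate
shared-prefix groups of two (three if odd) to exercise collapsing; the
count is deterministic, `round(n × rate)`.

**Counts.** The expected count of species *i*, length ℓ, sample *j* is
`sf_j · base_i · profile_{i,ℓ} · 2^(KO_j · (lfc_tdmd_i + lfc_short_i · [ℓ<19]))`,
drawn as gamma-Poisson with per-species dispersion α (variance μ + αμ²).
The design is fixed at 3 knockout vs 3 control libraries. Defaults, chosen
once as plausible for deeply sequenced AGO-bound small-RNA libraries and
documented rather than calibrated to any particular dataset: base
abundances log-uniform over 50–5,000 (500–5,000 where recovery benchmarks
specify well-expressed miRNAs), dispersion 0.05, true size factors
log-uniform over 0.7–1.4, passenger abundance 5% of a typical mature, 10%
of matures TDMD-sensitive at log₂ effect 1, a length profile peaked at
22 nt (discretized normal, sd 1.2 nt) over a 0.005 uniform floor so
trimmed isoforms exist, and a short-isoform effect of log₂ 0.5 below 19 nt.
The generator reproduces its stated expectation in Monte-Carlo means and is
deterministic per seed.

**FASTQ.** Each count unit becomes one read: isoform sequence + adapter +
random filler to 60 nt; good reads carry per-base qualities Q32–40, bad
reads Q ≤ 30 across all bases, making the quality filter's decision
unambiguous. Contamination adds Poisson(rate × n) extra reads, half
unmappable and half low-quality. Ground truth is written as a JSON sidecar
next to the FASTQ files. At zero contamination the pipeline reproduces the
generating count table exactly for species with unique prefixes — the
round-trip property the test suite enforces.

What the generators do **not** emulate: sequencing errors, UMIs, ligation
bias, rRNA contamination, and any batch structure beyond scalar library
size. Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those artifacts.

**Gels and titrations.** Band intensity is
`background + gain · fraction_bound · ε` with log-normal ε of unit mean and
specified CV, plus blank rectangles at the background level; the T6B lane
corresponds to fraction 1 and the 0 nM lane to fraction 0. Titration series
evaluate the quadratic isotherm and add truncated Gaussian noise.

## Problem sizes

Simulation-based checks use sizes chosen to make their statistical
tolerances meaningful while keeping the suite quick: ≥ 1,000 miRNAs for
type-I calibration, ≥ 200 for fold-change recovery, 50 replicates for noisy
titration fits, 100 replicate gels for the enrichment benchmarks, 200–500
random cases for the oracle-equivalence sweeps. The whole suite and the
benchmark script each run in a few minutes on one CPU.

## Known limitations

* The fold-change engine is a transparent moment-based estimator, not a
  GLM with shared dispersion shrinkage; at very low counts its power is
  below that of empirical-Bayes methods, which is why recovery guarantees
  are stated for well-expressed miRNAs.
* The "significant" set uses BH on Wald p-values; specialized mixture
  models for this setting are supported only through the pluggable
  adjuster interface.
* Prefix mapping is exact-match; sequencing errors in the first 13 nt make
  reads unassigned rather than mismatched.
* Duplex annotation scores contiguous pairing only (no bulges within the
  3′ block, no thermodynamics); architecture classes are operational
  definitions.
* Cross-gel comparisons of normalized binding are out of contract; only
  within-gel normalization is modelled.
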