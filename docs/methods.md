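# Methods

## Scope and design

`sncatlas` re-implements, as a tested pipeline over synthetic data, the
comparative analysis of sperm small non-coding RNA content across five
regions of the bovine male tract (PAR, CAP, COR, CAU, SPZ; three replicate
bulls).  The package's claims are therefore about the *methods* — that each
stage computes what it says it computes, verified against independent
oracles and planted ground truth — not about bovine biology: real
conclusions require the real sequencing data.

## Synthetic data generator

The generator is first-class, tested code.  Each region is described by a
`RegionProfile`: an sncRNA class mixture, piRNA 5'-U (`pirna_u1_frac`) and
position-10-A (`pirna_a10_frac`) fractions, a piRNA length mode, a tsRNA
subtype mixture, an rRNA species mixture, and the fraction of piRNA reads of
mitochondrial origin.  The default profiles encode the published per-region
trends: piRNA share 0.78 (PAR) → 0.57 (CAP) → 0.20 (COR) → 0.13 (CAU) →
0.18 (SPZ); miRNA rising from 0.01 to 0.38 at SPZ; rRNA fragments peaking at
COR (0.46); U1 ≈ 0.80 at PAR/CAP, inverted (0.35–0.40) at COR/CAU; A10 ≈
0.25 everywhere except ≈ 0.60 at COR; piRNA length mode 30 nt at PAR versus
22 nt elsewhere; i-tRF share of tsRNAs from 0.19 (PAR) to 0.62 (CAU); 28S
dominating PAR/CAP rRNA fragments, 5.8S inflated at COR, 16S at CAU/SPZ.
Where a per-region value was not published (e.g. the COR class mixture, the
mitochondrial piRNA fractions) we fixed one plausible value; the profiles
are data, not tuning knobs.

Mechanics worth knowing:

* **Traits are planted, not sampled post hoc.**  piRNA references are
  generated in balanced (5'-U, 10-A) pools, and reads are 5'-anchored
  prefixes, so a region's U1/A10 fractions are hit exactly in expectation
  and are recoverable from the truth table by a binomial check.
* **Every insert is an exact fragment of its named reference** (before the
  optional sequencing-error step, which flags affected reads in the truth
  table).  tsRNA fragments are cut by the same anchoring rules the
  classifier applies; mitochondrial piRNA references are exact substrings
  of the bundled circular mt genome, drawn outside its rRNA genes so the
  class hierarchy stays unambiguous.
* **Abundances are lognormal** (sigma = 1.5, fixed per study).  Real small
  RNA libraries are dominated by a few species; the skew also guarantees
  features detected in every library, which median-of-ratios requires.
* **Library artifacts**: reads are insert + 3' adapter (19 nt, QIAseq-like)
  + 12-nt UMI, padded to 75 nt; adapter layout and UMI length are
  configurable because the kit's exact layout is not published.  PCR
  duplicates share insert and UMI within a duplication group
  (`dup_rate` = 0.25 → a geometric number of copies, ~25% duplicate reads);
  per-base qualities are 30–40 with a small (0.002/base) chance of a
  sub-Q25 call; sequencing errors hit the insert at 0.001/base.
* **Not emulated**: base-caller error profiles, ligation bias, RNA
  modifications, genomic multi-mapping.  Passing tests show the analysis
  recovers planted structure under these idealized conditions; they cannot
  show robustness to artifacts the generator does not produce.

## Preprocessing

Order is fixed: extract (trim adapter/UMI) → UMI collapse → filter → stack.
Collapse precedes filtering so a molecule is kept on its consensus quality:
each (insert, UMI) group keeps one exemplar whose per-position quality is
the arithmetic mean of the group, rounded half-up to an integer (so the
integer Phred filter downstream is well defined).  The filter keeps inserts
of length ≥ 17 with every base ≥ Q25 (both boundaries inclusive); reads with
N bases are rejected (configurable) since N has no meaningful quality here.
Adapter matching is exact-first-occurrence; the generator emits exact
adapters, and error-tolerant trimming is out of scope.  Deduplication is
exact (insert, UMI) identity — no UMI-network collapsing.

## Classification

Classification is exact substring matching of each unique tag against
mature reference sets, not genome alignment: the genome-mapping +
novel-miRNA-prediction stage of a production pipeline is deliberately
replaced by this desk-scale substitute, which is exact by construction and
testable against a naive-scan oracle.  Multi-class hits are resolved by a
configurable priority (default miRNA > tsRNA > rsRNA > piRNA — the most
specific, smallest reference sets first); within a class, ties break by
longest match span, then lexicographic reference id.  tsRNA fragments are
typed against the anticodon loop (anticodon ± 2 nt, a 7-nt loop): 5'-anchored
fragments ending in the loop are 5'-tRHs, 3'-anchored fragments (measured
against the CCA-inclusive 3' terminus) starting in the loop are 3'-tRHs,
otherwise anchored fragments are tRF5/tRF3 and everything else is i-tRF.
`end_slack` (default 0, deterministic) can relax the anchors by a base.
The isomiR windows (5' ± 2 nt, 3' ± 5 nt) are our operationalization of
"sequence variants of a canonical mature miRNA"; with substring matching
only trimmed variants occur.  piRNA vs "piRNA-like" is not distinguished —
only reference provenance is reported.

## piRNA signatures

Positional frequencies at positions 1–35 are weighted by expression
(weights = normalized counts by default; unweighted mode available since
the choice is not settled): freq(p, b) = weight of sequences with base b at
p over weight of sequences of length ≥ p, T reported as U.  A10/B10 shares
are computed over length-≥ 10 piRNAs only, with the short mass flagged
separately rather than silently counted as B10.  Mitochondrial matching
keeps only perfect full-length hits, on both strands of the circular
genome; circularity is handled by scanning genome + prefix(L−1) and
reporting canonical + strand starts in [1, L], and a match is labelled with
the first feature containing its + strand start.

## Normalization and differential screening

Size factors are median-of-ratios: features with any zero are excluded
from the median, and at least one all-positive feature is required (the
error message says so; the generator's skewed abundances make this hold in
practice).  Note the estimator is equivariant only up to a common factor:
scaling one of n samples by 10 multiplies every geometric mean by 10^(1/n),
so the invariant checked is that the scaled sample's factor grows 10× *
relative to every other sample*.

The differential screen is a deliberately simple NB Wald test, documented
as a stand-in for a shrinkage-based engine (the scientific contribution
here is the downstream comparative analysis, not the DE machinery): per
feature, group means of normalized counts; method-of-moments dispersion
α = (s² − μ)/μ² averaged over the two groups and floored at 1e-8; Wald
z = ln((μ_A+½)/(μ_B+½)) / √(Σ_g (1/(μ_g+½) + α)/n_g); two-sided normal p;
BH across features per pair.  The ½ pseudocount appears in the variance as
well as the fold change so that presence/absence features (the dominant
real signal along the tract) remain callable; a group observed at zero
behaves as "< ½".  Significance requires adjusted p < 0.05 *and*
|log2 FC| > log2(2.5), with the fold computed on pseudocounted means.
Calibration is checked by simulation: at the study's scale the null
BH-significant fraction is ~2% (bound 7%) and power for 4-fold changes at
mean 100 with α = 0.1, n = 3 vs 3 is ~0.95.

## Profiling

Profiles are normalized counts averaged over replicates per region, rows
centered and scaled (sd 0 rows dropped and logged).  K-means is Lloyd with
random initialization, best of `n_starts` (default 100) by within-cluster
sum of squares, `max_iter` 1000, deterministic given one master seed; it is
delegated to scikit-learn's Lloyd implementation (empty clusters are
repaired by relocation from the farthest points), with centroids recomputed
as final-assignment means so betweenss + withinss = totss holds exactly
(ratio defined as 0 when totss = 0).  The elbow rule chooses the smallest k
whose ratio ≥ 0.90 with marginal gain to k+1 below 1 percentage point —
"no significant improvement" has no published numeric rule, so both
thresholds are configurable.  On the default synthetic study the elbow
picks small k (~3): the planted region profiles generate only a handful of
distinct profile shapes, unlike real data; the 12-cluster capability is
therefore validated separately on a planted 12-profile matrix (centroid
separation > 4 noise sd), where the elbow selects k = 12 with ~0.99
information retained and ARI 1.0 against the planted labels.

BCA is computed from the inertia definitions rather than an ordination
package, so the ratio is testable in closed form: after feature-wise
centering, ratio = Σ_g n_g‖mean_g‖² / Σ_s‖x_s‖²; axes are the right
singular vectors of the √n_g-weighted class-mean matrix and sample scores
their projections.  Adding a constant feature does not change the ratio.

## Clustering input

By default the profile set is the union of features significant in at
least one region pair (configurable to all detected features), matching
the published choice of clustering differentially expressed sncRNAs.

## Pipeline and reproducibility

All stages read and write plain-text artifacts in one run directory; every
random draw descends from a single master seed (per-sample seeds spawned
deterministically), so identical (config, seed) produce byte-identical
artifacts and `report.json` (floats rounded to 10 digits for stability;
checksums are SHA-256).  Problem sizes used by the bundled scripts and
tests — 15 × 20k reads for the worked example, 15 × 50k for composition
recovery, 5 × 2 × 12k for the double-run determinism check — were chosen
as the smallest studies at which the respective statistics are stable.

## Known limitations

* Exact matching cannot express genomic multi-mapping or mismatch-tolerant
  alignment; recall claims hold only at error-free or near-error-free
  rates.
* The NB Wald screen has no dispersion shrinkage; with 2–3 replicates its
  per-feature dispersion is noisy and power at small fold changes is low.
* The generator's piRNA reads are 5'-anchored prefixes; real piRNA 3' ends
  vary by trimming *and* untemplated additions, which are not modelled.
* BCA axes are unscaled principal directions of the class means; no
  row/column weighting options as in full ordination frameworks.
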