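# Methods

`kataegis-storm` detects and characterizes kataegis — focal clusters of
closely spaced somatic single-nucleotide variants produced by APOBEC3
deamination of single-stranded DNA — in tumour whole genomes, and runs the
cohort-level comparisons that typically accompany such an analysis in
prostate-cancer genomics: evolutionary timing, APOBEC3A/B attribution,
structural-variant (SV) co-localization, burden regression and survival
stratification.  Because the WGS call sets such studies use are
access-controlled, the package ships a synthetic-cohort generator with full
truth labels; every stage is tested against that truth.

## Event detection

Per sample and chromosome, SNVs are sorted, duplicate positions collapsed
(keeping the first record — a zero distance would break the log transform),
and the inter-mutational distances (IMD) `d_i = pos_{i+1} - pos_i` computed.
The rainfall signal `log10(d_i)` is segmented by piecewise-constant fitting
(PCF): the segmentation minimizing

    sum_segments SSE(segment) + gamma_eff * (number of segments)

is found **exactly** by O(n²) dynamic programming (`pcf_segment`), with ties
broken toward fewer segments, then leftmost breakpoints, so results are
bit-reproducible and oracle-testable by exhaustive enumeration at small n.

Following the convention of copy-number PCF, `gamma` (default 25) is a
penalty on noise-standardized data; the effective penalty on raw log10
values is `gamma * sigma²`.  For a homogeneous Poisson mutation background
the spacings are exponential, and `log10(Exp)` has standard deviation
`pi / (sqrt(6) ln 10) ≈ 0.557` regardless of the rate, so `sigma` is fixed
at that model constant — deterministic and free of per-sample estimation.
An un-normalized `gamma = 25` would need an SSE saving of 50 to cut out an
interior cluster, more than a 4–6-SNV cluster can supply, and would miss
most minimal events.

Each IMD is replaced by its segment's mean ("adjusted IMD").  The default
adjusted value is the back-transformed mean of log10 IMDs — the level PCF
actually fits.  The arithmetic mean of raw IMDs is available
(`DetectionParams.adjusted_mode = "arithmetic"`,
`adjusted_imd(..., mode=...)`) but is not the default: when a segment
bridges two nearby clusters across one long gap (a singleton outlier that a
per-segment penalty of 25 will not isolate), one raw gap of hundreds of kb
drags the arithmetic mean above any bp threshold and both clusters are
lost, whereas the geometric mean stays at the cluster level.

A kataegis event is a maximal run of consecutive adjusted IMDs below
`d_max = 1000` bp joining at least `kmin = 4` SNVs — the fixed,
cohort-wide threshold pair.  Runs are additionally split wherever the *raw*
distance itself reaches `d_max`, so no called event contains an
above-threshold gap between consecutive members; this restores the defining
consecutive-distance property that a segment mean alone cannot guarantee.
`expected_imd_diagnostic(n, L) = L / n` is reported per sample so users can
confirm `d_max` sits far below the random expectation (≈ 1 Mb at 1 SNV/Mb).

## Evolutionary timing

SNVs with a cancer-cell-fraction (CCF) estimate, a multiplicity and an
overlapping allele-specific copy-number segment are assigned to epochs:

* `ccf < 0.9` → **subclonal** (point-estimate threshold; no CI machinery);
* else clonal, sub-labelled by multiplicity timing: on a gained locus
  (major CN ≥ 2) multiplicity ≥ 2 → **clonal_early**, multiplicity 1 →
  **clonal_late**; copy-neutral loci carry no timing signal →
  **clonal_unspecified**;
* missing annotations → **unknown**, excluded from all proportions.

A helper computes multiplicity from VAF
(`round(vaf * (purity * CN_total + 2(1 - purity)) / purity)`) when only VAF
is available; the pipeline otherwise consumes multiplicity as input.

"Evolutionary kataegis" refines each event by epoch: members are grouped by
label, and a group becomes an evolutionary event when it has ≥ `kmin`
members and all successive within-group distances are below `d_max` (raw
distances — PCF is meaningless on event-sized subsets).  A group passes or
fails as a whole; `unknown` members never form events.  On a cohort whose
SNVs are all clonal, refinement returns exactly the parent events.

Cohort epoch summaries report, per sample, the clonal fraction of kataegic
SNVs against the clonal fraction of all SNVs, compared by the paired
two-sided Wilcoxon signed-rank test (samples without events excluded; an
all-tied comparison degenerates to p = 1).

## APOBEC attribution

All counting is pyrimidine-normalized: substitutions and motifs on the
minus strand are reverse-complemented so the mutated base reads as C.
Motifs use W = A/T, Y = C/T, R = A/G: TCW is the APOBEC target, with the
preceding base separating APOBEC3A (YTCW) from APOBEC3B (RTCW).

For each event, mutated-cytosine counts in C and TCW are compared with the
sample's non-clustered SNVs by a one-sided Fisher exact test.  Motif
*accessibility* is controlled by counting motif occurrences (both strands)
in the union of ±20 bp windows around each set's SNVs — overlapping windows
merged first so dense clusters do not double-count — and rescaling the
background TCW mutation count by

    a = (ctx_tcw_event / ctx_c_event) / (ctx_tcw_bg / ctx_c_bg),

clamped so the rescaled count stays within the background total.  Raw
counts are always reported so alternative table constructions can be
recomputed.  p-values are Benjamini–Hochberg adjusted across all events of
the run; an event is APOBEC-enriched when FDR < 0.05 with odds ratio > 1
(an infinite odds ratio — a zero margin on the enriched side — qualifies).
Enriched events are then tested for YTCW and RTCW preference against the
context ratio (`[[mut_ytcw, mut_rtcw], [ctx_ytcw, ctx_rtcw]]`, one-sided
each way, BH across events per family): exactly one significant preference
assigns A3A or A3B; both or neither is `ambiguous`; non-enriched events are
`none`.  Contexts containing N are dropped and tallied.

## SV proximity

An event's SV distance is 0 when a breakend lies within it, else the
minimum gap from the nearer event edge to a same-chromosome breakend;
chromosomes without breakends yield the BEYOND sentinel.  Translocation
breakends count at both loci.

The null follows the pseudo-event construction: for each event, 1,000
intervals of the same span are centred on non-clustered SNVs drawn with
replacement from the same sample (clipped at chromosome ends).  Per patient
group (ancestry × risk), distances are histogrammed into log-spaced bins
(0–1 kb, 1–10 kb, 10 kb–0.1 Mb, 0.1–1 Mb, 1–10 Mb, 10–100 Mb, beyond;
BEYOND merges into the final bin so totals are conserved) and simulation
replicate *j* pools the *j*-th pseudo interval of every event.  Empirical
rank p-values per bin and direction use the +1 correction
(`p = (1 + #{sim ≥/≤ obs}) / (n_sim + 1)`), are BH-adjusted across bins ×
groups per direction, and classify bins as enriched / sparse / neither
(enrichment wins a double hit, logged).  Events falling in enriched bins
are **SV-associated**, in sparse bins **SV-independent**, else
unclassified.  A per-SV-type two-sided Fisher test (near any event within a
window vs not, this type vs others; chromothripsis-flagged breakends as
their own pseudo-type) screens for type-specific co-localization.

Calibration note: the rank p-values are valid because each event's pseudo
events are drawn from its *own* sample's SNV pool and events are spread
over many samples.  Concentrating many events on one small pool adds
pool-sampling variance the null does not model; the calibration tests
therefore emulate the realistic regime (≈ 4 events per sample against a
450-SNV pool, 300 events per group, 200 replicate groups) and check
uniformity on bins whose mean observed count is at least 5 — bins with
essentially constant counts are pure tie mass and carry no rank
information.

## Cohort statistics

* **Outliers**: burden z-scores computed once on the raw vector; samples
  with z > 3 are excluded with a recorded reason (no iterative
  re-computation; zero variance → no outliers).
* **Group comparisons**: two-sided Wilcoxon rank-sum (signed-rank when
  paired), exact when both n ≤ 25 without ties, else the normal
  approximation with continuity and tie corrections; BH across the declared
  family.
* **Driver co-occurrence**: per-gene two-sided Fisher tests of kataegis
  positivity × mutation presence, BH across genes, Haldane-corrected odds
  ratios at zero margins; the gene list is configuration, never hardcoded.
* **Burden regression**: negative binomial (NB2, log link) fit by maximum
  likelihood; skewed covariates (SV burden, TMB, chromothripsis burden,
  PGA, CN gain) enter as `log(1 + x)` so zeros are tolerated; ancestry and
  risk are dummy-coded; the dispersion and Wald statistics are returned.
  Near-Poisson data pushes the dispersion to its boundary, where the
  quasi-Newton step can stall with a vanishing gradient; a derivative-free
  polish accepts such fits.
* **Survival**: Kaplan–Meier product-limit curves per stratum (kataegis
  positivity, or burden above/below 1) with the two-group log-rank test;
  endpoints are BCR-and/or-metastasis or metastasis-only, the latter
  excluding BCR-without-metastasis patients; strata with zero endpoint
  events flag the p-value undefined.

## Synthetic cohorts

The generator emulates the statistical structure of the real inputs at desk
scale; defaults are the study conditions used throughout the tests:

| parameter | default | basis |
|---|---|---|
| genome | 3 chromosomes × 50 Mb, i.i.d. uniform ACGT | desk-scale stand-in |
| background rate | 1 SNV/Mb, uniform positions and substitutions | primary prostate tumour TMB |
| prevalence | 0.4 of samples kataegis-positive | reported ~40–50% |
| events per positive | 1 + Geometric, median 2, max 13 | reported burden range |
| SNVs per event | 4 + Geometric, median 6 | reported median 6 |
| member gaps | uniform 100–900 bp (median span ≈ 2.5 kb at 6 members) | sub-kb consecutive distances; ~2.7 kb spans |
| APOBEC omega | 0.9 of members at genuine TCW sites, C→T/C→G | APOBEC-dominated events |
| strand coordination | 0.9 | single-strand processive deamination |
| SVs | 60 breakend pairs/sample (DEL/DUP/INV/TRA 3:2:2:3), 10% chromothripsis-flagged | HR prostate SV burden |
| coupling rho | 0.55 of events anchored near a breakpoint, lognormal offset (median 2 kb, σ 0.45) capped at 10 kb | spanning/<1 kb/<10 kb fractions ≈ 13/40/50% |
| clonality | 68% of background SNVs clonal; 65% of events clonal; subclonal CCF 0.4, observation noise sd 0.05; purity 0.7 | reported clonal medians |
| copy number | whole-chromosome segments, 1/3 gained (2+1); clonal SNVs on gains early (mult 2) half the time | minimal timing-informative CN |

Targeted members snap to the nearest TCW occurrence of the chosen strand
within ± half the minimum gap (opposite strand as fallback), so motif
counting runs against genuine sequence context rather than a rewritten
reference.  Planted events are kept ≥ 10 kb apart.  Everything derives from
one `SeedSequence` tree, so identical config + seed gives byte-identical
output files.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic trinucleotide background spectra,
replication-timing and expression covariates of mutation density, clustered
SV architectures (breakend pairs are independent), multi-segment CN
profiles, sample contamination/purity error, and caller artifacts.
Recovery rates on synthetic cohorts are upper bounds on real-data
performance.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest sizes chosen as
the package's own defaults: recovery on 20 samples × 3 × 50 Mb;
calibration on 200 replicate groups of 300 events; attribution power/null
on ≥ 200 / ≥ 500 events at 3 × 20 Mb; NB recovery on 200 replicates of
n = 500; determinism on 6 samples × 3 × 8 Mb; the acceptance script on 60
samples.  DP tie tolerance is 1e-9; empirical p-values use the +1
correction and can never be 0; BH is the FDR procedure throughout.
Detection recovery counts a truth event as found when a called event
overlaps it.

## Known limitations

* The O(n²) PCF is exact but not suited to chromosomes with ≫ 10⁴ SNVs;
  hypermutated genomes would need a pruned DP.
* Minimal events whose internal gaps approach `d_max` can be missed when
  two clusters fall into one PCF segment across a single bridging gap
  (isolating a singleton outlier costs two penalty units, more than its SSE
  contribution): on the default generator conditions sensitivity is
  ≈ 0.9–1.0, and ≥ 0.95 for events of ≥ 5 SNVs spanning ≤ 2.5 kb.
* Epoch rules are point-estimate based; no CCF uncertainty propagation and
  no subclonal cluster deconvolution.
* The accessibility-adjusted 2×2 construction rescales the background
  side; other constructions are recomputable from the reported raw counts.
* Events with mixed epochs count once per qualifying epoch subset in the
  evolutionary tally.
* The rank-test p-values are discrete (grid 1/1001) and slightly
  conservative under count ties.
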