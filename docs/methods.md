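# Methods

## Scope

psiforge implements the computational path from aligned reads to
biology-level calls for three assays that together profile the H/ACA-box
snoRNA → rRNA-pseudouridylation axis in a paired-sample design
(tumour/normal tissue, or knockout/control cells):

1. **Ψ-seq** — reverse-transcriptase (RT) stop profiling of pseudouridine
   (Ψ) on rRNA, quantified per annotated site as a Ψ-ratio;
2. **snoRNA-seq** — counting of C/D-box and H/ACA-box snoRNAs with paired
   differential expression;
3. **a pooled CRISPR knockout screen** — gRNA count time courses with
   target-level selection calls.

All analyses are exercised on a bundled synthetic-data generator with
known ground truth; no external data is required.

## The Ψ-ratio

For a site at 1-based position *p* on molecule *m*,

    Ψ-ratio(p) = starts(p) / overlap(p)

where `starts(p)` counts reads whose reference 5′-most aligned base is *p*
(RT termination events) and `overlap(p)` counts all reads whose alignment
covers *p*. A read beginning at *p* covers *p*, so the statistic is a
proper termination fraction in [0, 1]. Profiles are CIGAR-aware: deletions
count as covered, insertions/clips/skips do not; reverse-strand alignments
are discarded (rRNA is single-stranded) and counted.

Numerical choices:

* `min_coverage` default 20 — at ratio 0.5 the binomial standard error is
  below 0.12; sites under the threshold are reported missing, not zero.
* `offset` — some Ψ-seq chemistries leave the stop one base 3′ of the Ψ
  (the CMC-adduct convention). Default 0 (read starts at the Ψ itself),
  with `offset=1` available in both the simulator and the quantifier.
* Log2 fold changes of ratios use a 10⁻³ pseudocount to guard zeros.

## The RT-termination generator

cDNA synthesis is modelled 3′→5′: the 3′ start is uniform on the molecule;
the natural fragment length is geometric (mean `mean_read_length`, default
80 nt) truncated at the molecule 5′ end. Scanning from the 3′ start
downward, the RT terminates at each Ψ site crossed with probability `f·e`
(site stoichiometry × termination efficiency) and at each non-site
nucleotide with a background rate `b ≤ 0.05`. Reads are emitted as mapped,
coordinate-sorted SAM records until the total simulated bases reach
`coverage × length`, which pins mean coverage to the target within a
read length.

The implementation samples the first background stop within each non-site
run from a geometric distribution rather than walking base by base; the
two schemes are distributionally identical. Tests verify the estimator
against an independent closed-form enumeration of
E[starts]/E[overlap] over all 3′ starts, fragment lengths and stop events
(`tests/oracles.py`), which also establishes strict monotonicity of the
expected ratio in `f`.

What the generator does **not** model: sequencing errors, adapter
artefacts, alignment ambiguity (reads are emitted pre-mapped), a
mock-treatment/input control library, or secondary-structure-dependent RT
drop-off. Passing tests therefore demonstrate correctness of the counting
and testing machinery under the stated stochastic model, not robustness
to real-library artefacts.

## Paired differential tests

* **Per site**: paired t-test (default; Wilcoxon available) on per-pair
  Ψ-ratio differences, ≥ 3 complete pairs required; zero-variance
  differences are flagged degenerate with p = 1. Raw p and BH q are both
  reported; the significance flag uses raw p < 0.05 — the convention of
  volcano-style per-site displays — with q alongside for modern practice.
* **Hotspot regions** (e.g. the three adjacent 18S sites at 105/109/119,
  or 28S 3700–3732): paired t on per-sample *sums* of ratios over the
  region; samples missing any site drop the pair.
* **Global shift**: Wilcoxon signed-rank across sites on per-condition
  mean ratios, restrictable to a subset (e.g. H/ACA-guided sites). Exact
  null distribution up to 25 informative pairs, normal approximation with
  continuity correction above; zero differences dropped (the classical
  Wilcoxon convention — packages differ, so this is pinned and tested).

## snoRNA counting and differential expression

A read is assigned to a snoRNA when ≥ 50% of its aligned length overlaps
the annotated interval on the same strand; multi-hits go to the larger
overlap and exact ties are discarded (logged; a warning fires when ties
exceed 1% of reads). Read-count conservation
(assigned + unassigned + ties + reverse = total) is asserted in tests.

Expression is normalised to counts-per-million of **total mapped reads**
(not snoRNA-only totals), matching how class compositions are reported,
with pseudocount 0.5 before log2. Paired DE uses the Wilcoxon signed-rank
test per snoRNA (paired t by flag); a snoRNA is called *enriched* when
mean log2 FC (T/N) > 1.5 AND p < 0.05, *depleted* symmetrically. With
n = 7 pairs the exact Wilcoxon null attains p < 0.05 with probability
6/128 ≈ 4.7%, which the type-I tests check.

The paired count generator draws negative-binomial counts
(Gamma–Poisson, var = μ + φμ²; φ default 0.1) around log-normal
baselines partitioned so that C/D-box and H/ACA-box snoRNAs receive 16%
and 4.4% of total mapped reads in expectation — the lung-tissue
composition the class-fraction summary emulates — with a per-patient
pairing effect (log-normal, σ = 0.15) shared within each pair, per-sample
library sizes (log-normal, σ = 0.1), and a designated up-regulated subset
(default: the nine highest-expressed H/ACA snoRNAs at fold change 4,
n = 7 pairs).

## Screen analysis

Counts are normalised to CPM per sample; per-gRNA LFC is
log2((CPM_t + 0.5)/(CPM_0 + 0.5)) against the day-0 baseline within each
replicate. Replicate concordance is Pearson's r with a least-squares
line. The generator evolves clone abundance as `(1+s)^doublings`
(|s| < 1, doublings = day × doublings/day, default 1/day over days
0/3/5/9) and draws each sample as one multinomial of the configured depth,
so per-sample totals are conserved exactly and replicates share truth but
not noise.

Target-level calls use a deliberately transparent aggregation: the
statistic is the mean over replicates of the median gRNA LFC; the null is
built by resampling size-matched gRNA sets from the full library
(replicate columns kept together); one-sided permutation p-values use the
add-one estimator (minimum 1/(n_perm+1)); BH FDR is applied across
targets and a direction is called at FDR ≤ 0.8 by default — the
permissive threshold screens use to rank candidates for follow-up
(0.25 and stricter are flags away). Published model-based screen
aggregators (e.g. MAGeCK's α-RRA) are intentionally **not** reimplemented
or emulated; the FDRs here are defined by this permutation scheme. Note
that at permissive q a pure-null screen yields some calls with
probability approaching q — that is the BH guarantee operating as
designed, and the null-screen tests check empirical FDR ≤ nominal rather
than zero calls.

## Integration

The guide map joins each snoRNA to its rRNA target site(s); shared
targets (two guides, one site) count once on the site axis, and a site is
*linked to up-regulation* if any of its guides is called enriched. A site
is *hyper-Ψ* when its differential-Ψ raw p < 0.05 with positive delta
(BH q by flag). Concordance is tested either by Fisher's exact test on
the resulting 2×2 table — implemented by hypergeometric enumeration with
exact integer tie handling, validated against exhaustive rational
arithmetic for every table with total ≤ 60 and cross-checked against
scipy — or by permutation: a random bijection of the site universe is
applied to the whole guide map, which preserves each snoRNA's target
count, every site's multiplicity and hence both margins, while
randomising the linkage. The Fisher p is conservative (discrete), so null
calibration is asserted as rejection rate ≤ α, not exact uniformity.

## Pipeline determinism and problem sizes

One master seed drives everything; child streams are derived from fixed
labels (CRC32 of e.g. `psi-reads/<sample>/<molecule>`), so adding a
generator never perturbs another's stream. Re-running the demo pipeline
with the same config reproduces every output byte-for-byte; output TSVs
carry the tool version, config hash and seed as `#` header comments, and
`report.json` records per-stage record counts.

The bundled demo runs two mock rRNA molecules (600/800 nt, 30 Ψ sites,
150× coverage, 5 pairs), a 70-snoRNA count study over 7 pairs, and a
63-target screen — sizes chosen so the full pipeline completes in a few
seconds on one CPU while every downstream test retains power. The
acceptance studies use the full stated conditions (2000× coverage for
recovery; 100-seed simulation studies; a 203-target screen at 10⁶ reads
per sample).

## Known limitations

* Ψ-site discovery is out of scope: only annotated sites are quantified.
* The screen aggregation ranks targets well but its permutation null
  shares draws across targets of equal size; p-values are therefore
  positively dependent (BH remains valid under this dependence in all
  null simulations run here).
* The concordance test treats sites as exchangeable; genomic clustering
  of hotspot sites is not modelled in the permutation null.
* No covariate adjustment or mixed-effects modelling for patient-level
  confounders.
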