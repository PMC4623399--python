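# Methods

## Setting

The package implements the statistical layer of a tri-omic comparison
between a high-ATP transgenic *Arabidopsis* line (OE) and wild type
(WT), sampled at the end of night (0 h) and at 1 h and 8 h after
illumination: unreplicated RNA-seq libraries covering the nuclear,
mitochondrial and chloroplast gene sets; iTRAQ protein quantification
with four replicate OE/WT ratios per protein; GC–MS metabolite panels;
an enzymatic ATP/ADP/NADP⁺/NADPH panel; and qPCR validation. No raw
sequencing or spectral processing is in scope — inputs are count,
ratio and Ct tables, and a ground-truth simulator stands in for the
deposited raw data.

## Transcript quantification

Abundance is RPKM = 10⁹·C/(N·L) per gene per library, with C the reads
on the gene, N the library's total mappable reads (each library's own
total, not a pooled figure) and L the gene length in bp. A gene is
"expressed" when it reaches `min_count` reads (default 1) in at least
one library; the threshold is explicit because detection criteria vary
between annotation releases. Summaries cross-tabulate expressed
features by genome of origin (Chr1-5 / ATMG / ATCG) and gene type and
work at either gene or transcript level, depending on what the
annotation rows denote.

## Exact two-library test

With one library per genotype there are no replicates, so gene-level
inference uses the conditional form of the two-Poisson comparison
(the Audic–Claverie construction): given x reads in library 1 and the
null of equal expression, the count y in library 2 follows

    p(y | x) = r^y (x+y)! / (x! y!) / (1+r)^(x+y+1),   r = N2/N1,

a negative binomial with size x+1 and success probability 1/(1+r),
free of the unknown Poisson rate. The two-sided p doubles the smaller
conditional tail. The observed count is included in whichever tail is
summed; this keeps the discrete test conservative and reproduces the
textbook closed forms (p = 1 at x = y with equal libraries,
p(0, 10) = 2⁻⁹). The inclusive convention is **not** exactly
exchange-symmetric under (x, N1) ↔ (y, N2) — the exclusive 2·(1−S)
variant is, via the incomplete-beta identity
I_{1−q}(y+1, x+1) = 1 − I_q(x+1, y+1) — so the exclusive variant is
available as `include_observed=False`.

Numerics: single terms use log-gamma; lower tails are log-sum-exp
accumulations of the term array; upper tails are summed directly from
the observed count with the multiplicative recurrence
p(i+1|x) = p(i|x)·r·(x+i+1)/((i+1)(1+r)), which avoids the
catastrophic cancellation of 1−S when the tail is tiny and works far
beyond the factorial overflow point (x+y ≈ 170). p-values underflowing
double precision are clamped to the smallest positive double rather
than zero. Agreement with an 80-bit extended-precision direct-summation
oracle is ≤ ~1e-12 relative over (x, y) ∈ [0, 200]² at library ratios
0.5, 1 and 2.

Calling: Benjamini–Hochberg q-values across all tested genes (step-up;
the standard referent where only "FDR correction" is specified), then
up if q ≤ 0.001 and FC > threshold, down if q ≤ 0.001 and
FC < 1/threshold. The genome-wide threshold is 2-fold; the organellar
gene sets are additionally screened at 1.5-fold. Fold change is
computed on library-size-normalized counts, (y/N2)/(x/N1) — gene length
cancels within a gene, so this equals the RPKM ratio. Zero counts give
sentinel FCs (+inf / 0) that pass the fold filter: a gene whose reads
vanish in one line is a legitimate call. Genes with x = y = 0 are
undetected and excluded from testing entirely rather than assigned
p = 1, so they never dilute the FDR pool.

## Protein statistics

Identification keeps proteins with unused ProtScore ≥ 1.3 and ≥ 2
peptides at ≥ 95% confidence (both boundaries inclusive). The 2
biological × 2 technical replicate ratios are treated as four
independent ratios — the same simplification the n = 4, df = 3 t-test
makes. For each tier μ₀ ∈ {1.2, 1.33, 1.5}:
t = (x̄−μ₀)/(s/√4) on the arithmetic mean of raw ratios (a log-scale
mode would be the geometric alternative; the arithmetic form is the
documented procedure), upper-tail p at df = 3. Down-regulation tests
against the reciprocal null 1/μ₀ with the lower tail (symmetric on the
log scale; `down_mode="lower_tail"` tests at μ₀ instead). Zero sample
SD is degenerate: p is NaN and the protein is never significant. No
correction is applied across proteins — calls are raw per-protein
P < 0.05, matching the procedure being reproduced; pipe the p columns
through `detest.bh_fdr` for an FDR-controlled variant. Up-calls nest
across tiers (significant at 1.5× ⇒ at 1.33× ⇒ at 1.2×) whenever the
mean clears the top tier, since t is decreasing in μ₀.

## Assays

GC–MS: per-record response = peak height / ribitol height / fresh
weight (g), then each metabolite is rescaled by the mean of the WT 0 h
reference group, so the reference mean maps to 1 and the operator is
invariant to global detector scale. Energy panel: ATP/ADP, ATP+ADP,
NADPH/NADP⁺, NADP⁺+NADPH and ATP/NADPH are computed per replicate and
then summarized as mean ± SD — ratio-of-replicates rather than
ratio-of-means, to preserve replicate-level variance (the ratio of
group means is the one alternative the data would support; with n = 3
the two differ visibly, which is why the per-replicate table is kept).
Genotype contrasts use the Welch t-test by default with a
pooled-variance option (`equal_var=True`); published analyses of such
panels rarely state which was used, and at n = 3 both are reported in
the output rather than silently chosen.

qPCR: ΔCt = Ct_target − Ct_reference per sample (the reference gene
plays the Actin-2 role), ΔΔCt = mean ΔCt(treatment) − mean
ΔCt(control), fold = 2^(−ΔΔCt). Relative abundances are 2^(−ΔCt)
rescaled so the maximum across the compared groups is 1 — i.e.
"normalize to the maximum" is applied after the exponential transform,
the common practice where the order of operations is not stated.
Significance is a two-tailed paired t-test on replicate-matched ΔCt
values; unequal replicate counts are an error, not silently unpaired.

## Enrichment

Bins are hierarchical category paths supplied as a two-column
feature→bin table (the shipped ontology is synthetic: bin content is
data, not method). Per category, against the full tested universe:
Fisher's exact one-sided overrepresentation of DE calls
(hypergeometric upper tail) and a two-sided Wilcoxon rank-sum test of
the members' log2 ratios versus the complement (category vs complement,
counted once per category). The rank test enumerates the exact null
for categories of ≤ 10 members and uses the tie-corrected normal
approximation above that. Significance is raw P < 0.01 per category
by default — no cross-category correction, matching the display
convention being emulated — with a BH option.

## Synthetic data

Generator defaults are the study conditions: 23,250 nuclear + 126
mitochondrial + 96 chloroplast genes with gene types drawn in the
annotation-summary proportions; 10⁷ mappable reads per library
(typical of a HiSeq2000 lane after filtering; the analyses condition
on N, so its exact value is immaterial); gene lengths uniform on
300–3000 bp to exercise the L term; RPKM log-normal (ln-mean 1.0,
ln-sd 1.5), giving per-gene Poisson rates from <1 to several thousand;
10% of genes carry ±2 log2-unit spike-ins; 2,000 proteins with four
ratios r·exp(ε), ε ~ N(0, 0.1²), 10% at true ratio 2.0 or 0.5, 10%
failing identification; triplicate metabolite/energy panels with 10%
CV at plausible leaf pool sizes (tens of nmol/g FW for adenylates);
triplicate qPCR with 0.1-cycle Ct noise. Counts are pure Poisson —
exactly the model the test assumes — with an optional Gamma-mixed
(negative-binomial) overdispersion knob, default off, for robustness
studies. Each generator owns an RNG stream seeded as (config seed,
fixed offset), so adding or resizing one generator never perturbs
another, and ⌊frac·n⌋ features are changed, chosen as the first
features of a shuffled order.

What the generator does not emulate: multi-mapping between homologous
nuclear/organellar copies, rRNA carryover, iTRAQ reporter-ion
compression and isotope impurity, GC–MS peak-picking artifacts, or
biological covariance between the omic layers (protein truth is drawn
independently of transcript truth, so the cross-omic correlation is
null by construction). Passing tests therefore certify the statistics
under their own assumptions, not robustness to those real-data
violations — the overdispersion knob exists precisely to probe the
first-order departure.

## Verification scale

The shipped checks run at: the full (x, y) ∈ [0, 200]² oracle grid ×
3 ratios; 20,000 null genes with rates spanning 1–10⁴ for calibration;
a 10,000-gene 10% spike-in for realized FDR; 4,000 proteins
(half null / half 2.0-ratio) for recovery; 1,000 label shuffles for
the enrichment null and 100 runs for shift power; and a 6,222-gene
bundled pipeline config (full organellar sets, reduced nuclear set)
for byte-level reproducibility. These sizes give Monte-Carlo error
comfortably below the 3·SE bounds asserted.

## Known limitations

* The exact test inherits the Poisson assumption; with biological
  replicates a dispersion-aware model (negative-binomial GLM) is the
  right tool, and this package deliberately does not provide one.
* Protein calls at raw P < 0.05 with n = 4 have limited power and no
  FDR control; the tier thresholds (1.2×) are close to iTRAQ's known
  ratio-compression scale, so real-data calls at that tier are fragile.
* The doubled-tail two-sided p is conservative near x ≈ y and exceeds
  1 before clamping at S = 0.5; one-sided use should take S or 1−S
  directly.
* `relative_to_reference_group` propagates reference-group noise into
  every scaled value; with n = 3 reference replicates this is a
  non-trivial variance contribution.
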