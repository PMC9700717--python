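# Methods

## Coordinate conventions

All intervals are 0-based, half-open; GTF's 1-based closed intervals are
converted on read. Codon indices are 1-based with codon 1 at the start
codon, so a nonsense mutation named R213X sits at codon index 213. The
canonical stop codon has index N = (stop_tx − start_tx)/3 + 1. When an
annotation carries `stop_codon` features the CDS is taken to exclude the
stop (Ensembl GTF); otherwise the last three CDS nucleotides are the stop.
Genome→transcript projection is per-base and exact: a read is compatible
with a transcript only if every aligned base is exonic, the projected bases
form one contiguous transcript interval (splices must match introns), and
read strand equals transcript strand. Multimappers (NH tag) above a
configurable maximum (default 1, unique mappers only) are discarded and
tallied; at every stage assigned + discarded equals input.

## Footprint simulator

The generator emulates the statistical structure of a cycloheximide
Ribo-seq library rather than sequence-level artifacts:

- **Elongation density**: ribosome counts per codon are Poisson(λ) on the
  CDS upstream of the PTC (default λ = 20/codon in recovery tests, 5/codon
  in metagene-scale runs — enough depth for stable ratios at desk-scale
  run times).
- **Readthrough**: density is ρ_PTC·λ between the PTC and canonical stop,
  and ρ_canonical·λ for up to 50 codons of in-frame 3'UTR extension past a
  canonical stop (ρ compounds multiplicatively for readthrough past both).
- **Termination pile-up**: the stop codon being used for termination gets a
  ×5 density multiplier, emulating ribosomes queued before release. This is
  why the readthrough statistics exclude the stop/PTC codon.
- **Periodicity**: a footprint's P-site is the codon first nucleotide with
  probability π (default 0.9); the remaining mass shifts ±1 nt with equal
  odds — the simplest symmetric sub-codon blur.
- **Lengths and offsets**: footprint lengths are drawn from a distribution
  concentrated at 28–29 nt (default 50/50); the 5' end is
  P-site − offset(length) with true offsets defaulting to 12 nt.
- **Background**: optional uniform reads at β per nt, any frame.

Footprints that would extend past either transcript end are dropped before
truth accounting, so the recorded truth equals the emitted reads per
category exactly (each read id encodes its category). One seeded numpy
generator per call; no global RNG state.

Not emulated: nucleotide sequences, ligation/PCR bias, rRNA contamination,
UMI duplicates, and initiation/termination kinetics beyond the pile-up
multiplier. Passing recovery tests therefore demonstrates estimator
correctness under the declared statistical model, not robustness to
sequence-specific artifacts in real libraries.

## Offset calibration

For each footprint length, candidate offsets 10–14 nt are scored on the
start-codon metagene aggregated over transcripts:

    score(o) = #{P-sites exactly at the start-codon first nt}
             − #{P-sites in the 3 nt immediately upstream}

Under uniform CDS density a bare peak count cannot separate offsets
differing by 3 nt (the comb of codon positions shifts onto itself); the
upstream term breaks that degeneracy because only offsets that are too
small push first-codon ribosomes upstream of the start, where a correct
offset leaves (nearly) nothing. Ties break toward the higher in-frame
fraction. Lengths with fewer than `min_reads_per_length` (default 100)
reads fall back to the default offset 12 with confidence `default`;
lengths whose best frame-0 fraction is below 0.4 (the 1/3 null plus
margin) are marked `failed` and excluded downstream. Calibration pools the
start codons of all supplied transcripts, so per-length depth should be
spread over many genes, as in real libraries; a single-gene library
concentrates the anchor signal in one codon and is noise-limited.

## Readthrough statistics

The PTC ratio and metagene ratio are both length-normalized in-frame
density ratios, downstream/upstream of the stop in question, with the stop
codon excluded from both sides (see simulator rationale above; the
exclusion is a deliberate choice the underlying data cannot arbitrate, so
the codon boundaries are explicit in the result object). Only frame-0
P-sites in the annotated CDS frame are counted, including past the stop —
off-frame 3'UTR reads are ignored. Metagene windows default to 50 codons
per side, bin width 1 codon; the "stop bin" in the binned profile is
always exactly the stop codon regardless of bin width, which is what makes
the ratio invariant to bin width (a wider stop bin would swallow flanking
codons). Genes qualify with ≥ 32 in-frame CDS reads on their longest-CDS
transcript — an operational definition of "translated"; genes whose
transcript cannot supply part of the window contribute only their defined
codon offsets. Condition summaries report median, quartiles and a seeded
percentile-bootstrap 95% CI of the median (degenerate and flagged for
single replicates).

## GI50 screen

Group means are arithmetic on the linear molar scale by default; since
GI50 archives are often stored as −log10 M, a geometric-mean option
(`log_mean=True`) is exposed rather than silently choosing one convention.
Missing values are ignored within a group; a compound with no nonsense
value in a tissue is unevaluable there and cannot be selected. Thresholds
(>4, >1.5) are strict inequalities. The default synthetic panel mirrors
the 15 colon/renal NCI-60 lines (1 nonsense + 1 WT + 5 other-mutant colon;
1 nonsense + 4 WT + 3 other-mutant renal). Planted compounds realize their
target ratios exactly at zero noise by construction (each group's lines
share a common value), so screen exactness is testable without tolerance.

## Logistic growth

"Logistic model" here is the 4-parameter logistic growth curve, not
binary-outcome logistic regression — the quantity of interest is a rate in
%confluency/h. Fitting is `scipy.optimize.curve_fit` with analytic-free
bounds A ∈ [0, 105], K ∈ [0, 105] (5% headroom above full confluency for
noisy plateaus), r ∈ (0, 50] /h, and t0 within twice the observation span;
initialization uses min/max for A/K, the half-range crossing for t0, and
the finite-difference slope there for r (dC/dt at t0 = r(K−A)/4). A series
with zero range is flagged "no growth"; a converged solution with K ≤ A is
reported unconverged rather than silently returned. The critical point cp
is the control's t0 (mean over converged control replicates when several
are supplied); rates at cp come from each condition's own fitted curve via
the closed-form derivative. Replicates are fitted independently and
summarized as mean ± SEM.

## Problem sizes and numerical choices

Recovery tests and the acceptance script run at desk scale by design: a
single 394-codon PTC transcript at λ = 20/codon for PTC-ratio recovery
(≈ 9 × 10³ footprints per library, 4 replicate libraries per condition),
100–200 genes of 151 codons at λ = 5/codon for metagene recovery
(8 replicates per condition), a 60-gene library at ≈ 5 × 10³ reads per
length for the offset grid, 1000 compounds for the screen, and 25 time
points (3 h over 72 h) for growth fitting. These sizes give relative
standard errors comfortably inside the tolerances asserted while keeping
the full suite under ten seconds. Noiseless constructions (screen,
logistic) are checked exactly or at 10⁻⁶ relative error; stochastic
recoveries at 3 standard errors or 10% relative error on the median.

## Known limitations

- Per-base projection is exact but O(read length × candidate transcripts);
  it targets annotation-scale fixtures and focused gene panels, not
  whole-transcriptome BAMs, for which an interval-tree lookup would be the
  natural extension.
- Offset calibration assumes the annotation's start codons are correct and
  needs aggregate start-codon signal; it does not model heterogeneous
  offsets within one length.
- The metagene ratio pools counts across genes (a coverage-weighted
  estimate); very highly expressed genes therefore dominate, as they do in
  the underlying libraries.
- The screen treats cell lines as exchangeable replicates within a status
  group; it does not model per-line covariates or assay noise structure.
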