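# ribortc

Quantification of **translational readthrough at stop codons** from
ribosome-profiling (Ribo-seq) footprints, plus two companion analyses used
when characterizing readthrough-inducing compounds: an NCI-60-style
**GI50 differential-sensitivity screen** and **logistic confluence
growth-curve** kinetics. The package is aimed at groups studying
pharmacological suppression of nonsense mutations (e.g. *TP53* R213X, a UGA
premature termination codon at codon 213), where the central question is:
what fraction of ribosomes keep translating past a stop codon under a given
treatment?

Everything is exercised on synthetic data with exact ground truth: the
`ribosim` module generates footprint libraries, GI50 matrices and
confluence curves whose true parameters are recorded, so every estimator in
the package has a recovery test.

## The statistics

**PTC readthrough ratio.** On a transcript with a premature termination
codon (PTC) at codon *p* and canonical stop at codon *N*, with in-frame
P-site counts `n_pre` over codons 1..*p*−1 and `n_post` over codons
*p*+1..*N*−1,

    ratio = (n_post / L_post) / (n_pre / L_pre),   L_pre = p−1, L_post = N−1−p

i.e. the length-normalized in-frame ribosome density downstream of the PTC
relative to upstream. The PTC codon itself (and the canonical stop) are
excluded — terminating ribosomes pile up there. A ratio of 0.10 means 10%
of ribosomes read through.

**Metagene stop-codon readthrough.** Genes (one longest-CDS transcript per
gene, ≥ 32 in-frame CDS reads) are aligned at their annotated stop codon;
in-frame P-site counts in windows of 50 codons before and after the stop
(stop codon excluded, annotated frame extended into the 3'UTR) give the
same density ratio translatome-wide.

**P-site machinery.** P-site = footprint 5' end + length-specific offset.
Offsets are calibrated per length from the start-codon metagene (candidates
10–14 nt, default 12); lengths whose in-frame fraction stays near the 1/3
null are excluded. QC reports length histograms, 3-nt periodicity and
CDS/UTR fractions.

**GI50 screen.** With cell lines labelled by tissue and TP53 status, a
compound is selected when, in *every* required tissue,

    mean GI50(other-mut) / mean GI50(nonsense) > 4   and
    mean GI50(WT)        / mean GI50(nonsense) > 1.5    (strict)

**Growth at the control critical point.** Each confluence series is fitted
with a 4-parameter logistic C(t) = A + (K−A)/(1+e^(−r(t−t0))); the
control's inflection t0 is the critical point (cp), and each condition's
dC/dt at cp is reported in %confluency/h (the control's own value is
r(K−A)/4).

## Worked example

Simulate a Ribo-seq library on a TP53-like transcript (394 CDS codons, PTC
at codon 213) with 10% PTC readthrough and 1% canonical-stop readthrough,
then run the analysis from the shell:

```
$ ribortc simulate footprints --out-sam f.sam --out-truth t.tsv \
    --out-gtf sim.gtf --out-ptc ptc.tsv --seed 1 \
    --rho-ptc 0.1 --rho-canonical 0.01 --n-genes 10 --lambda-pre 10
wrote 16606 footprints

$ ribortc readthrough --sam f.sam --gtf sim.gtf --ptc ptc.tsv --out rt.tsv
$ cat rt.tsv
transcript_id   sample_id   n_pre   n_post  ratio               percent
TP53sim         sample      1866    179     0.11298082648564964 11.298082648564964

$ ribortc metagene --sam f.sam --gtf sim.gtf --min-cds-reads 100 --out mg.tsv
readthrough ratio 0.8799% over 10 genes

$ ribortc psite --sam f.sam --gtf sim.gtf --out-prefix qc
{"cds": 0.9970492593038661, "utr5": 0.00042153438516198964, "utr3": 0.002529206310971938}
```

The estimated PTC readthrough (11.3%) recovers the simulated 10% within
counting noise (179 in-frame reads downstream), the metagene ratio (0.88%)
recovers the simulated 1% at this small gene set, and QC confirms the
footprints sit almost entirely in coding sequence. The same operations are
available as library functions (`ribortc.ptc_readthrough_ratio`,
`ribortc.metagene_stop_readthrough`, ...), which is the recommended
interface for anything beyond one-off runs.

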