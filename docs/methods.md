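# Methods

## NOMe-seq model

A NOMe-seq experiment treats intact nuclei with the GpC methyltransferase
M.CviPI, which methylates GpC dinucleotides wherever chromatin is accessible;
nucleosome-bound DNA is refractory. After bisulfite conversion, one cloned
molecule therefore reports two signals: endogenous CpG methylation at HCG
sites and accessibility at GCH sites (H = A/C/T). GCG trinucleotides are both
a CpG and a GpC, so the two signals are confounded there; they are simulated
with endogenous-methylation behaviour but flagged ambiguous and excluded from
both analysis channels, the standard practice for this assay. Cytosines in
neither context are unmethylated in vivo, so the fraction converted to T
measures the per-clone bisulfite conversion rate.

The generator draws, per clone: endogenous methylation per HCG site from
per-site probabilities; nucleosome occupancy per footprint interval
(Bernoulli with the interval's occupancy, all-or-none across the interval,
intervals ≥ 120 bp by default because a nucleosome core protects ~147 bp);
accessibility of non-protected GCH sites with `open_gpc_prob`; enzyme
labelling of accessible sites with efficiency `e_gpc` (default 0.95); and
conversion of every unmethylated cytosine with rate `c_bis` (default 0.99).
Only the bisulfite-converted top strand is simulated and analysed — amplicon
PCR primers select one strand, and nothing downstream depends on the choice.
No sequencing-error model is applied by default (Sanger-sequenced plasmid
clones).

### Calling and QC

Clones of the expected amplicon length map positionally; a length deviation
within ±10 % falls back to a gapped global alignment with a bisulfite-aware
scoring (reference C read as clone T is not a mismatch). Clones with > 5 %
true mismatches fail alignment; clones with conversion rate < 0.95
(inclusive threshold, i.e. exactly 0.95 passes) fail QC. Failing clones stay
in the matrix for inspection but never enter statistics. Missing bases (N,
or positions lost to an alignment gap) propagate as missing states and are
excluded from all denominators. Terminal cytosines, whose trinucleotide
context is undefined, are treated as conversion-QC sites.

### Estimators

The region mean is the pooled ratio 100 × methylated calls / informative
calls over all sites and clones — not a mean of per-clone means — which is
robust to partial clones and identical to it for rectangular matrices.
Frequencies are reported raw, without correcting for conversion failure;
this leaves an upward bias of (1 − p)(1 − c_bis) at true methylation p
(about +0.8 points at p = 0.2, c_bis = 0.99). The packaged condition
profiles are therefore calibrated on the raw scale: per-site probabilities
are solved so the *expected raw estimate* equals the condition's target mean
(`mean(p) = (target/100 − (1 − c_bis)) / c_bis`), with the region-I dual
domain structure imposed as distal = 4 × proximal probability (boundary at
−200 bp), and uniform probabilities in region II.

Condition comparison uses a per-position Kruskal–Wallis test with clone-level
binary calls as replicates (midranks with tie correction; for two groups
this is algebraically the tie-corrected two-sided Mann–Whitney normal
approximation). No multiple-testing correction is applied by default, to
match the per-position presentation convention of single-amplicon NOMe
studies; Benjamini–Hochberg is available via `correction="fdr_bh"`.
Footprints are per-clone maximal runs of protected GpCs spanning ≥ 140 bp
(just under a nucleosome core; configurable), turned into consensus
intervals where ≥ 50 % of passing clones are covered by such a run.

## 3D-FISH model

Each simulated nucleus (radius 3 µm) holds two chromosome-5 homologs at
territory centres ≥ 2.5 µm apart — far enough that a probe pair (≤ 1.4 µm)
can never reach across to the other homolog, which keeps mutual-nearest-
neighbour pairing essentially error-free, as it is in well-segmented images.
Each homolog carries a red (gene locus) and green (subtelomere) spot whose
3D separation is drawn uniformly from its proximity class's support; class
supports keep a 10 nm margin inside the cell line's thresholds (adjacent
< 300 / 340 nm, separated > 665 / 730 nm for NB4-LR1 / NB4-LR1^SFD) so class
identity is unambiguous. Proximity classes are allocated to homolog slots by
stratified exact-count assignment (largest-remainder rounding, shuffled):
the mixture weights are the condition being encoded — the quantity the
classifier must recover — so they are not treated as an extra noise source.
z coordinates are quantised to the 0.37 µm optical-section spacing by
drawing the z displacement on the section grid first, which preserves the
encoded pair distance exactly.

`trans_rate` (default 0.1) is the per-nucleus probability that only one
homolog is detected (territory outside the imaged stack). A one-red/one-green
nucleus still yields a same-homolog (cis) pair; genuinely trans pairings
arise as the non-mutual cross-combinations in fully detected nuclei and are
excluded from classification, mirroring the cis-only analysis convention.
Classification uses strict inequalities at both thresholds; boundary
distances fall in the intermediate class. Condition comparison is a
two-sided Mann–Whitney U test on raw cis distances.

What the generator does not emulate: chromatic shift, spot-detection noise,
segmentation errors and aneuploidy (beyond the > 2-spots-per-channel
exclusion rule). Passing tests show the pairing/classification machinery
recovers what imaging hands it, not that imaging is error-free.

## qPCR model

Percent input is `100 · dilution · E^(Cq_input − Cq_IP)` with amplification
efficiency E = 2.0 per cycle unless configured; the dilution factor defaults
to 1 (percent of the measured input aliquot) because the input fraction of
total chromatin is an experiment-level constant that belongs in metadata.
IgG background is reported, never subtracted. Relative expression is
`100 · 2^(−ΔΔCq)` against a reference gene and calibrator sample; the
calibrator's own mean is 100 by construction. The Cq generator inverts these
formulas exactly at zero noise and adds independent Gaussian cycle noise to
each well otherwise. Group statistics: two-tailed Student's t-test for two
groups, one-way ANOVA + Tukey HSD for more, stars at P < 0.05/0.01/0.001.

## Beta-matrix clustering

Patient-style data are Beta-distributed per group and domain (mean/sd
parameterisation; defaults: diagnosis distal 0.60 ± 0.05 vs 0.20–0.25 for
remission/healthy, all proximal 0.05 ± 0.05; 18/8/8/8 samples; 10 % missing
at random) over 30 proximal (−199..+150) and 30 distal (−600..−201) CpGs.
Clustering uses pairwise-complete Euclidean distance (squared differences
over shared observed CpGs rescaled by the observed fraction) with average
linkage — common heatmap-tool defaults; both are configurable, and columns
observed in < 2 samples are dropped. The two-cluster cut is scored for
purity because the expected structure is a diagnosis vs remission/healthy
split. The boundary of the "distal" domain is set at −200 bp; an alternative
−600..−200 window reading exists in the literature and is supported by
passing a different `domain_boundary` when reading matrices.

## Problem sizes and numerical choices

The bundled scenarios run at 500 clones for region means, 2000 clones for
QC-rate estimation, 200 nuclei per FISH condition and 42 × 60 beta matrices —
sizes at which every Monte-Carlo check in the test suite resolves its
tolerance comfortably while the whole suite runs in about a minute.
Randomness is always an explicit `numpy` seed; identical (profile, seed)
arguments give byte-identical outputs. Reference sequences are synthetic
GC-rich fixtures (seeded, CpG-island-like densities) rather than the true
genomic sequence, so no download is required; the informativeness
invariants (≥ 10 HCG, ≥ 20 GCH sites) are enforced at generation.

Known limitations: no HMM nucleosome positioning (amplicon-scale consensus
runs only), no bottom-strand or NGS bisulfite support, no standard-curve
efficiency fitting, no image processing upstream of spot centroids, and no
differentially-methylated-region calling beyond the two fixed domains.
Clone counts of 10–20 per experiment are interpreted as pre-QC counts.
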