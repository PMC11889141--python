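# Methods

`sialotools` re-implements, as a reusable library, the analysis chain used
to characterise a salivary-gland transcriptome (a *sialotranscriptome*)
under viral infection: coding-sequence extraction from assembled
transcripts, consolidation, TPM quantification and filtering,
vocabulary-driven functional classification, abundance summaries, and
two-group negative-binomial exact-test differential expression. This note
documents the models, the defaults and the design choices that were
genuinely open.

## Coding-sequence extraction

ORFs are enumerated over all six frames as maximal stop-delimited codon
runs. A run qualifies as an ORF when it abuts at least one stop codon:
stop-to-stop, edge-to-stop, and truncated stop-to-edge segments all
qualify (assemblies truncate transcript ends), but a frame never
interrupted by a stop is not an ORF. The nucleotide length counts the
terminal stop codon when present; the default floor is 150 nt.

Two routes promote an ORF to a coding sequence:

* **Homology.** A protein hit qualifies when it covers at least 70% of
  its *subject* — the fraction of the matching protein, `(send − sstart
  + 1)/slen` — and overlaps the ORF on the transcript. Among qualifying
  hits the highest bitscore supplies the reported evidence; the ORF is
  kept whole, not trimmed to the hit, because the paper trail for
  trimming does not exist and full ORFs maximise downstream sequence
  recovery. Hit query coordinates are interpreted as 1-based nucleotide
  positions on the forward strand of the transcript (blastx convention).
* **Signal peptide.** Every Met-initiated sub-ORF of at least 40 aa is
  scored by the signal-peptide caller; the most 5′ signal-positive
  methionine becomes the start.

When both routes qualify, the homology anchor wins (it fixes the reading
frame more reliably) and the signal evidence is recorded alongside.

Consolidation is greedy longest-first clustering at 95% nucleotide
identity (CD-HIT style): sequences sorted by length descending (ties by
id), each joining the first cluster whose representative aligns at or
above the threshold. Identity is matches / alignment columns of a global
pairwise alignment with match 1, mismatch 0, gap open −10, gap extend −1.
Two *exact* prefilters avoid most alignments: identity can never exceed
the shorter/longer length ratio, and at ≥ 90% identity two sequences of
≥ 150 residues must share a 12-mer. Consolidation defaults to the
nucleotide level; amino-acid level is a flag.

## Signal-peptide caller

The external neural-network predictor used in the original workflow is
replaced by a transparent three-rule caller testing the canonical
n/h/c-region architecture:

1. net charge of residues 1–5 (K, R = +1; D, E = −1) is ≥ 0;
2. an h-region exists: an 8-residue window within residues 3–20 (1-based)
   with mean Kyte–Doolittle hydropathy ≥ 2.0 and **no charged residue**
   inside the window;
3. a cleavage site exists at 0-based offset p in [12, 35) with a small
   residue (A, G, S, C, T) at p and no charged or aromatic residue at
   p − 2 (the −3/−1 rule); the smallest qualifying p is reported.

Sequences shorter than 15 aa are negative (`too_short`). A looser
mean-only rule (7-residue window at threshold 1.6) was considered and
rejected: on any realistic background composition (uniform sense-codon
translation, ~36% hydrophobic residues) it fires on 20–35% of
non-signal N-termini, which defeats the purpose of the caller. The
stricter h-region rule keeps 100% recall on the generative template
while holding the scrambled-sequence positive rate near 6%. External
predictions can replace the heuristic wholesale via
`parse_external_sp_table` (1-based between-residue cleavage indices are
converted to the internal 0-based convention).

## Quantification

TPM per sample is `rate_i / Σ rate` × 10⁶ with `rate_i = count_i /
eff_length_i`; effective lengths are taken from the count input (no
internal length modelling). Detection in a condition means the
*condition mean* TPM reaches the threshold (default 3) — the mean, not
the replicate max, matching the convention of condition-average TPM
tables. The presence partition splits transcripts into
detected-in-both / A-only / B-only / dropped. Heatmap input is the
row-wise z-score (sample sd, ddof 1); constant rows map to zero.

## Functional classification

Classification scans the description string of the best homology hit
against an ordered keyword lexicon (term → class, and for the secreted
class a protein family). Databases are visited in precedence order;
within a database the best hit by bitscore that clears the acceptance
floor (percent identity ≥ 35, subject coverage ≥ 0.50 by default) is
scanned. Term selection is **priority tier first, text position second,
lexicon file order third**: specific family terms ("kunitz", priority 3)
outrank generic enzyme terms ("serine protease", priority 1) wherever
both occur, while terms of equal priority resolve by order of appearance.
A pure leftmost-match rule was rejected because compound descriptions
("serine protease inhibitor, Kunitz type") would then take the generic
enzyme class. Viral-source sequences are class `virus` outright.
Sequences with no accepted hit or no matching term fall back to
`secreted`/`Unknown` when signal-positive, else `unknown`.

The shipped lexicon (~125 terms, 26 entry classes plus `virus` and
`unknown`) is a reconstruction: the original ~450-word vocabulary is
unpublished, so the lexicon is data, fully user-replaceable, while the
scanning algorithm is the fixed part.

Class abundance is the percent of each sample's total TPM per class
(mean ± sd across replicates per condition); the secreted family table
counts detected members per family and condition and sums their
condition-mean TPMs, with a percent-reduction column relative to the
reference condition.

## Differential expression

Counts for gene g, sample s in group k are modelled NB(μ_gk, φ) with a
single common dispersion φ. All samples are scaled to the geometric-mean
library size; library sizes are plain column sums by default, with TMM
(30% M-trim, 5% A-trim, factors centred to geometric mean 1) as an
option.

* **Dispersion** maximises the conditional (given per-group totals)
  log-likelihood summed over genes — the classical qCML estimator — over
  a 31-point log-grid on [10⁻⁶, 10] refined by golden-section search.
* **Exact test.** The sum of n iid NB(μ, φ) is NB(nμ, φ/n), so the two
  group totals are NB with means proportional to group sizes under the
  null; conditioning on the grand total s, the two-sided p-value sums
  P(x) over all splits with P(x) ≤ P(observed) (probability-mass rule,
  no doubling). φ = 0 uses the Poisson limit (conditional Binomial).
  Scaled group totals are rounded to integers before conditioning; the
  exactness of conditioning under originally-unequal library sizes is
  therefore approximate. The implementation agrees with the Bioconductor
  reference (exactTest, small-p rejection region) to ~10⁻¹⁴ on equal-
  library fixtures.
* **logFC** is log2((other/n_other + c)/(ref/n_ref + c)) with
  pseudo-count c = 0.125 — display only; p-values never use it.
* **Calls.** BH step-up FDR; with the reference group as baseline, `up`
  means up-regulated in the *reference* (logFC ≤ −2 at FDR < 0.05),
  `down` the converse. This matches a census that reports "up-regulated
  in the reference-injected samples".
* **MDS.** Pairwise sample distance is the RMS of the top-500 largest
  |log2FC| of log-CPM profiles (pseudo-count 2); classical Torgerson MDS
  with per-axis variance shares.

## Synthetic data: what it emulates, what it does not

The generator builds a fully-labelled world: host transcripts with one
planted Met-initiated ORF each (uniform 150–1800 nt including the stop,
random 30–300 nt UTRs, an in-frame stop planted immediately upstream so
the planted interval is exactly a maximal ORF), secreted-class
transcripts starting with a template signal peptide (M + 1–3 of K/R/N/S,
8–10 of L/A/V/I/F, then AQA), a 108-member viral CDS set with seven
designated ORFs at zero counts everywhere, hit tables embedding exactly
one lexicon term per informative description, and NB counts (default
φ = 0.1, 3+3 replicates, library size ≈ 3 × 10⁵).

Per-condition expected TPM follows the printed class-share calibration
(PBS: secreted 38.8%, Met/Energy 22.6%, unknown 20.2%, virus 0; infected:
virus 62.1%, unknown 22.8%, secreted 4.3%), the remainder spread evenly
over the unpinned classes; within a class the share is partitioned by a
symmetric Dirichlet (α = 5 — concentrated enough that every present
member clears TPM 3, so the 101-of-108 viral census is deterministic).
Expected *counts* are TPM × length renormalised, so TPM recomputed from
the counts matches the calibration in expectation.

Two deliberate simplifications: decoy "non-coding" sequences are 100–149
nt fragments (a random sequence of realistic length almost surely
contains a ≥ 150 nt stop-free stretch in one of six frames, so rejection
sampling long ORF-free decoys does not terminate); and each classed
transcript's best hit is forced to ≥ 75% subject coverage so the
homology route fires deterministically (secondary hits keep the looser
U(0.55, 1) coverage). The generator does not emulate assembly errors,
chimeras, multi-ORF transcripts, read-level noise, or hit-description
ambiguity — a green end-to-end test establishes that the pipeline's
logic is self-consistent on clean inputs, not that it is robust to messy
annotation text.

## Numerical choices and degenerate inputs

All-zero samples quantify to all-zero TPM columns with a warning; an
all-zero count matrix is an error for dispersion estimation. Totals of
zero give p = 1 and logFC 0. Constant z-score rows map to zero. BH
adjustment is clipped to [p, 1] and is monotone in the sorted order.
Dispersion estimates at the grid edge return the bound (10⁻⁶ ≈ Poisson).
Consolidation ties (equal length) break by id ascending, making the
whole pipeline deterministic given input order and seed.

## Known limitations

The exact test conditions on *rounded, equalised* group totals rather
than edgeR's quantile-adjusted pseudo-counts; with strongly unequal
library sizes the two diverge slightly. Common dispersion only — no
tagwise/trended shrinkage, no GLM covariates. The lexicon is a
reconstruction and makes no claim to reproduce the original 25-class
census on real data. The signal-peptide caller is a rule-based stand-in,
not a learned predictor; its operating point is tuned for the synthetic
template family, and real-data users should import external predictions.
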