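# Methods

## Screening model

The pipeline treats exogenous-miRNA calling as sequential hypothesis
elimination. A tag (unique cleaned insert with its read count) is called a
plant miRNA only if it (a) matches a mature plant miRNA under the
containment criterion and (b) cannot be attributed to the host
transcriptome, the host genome (allowing for sequencing error and A-to-I
editing), or the microbiome. The cascade only removes tags, so survivor
sets are nested and the stage report is a monotone audit trail.

**Containment criterion.** "Match" means a gap-free, mismatch-free
alignment in which the shorter of tag and miRNA is wholly contained in the
longer and their lengths differ by at most one nucleotide. This is the
only gap-free, mismatch-free reading of a coverage difference of one
nucleotide, and it makes the match relation checkable by three hash
lookups per tag. An explicit E-value check is not needed at this stage:
for a ≥ 17 nt exact match against a miRNA-sized database, E = K·m·n·e^{−λS}
is below 10⁻⁴ for any realistic database size (the packaged example
prints the numbers), so the containment rule strictly subsumes an E ≤ 0.01
screen.

**Local similarity screens.** The host ncRNA and mRNA/repeat stages use a
seed-and-extend search: exact 7-mer words nominate subjects, every
nominated subject is scored by a full affine-gap Smith–Waterman (match +1,
mismatch −2, gap open −5, extend −2), and significance uses ungapped
Karlin–Altschul statistics. λ is solved from
Σᵢⱼ pᵢpⱼ e^{λsᵢⱼ} = 1 by Brent root finding (residual < 10⁻⁹); K by the
classical lattice-case series with exact convolution of the score
distribution (60 terms; for +1/−2 uniform this gives λ = 1.3327,
K = 0.6210). Applying ungapped statistics to gapped scores is the usual
conservative approximation. Both strands of each tag are screened.

**Mismatch-limited mapping.** Genome passes use an exhaustive pigeonhole
mapper: the read is split into k+1 exact segments, each segment occurrence
(from a k-mer position index) seeds full verification, so no placement
with ≤ k mismatches can be missed. The editing-aware pass keeps placements
with ≤ 2 mismatches of which at least one is reference-A→read-G or
reference-T→read-C (the antisense image of A-to-I deamination); whether
the editing mismatch may be "either of up to two" versus "exactly one
editing plus one other" is not decidable from the protocol being modelled
— the implementation requires *at least one* editing-compatible mismatch,
the laxer and simpler reading. APOBEC-type C→T/G→A changes can be added
via a parameter but are off by default.

**Abundance threshold.** The ≥ 5-read rule is applied per sample to
miRNA-species counts after all sequence filters, not to tag counts: a
species supported by two tags of 3 and 2 reads passes. A tag contributes
its count to every species it matches (mature sequences are often shared
across family paralogs); the family roll-up deduplicates shared tags
before summing so a family never double-counts a read.

## Statistics

Pairwise profile correlations are plain Pearson r on raw counts over the
*union* of species in the two profiles, absent species as zero — the only
convention that uses all data; an intersection mode exists for sensitivity
analysis. p-values are two-sided from the t reference with n−2 degrees of
freedom (the convention is an assumption; the summary statistic is r).
Constant vectors make r undefined and are propagated as NA, never as 0.
The packaged six-sample porcine correlation table is summarized by the
arithmetic mean of its 15 upper-triangle r values, 0.23080; note that the
printed cells are 3-decimal roundings, so a mean recomputed from them can
differ from an average computed on unrounded correlations by up to
0.0005 (and its published rounding adds another 0.0005).

## Energy model

`duplex_mfe` and `fold_mfe` share a compact nearest-neighbor model:
16 Watson–Crick and G·U wobble stack energies (kcal/mol, 37 °C, shipped
as `data/stack_energies.tsv`), duplex initiation +4.09, and linear
penalties — bulge 3.8 + 0.5·(n−1), internal loop 1.7 + 0.5·n (admissible
when each side ≤ the cap), hairpin 5.4 + 0.3·(n−3) with minimum loop 3,
multibranch 3.4 + 0.4·branch + 0.1·unpaired. Dangling ends, terminal-AU
penalties and partition functions are deliberately omitted: every
returned structure can be re-scored term-by-term to 10⁻⁹ and exhaustively
enumerated at small n, which is what makes the enumeration-oracle tests
exact rather than approximate. The cost is that *absolute* energies are
only Turner-style approximations — the −17 and −10 kcal/mol acceptance
thresholds are therefore configuration, and reproduction of any specific
published target list is explicitly out of scope.

The duplex DP is over antiparallel intermolecular pair chains with
bulges ≤ 2 and internal-loop sides ≤ 2 by default; if the best bound
structure is energetically positive the unbound state (MFE 0, empty
structure) is reported. The fold is a Zuker-style V/M1/M recursion with
helix-internal bulges and loop sides capped at 10 nt (keeps the DP cubic;
the enumeration oracle applies the same admissibility). Site
accessibility is ΔG_open = MFE(site forced unpaired) − MFE ≥ 0 computed
on a window of 70 nt flanking the site, an MFE difference rather than
PITA's ensemble free energies (a documented simplification flagged as
such in the scanner).

## Target scanners

*Complementarity scanner* (miranda-like): local affine alignment of the
miRNA against antiparallel transcript windows; canonical pair +5, G:U
wobble +2, mismatch −3, gap −8/−2, with positions 1–10 of the miRNA
weighted ×4 (a perfect 21-nt site scores 5·(4·10+11) = 255). Sites
require score > 130 (strict), duplex MFE < −17, and a seed (miRNA
positions 2–8) that is gap-free and purely Watson–Crick. Only +5/+2, the
seed rule and both thresholds are fixed by the protocol being modelled;
the remaining constants follow the reference implementation's conventions
and are config-exposed.

*Hybridization scanner* (RNAhybrid-like): windowed duplex MFE with the
2-nt loop caps; kept at MFE ≤ −17 (boundary inclusive).

*Accessibility scanner* (PITA-like): anchors are exact Watson–Crick
complements of miRNA positions 2–8 (7-mer) or 2–9 (8-mer) — both probed,
best ΔΔG per site kept; ΔΔG = duplex MFE + ΔG_open, kept below −10.

*Consensus*: a transcript must be called by all three scanners; ranking
is lexicographic — alignment score descending, then duplex MFE ascending,
then transcript id — truncated to the top 25.

## Synthetic data

The generator emulates a 36 bp single-end run: insert (17–25 nt) +
3′ adapter, padded with random bases to 36 nt, qualities from a clipped
normal (mean 38, sd 2), optional per-base substitution errors (default
rate 0 — the fixture is a correctness oracle, not an error-model study).
Default composition per sample: 10 planted plant miRNAs of 20–24 nt with
counts (40, 31, 25, 18, 14, 11, 8, 5, 4, 3) — two below and one exactly
at the count-5 threshold so the boundary is always exercised; 15 decoy
plant-reference entries (3 per exclusion stage) drawn from host ncRNA,
mRNA, genome, genome-with-editing-signature and microbiome sequences,
5 reads each; 60 host and 20 microbiome background reads (removed at the
plant-match stage); 5 adapter dimers.

Class structure is enforced, not hoped for: planted miRNAs are
rejection-sampled until the pipeline's own matchers find no signal
against any host or microbiome reference (no shared 17-mer — the
pipeline's minimum tag length — no ≤ 2-mismatch genome placement, no
E ≤ 0.01 local hit), and each decoy is verified to be caught at its
intended stage and no earlier. Host ncRNA/mRNA are genuine genome
substrings so they map back. Everything is a pure function of the seed;
identical configurations produce byte-identical FASTA/FASTQ/manifest.

What the generator does **not** model: position- and quality-dependent
Illumina error profiles, PCR duplicates, and the 3′-ligation bias against
2′-O-methylated plant miRNAs. Passing the planted-recovery tests
therefore demonstrates the cascade's logical correctness (no leakage, no
false rejection, exact counting) under clean conditions, not calling
performance on real libraries.

## Problem sizes and numerical choices

Test and reproducibility runs use desk-scale inputs chosen to keep the
oracle cross-checks exhaustive: host genomes of a few kb (the sliding-
window Hamming oracle is run up to tens of kb), duplex enumeration at
≤ 12 nt and fold enumeration at ≤ 15 nt per sequence, 300–1000 randomized
trials per engine. Ties in the duplex/fold DPs are broken toward the
lexicographically smallest end cell; tag ordering is by descending count
then sequence, so all outputs are independent of input order. Coordinates
are 0-based half-open throughout; minus-strand map hits report
forward-reference positions with mismatches in original-read orientation.

## Known limitations

- Karlin–Altschul statistics are ungapped but applied to gapped local
  scores; E-values near the 0.01 threshold are approximate (conservative
  in the direction of removing more tags).
- The energy tables are compact approximations; scanner thresholds are
  calibrated to them only in the sense of being config-exposed.
- The windowed complementarity scanner reports one best site per locus;
  overlapping weaker sites are suppressed.
- Multi-sample handling is a loop over samples; there is no cross-sample
  tag borrowing or batch normalization (profiles are raw counts by
  design).
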