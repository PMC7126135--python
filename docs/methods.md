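# Methods

## The conservation model

Each alignment column is treated as a sample from a residue distribution
*P*, compared against background amino-acid frequencies *Q* by relative
entropy (Kullback–Leibler divergence) in base 2:

    D_KL(P‖Q) = Σ_a P(a) · log2(P(a)/Q(a))   [bits]

and gap-weighted by the column's non-gap fraction:

    G_W = D_KL(P‖Q) · n_nongap / n_rows.

A column is conserved iff `G_W > log2(1/Q(R))`, the score of a hypothetical
gapless all-arginine column. The yardstick is arginine because protamine
sequences are arginine-saturated: any measure that rewards mere purity
would flag most of an alignment, whereas demanding *more* surprise than
pure arginine isolates the sparse cysteine/tyrosine/histidine positions
that plausibly carry structure (cross-linking, zinc binding).

Conventions, each of which materially affects the numbers:

- **Base-2 logarithm.** Pins the all-arginine threshold at
  `log2(1/0.0569) = 4.13543` bits with the bundled background. A natural
  log would require an implausible Q(R) ≈ 1.6% to produce the same number.
- **P(a) over non-gap symbols only.** Gaps appear in neither numerator nor
  denominator of P; the gap penalty enters exclusively through the `G_W`
  multiplier. Column "purity" figures (majority symbol fraction) use the
  same non-gap denominator.
- **Strict inequality.** A column scoring exactly the threshold (e.g. a
  gapless pure-arginine column) is *not* conserved. Comparisons are done in
  full float precision, never on rounded values.
- **Initiator-Met masking.** Each row's first non-gap symbol, if `M`, is
  treated as a gap in all column statistics (it is a translation artifact,
  not a conserved choice). The masked cell counts on the gap side of the
  non-gap fraction. The same convention removes the leading Met from
  whole-sequence density denominators.
- **Gap-weight denominator.** The raw row count, not the count of rows
  surviving masking.
- **Ambiguity codes.** B/Z/X are scoreable symbols with derived
  backgrounds: Q(B)=Q(D)+Q(N), Q(Z)=Q(E)+Q(Q), and Q(X)=1, an upper bound
  that makes any X contribute a non-positive term — unknowns can only
  deflate a score. These assignments are configurable via the background
  table.
- **0·log 0 = 0**; Q(a)=0 is rejected at background-load time.

## Background frequencies

The bundled table (`protascan/data/uniprot_2019_abundance.tsv`) carries
UniProt-knowledgebase-scale natural abundances for the 20 standard residues
with Q(R)=0.0569, the arginine value consistent with the 4.1354-bit
all-arginine threshold. The 20 values sum to 0.9991; the loader accepts
sums in (0.98, 1.02] so alternative published tables load unchanged. Any
two-column (symbol, frequency) file can be substituted — a uniform table
(Q=1/20) is a useful null background under which the threshold becomes
log2(20) for every residue.

## Group assembly

Records come from an already-downloaded UniProt-style export (FASTA with
`sp|ACC|NAME`/`tr|ACC|NAME` headers, or a tab-separated table carrying
accession, reviewed flag, gene names, organism, ordered lineage,
description, sequence). Live querying is deliberately out of scope — it
depends on a moving service, and lineage strings are taken as given rather
than resolved against a taxonomy database.

Group rules are (lineage taxon, accepted gene names, description
exclusions): eutherian P1 = `Eutheria` + {PRM1, Prm1}; eutherian P2 =
`Eutheria` + {PRM2, Prm2}; metatherian P1 = `Metatheria` + {PRM1, Prm1};
fish = `Actinopterygii` with no gene-name constraint and a case-insensitive
"like" description exclusion (dropping protamine-like proteins). Gene-name
matching is exact and case-sensitive against every synonym a record lists.
Mammalian groups are deduplicated to one entry per organism: reviewed
(Swiss-Prot) entries win; among equally reviewed candidates the
lexicographically smallest accession wins, and the output is sorted by
accession — both choices exist to make the result independent of input
order. Known-bad members (e.g. P2 sequences lacking translational
expression, pseudogenes) are removed by an explicit exclusion list with the
reason recorded in provenance; an exclusion that matches nothing is a
warning, not an error.

## Alignment handling and P2 truncation

Alignment itself is external and pluggable: a command template (default
`muscle -in {in} -out {out}`; any tool with a FASTA-in/FASTA-out interface
works, e.g. `mafft --quiet {in}`) or a pre-made aligned FASTA in
passthrough mode. In either case the de-gapped rows are checked against the
input sequences. Gap character is `-`; `.` is normalized on read; row order
is preserved; columns are 1-based everywhere, matching how positions are
reported.

Unprocessed P2 protamines lose ~40% of their N-terminus post-
translationally; conservation and density of the mature protein are only
meaningful on the processed region. Truncation is anchored, not hard-coded:
the configured reference row (mouse P2) and processing-site residue index
(44) are mapped through the alignment to a column, and all columns from
that column (inclusive) onward are kept. For the published alignment this
anchor lands on column 48; recomputing it per alignment keeps the pipeline
valid under different aligner outputs. Rows that become all-gap are
retained and flagged in provenance. Downstream, whole-sequence densities
for a truncated group use the truncated (processed) sequences.

## Charge-density analysis

Per-sequence density = (count of residues in the configured set)/(sequence
length), after dropping the initiator Met. The default set is {R, K}:
histidine is excluded because it is mostly deprotonated at physiological
pH, and the set is configurable for sensitivity analyses (adding H, S, T,
etc.). Region densities are computed over the row's non-gap symbols inside
a 1-based inclusive column window (eutherian P1 DNA-binding region: columns
17–46; metatherian: 16–56); the denominator is the non-gap count, not the
window width, so gap-heavy rows remain comparable across species — a row
with no residues in the window yields a missing value rather than zero.
Quartile summaries use linear interpolation between closest ranks (the
numpy default), recorded explicitly because quartile conventions differ.
Group comparisons use Welch's two-sided unequal-variance t-test with
Welch–Satterthwaite degrees of freedom; t and df are computed from the
explicit formulas, p from the t distribution. Degenerate inputs: samples
under two observations are errors; two zero-variance samples give p=1 when
means agree and p=0 otherwise. Pairwise p-values are reported raw — no
multiple-testing correction, matching the analysis the outputs mirror.

## Synthetic families

The generator emulates the statistical structure of protamine alignments
rather than their evolution: rows are drawn i.i.d. per cell from an
arginine-heavy composition (default 70% R, the fish-protamine regime —
deliberately the stress case for the all-arginine threshold, since
background columns then hover near but not above it); designated "planted"
columns emit a chosen residue with purity π and a background draw
otherwise; gaps are i.i.d. per cell at rate γ (the conservation score
depends only on per-column gap fractions, so block-indel realism buys
nothing here); optionally every row starts with an initiator Met. Ground
truth records each column's label and realized purity/gap fraction. A
planted column's expected score has the closed form
`(1−γ)·D_KL(π·δ_r + (1−π)·bg ‖ Q)`, exposed as `expected_planted_score`.

What the generator does *not* model — phylogenetic correlation between
rows, indel blocks, length variation, compositional drift along the
sequence — bounds what passing tests show: they validate the scoring
machinery and its calibration against known truth, not robustness to
tree-structured redundancy (the scorer uses unweighted frequencies, so a
clade of near-duplicates inflates purity in real data and synthetic tests
alike).

A second generator produces two sequence sets with chosen R+K emission
probabilities (charged positions split 85:15 between R and K, mirroring
arginine dominance) for calibration and power checks of the Welch test.
Per-sequence frequencies are then binomial around the targets.

Sampling noise matters when interpreting recovery tests: at n=50 rows, a
planted column's realized score has a standard deviation of roughly
`log2(π/Q(r)) · √(π(1−π)/50)` ≈ 0.3 bits at π=0.8 — the same order as any
fixed margin one might demand over the threshold, so recovery of
0.8-purity columns is intrinsically probabilistic at this family size
while π ≥ 0.9 columns at full coverage are recovered reliably.

## Pipeline and reporting

A YAML config drives ingest → grouping → alignment → truncation → scan →
density → tests for any number of groups; every stage error is labelled
with its stage. Outputs are TSV tables (per-column scores, conserved
positions sorted by descending score, per-sequence densities, quartile
summaries, pairwise Welch matrix) plus text/HTML alignment renderings with
conserved columns highlighted; each table is stamped with a config hash
and the background-table label so numbers are traceable to their exact
settings. Reruns with identical inputs and config are byte-identical.

## Test-suite problem sizes

The suite exercises the scanner against an independent brute-force
summation on 100 random 10×30 alignments (1e-9-bit agreement), recovery on
synthetic families of 50 sequences × 60 columns across a purity/gap grid
over 20 fixed seeds, and Welch calibration on 1000 replicate null
simulations of two 50-sequence groups (Kolmogorov distance to uniform,
plus a power check at R+K 0.5 vs 0.7). These sizes keep the full suite
under ten seconds while leaving the statistical checks well-powered.
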