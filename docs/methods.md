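# Methods

## Spectral-count quantification (RPSM)

The abundance proxy is RPSM = 100 · PSM / n, where PSM is a protein's
spectral count in one replicate and n is its number of predicted tryptic
peptides. The denominator uses fully tryptic peptides (both ends at a
cleavage site or terminus), cleavage after K/R, **zero** missed cleavages,
minimum length 6 residues, proline rule off. The original tooling for this
denominator does not document its settings, so the package adopts the most
common "distinct observable peptides" convention and exposes every option
(`DigestOptions`) so any other convention can be reproduced; search-engine
emulation (e.g. matching a database search that allowed up to two missed
cleavages) sets `max_missed_cleavages=2`. The initial Met is not stripped,
and I/L stay distinct during digestion — they collapse only in de-novo tag
matching, where the isobaric pair genuinely cannot be distinguished.

A protein with no predicted peptide cannot be normalised; the operation
raises rather than divides, and such proteins must be excluded upstream.
Replicate aggregation reports the arithmetic mean RPSM, the accumulated PSM
(sum over replicates), and a dispersion statistic (max − min over mean).

## Replicon summaries and percentage formatting

Identified proteins are tallied per replicon (chromosome + plasmids) with
percentages against the column total, rendered to one decimal with
round-half-away-from-zero. The published genome column is a special case:
the printed per-replicon counts sum to 7571, yet every printed percentage
corresponds to a denominator of 7318 (the printed total). The summary
operation therefore accepts an explicit denominator instead of silently
"fixing" the table; the shipped reference table documents this in its
header. Note that no rounding rule reproduces all printed cells of that
table — three cells (vegetative chromosome, vegetative pRlvC, lentil pRlvB)
differ from their printed value by one unit in the last decimal, which is a
transcription-level inconsistency in the source rather than an arithmetic
choice here.

The symbiotic-performance comparison uses
percent reduction = 100 · (reference − treatment) / reference, reported to
the nearest integer, e.g. 21.96 → 15.74 mg N/plant gives 28%.

## Host-specific calls and iTRAQ classification

A protein is host-specific iff (i) PSM > 0 in every replicate of the
detecting host, (ii) its accumulated spectra in that host are ≥ 10, and
(iii) PSM = 0 in every replicate of the other host. Absence is strict: one
spectrum in one other-host replicate disqualifies, and a protein missing
from a PSM table counts as zero everywhere (non-detection, not missing
data). The accumulated-spectra clause applies to the detecting host only.
The rule is a conjunction, so the order of applying (i)–(iii) is
irrelevant. The two host-specific sets are disjoint by construction.

iTRAQ pea/lentil ratios are classified with inclusive boundaries
(≥ 2 pea-over, ≤ 0.5 lentil-over): the published table lists ratios printed
as exactly 2.00 and 0.50 among the significant entries, which forces the
inclusive reading. Thresholds ≤ 1 are rejected as configuration errors.
Reconciliation marks a presence/absence call without a measurable ratio as
"not_measurable" and agreeing (one method silent); a conflict is flagged
only when both methods point at different hosts.

## NCR mining

Conserved tags are 3-residue windows of a reference NCR alignment in which
no sequence has a gap and each column's majority residue reaches 80%
conservation (configurable; the source procedure states only that conserved
3-residue sequences were used). Tag search and alignment identity treat I
and L as equivalent. ORFs are maximal stop-free stretches in all six frames
(no start-codon requirement, since proteomically observed fragments may be
internal), minimum 30 residues. Candidate validation aligns each
tag-positive peptide to every ORF with Smith–Waterman (BLOSUM62, gap open
11 / extend 1) and keeps the best-scoring hit iff identity > 90% of aligned
columns and coverage > 50% of the query — strict inequalities, as printed.
Score ties resolve to the lexicographically smallest contig id.

Signal-peptide cleavage positions are an input (they come from an external
predictor); a (−3,−1) small-residue heuristic is provided as a fallback but
is off by default. Isoelectric points of mature peptides solve
Q(pH) = 0 by bisection on [0, 14] to |Q| < 1e−6, with Q the
Henderson–Hasselbalch net charge over the termini and K/R/H/D/E/C/Y side
chains. Q is strictly decreasing in pH, so the root is unique and bisection
always converges. The pKa table (EMBOSS-style: N-term 8.6, C-term 3.6,
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) ships as an editable
JSON file because the exact table of the original web tool is not
published; absolute pI values shift slightly under other tables, the
anionic/neutral/cationic ordering does not. Charge classes: anionic
pI < 6.5, neutral 6.5–7.5 (both boundaries neutral), cationic > 7.5;
values outside [4, 10] classify with a warning.

## Neighbor joining

Distances are p-distances (mismatches over compared columns) with pairwise
gap deletion — the distance model and gap treatment of the source figure
are not stated, so the simplest peptide default was chosen and both are
documented here. Tree inference is classic Saitou–Nei NJ on the Q
criterion. Two choices make output deterministic: Q ties break on the
lexicographically smallest label pair (internal nodes labelled by their
smallest descendant leaf), and negative limb lengths clamp to zero (limbs
only — reduced distances are never clamped, which would change join
order). Newick output uses 6 significant digits and sorts children by
smallest descendant label, so rerun output is byte-identical. On additive
matrices the generating tree is recovered exactly (verified for all 24
four-taxon label orders); on arbitrary matrices the topology matches
independent NJ implementations (skbio, ape) up to rooting of the
trifurcation.

## Synthetic data

The generator emulates the study's input structure at its design scale:
three replicates per host, replicon proportions matching the published
genome shares, 28 + 25 planted host-specific proteins, a default proteome
of 600 proteins (scaled from the ~7300-protein genome to keep a full run
fast while leaving hundreds of background proteins), and NCR corpora of 52
(pea-like) or 65 (lentil-like) peptides with 4 or 6 cysteines and target
charge-class mixes of 44% / 51% cationic respectively.

Spectral counts are negative-binomial (gamma–Poisson, default mean 20,
dispersion 0.3) — over-dispersed as real spectral counts are; the source
provides no count distributions, so these are plausibility choices exposed
in `GeneratorSpec`. Planted host-specific proteins are positive in every
replicate of their host with accumulated counts ≥ 12 (a margin above the
10-spectra cut-off) and exactly zero in the other host; background proteins
are forced to at least one detection per host so they can never satisfy the
absence criterion; near-miss distractors (present in 2 of 3 replicates, or
accumulated 5–9) are labelled in the truth table. iTRAQ nulls are
log-normal (σ = 0.25) around 1 with planted shifts at 2.5, 3.2 and 0.4.
NCR matures embed a K-delimited, K/R-free conserved core block shared with
the reference alignment, so at least one tryptic fragment of every planted
peptide carries a tag; coding sequences are embedded in contigs (half on
the reverse strand) among random decoys; decoy de-novo peptides are
screened to contain no tag (I/L-blind). Target pI classes are achieved by
composition-biased accept/reject sampling with a bounded retry count.

These constructions make pipeline recovery exact by design (recall 1.0,
zero decoy leakage at default thresholds), which is what the recovery tests
assert. That is deliberate idealisation: real de-novo lists contain
chimeric and error-containing peptides, real contigs contain assembly
artefacts and (in genomic copies) introns, real spectral counts share
peptides between homologous proteins, and none of these are modelled — so
a passing recovery test demonstrates the pipeline's correctness on
separable inputs, not its error tolerance on real data. Weakening the
margins in the spec degrades recovery monotonically, which is also tested
behaviour for the thresholds.

## Problem sizes used in checks

Deterministic arithmetic checks run on the shipped reference tables
directly. Property checks use 200 random sequences (length ≤ 60) for the
digestion oracle, 1000 background proteins for the iTRAQ false-positive
closed form (3σ binomial band), a 1e−4 pH grid for the pI oracle, all 24
four-taxon label orders for NJ exactness, and the full pea-like preset
(600 proteins, 52 NCR peptides) for end-to-end recovery.

## Known limitations

- Printed RPSM values of the source study are not reproducible because the
  underlying PSM tables live in a raw-data repository and the digestion
  settings behind the published denominators are unstated; RPSM correctness
  is instead established against oracles and closed forms.
- The pipeline's tree stage expects aligned matures; given unaligned ones
  it right-pads to equal length, which is a smoke-level stand-in for a real
  aligner.
- The identity/coverage validation is protein-level (translated ORFs),
  whereas the original genome-level confirmation used nucleotide BLAST;
  mining operates on peptides, so protein-level matching is the natural
  formulation here.
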