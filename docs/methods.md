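# Methods

This note documents the models, the numerical choices and the open design
decisions behind `toxscan`, and what the synthetic corpus does and does not
establish about real data.

## The genomic model

The pipeline assumes annotated proteomes: per assembly, a set of contigs
carrying strand-annotated CDS features (1-based inclusive nucleotide
coordinates, `feature_index` ordinal by start within a contig) and the
corresponding protein sequences. "Upstream" and "downstream" are always in
gene orientation: the downstream neighbor of a plus-strand gene is the next
CDS by index, of a minus-strand gene the previous one. A neighbor only
counts when it is the immediately adjacent CDS *and* on the same strand;
this is the strict reading of "directly upstream/downstream". An optional
`skip_opposite` relaxation steps over intervening opposite-strand genes —
off by default, because effector/immunity pairs are operonic and an
interleaved antisense gene breaks the operon assumption.

## Profile search

A family profile is a pseudocounted log-odds matrix over the 20 canonical
amino acids:

    f_ja = (c_ja + α·q_a) / (N_j + α)        score(j,a) = log2(f_ja / q_a)

with pseudocount weight α = 1 and background q taken from a fixed
Robinson–Robinson-style frequency table (renormalized over 20 letters).
B/Z/U/O/J map to X on input, and X scores exactly 0 in every column, so
ambiguous residues neither help nor hurt a window. Neither the pseudocount
scheme nor the background of the original search tool is published; both
are exposed in the API and their defaults documented here.

Scanning is ungapped: every length-L window is scored as the sum of its
column scores and the best non-overlapping windows are reported. Gapped
extension is a deliberate non-goal — for domain *presence/localization*
(what curation and neighborhood analysis consume) the ungapped window
suffices, and it keeps scanning deterministic and vectorizable.

Significance is empirical rather than analytic. A calibration set of decoy
proteins is emitted from the background distribution with lengths resampled
from the database; the expect value of score s is the fraction of decoys
whose best window reaches s, times the decoy count — i.e. the expected
number of decoys at that score. Beyond the best decoy score the mapping is
extrapolated with an exponential tail fitted to the top decile of decoy
scores and capped at 1/n_decoys, keeping it monotone non-increasing. The
published thresholds (inclusion 1e−6, report 1e−9) are therefore rank
cut-offs on this empirical scale, not Karlin–Altschul E-values; the
semantics of "admit at ≤ 1e−6, report at ≤ 1e−9" is preserved. Planted
family members at the default divergence score hundreds of bits above the
decoy maximum, so the conclusions are insensitive to the tail-fit details.

The iterative search runs 5 rounds with a 500-hit admission cap per round:
scan, admit new proteins passing the inclusion threshold (ties at the cap
broken by score descending, then protein id), realign all admitted hit
windows to the reference by the star alignment below, rebuild the profile,
recalibrate. The admitted set never shrinks, and rebuilding from an
unchanged hit set reproduces the profile bit for bit.

## Curation

Three filters, each a pure predicate of the hit and the static feature
table, hence order-invariant and idempotent:

* expect ≤ 1e−9 (inclusive — our choice, documented) and, for toxin-domain
  hits only, protein length ≥ 80 aa (inclusive, "at least 80");
* contig ends: a hit whose CDS has `feature_index` 1 or the contig maximum
  is dropped. "At the end of a contig" is not quantified anywhere; the
  first/last-CDS reading is an interpretation and the one this package
  fixes;
* multi-contig dedup: copies of one accession on several contigs of one
  assembly collapse to the lexicographically smallest contig when every
  copy shows the same downstream gene at the same intergenic distance.
  "Same downstream gene" is matched by product label (accession vs domain
  content being unstated upstream of us), and distance is the bp gap
  between CDS boundaries in gene orientation.

## Flank clustering

Flanks (C-terminal of marker hits, N-terminal of toxin hits) are clustered
greedily: sequences in canonical order (length descending, id ascending),
each compared against existing cluster representatives only, joining the
representative of **maximal** identity among those with identity ≥ 0.40 and
candidate length ≥ 0.50× the representative's; ties go to the
earliest-founded cluster. Identity is the number of identical aligned pairs
in a global end-gap-free BLOSUM62 alignment (gap open −11, extend −1)
divided by the shorter sequence's length — consistent with short-sequence
containment semantics. CD-HIT's exact identity definition differs in edge
cases (alignment-length denominators, word heuristics); this is documented,
not resolved, and no k-mer prefilter is used at desk scale.

## Neighborhood statistics

A toxin locus is *paired* when its same-strand downstream neighbor's
protein carries DUF1911 (DUF1910 co-presence is a secondary flag).
Percentages are half-up rounded to 2 decimals (1389/1546 → 89.84). The
upstream-domain share is computed over loci that *have* a same-strand
upstream neighbor; the T6SS-component share counts VgrG, TssL, DUF4123 and
the core-component COGs. Architecture classification walks the fixed
precedence list PAAR → DUF4280 → LXG → WXG100 → DUF637 → Fil_haemagg_2 →
VgrG → SP and requires the delivery domain to lie N-terminal to the toxin
hit; SP requires both predictor calls (logical AND of the Phobius-type and
SignalP-type annotations, encoded as `SP_Phobius`/`SP_SignalP` rows).

## T6SS classification

A genome is T6SS-positive at ≥ 9 of the 11 core COGs {COG3516, COG3517,
COG3157, COG3521, COG3522, COG3455, COG3523, COG3518, COG3519, COG3520,
COG3515}. VgrG (COG3501) is correlated with T6SS but excluded from the
9-count (a switch includes it for sensitivity analysis). Presence is binary
per assembly; copy number is ignored; unknown COG labels never count.

## Conservation and motif

Members are star-aligned to the reference (global BLOSUM62, affine −11/−1,
end gaps free) and projected onto reference columns; member insertions are
discarded. This replaces a full progressive MSA: since downstream analysis
prunes to reference columns anyway, the projection loses nothing the logo
uses, at the cost of ignoring member-member covariation during alignment.
Column frequencies exclude gaps; information content is
`IC = log2 20 − H − e_n`, heights `p_a·IC`; the small-sample correction
`e_n = 19/(2·ln2·n)` is off by default (the original logo-server settings
being unstated) behind an `--ssc` flag.

The consensus motif emits a residue token where the majority residue
reaches `tau_cons` **and** at least half the rows carry a residue in the
column (gap-dominated columns never read as letters); runs of non-conserved
columns emit fixed spacers `x_k`, or `x_n` when ≥ 5% of members have a
projected gap inside the run. `tau_cons` defaults to **0.8**: at the
corpus's family divergence of 0.3, ordinary columns retain the archetype
residue at ≈ 0.70 frequency while anchor columns (mutating at one tenth the
rate) retain ≈ 0.97, so 0.8 sits in the gap and reads exactly the
constrained positions as letters. A 0.5 threshold would letter every
column of such a family; the appropriate value always depends on the
divergence of the family being summarized, which is why it is a parameter.

## Phylogeny

Conserved sites are columns with no gap and no non-ACGT code in any row
(complete deletion — one global site set, matching a single printed site
count rather than pairwise deletion). JC69:
`d = −(3/4)·ln(1 − 4p/3)`, defined for p < 3/4; a saturated pair raises an
error naming the taxa. Neighbor joining is the standard Saitou–Nei
agglomeration on Q(i,j) = (n−2)d(i,j) − r_i − r_j, with clusters keyed by
their lexicographically smallest leaf and ties in Q broken on that key pair
— determinism is part of the contract. Negative branch-length estimates are
clamped to 0 with a warning. NJ's exactness on additive matrices is the
module's primary oracle (100 random 5–8-taxon trees recovered to 1e−9),
with an independent implementation cross-check on tie-free matrices.

## The synthetic corpus

The generator emulates the statistical structure the pipeline assumes: per
genome, 2–4 contigs of 6–14 CDS; decoy proteins i.i.d. from the background
table (lengths ≈ N(300, 90²), floored at 50); intergenic gaps uniform in
[1, 200] bp; operon strand persistence 0.8. A genome carries a marker locus
with probability 0.8; a marker locus carries the C-terminal nuclease domain
with probability 0.7 (neither rate is published — they only set how much
signal the corpus contains). The rates the downstream statistics measure
default to the published values: downstream-immunity pairing 0.8984, T6SS
cluster presence 0.965, T6SS-component upstream neighbor 0.7014. Family
members diverge from a fixed 449-residue archetype by per-site substitution
(anchors at one tenth the rate, length preserved); divergence defaults to
0.3, a free parameter, since no natural divergence statistics are published
for the family. Contig-end truncations (rate 0.05) and duplicated contigs
(rate 0.05, exact copies dedupable and distance-perturbed copies not)
exercise both branches of every curation rule, and the ground-truth table
records a `should_survive` flag computed from the same rules.

What passing on this corpus shows: the search, curation, pairing,
classification, logo and tree code compute the defined quantities
correctly, deterministically, and at the configured rates. What it does not
show: performance on real proteomes — no gapped homology, no compositional
bias, no paralog structure, no annotation errors, no operon rearrangements
beyond strand flips. The published corpus-scale hit counts depend on a
reference-database snapshot and are out of reach at desk scale; the
`presets` module instead replays the published *marginal* counts
(1546/1389 pairing; 3507/5000 upstream components; 107/2881 delivery
domains; 965/1000 co-occurrence) through the same code paths that would
process real tables. The upstream denominator 5000 is invented (the
source tables print only the percentage), chosen as the smallest round
count that reproduces it exactly at 2 decimals.

## Problem sizes and determinism

Default analysis preset: 200 genomes (≈ 6,500 proteins), 5 search
iterations, 1000 calibration decoys — chosen so a full run completes in
well under a minute on one CPU while leaving > 100 planted loci per family
for the rate statistics. All randomness derives from one seed via the
child-seed map `(seed·9973 + stage) mod (2³¹−1)`; report files use fixed
float formats (percentages 2 dp, identities 3 dp, branch lengths 6 dp) and
LF newlines, so a config+seed pair reproduces a bundle byte for byte
(verified by manifest SHA-256 hashes).

## Known limitations

* Ungapped scanning cannot localize domains split by long insertions.
* Empirical E-values are only as fine-grained as the decoy count; below
  1/n_decoys they are a smooth extrapolation, not a measurement.
* The star alignment anchors everything to one reference; families with
  regions absent from the reference are invisible to the logo by design.
* Greedy clustering is representative-based and order-canonicalized, not a
  global optimum.
* `tau_cons` and the family divergence trade off directly; motif letters
  from a family of unknown divergence should be read with that in mind.
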