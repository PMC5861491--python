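# Methods

This note documents the models, parameter choices, and numerical
conventions behind `interomap`, and what the synthetic fixtures do and do
not establish about behaviour on real data.

## Interface contacts

A contact is an inter-chain residue pair whose closest heavy-atom distance
is ≤ `contact_cutoff` (default **4.5 Å**, the common interface convention).
It is sub-typed, in order:

1. **hbond** — a donor–acceptor heavy-atom pair (backbone N/O plus the
   standard sidechain N/O sets) within `hbond_cutoff` (default **3.5 Å**).
   No angle criterion is applied because template coordinates generally
   lack hydrogens; this makes the definition reproducible from heavy atoms
   alone at the cost of some over-calling.
2. **electrostatic** — oppositely charged residues (Asp/Glu vs Lys/Arg)
   with charged atoms within `hbond_cutoff`. Because every charged N/O atom
   is also in the donor/acceptor sets, salt bridges inside the H-bond
   cutoff classify as *hbond* first; the electrostatic class is therefore
   nearly empty under defaults. Downstream analyses group the two classes
   anyway (they share one energy term), so this ordering has no practical
   effect.
3. **vdw** — everything else within the contact cutoff.

Internal residue numbering is the 1-based index into the chain's observed
gap-free sequence (author numbering kept as metadata); alignment transfer
needs gap-free indices. Non-standard residues become `X` and never form
contacts. Alternate locations resolve to the highest-occupancy conformer;
the first model of multi-model files is used.

## Homolog families

The primary ingest path is 12-column BLAST tabular output. The built-in
fallback is a Smith–Waterman search (BLOSUM62, gap open 11 / extend 1 — the
BLASTP defaults) with Karlin–Altschul E-values `E = K·m·n·e^(−λS)` using
published *ungapped* (λ, K) per matrix. Ungapped parameters applied to
gapped scores make these E-values approximate (generally conservative);
the family threshold **E ≤ 1e-10 (inclusive)** is the same on both paths.
One best hit is kept per subject.

## Candidate scoring and acceptance

Candidates are aligned globally to their template chain (same matrix and
penalties; the aligner's first optimal alignment is taken, a deterministic
tie-break). Template contacts map through both alignments; a contact gapped
on either side contributes only a fixed `gap_penalty` (default **−4.0**,
on the BLOSUM62 scale of roughly one strong mismatch plus a gap) to
`E_sim` and nothing elsewhere.

- `E_vdw`, `E_SF`: symmetric 20×20 residue-pair tables applied to the
  candidate residues at vdW and hbond/electrostatic contacts respectively.
  The original method's calibrated energy functions are not published in
  full, so the shipped defaults are a documented surrogate: a
  Kyte–Doolittle hydrophobic-packing product for the vdW table and a
  donor/acceptor-capacity × charge-complementarity score for the
  hbond/electrostatic table (`src/interomap/data/*.tsv`, swappable via
  `PotentialTable`). Absolute scores are therefore not comparable to the
  original server; the architecture, acceptance logic, and every statistic
  downstream are.
- `E_sim`: BLOSUM62 similarity of candidate vs template residues over the
  aligned contact positions of both chains. The template's own pair
  maximizes this term by construction (substitution matrices are
  self-dominant), giving the self-template dominance invariant.
- `E_cons`: `w_cons` (default **1.0**) per couple-conserved contact — both
  template columns conserved in the family alignments *and* the candidate
  matching the template residue at both positions. It is a bonus: higher
  `E_tot` is better throughout, and acceptance takes the upper tail.
  A column is conserved when ≥ `c_min` (default **0.7**) of the non-gap,
  non-template rows match the template residue. Conservation context is
  computed from the family-wide template-anchored alignments (all
  family members), since the accepted set does not exist yet at scoring
  time; the reported `PPIFamily` restricts MSA rows to accepted proteins.

The **Z background** draws `n_bg` (default **200**) sequence pairs
uniformly at random (seeded) from the whole database and scores them
through the identical align–map–score path; `z = (E_tot − mean)/sd` with
the n−1 standard deviation, and acceptance is **z ≥ z_min = 3.0**,
per-template. A degenerate (zero-variance) background is an error, not a
silent pass.

MSAs are pairwise alignments projected onto template columns (candidate
insertions dropped, no iterative realignment) — deterministic and
template-anchored.

## Network topology

Edges are unordered protein pairs; duplicate support merges with the
best-Z template first and contact maps unioned. Self-loops are stored but
excluded from degree fitting by default. The degree exponent γ offers
three estimators:

- `mle` (default): exact discrete power-law MLE, maximizing the
  Hurwitz-zeta likelihood over degrees ≥ xmin. This is the estimator the
  recovery tests use.
- `mle_approx`: the closed-form continuous-proxy estimator
  `1 + n/Σ ln(k_i/(xmin−0.5))`. At xmin = 1 it is materially biased
  (≈ 1.83 on exact zeta samples drawn at γ = 2.05), which is why it is not
  the default; it is kept for comparison with literature that uses it.
- `loglog_ls`: negated least-squares slope of log P(k) vs log k, the
  legacy graphical method, known to be noisy.

Degree samples in the fixtures come from inverse-CDF sampling on the
zeta-normalized pmf tabulated to k = 10⁶ (residual tail mass ~10⁻⁶ at
γ ≈ 2 collapses onto the last bin).

## Mutation classification

Only in-frame point substitutions are classified (truncating `X…*`
mutations pass through flagged; in-frame indels are out of scope). An
*interacting domain* is a Pfam/SCOP region containing ≥ 1 template-mapped
contacting residue of that protein on some edge — the minimal reading of
domain assignment "based on the structural templates". Electrostatic
contacts group with the hydrogen-bond class by default (one energy term
covers both; configurable). Domain placement partitions into
interacting / non-interacting / outside; contact sub-classes
(hbond ∧ conserved, hbond-only, conserved-only, neither) partition the
contacting set. Optional wild-type checking rejects mutations whose stated
wild-type disagrees with the stored sequence. Mutation positions are
assumed to share the stored sequences' numbering (no isoform mapping).

## Enrichment statistics

Odds ratios are evaluated on exact fractions and only rounded for display;
degenerate proportions (0 or 1) are flagged and reported alongside a
Haldane (+0.5) alternative. Fisher exact (scipy, probability-ordering
two-sided) and Mann–Whitney U (exact permutation distribution up to n = 20
per sample without ties, tie-corrected continuity-corrected normal
approximation otherwise) are reported with both sidedness choices where
the analysis direction matters, since a single sidedness is not dictated
by the method. The test suite checks both against independent brute-force
enumeration oracles.

ddG hot-spot analysis cross-tabulates (contacting × ddG > threshold),
threshold default **1.5 kcal/mol** (the conventional hot-spot cut), and
reports class means, the table's odds ratio, Fisher p (one- and
two-sided), and the U-test on the two ddG distributions.

**RSS.** The relative-specificity similarity of two GO terms is
implemented as `depth(c) / (depth(c) + d1 + d2)` where `c` is the deepest
common ancestor, `depth` the longest is_a path from the aspect root, and
`d_i` the shortest up-path distances to `c`. Conventions fixed here and in
the tests: identical non-root terms score 1; pairs whose only common
ancestor is the aspect root score 0; scores live in [0,1] and are
symmetric. The protein-pair score is the maximum over annotation term
pairs. The scorer is pluggable for alternative semantic similarities.

**Co-expression** is Pearson correlation on log2(x+1)-transformed
expression over shared samples (Spearman available); edges with an
unmeasured endpoint are counted as uncovered, constant vectors skipped.

## Synthetic fixtures: what they do and do not show

The template fixture places two chains on parallel lines 20 Å apart with
designed sidechain-atom contact pairs (2.9 Å Ser–Gln donor–acceptor for
hbond, 3.8 Å Leu–Leu carbons for vdW) spaced 30 Å apart along the
interface so no unintended contact arises. The database implants, per
chain, 3 homologs at 90% identity (contact residues preserved) among 20
shuffled, composition-matched decoys — so E-value separation, not
composition bias, drives family recovery. Default sizes (40/35-residue
chains, 3 contacts, 3 implants, 20 decoys, n_bg = 200) keep the full
pipeline under a few seconds while leaving implant and decoy score
distributions separated by far more than 3 background SDs.

Passing these tests establishes the machinery: contact detection equals a
brute-force scan, alignment scores equal DP oracles, implanted truth is
recovered exactly, statistics match enumeration, and everything is
deterministic under a seed. It does **not** establish performance on real
structures (flexible interfaces, crystal contacts, domain rearrangements),
real homology (paralog interference, alignment error at low identity), or
the original method's calibrated energies — reconstructing the published
human network requires the full PDB-derived template library and a
complete-proteome database, which are outside the scope of this artifact.

## Degenerate inputs and tie-breaks

Empty homolog families yield empty results with a notice, not an error.
Largest-component ties break toward the component containing the
lexicographically smallest protein id. Equal-score alignments resolve to
the aligner's first enumeration. Domain rows with start > end are rejected
with a warning; overlapping same-accession regions merge; overlapping
distinct accessions in one database are kept with a warning. Unknown
residues score zero in every table. All randomness flows through seeded
`numpy` generators; identical seeds give byte-identical outputs.
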