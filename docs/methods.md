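# Methods

This note records the conventions, parameter choices and numerical details
behind each stage, the design decisions taken where the procedure was
genuinely open, and what the synthetic benchmark does and does not show.

## Catalog curation

An entry is one isoallergen or variant row compiled from up to four source
databases (WHO/IUIS, AllergenOnline, COMPARE, Allergome). Designations are
normalized before keying: internal whitespace collapsed, the genus token
capitalized, species tokens lowercased, so `gad  M 1.01` and `Gad m 1.01`
merge. The isoallergen and variant codes are two digits each; any other
digit count after the dot is a parse error naming the offending token.

Deduplication keys rows by normalized designation, falling back to the
primary accession for IUIS-unassigned rows. The primary accession is chosen
as UniProt > RefSeq > GenBank protein > PDB; a GenBank nucleotide accession
is accepted only as a last resort so nucleotide-only rows still obtain a
stable key. Merging unions accessions and PMIDs and ORs the source flags;
two sources giving *different sequences* for one key is raised as an error
rather than silently resolved, because such conflicts need manual curation.
Completeness (`complete` / `partial` / `absent`) is metadata, never inferred
from the sequence, and only complete entries enter downstream analysis.

Tool sensitivity is `100 × detected / total` over a panel of known
allergens, rounded half-up to one decimal. Sequences a tool rejects for
nonstandard residues (any character outside the 20 canonical one-letter
codes, e.g. `X`) count as missed: an unprocessable allergen is a failed
prediction, not a excluded case. The bundled benchmark inputs
(`reference_data.py`) score weak-evidence predictions as missed, which is
the convention the published sensitivities imply.

## Percent identity

Identities come from direct pairwise global alignment rather than a
multiple alignment: Gotoh's affine-gap algorithm with BLOSUM62, gap open 10
and gap extend 0.5 (ClustalW-style protein defaults), where a gap of length
k costs `open + (k−1)·extend` and end gaps are penalized. The traceback is
deterministic — on score ties a match/mismatch column is preferred to a gap
in the second sequence, which is preferred to a gap in the first — so
alignments are reproducible, and the scores are cross-checked in the test
suite against Biopython's `PairwiseAligner` and an exhaustive enumeration
oracle on short sequences.

Percent identity = identical columns / columns where *both* sequences hold
residues (the standard identity-matrix convention; the denominator is
stated because published tables rarely state theirs). `X` never counts as
identical, even to another `X`. Group summaries round each pairwise value
half-up to one decimal first, then drop values at exactly 100% (duplicate
sequences carry no information about family divergence); the mean, sample
SD (ddof = 1) and min–max are taken over the remainder. A single surviving
pair — always the case for two-sequence families — is reported without an
SD; a family whose pairs are all at 100% is an error, not a silent zero.
Because pairwise and MSA-derived identities can differ slightly on
divergent pairs, published identity values should be compared with about
±1 percentage point of slack.

## Epitope mapping

Mapping is ungapped Hamming comparison of an epitope peptide against every
window of the target: substitutions only, no indels, case-insensitive,
with nonstandard residues never matching anything (a masked position always
spends a mismatch). Counts are per **distinct epitope peptide** — an
epitope hitting four windows counts once, and identical peptides reported
from different source species collapse to one epitope before counting.
Four statistics are computed per sequence: exact and ≤2-mismatch counts for
positive-assay and negative-assay epitope sets. The two external predictor
scores (percent identity over an 80-residue window and over the 3D epitope
surface) are pass-through annotation columns only; this package never calls
the predictors.

The per-sequence count is monotone in the mismatch allowance by
construction, and the scanner is validated against a naive double-loop
oracle on randomized instances.

## Threshold and statistics

Classification is a one-sided integer cut: `count ≥ T` ⇒ allergenic (the
boundary is inclusive). The scan evaluates every T in `0..max(count)+1` and
maximizes **balanced accuracy** (mean of per-class accuracies) — chosen
because the panels are small and class-imbalanced and no objective is
canonical for this task; ties break to the smallest T so results are
deterministic. Capture rate is the count and whole-percent fraction of
values at or above T.

Welch's t-test is computed from summary statistics
(`t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂)`, Welch–Satterthwaite df, two-tailed p from
the t distribution via scipy), so published mean ± SD tables are usable
directly. Degenerate inputs (n < 2, negative SDs, both variances zero) are
errors. Note that p-values recomputed from *rounded* summary statistics can
differ from the original in the last significant digit; the reference
parvalbumin comparison (17.1 ± 9.6, n = 11 vs 0.44 ± 0.53, n = 9) yields
p = 1.8 × 10⁻⁴ from the printed summaries.

## Phylogeny

The tree is an annotation scaffold, so a fully specifiable distance method
is used: pairwise distances from a supplied alignment with **pairwise gap
deletion** (columns gapped in either member of a pair are skipped for that
pair), as p-distance or Poisson-corrected `−ln(1−p)`. The Poisson
correction diverges as p → 1, which unrelated sequences approach, so the
pipeline default is p-distance; Poisson correction is appropriate for
clearly homologous panels. A saturated pair (p = 1) under Poisson is an
error, not a clamped value.

Neighbor joining is the standard Q-criterion agglomeration with two
determinism rules: ties on Q break to the lexicographically smallest label
pair (internal nodes inherit the smallest leaf label beneath them), and a
negative limb length is clamped to zero with the remainder shifted to the
sibling edge, so all branch lengths are ≥ 0. The result is the unrooted NJ
tree with a trifurcating root; midpoint rooting is available for display.
Correctness is tested by round-tripping random additive trees
(Robinson–Foulds distance 0 up to 12 taxa) and against scikit-bio's NJ.

Bootstrap supports resample alignment columns with replacement (seeded NumPy
generator), rebuild the NJ tree per replicate, and report the percentage of
replicates containing each internal bipartition of the full-data tree.
Newick output writes supports as internal-node labels with branch lengths
at six decimals; reading maps numeric internal labels back to supports, and
the round-trip is lossless at that precision. An externally built Newick
tree can be supplied in place of the built-in construction. Maximum
likelihood inference and rate-model estimation are out of scope.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes: two
classes of fixed-length sequences over a uniform residue background, with a
random positive-epitope library planted into the allergenic class inside
the mapper's mismatch horizon and (at most) heavily mutated decoys in the
other class outside it.

Defaults are the intended study conditions: 11 allergenic vs 9
non-allergenic sequences (the representative parvalbumin panel's class
sizes), 109-residue sequences (a typical parvalbumin length), positive and
negative libraries of 92 and 83 peptides (the sizes of the curated linear
epitope sets), epitope lengths uniform in 8–20 (the typical linear B-cell
epitope range), and up to 2 substitutions per planted copy. Each allergenic
sequence receives `max(4, Poisson(6))` distinct epitopes — the floor of 4
matches the family threshold, so allergenic labels are consistent with
planting by construction; the Poisson draw is truncated to what fits the
sequence without overlap (placement is left-to-right with multinomially
distributed gaps), and a configuration whose *minimum* cannot fit is an
error. Planted copies replace background residues, preserving sequence
length, and carry exactly the drawn number of substitutions, each recorded
as ground truth `(sequence, epitope, start, mismatches)` that
`verify_truth` re-checks with the mapper. Non-allergenic sequences receive
0 or 1 copy at 3–4 substitutions. Negative-epitope libraries are generated
but not planted, so negative counts reflect chance matching only.

What passing synthetic tests shows: the mapper, scanner and pipeline
plumbing are correct, deterministic and sensitive to planted signal at
realistic sizes. What it does not show: performance on real parvalbumins,
whose residue composition, epitope clustering (calcium-binding motifs) and
phylogenetic correlation between classes the uniform background does not
emulate. On real data the classes are homologous (41–99% identity), so
background epitope matches are far more common than here; the clean
separation observed on synthetic panels is therefore a correctness check,
not an accuracy claim.

## Numerical conventions and problem sizes

- Percentages are rounded half-up (decimal arithmetic, not banker's
  rounding): sensitivities to 1 decimal, capture rates to whole percent.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline's run seed overrides the synthetic config's seed so a single
  knob controls a run, and reruns are byte-identical.
- The test suite and acceptance script size their simulations to run on one
  CPU in a few minutes: 100-seed threshold-recovery sweeps on the default
  panel, 1000 randomized mapper-oracle instances, additive-tree recovery up
  to 12 taxa, and bootstrap panels of 6 sequences × 60 columns at up to 500
  replicates.

## Known limitations

- Identity values are pairwise, not MSA-derived; expect ±1 point deviations
  from MSA-based tables on divergent pairs.
- The threshold scan formalizes a procedure that is usually done by
  inspection; with tiny panels the optimal T is a range, and only the
  smallest-T tie-break makes the reported value unique.
- Negative-epitope planting is not modelled; synthetic negative counts are
  near zero and exercise plumbing, not discrimination.
- The aligner is quadratic-time pure Python: fine for parvalbumin-scale
  panels (hundreds of pairs at ~110 residues), slow for collagen-scale
  sequences (>1300 residues) in large batches.
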