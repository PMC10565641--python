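# Methods

## The motif model

A consensus motif is an ordered list of L columns, each either an explicit
residue class (a subset of the 20 standard amino acids) or a wildcard.
Matching is a **hard class match**: a window satisfies the motif iff every
non-wildcard column contains the window's residue. There is no log-odds
scoring and no threshold calibration — the contract is the one used in
degron scanning practice, where the printed consensus is the search
pattern. The reference CPD consensus is `[LP][LP][TS]P..[TSDE]`, with the
phospho-acceptor ('0') at column 3 and the '+4' at column 7. This
column assignment follows the CPD convention (S/T acceptor immediately
followed by an invariant proline, acidic/phospho residue four positions
downstream); the pattern parser applies the same rule to annotate any
parsed motif whose geometry supports it.

Motif equality is per-column **set** equality, never string equality:
`[TS]` and `[ST]` are the same class. Canonical serialization is
alphabetical (`[LP][LP][ST]P..[DEST]`); a frequency-ordered serialization
is available when a frequency matrix is attached.

### Frequency matrix and information content

`build_pfm` tallies exact column-wise residue counts over the catalog
windows (duplicated windows legitimately up-weight the tally and are
allowed, with a logged warning). Per-column information content is
`IC = log2(20) − H` with `H` the Shannon entropy of the empirical column
distribution, optionally with the small-sample penalty
`(|A|−1)/(2·ln2·n)`, `|A| = 20`, floored at zero. Logo rendering is
deliberately out of scope; only the information content is computed.

### Consensus derivation

`derive_consensus(pfm, include_threshold=0.2, max_class=4)` keeps, per
column, the residues with empirical frequency ≥ the threshold; an empty or
oversized class becomes a wildcard. The defaults are package conventions:
0.2 admits residues seen in at least a fifth of the training windows
(robust to one-off curation noise at typical catalog sizes of 10–40), and
a class larger than 4 of 20 residues carries little constraint, so it is
treated as unconstrained. Because no published derivation rule exists for
the reference CPD, downstream analyses treat the **printed pattern**
(via `parse_pattern`) as the authoritative artifact; re-derivation is
provided for new catalogs. The packaged degron catalog is synthetic —
twelve constructed windows whose frequencies reduce to the reference
pattern at the default settings — and is labelled as such; it is a
format fixture and a derivation check, not biological ground truth.

## Proteome scanning

Scanning reports **all** matches, overlapping ones included, at every
window position, because per-gene match counts are part of the output
contract and no suppression rule is defined for degron scanning.
Coordinates are 1-based inclusive (protein-database convention).
Ambiguity codes (X, B, Z, U, O) are accepted in sequences; they never
satisfy an explicit class but do satisfy wildcards — a class is an
explicit residue set, a wildcard is the absence of a constraint. The
implementation compiles the motif to a regular expression inside a
lookahead (for overlaps); the test suite checks it exhaustively against
an independent brute-force window enumeration.

FASTA headers are parsed in two dialects: `uniprot` (`db|ACC|NAME` plus a
`GN=` gene token) and `plain` (first token is both id and gene). A record
with no gene symbol aggregates under its protein id, with a logged
warning. Isoform collapsing is the caller's responsibility: supply a
canonical-sequence FASTA.

## Conservation scores

Conservation of a matched window is scored over a user-supplied MSA, not
over an alignment pipeline of our own — alignment construction is out of
scope and the two scores are chosen to be auditable by eye:

* **motif retention**: fraction of non-reference members whose aligned
  window (reference-gap columns skipped) satisfies the motif. A gap never
  counts as satisfying any column, wildcards included: "no residue
  present" cannot evidence conservation.
* **per-column identity**: fraction of non-reference members matching the
  reference residue, gaps counting as mismatches.

The default reporting threshold for "highly conserved" is retention
≥ 0.8. This is a package convention, not a published value.

## Enrichment and count statistics

The statistics are implemented from first principles in `degscan.stats`
(the test suite cross-checks them against independent library oracles).

* `hypergeom_upper_tail(k, K, n, N)` = P(X ≥ k). Exact integer
  arithmetic (one final division) for N ≤ 10,000 — at that size the
  binomial coefficients are exact machine integers, so the result is
  correct to the last floating-point digit — and log-gamma space
  summation beyond.
* `ora` intersects each gene set with the universe before computing K,
  drops (and logs) candidates outside the universe, and applies BH-FDR
  **across all sets tested in one call**. The default universe is all
  genes of the scanned proteome; it can be overridden, and the choice
  materially affects p-values. Fold enrichment is `(k/n)/(K/N)`.
* `bh_fdr` is the Benjamini–Hochberg step-up, `q_(i) = min_{j≥i} m·p_(j)/j`
  clipped at 1, original order restored.
* `fisher_exact_2x2` is the two-sided minimum-likelihood convention: sum
  the point probabilities of every table with the observed margins whose
  probability is ≤ the observed one within a relative factor 1 + 1e−7.
  Two-sided Fisher definitions differ between packages; this is the
  dominant one, stated explicitly.
* `odds_ratio` is `ad/bc`, with the Haldane–Anscombe +0.5 correction on
  request when a cell is zero; `bc = 0` without the correction raises
  rather than returning infinity silently.
* `proportion_percent` rounds half-up (not banker's), matching how such
  percentages are conventionally printed.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of its arguments and one integer seed.

* **Proteomes**: i.i.d. residues from a supplied background distribution
  (default uniform over 20). Implanted windows are drawn uniformly from
  the motif's satisfying sequences — independent uniform choice per
  column from its class — at non-overlapping recorded positions. With
  `clean_background` the protein is redrawn while accidental matches
  remain (bound: 100 redraws), then remaining accidents are destroyed
  deterministically by substituting the most-constrained column's residue
  with one outside its class, never touching implanted residues. Under a
  uniform background the analytic per-window match probability of the CPD
  consensus is `(2/20)³ · (1/20) · (4/20) = 1.0 × 10⁻⁵`, which the scan
  reproduces empirically at 10⁷ windows within Poisson error.
* **Ortholog families**: gapless identity alignments in which each
  ortholog substitutes each site independently with probability
  `sub_prob` to a uniformly chosen different residue, optionally sparing
  a protected window. No indels, no rate heterogeneity, no phylogenetic
  structure.
* **Gene sets**: null sets are uniform draws without replacement from the
  universe; the spiked set is built with an exact, specified overlap with
  a given candidate list.

These generators validate the *machinery* — coordinate bookkeeping,
calibration, ranking, error control. They do not emulate real proteome
composition (amino-acid frequencies, repeats, domain structure),
correlated evolution, or the gene-multifunctionality and annotation bias
of real gene-set collections, so passing tests demonstrate correctness of
the analysis, not biological recall of any particular substrate list.

## Numerical and design choices

* Validation problem sizes: implant recovery uses 50 proteins × 500
  residues with 20 implants; background calibration uses 10⁷ windows
  (1,000 × 10,006 residues), where the expected match count is 100 and
  3 Poisson SDs span ±30; enrichment recovery uses a universe of 5,000
  genes, 250 candidates, 50 null sets of 50 genes and a spiked set with
  overlap 12 — five times the expected overlap of 2.5, rounded down —
  over 200 seeds.
* Null-calibration testing of the enrichment p-values uses the
  **randomised p-value** `p − U·P(X = k)`, `U ~ Uniform(0,1)`, which is
  exactly uniform under the null. The raw upper-tail p-value of a
  discrete test is super-uniform by construction (P(p ≤ t) ≤ t, with
  atoms — e.g. every zero-overlap set reports p = 1), so a
  Kolmogorov–Smirnov test against Uniform(0,1) on raw p-values would
  reject for any well-implemented discrete test; the randomised transform
  is the standard way to test calibration in that setting.
* The pipeline writes a JSON manifest (package version, parameters,
  input SHA-256 checksums, stage list, completeness flag) sufficient to
  re-run bit-identically; outputs carry no timestamps, so identical
  configurations produce byte-identical artifacts.
* Degenerate inputs: empty catalogs, empty universes, families with
  fewer than two members, and inconsistent hypergeometric counts raise
  immediately with a message naming the offending record or line.

## Known limitations

* The hard-class match has no notion of match strength; a PSSM score is
  deliberately not provided.
* Gene-symbol matching in enrichment and Venn overlap is uppercased exact
  string comparison; alias or cross-species mapping must be supplied by
  the caller.
* Conservation scoring trusts the supplied MSA; misalignment around the
  window silently degrades both scores.
* A real canonical-proteome scan's candidate count depends on the
  database release and isoform policy; no attempt is made to pin one.
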