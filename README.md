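# degscan

Discovery of candidate E3-ubiquitin-ligase substrates by short-linear-motif
scanning, built around the FBXW7-recognised **Cdc4 phosphodegron (CPD)**.

FBXW7 is the substrate-recognition subunit of an SCF ubiquitin-ligase
complex. It binds a short phosphorylated degron whose convention places the
phospho-acceptor (S/T) at position **0**, an obligatory proline at **+1**,
and a phospho- or acidic residue at **+4**. `degscan` implements the full
in-silico substrate-discovery workflow around this motif:

1. **Catalog** — read and validate a table of experimentally validated
   degron windows (fixed length L, aligned on the '0' residue).
2. **Motif model** — tally a position-frequency matrix (PFM), compute
   per-column Shannon information content
   `IC_j = log2(20) − H_j`, and reduce the PFM to a degenerate consensus in
   bracket notation. The reference CPD consensus is
   `[LP][LP][TS]P..[TSDE]` (7 columns; '0' = column 3, '+4' = column 7).
3. **Proteome scan** — report every (overlapping) window of a protein
   FASTA satisfying all column classes, with 1-based coordinates of the
   match, its '0' and '+4' positions, and per-gene match counts.
4. **Annotation** — flag matches whose '0'/'+4' positions are known
   phosphosites (position *and* residue must agree), and compute Venn
   overlap counts between candidate genes and a named gene set.
5. **Conservation** — score a matched window across a user-supplied
   ortholog alignment: *motif retention* (fraction of orthologs whose
   aligned window still satisfies the motif) and per-column identity.
6. **Enrichment** — hypergeometric overrepresentation (upper tail
   `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`) of the candidate gene list
   against GMT gene-set collections, with Benjamini–Hochberg FDR across
   all sets tested; plus exact 2×2 Fisher tests, odds ratios and
   proportion summaries for contingency counts.
7. **Synthetic data** — seeded generators for background proteomes with
   implanted motif windows (and recorded ground truth), ortholog families
   with a per-site substitution probability, phosphosite tables, and
   gene-set collections with one deliberately enriched set — so the whole
   pipeline is testable end-to-end without external downloads.

Intended users: computational biologists prioritising candidate substrates
of degron-recognising ligases, and anyone needing a transparent, tested
SLiM-scanning pipeline with analytic calibration.

## Worked example

Generate a synthetic proteome with 20 implanted CPDs on a scrubbed
background, scan it, and inspect a match:

```python
from degscan import cpd_motif, gen_proteome, scan_proteome

cpd = cpd_motif()                       # [LP][LP][TS]P..[TSDE]
records, truth = gen_proteome(
    50, 500, seed=7, motif=cpd, n_implants=20, clean_background=True
)
table = scan_proteome(cpd, records)
print(f"{len(table.matches)} matches in {len(table.candidate_genes)} genes")
m = table.matches[0]
print(m.gene_symbol, m.start_pos, m.match_seq, m.zero_pos, m.plus4_pos)
```

prints

```
20 matches in 17 genes
GSYN0002 149 PLSPDPT 151 155
```

exactly the 20 implanted windows (`truth` records their positions): the
match starting at residue 149 of this protein has its phospho-acceptor '0'
at position 151 and its '+4' at 155. The same scan is available from the
shell, as is a 2×2 contingency summary:

```sh
$ degscan stats2x2 8,3,1,9
fisher_two_sided_p = 0.0075188
odds_ratio = 24
row1 = 72.7%  row2 = 10.0%
```

i.e. 8/11 (72.7%) events in row 1 versus 1/10 in row 2, two-sided Fisher
exact p = 0.0075. The full workflow (motif → scan → annotate → conserve →
enrich, with a run manifest) runs from a YAML config via `degscan run
--config config.yaml`; see `degscan --help` for all subcommands.

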