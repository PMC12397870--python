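# pepspace

Exhaustive proteogenomic search-space construction and data-driven
pre-filtering for proteomics and HLA-I immunopeptidomics.

Noncanonical peptides — from off-frame ORFs, UTRs, introns, intergenic
regions, lncRNAs, or proteasome-catalysed peptide splicing (PCPS) — can
only be identified by mass spectrometry if they are in the search
database, but enumerating them exhaustively inflates the database by
orders of magnitude and erodes identification sensitivity.  `pepspace`
builds these search spaces explicitly, counts them analytically, and
shrinks them with experiment-driven filters before any search engine
sees them.

## What it does

* **ORF strata** — from a genome FASTA and GTF annotation, discovers all
  ORFs (starts ATG/CTG/GTG/ATC/ACG, one longest ORF per stop codon,
  ≥ 8 aa) per feature stratum: CDS main ORF, CDS off-frame, 5′/3′-UTR,
  intron, intergenic, lncRNA; optionally restricted to transcripts with
  ≥ 10 RNA-seq counts in every replicate.
* **Peptide generation** — tryptic and nonspecific digestion with origin
  coordinates; forward/reverse cis-spliced (and trans-spliced) peptides
  via precomputed splice-reactant coordinate indices (i, j, k, n).
* **Analytic counting** — closed forms for the number of peptide events.
  For a substrate of length *L* and peptide length *N* (minimal
  splice-reactant length *L*<sub>ext</sub>, unrestricted intervening
  length):

  X<sub>non-spliced</sub> = L − N + 1,
  X<sub>fwd cis</sub> = ½(N − 2L<sub>ext</sub> + 1)(L − N)(L − N + 1),
  X<sub>rev cis</sub> = ½(N − 2L<sub>ext</sub> + 1)(L − N + 1)(L − N + 2),

  with capped-I<sub>max</sub> variants, a trans-splicing sum over
  first-reactant lengths, and the finite-sampling upper bound
  20<sup>N</sup>(1 − (1 − 20<sup>−N</sup>)<sup>M</sup>) on unique
  sequences after *M* splicing events.  Every closed form is validated
  against brute-force coordinate enumeration.
* **PTM expansion** — monoisotopic masses and combinatorial expansion of
  variable modifications (≤ 2 per peptide, ≤ 1 per site), with positional
  and isomer-collapsed counts.
* **Filters** — keep a peptide only if an MS1 observation explains it:
  precursor-mass windows (ppm of the observed neutral mass), a
  calibrated additive retention-time model (cross-validated
  0.99-quantile error threshold), and pluggable HLA-I binding prediction
  (IC50 ≤ 5000 nM for 8–15-mers).  Decoy databases by protein reversal
  are filter-symmetric by construction.
* **Post-processing** — target-decoy q-values, combined
  canonical/expanded search merging, group-specific FDR, and peptide
  multimapping statistics across strata.

## Worked example

```bash
pepspace fixtures --seed 3 --out fx          # toy genome + MS tables
pepspace count --l-min 9 --l-max 12 --length 9 --imax 25
```

```
L   N  Lext  Imax  nonspliced  cis_forward  cis_reverse  cis_total
9   9  1     25    1           0            8            8
10  9  1     25    2           8            24           32
11  9  1     25    3           24           48           72
12  9  1     25    4           48           80           128
```

A 9-mer substrate yields a single non-spliced 9-mer but already 8
reverse cis-spliced 9-mers (the adjacent split-swaps); one extra residue
quadruples the spliced space — the cubic growth that makes exhaustive
PCPS databases explode.

```bash
pepspace build-strata --genome fx/genome.fasta --gtf fx/annotation.gtf \
    --expression fx/expression.tsv --out strata
```

```
cds_main      3     strata/cds_main.fasta
cds_offframe  12    strata/cds_offframe.fasta
utr5          7     strata/utr5.fasta
...
intergenic    1928  strata/intergenic.fasta
```

Three of the four coding transcripts survive the ≥ 10-counts-per-replicate
expression gate (the fourth has 9 counts in one replicate); random
intergenic sequence dominates the ORF count, exactly the inflation the
filters then prune.  `pepspace run --fixtures fx --out results` executes
the full chain and prints the per-stage unique-peptide statistics.

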