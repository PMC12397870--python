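# Methods

## Scope and model

`pepspace` treats the proteogenomic search space as a generative object:
a set of substrate polypeptides (stratified by genomic origin), a set of
generation rules (hydrolysis or splicing), and a set of data-driven
filters.  Every peptide record keeps its origin coordinates so that any
downstream statistic — uniqueness, multimapping, decoy symmetry — can be
recomputed exactly from the mapping tables.

## ORF strata

Annotation is parsed from GENCODE-dialect GTF (1-based inclusive,
converted to 0-based half-open at the parser boundary; all internal
interval arithmetic is half-open).  Introns are the gaps between
consecutive exons of a transcript; intergenic regions are the
chromosome complement of gene spans and are strandless (both strands are
scanned); lncRNA transcripts are flagged from the
`gene_type`/`transcript_type` attribute.

ORF discovery reports, per forward frame and per stop codon, the single
longest ORF (most upstream start among ATG, CTG, GTG, ATC, ACG) of at
least 8 amino acids, the length counted excluding the stop.  ORFs
reaching the sequence end without a stop are included and flagged
`has_stop=False`; inclusion is the permissive choice and the flag allows
filtering.  Codons containing IUPAC ambiguity letters translate to a
residue only when every expansion agrees on that residue (or all
expansions are stops, giving the `*` sentinel); otherwise they become X.
Peptides containing X are dropped at generation, since their mass is
undefined.  Selenocysteine and annotated readthrough are not modelled;
U maps to X.

CDS overlap is classified on per-base genomic position lists in reading
order: no shared base → `none`; all shared bases with equal codon phase
→ `in_frame`; anything else (including opposite reading order) →
`frameshift`.  The main ORF of a coding transcript is the six-frame
translation (frames 0–2 forward, 3–5 reverse-complement) minimising
Levenshtein distance to the annotated protein, ties to the lowest index.
Edit distance is computed with the `edlib` C library; a textbook DP
implementation serves as the test oracle.

Expression gating keeps a transcript iff it has ≥ 10 counts in *every*
biological replicate — the stricter reading of "per biological
replicate" — with an `any`-replicate mode available.  Gating restricts
transcript-derived strata only; intergenic regions have no transcript
and are unaffected.  Stratum databases drop exact (id, sequence)
duplicates (e.g. X/Y pseudo-autosomal double annotation) and products
shorter than 5 aa.

## Generation rules

*Tryptic*: cleavage after every K and R; the proline suppression rule is
off by default (configurable) since exhaustive search spaces enumerate
all backbone cleavages.  Missed cleavages are unlimited within the
length cap (default 5–30 aa) to match an exhaustive space; a maximum is
configurable.  Tryptic digestion always sees the whole protein — chunk
boundaries would masquerade as cleavage sites.

*Nonspecific*: every substring of each length in 8–15; exactly
L − N + 1 windows per length.

*Splicing*: a spliced peptide is substrate[i..j] + substrate[k..n] with
reactant lengths ≥ L<sub>ext</sub> (default 1) summing to N, reactant
intervals disjoint.  Forward cis requires intervening length
k − j − 1 ∈ [1, I<sub>max</sub>] — a gap of 0 would reproduce a
contiguous peptide; reverse cis requires i − n − 1 ∈ [0, I<sub>max</sub>]
(adjacent reverse-order ligation is a genuine rearrangement, and the
reverse closed form at L = N requires gap 0 to be legal).
I<sub>max</sub> defaults to 25 ("cis25"); ∞ removes the cap.  The tuple
index is computed once per (L, N, L<sub>ext</sub>, I<sub>max</sub>,
direction) and reused for shorter substrates by range filtering.  Trans
splicing (reactant 1 from protein A, reactant 2 from B) is generated
only for counting and testing; the pipeline treats it analytically.

Long substrates are split into chunks overlapping by
N<sub>max</sub> + I<sub>max</sub> residues, which guarantees every
window and every cis event (span ≤ N + I<sub>max</sub>) lies wholly in
some chunk; chunked generation followed by deduplication is proven equal
to whole-protein generation in the tests.  The stated overlap of twice
the maximum intervening length is available as a compatibility option
and coincides in effect when I<sub>max</sub> ≥ N<sub>max</sub>.

## Counting

The closed forms (README) are validated against a brute-force
enumeration of all (i, j, k, n) tuples on the grid L ∈ [2, 60],
N ∈ [2, 15], L<sub>ext</sub> ∈ {1, 2}, I<sub>max</sub> ∈ {0, 1, 2, 5,
25, ∞} with zero tolerance.  The I<sub>max</sub>-restricted formulas are
used iff the cap binds, i.e. I<sub>max</sub> < L − N (the maximum
achievable intervening length); at the boundary both branches coincide
algebraically.  The expected-unique bound
20^N (1 − (1 − 20^−N)^M) is evaluated symbolically with SymPy: the
binomial power is kept unevaluated (the exact rational would have ~10^16
digits for realistic M) and `evalf(50)` evaluates it at arbitrary
precision; tests check agreement with exact `Fraction` arithmetic at
small M and with a 300-digit evaluation at M = 10^16.  The alphabet size
(20) is a named constant.

## PTMs

Residue monoisotopic masses come from `pyteomics.mass`; water
(18.0105646863 Da) and the proton (1.00727646688 Da) are centralised
constants.  Fixed residue modifications fold into the residue mass;
fixed terminal modifications are added once.  Variable expansion assigns
0..2 modifications, at most one per site; the N-terminus is a site
distinct from residue position 1, so N-terminal acetylation can co-occur
with a side-chain modification there (terminus and side chain are
chemically distinct).  Two copies of the same PTM type on two sites are
allowed.  Counts are reported positionally and with positional isomers
collapsed (distinct (sequence, PTM multiset)).  The bundled preset is
the eight common modifications: N-term acetyl, carbamidomethyl-C,
deamidation-N/Q, oxidation-M, phospho-S/T/Y.  Variable-PTM forms are
filtered by MW only — RT prediction for arbitrary modifications is not
reliable — while fixed-PTM peptides pass both MW and RT filters.

## Filters

MW: keep iff some observation satisfies |m<sub>pep</sub> − m<sub>obs</sub>|
≤ ppm·10⁻⁶·m<sub>obs</sub> (window relative to the *observed* neutral
mass, symmetric; default 5 ppm).  Because both window endpoints are
monotone in the observed mass, the interval join reduces to two binary
searches and is tested equal to the all-pairs brute force.
Observations are deduplicated on (mass, RT) rounded to (10⁻⁵ Da,
10⁻³ min); duplicates carry no filtering information.

RT: an additive model (least squares on residue counts + intercept).
Cross-validation splits on unique sequences (5 seeded folds, logged);
the error threshold is the mean across folds of the 0.99 quantile of
held-out absolute residuals — on Gaussian noise σ this recovers
2.576 σ.  Residues absent from calibration are excluded from the trained
set and peptides carrying them fall back to MW-only with a flag.  The
joint filter requires a *single* observation to satisfy both the mass
and the RT window (configurable to independent conditions).  A deep
predictor can be plugged through the same callable interface.

HLA: peptides of 8–15 aa are kept iff the minimum predicted IC50 over
alleles is ≤ 5000 nM; other lengths pass through flagged as
not evaluated.  The bundled predictor is a synthetic position-weight
scorer for anchors P2 and C-terminus mapped monotonically onto an
IC50-like scale — for tests and examples only; external predictors plug
in as callables or exchange tables.

Decoys are reversed proteins with suffixed ids; reversal preserves
composition, so per-protein nonspecific event counts and mass multisets
are identical to targets before deduplication.

## FDR post-processing

FDR̂(s) = #decoys(score ≥ s) / max(1, #targets(score ≥ s)) without the
+1 correction (available by flag); q-values are the running minimum of
FDR̂ from the most permissive threshold upward.  The combined strategy
keeps, per spectrum, the record with the smaller q between the canonical
and expanded searches, ties to canonical (preferential selection of
canonical peptides).  Group-specific FDR applies the estimator
independently per stratum.  Merging happens at PSM level with a
peptide-level rollup reported separately.

## Synthetic data

The fixture generator emulates all pipeline inputs at desk scale: a
two-chromosome genome (50 kb total) with four two-/single-exon coding
genes (designed UTR–CDS–intron structure on both strands), one lncRNA
and random intergenic background; an expression table (two replicates,
one transcript deliberately at 9 counts in one replicate so the
expression gate has work to do); MS1 observations built by jittering
true peptide masses within ±2 ppm plus 200 uniform mass decoys; RT
calibration peptides from a known additive model (the achrom
retention-coefficient set shipped with pyteomics, σ = 0.5 min Gaussian
noise, n = 2000); and simulated PSM scores with known true/false labels
(true targets N(3, 1), false targets and decoys N(0, 1)).  Everything is
deterministic per seed.

What the toy data does *not* emulate: realistic codon usage, sequence
homology and isoform structure (so multimapping rates on the toy genome
are near zero, unlike real proteomes), correlated RT/mass errors,
retention behaviour of modified peptides, and engine-specific score
distributions.  Passing tests therefore demonstrate correctness of the
machinery — exact counts, filter semantics, calibration recovery — not
the paper-scale magnitudes of real search spaces, which require a full
genome annotation and real MS runs.

## Numerical and design choices

* Coordinates 0-based half-open internally; 1-based inclusive at GTF and
  peptide-record boundaries (field convention).
* Problem sizes in tests/acceptance: counting grid to L = 60 (~10⁴
  parameter combinations), 1000 random sequences for the ORF-scanner
  oracle, 10⁴ × 10³ for the filter oracle, 20 × 2000 for RT calibration,
  100 replicates for FDR calibration — sizes at which the brute-force
  oracles are exact and fast.
* The pipeline is organised as independent work units
  (stratum × rule × chunk) whose outputs merge in any order; storage is
  hive-partitioned parquet keyed by rule, stratum, length and sequence
  prefix (1 leading residue for tryptic, 2 otherwise), with a delimited
  fallback.
* Known limitations: no protein-similarity clustering before chunking
  (an optimisation, not a correctness requirement); trans-spliced
  peptides are counted, not enumerated, in the pipeline; PCPS events are
  enumerated exhaustively without biological preference scoring; raw
  mass-spectrometer files are out of scope (observations arrive as
  tables).
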