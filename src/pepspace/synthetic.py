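"""Synthetic toy data: genome + annotation, MS1 observations, calibration PSMs.

The generator emulates every input the pipeline consumes, at desk scale:
a two-chromosome genome with multi-exon coding genes, UTRs, introns, a
lncRNA and intergenic gaps; an expression table with per-replicate
counts; MS1 precursor observations sampled from true peptide masses
(plus mass decoys); RT calibration peptides drawn from a known additive
model with Gaussian noise; and simulated PSM score tables.  Everything
is deterministic given a seed.

True RT coefficients are the achrom retention-coefficient set shipped
with pyteomics, so synthetic retention behaves like reversed-phase
chromatography and the additive model is exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics.achrom import RCs_guo_ph7_0

from .genome_strata import reverse_complement, translate
from .ptm import PROTON_MASS, peptide_mass

NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
)
STOP_CODONS = ("TAA", "TAG", "TGA")
AA20 = "ACDEFGHIKLMNPQRSTVWY"

TRUE_RT_COEFFICIENTS = {aa: RCs_guo_ph7_0["aa"][aa] for aa in AA20}
TRUE_RT_INTERCEPT = 5.0


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + stop."""
    body = "".join(rng.choice(NON_STOP_CODONS, size=n_codons - 2))
    return "ATG" + body + str(rng.choice(STOP_CODONS))


@dataclass
class ToyGenome:
    genome: dict[str, str]
    gtf: str
    expression: pd.DataFrame
    reference_proteins: dict[str, str] = field(default_factory=dict)


def _gtf_line(chrom, ftype, start0, end0, strand, gene, tx, biotype) -> str:
    attrs = f'gene_id "{gene}"; gene_type "{biotype}";'
    if tx:
        attrs += f' transcript_id "{tx}"; transcript_type "{biotype}";'
    return "\t".join(
        [chrom, "toy", ftype, str(start0 + 1), str(end0), ".", strand, ".", attrs]
    )


def make_genome(
    seed: int = 0,
    chrom_lengths: Sequence[int] = (30000, 20000),
    expression_replicates: int = 2,
) -> ToyGenome:
    """Two-chromosome toy genome with coding, lncRNA and intergenic content.

    chr1 carries two plus-strand two-exon coding genes (UTR5-CDS-intron-
    CDS-UTR3) and a lncRNA; chr2 carries a minus-strand single-exon
    coding gene and a plus-strand coding gene.  One transcript is left
    under-expressed in one replicate so expression gating has something
    to remove.
    """
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i+1}": list(random_dna(rng, L)) for i, L in enumerate(chrom_lengths)}
    gtf_lines: list[str] = []
    reference: dict[str, str] = {}

    def implant(chrom: str, offset: int, pieces: str) -> None:
        chroms[chrom][offset : offset + len(pieces)] = list(pieces)

    def coding_gene(chrom, gene, tx, offset, utr5, n_codons, intron, utr3, split):
        """Plus-strand two-exon coding gene; ``split`` cuts the CDS."""
        cds = random_cds(rng, n_codons)
        seq_parts = [
            random_dna(rng, utr5) + cds[:split],
            random_dna(rng, intron),
            cds[split:] + random_dna(rng, utr3),
        ]
        implant(chrom, offset, "".join(seq_parts))
        e1s, e1e = offset, offset + len(seq_parts[0])
        e2s = e1e + intron
        e2e = e2s + len(seq_parts[2])
        gtf_lines.append(_gtf_line(chrom, "gene", e1s, e2e, "+", gene, "", "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "transcript", e1s, e2e, "+", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "exon", e1s, e1e, "+", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "exon", e2s, e2e, "+", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "UTR", e1s, e1s + utr5, "+", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "CDS", e1s + utr5, e1e, "+", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "CDS", e2s, e2s + (len(cds) - split), "+", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "UTR", e2s + (len(cds) - split), e2e, "+", gene, tx, "protein_coding"))
        reference[tx] = translate(cds).rstrip("*")

    def minus_gene(chrom, gene, tx, offset, utr5, n_codons, utr3):
        """Minus-strand single-exon coding gene."""
        cds = random_cds(rng, n_codons)
        sense = random_dna(rng, utr5) + cds + random_dna(rng, utr3)
        implant(chrom, offset, reverse_complement(sense))
        start, end = offset, offset + len(sense)
        cds_s = start + utr3  # genomic coords flip the sense layout
        cds_e = cds_s + len(cds)
        gtf_lines.append(_gtf_line(chrom, "gene", start, end, "-", gene, "", "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "transcript", start, end, "-", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "exon", start, end, "-", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "UTR", start, cds_s, "-", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "CDS", cds_s, cds_e, "-", gene, tx, "protein_coding"))
        gtf_lines.append(_gtf_line(chrom, "UTR", cds_e, end, "-", gene, tx, "protein_coding"))
        reference[tx] = translate(cds).rstrip("*")

    def lnc_gene(chrom, gene, tx, offset, length):
        start, end = offset, offset + length
        gtf_lines.append(_gtf_line(chrom, "gene", start, end, "+", gene, "", "lncRNA"))
        gtf_lines.append(_gtf_line(chrom, "transcript", start, end, "+", gene, tx, "lncRNA"))
        gtf_lines.append(_gtf_line(chrom, "exon", start, end, "+", gene, tx, "lncRNA"))

    coding_gene("chr1", "G1", "T1", 2000, 90, 120, 300, 120, 101)
    coding_gene("chr1", "G2", "T2", 9000, 60, 90, 240, 90, 80)
    lnc_gene("chr1", "G3", "T3", 16000, 900)
    minus_gene("chr2", "G4", "T4", 3000, 75, 100, 90)
    coding_gene("chr2", "G5", "T5", 9000, 60, 80, 210, 75, 64)

    counts = {
        "T1": [40, 55], "T2": [25, 18], "T3": [30, 22],
        "T4": [12, 9],  # fails the every-replicate threshold of 10
        "T5": [70, 64],
    }
    expression = pd.DataFrame(
        {
            "transcript_id": list(counts),
            **{
                f"rep{r+1}": [counts[t][r] for t in counts]
                for r in range(expression_replicates)
            },
        }
    )
    return ToyGenome(
        genome={c: "".join(s) for c, s in chroms.items()},
        gtf="\n".join(gtf_lines) + "\n",
        expression=expression,
        reference_proteins=reference,
    )


def true_rt(sequence: str) -> float:
    """Retention time under the known additive ground-truth model (minutes)."""
    return TRUE_RT_INTERCEPT + sum(TRUE_RT_COEFFICIENTS[aa] for aa in sequence)


def make_calibration(
    seed: int = 0,
    n: int = 2000,
    sigma: float = 0.5,
    length_range: tuple[int, int] = (8, 15),
) -> pd.DataFrame:
    """Calibration PSMs: random peptides with additive RT + N(0, sigma) noise."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    seqs = [random_protein(rng, int(L)) for L in lengths]
    rts = np.array([true_rt(s) for s in seqs]) + rng.normal(0, sigma, n)
    return pd.DataFrame({"sequence": seqs, "rt_minutes": rts})


def make_observations(
    planted_peptides: Sequence[str],
    seed: int = 0,
    n_decoy_masses: int = 200,
    ppm_jitter: float = 2.0,
    rt_jitter: float = 0.3,
    source_run: str = "run1",
) -> pd.DataFrame:
    """MS1 observation table explaining the planted peptides.

    Each planted peptide yields one precursor whose neutral mass is
    jittered within +/- ppm_jitter and whose RT sits near the additive
    ground truth; decoy masses are drawn uniformly over the peptide mass
    range and paired with random RTs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    masses = [peptide_mass(p) for p in planted_peptides]
    for pep, mass in zip(planted_peptides, masses):
        jittered = mass * (1 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)
        charge = int(rng.integers(2, 4))
        rows.append(
            {
                "mz": (jittered + charge * PROTON_MASS) / charge,
                "charge": charge,
                "rt_minutes": true_rt(pep) + rng.uniform(-rt_jitter, rt_jitter),
                "source_run": source_run,
            }
        )
    lo, hi = (min(masses), max(masses)) if masses else (800.0, 1600.0)
    for _ in range(n_decoy_masses):
        mass = rng.uniform(lo * 0.9, hi * 1.1)
        charge = int(rng.integers(2, 4))
        rows.append(
            {
                "mz": (mass + charge * PROTON_MASS) / charge,
                "charge": charge,
                "rt_minutes": rng.uniform(0, 60),
                "source_run": source_run,
            }
        )
    return pd.DataFrame(rows)


def generate_fixtures(
    seed: int, outdir: Optional[Path] = None, n_calibration: int = 2000
) -> dict:
    """Produce all toy inputs; optionally write them as plain-text files.

    Returns a dict with the in-memory objects (genome, gtf, expression,
    calibration, observations, psms) and, when ``outdir`` is given,
    writes genome.fasta, annotation.gtf, expression.tsv, calibration.tsv,
    observations.tsv and psms.tsv.
    """
    from .identification import simulate_psm_scores

    toy = make_genome(seed)
    calibration = make_calibration(seed + 1, n=n_calibration)
    # plant peptides from the reference proteins themselves
    rng = np.random.default_rng(seed + 2)
    planted = []
    for protein in toy.reference_proteins.values():
        for _ in range(8):
            length = int(rng.integers(8, 13))
            start = int(rng.integers(0, len(protein) - length + 1))
            planted.append(protein[start : start + length])
    observations = make_observations(planted, seed=seed + 3)
    psms = simulate_psm_scores(300, 300, np.random.default_rng(seed + 4))
    out = {
        "genome": toy.genome,
        "gtf": toy.gtf,
        "expression": toy.expression,
        "reference_proteins": toy.reference_proteins,
        "calibration": calibration,
        "observations": observations,
        "planted_peptides": planted,
        "psms": psms,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fasta", "w") as fh:
            for chrom, seq in toy.genome.items():
                fh.write(f">{chrom}\n")
                for pos in range(0, len(seq), 80):
                    fh.write(seq[pos : pos + 80] + "\n")
        (outdir / "annotation.gtf").write_text(toy.gtf)
        toy.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        calibration.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
        observations.to_csv(outdir / "observations.tsv", sep="\t", index=False)
        psms.to_csv(outdir / "psms.tsv", sep="\t", index=False)
    return out
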