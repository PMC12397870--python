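"""Pipeline orchestration: strata -> peptides -> filters -> statistics.

Work units are independent (stratum x rule x chunk); their outputs are
mergeable in any order and the whole run is deterministic given the
configuration seed.  Mapping tables are stored as hive-partitioned
parquet datasets keyed by rule, stratum, peptide length and sequence
prefix (one leading residue for tryptic peptides, two for nonspecific
and spliced ones); a delimited fallback writer is available.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import digestion, filters, genome_strata, ptm, splicing

logger = logging.getLogger(__name__)

FILTER_STAGES = ("unfiltered", "mw", "mw_rt", "mw_rt_hla")


@dataclass
class PipelineConfig:
    """All thresholds in one place, with the standard defaults:
    5 ppm MS1 error, 0.99 RT-error quantile, 5000 nM IC50, expression
    >= 10 counts per replicate."""

    tryptic_length_range: tuple[int, int] = (5, 30)
    nonspecific_length_range: tuple[int, int] = (8, 15)
    splice_length: int = 9
    Lext: int = 1
    Imax: int = 25
    rules: tuple[str, ...] = ("tryptic", "nonspecific", "cis_spliced")
    splice_strata: tuple[str, ...] = ("cds_main",)
    chunk_max_len: int = 2000
    ppm: float = 5.0
    rt_quantile: float = 0.99
    rt_folds: int = 5
    ic50_threshold: float = 5000.0
    hla_alleles: tuple[str, ...] = ()
    hla_length_range: tuple[int, int] = (8, 15)
    expression_threshold: float = 10.0
    max_missed: Optional[int] = None
    seed: int = 0

    @property
    def chunk_overlap(self) -> int:
        # no spliced or nonspecific peptide is lost across a chunk boundary
        return self.nonspecific_length_range[1] + self.Imax


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def generate_peptides(
    proteins: dict[str, str], rule: str, config: PipelineConfig
) -> list[digestion.PeptideRecord]:
    """One generation work unit per protein chunk; duplicates from chunk
    overlaps are removed downstream by :func:`digestion.dedup_peptides`."""
    records: list[digestion.PeptideRecord] = []
    for pid, protein in proteins.items():
        if rule == "tryptic":
            # chunk boundaries would masquerade as cleavage sites, so
            # tryptic digestion always sees the whole protein
            records.extend(
                digestion.tryptic_digest(
                    protein,
                    origin_id=pid,
                    length_range=config.tryptic_length_range,
                    max_missed=config.max_missed,
                )
            )
            continue
        chunks = digestion.chunk_protein(
            protein, config.chunk_max_len, config.chunk_overlap, origin_id=pid
        )
        for chunk in chunks:
            if rule == "nonspecific":
                chunk_records = digestion.nonspecific_windows(
                    chunk.sequence,
                    origin_id=pid,
                    length_range=config.nonspecific_length_range,
                )
            elif rule == "cis_spliced":
                chunk_records = [
                    r
                    for r in splicing.generate_cis_both(
                        chunk.sequence,
                        config.splice_length,
                        config.Lext,
                        config.Imax,
                        origin_id=pid,
                    )
                    if digestion.AMBIGUOUS_RESIDUE not in r.sequence
                ]
            else:
                raise ValueError(f"unknown rule {rule!r}")
            if chunk.offset:
                chunk_records = [
                    digestion.PeptideRecord(
                        r.sequence, pid, r.start + chunk.offset,
                        r.end + chunk.offset, r.rule,
                        tuple(c + chunk.offset for c in r.sr_coords)
                        if r.sr_coords else None,
                        r.intervening,
                    )
                    for r in chunk_records
                ]
            records.extend(chunk_records)
    return records


def write_mapping_parquet(table: pd.DataFrame, path) -> None:
    """Hive-partitioned parquet: rule / stratum / length / prefix keys."""
    table = table.copy()
    table["length"] = table["sequence"].str.len()
    width = np.where(table["rule"] == "tryptic", 1, 2)
    table["prefix"] = [s[:w] for s, w in zip(table["sequence"], width)]
    table.to_parquet(
        path, partition_cols=["rule", "stratum", "length", "prefix"],
        index=False, max_partitions=20000,
    )


def write_mapping_delimited(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def run_pipeline(
    genome: dict[str, str],
    gtf: str,
    observations: pd.DataFrame,
    calibration: pd.DataFrame,
    expression: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[Path] = None,
    hla_predictor=None,
) -> dict:
    """Full toy-scale run: strata, generation, filtering, statistics.

    Returns a dict with the strata, per-(stratum, rule) mapping tables
    annotated with per-stage keep flags, the fitted RT model and the
    stage-wise unique-count statistics table.  When ``outdir`` is given,
    partitioned parquet mapping tables, per-stratum FASTA databases and
    the stats table are written there.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    features = genome_strata.parse_annotation(gtf, chrom_lengths)
    strata = genome_strata.build_strata(
        features, genome, expression,
        expression_threshold=config.expression_threshold,
    )
    logger.info("strata built in %.1fs: %s", time.time() - t0,
                {s: len(v) for s, v in strata.items()})

    rt_model = filters.fit_rt_model(
        calibration, folds=config.rt_folds, quantile=config.rt_quantile,
        seed=config.seed,
    )

    obs = observations.copy()
    if "neutral_mass" not in obs.columns:
        obs["neutral_mass"] = [
            filters.neutral_mass(mz, z) for mz, z in zip(obs["mz"], obs["charge"])
        ]
    if "rt" not in obs.columns:
        obs["rt"] = obs["rt_minutes"]

    if hla_predictor is None and config.hla_alleles:
        hla_predictor = filters.ToyHLAPredictor(config.hla_alleles)

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    stats_rows = []
    for stratum, orfs in strata.items():
        proteins = {orf.orf_id: orf.aa_seq for orf in orfs}
        if not proteins:
            continue
        for rule in config.rules:
            if rule == "cis_spliced" and stratum not in config.splice_strata:
                continue
            records = generate_peptides(proteins, rule, config)
            unique_seqs, table = digestion.dedup_peptides(records)
            if table.empty:
                continue
            table.insert(1, "stratum", stratum)
            seqs = table["sequence"].tolist()
            masses = ptm.peptide_masses(seqs)
            table["mass"] = masses
            table["keep_mw"] = filters.mw_filter(
                masses, obs["neutral_mass"].to_numpy(), config.ppm
            )
            keep_mwrt, rt_eval = filters.mw_rt_filter(
                seqs, masses, obs, rt_model, config.ppm
            )
            table["keep_mw_rt"] = keep_mwrt & table["keep_mw"]
            table["rt_evaluated"] = rt_eval
            if hla_predictor is not None:
                keep_hla, hla_eval = filters.hla_filter(
                    seqs, hla_predictor, list(config.hla_alleles),
                    config.ic50_threshold, config.hla_length_range,
                )
                table["keep_mw_rt_hla"] = table["keep_mw_rt"] & keep_hla
                table["hla_evaluated"] = hla_eval
            else:
                table["keep_mw_rt_hla"] = table["keep_mw_rt"]
                table["hla_evaluated"] = False
            tables[(stratum, rule)] = table
            for stage, mask in (
                ("unfiltered", np.ones(len(table), dtype=bool)),
                ("mw", table["keep_mw"]),
                ("mw_rt", table["keep_mw_rt"]),
                ("mw_rt_hla", table["keep_mw_rt_hla"]),
            ):
                kept = table.loc[np.asarray(mask), "sequence"]
                for length, n_unique in kept.groupby(kept.str.len()).nunique().items():
                    stats_rows.append(
                        {
                            "stratum": stratum, "rule": rule, "length": int(length),
                            "stage": stage, "unique_peptides": int(n_unique),
                        }
                    )
            logger.info(
                "%s/%s: %d events, %d unique, %d mw, %d mw_rt, %d mw_rt_hla",
                stratum, rule, len(records), len(unique_seqs),
                int(table["keep_mw"].sum()), int(table["keep_mw_rt"].sum()),
                int(table["keep_mw_rt_hla"].sum()),
            )

    stats = pd.DataFrame(
        stats_rows,
        columns=["stratum", "rule", "length", "stage", "unique_peptides"],
    ).sort_values(["stratum", "rule", "length", "stage"], ignore_index=True)

    results = {
        "strata": strata,
        "tables": tables,
        "rt_model": rt_model,
        "stats": stats,
        "config": config,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome_strata.write_strata_fasta(strata, outdir / "strata")
        store = outdir / "mapping"
        for (stratum, rule), table in tables.items():
            write_mapping_parquet(table, store)
        stats.to_csv(outdir / "strata_statistics.tsv", sep="\t", index=False)
        unique_kept = sorted(
            {
                seq
                for table in tables.values()
                for seq in table.loc[table["keep_mw_rt_hla"], "sequence"]
            }
        )
        with open(outdir / "unique_peptides.fasta", "w") as fh:
            for idx, seq in enumerate(unique_kept):
                fh.write(f">peptide_{idx}\n{seq}\n")
    return results


def strata_statistics(
    tables: dict[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    """Exact distinct-sequence counts per (stratum, rule, stage)."""
    rows = []
    for (stratum, rule), table in tables.items():
        for stage in FILTER_STAGES:
            col = {"unfiltered": None, "mw": "keep_mw", "mw_rt": "keep_mw_rt",
                   "mw_rt_hla": "keep_mw_rt_hla"}[stage]
            sub = table if col is None else table[table[col]]
            rows.append(
                {
                    "stratum": stratum, "rule": rule, "stage": stage,
                    "unique_peptides": sub["sequence"].nunique(),
                }
            )
    return pd.DataFrame(rows)


def load_mapping_store(path) -> pd.DataFrame:
    """Read back a hive-partitioned mapping dataset."""
    return pd.read_parquet(path)
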