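"""Peptide multimapping analytics within and across origin strata.

A mapping table records every (peptide, origin) relation produced by
generation.  These utilities quantify how ambiguous a peptide's origin
is: the distribution of distinct origins per peptide, pairwise sharing
between strata, and the fraction of ORFs identifiable through at least
one stratum-unique peptide.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

MAPPING_COLUMNS = ("sequence", "stratum", "origin_orf", "origin_gene", "rule")


def count_origins(table: pd.DataFrame, level: str = "orf") -> pd.Series:
    """Histogram: number of peptides per number of distinct origins.

    ``level`` chooses the origin granularity (``orf`` or ``gene``).  The
    histogram total equals the number of unique peptide sequences.
    """
    col = {"orf": "origin_orf", "gene": "origin_gene"}[level]
    origins_per_peptide = table.groupby("sequence")[col].nunique()
    hist = origins_per_peptide.value_counts().sort_index()
    hist.name = "n_peptides"
    hist.index.name = "n_origins"
    return hist


def strata_overlap(strata_sets: Mapping[str, set]) -> pd.DataFrame:
    """Pairwise shared peptide counts and fractions between strata.

    For each ordered pair (A, B): |A ∩ B| and |A ∩ B| / |A| — the
    fraction is relative to the first stratum, so the matrix is not
    symmetric although the counts are.
    """
    if len(strata_sets) < 2:
        raise ValueError("need at least 2 strata")
    rows = []
    for name_a, set_a in strata_sets.items():
        for name_b, set_b in strata_sets.items():
            shared = len(set_a & set_b)
            rows.append(
                {
                    "stratum_a": name_a,
                    "stratum_b": name_b,
                    "size_a": len(set_a),
                    "shared": shared,
                    "fraction_of_a": shared / len(set_a) if set_a else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def unique_peptide_orf_fraction(
    stratum: str, tables: Mapping[str, pd.DataFrame], rule: str = "tryptic"
) -> float:
    """Fraction of a stratum's ORFs having >= 1 peptide unique to that ORF.

    A peptide is ORF-unique when it maps to no other ORF in any stratum
    (under the given generation rule).  Returns NaN for an empty stratum.
    """
    frames = [
        t[t["rule"] == rule] if "rule" in t.columns else t for t in tables.values()
    ]
    universe = pd.concat(frames, ignore_index=True)
    if stratum not in tables or tables[stratum].empty:
        return float("nan")
    own = frames[list(tables).index(stratum)]
    if own.empty:
        return float("nan")
    orfs_per_peptide = universe.groupby("sequence")["origin_orf"].nunique()
    unique_seqs = set(orfs_per_peptide.index[orfs_per_peptide == 1])
    orfs = own["origin_orf"].unique()
    identifiable = own[own["sequence"].isin(unique_seqs)]["origin_orf"].nunique()
    return identifiable / len(orfs)


def canonical_priority_sets(
    strata_sets: Mapping[str, set], canonical: str = "cds_main"
) -> dict[str, set]:
    """Reporting view: peptides present in the canonical stratum are
    attributed to it and removed from the noncanonical sets (the raw
    tables stay unprioritized)."""
    canon = strata_sets.get(canonical, set())
    return {
        name: (peptides if name == canonical else peptides - canon)
        for name, peptides in strata_sets.items()
    }


def average_over_runs(per_run_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean of numeric summary columns across MS runs (replicates are a
    first-class grouping key; figures use the per-run average)."""
    merged = pd.concat(per_run_tables, ignore_index=True)
    keys = [c for c in merged.columns if merged[c].dtype == object]
    return merged.groupby(keys, as_index=False).mean(numeric_only=True)
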