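"""Target-decoy FDR utilities and identification strategies.

Post-processing of search-engine PSM tables: q-value assignment by
target-decoy competition, the combined strategy (per spectrum, keep the
lower-q assignment between a canonical-database and an expanded-database
search, ties to canonical), group-specific FDR (independent estimation
per stratum), and identification reports over an FDR grid.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSM_COLUMNS = (
    "spectrum_id", "sequence", "score", "is_decoy", "database_label", "group",
)


def tdc_qvalues(psms: pd.DataFrame, plus_one: bool = False) -> pd.DataFrame:
    """Assign q-values by target-decoy competition.

    FDR̂ at score threshold s is #decoys(score >= s) / max(1,
    #targets(score >= s)) (``plus_one`` adds the usual +1 to the decoy
    count); the q-value is the running minimum of FDR̂ from the most
    permissive threshold upward, hence monotone non-increasing in score.
    With no decoys present all q are 0 (warned).
    """
    out = psms.copy()
    if not out["is_decoy"].any():
        logger.warning("no decoys present; all q-values set to 0")
        out["q_value"] = 0.0
        return out
    order = np.argsort(-out["score"].to_numpy(), kind="stable")
    decoy = out["is_decoy"].to_numpy()[order]
    n_decoys = np.cumsum(decoy) + (1 if plus_one else 0)
    n_targets = np.maximum(1, np.cumsum(~decoy))
    fdr = n_decoys / n_targets
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    qvals = np.empty(len(out))
    qvals[order] = np.clip(q, 0.0, 1.0)
    out["q_value"] = qvals
    return out


def combined_strategy(
    psms_canonical: pd.DataFrame, psms_expanded: pd.DataFrame
) -> pd.DataFrame:
    """Merge two q-valued searches: per spectrum keep the smaller-q record.

    Ties break toward the canonical database (preferential selection of
    canonical peptides); spectra present in only one table pass through.
    """
    for name, table in (("canonical", psms_canonical), ("expanded", psms_expanded)):
        if "q_value" not in table.columns:
            raise ValueError(f"{name} PSM table lacks q_value")
    canonical = psms_canonical.assign(_prio=0)
    expanded = psms_expanded.assign(_prio=1)
    merged = pd.concat([canonical, expanded], ignore_index=True)
    merged = merged.sort_values(
        ["spectrum_id", "q_value", "_prio"], kind="stable"
    ).drop_duplicates("spectrum_id", keep="first")
    return merged.drop(columns="_prio").reset_index(drop=True)


def group_specific_fdr(
    psms: pd.DataFrame, group_column: str = "group", plus_one: bool = False
) -> pd.DataFrame:
    """q-values estimated independently within each group (stratum)."""
    pieces = []
    for name, sub in psms.groupby(group_column, sort=False):
        if not sub["is_decoy"].any():
            logger.warning("group %s has no decoys; its q-values are 0", name)
        pieces.append(tdc_qvalues(sub, plus_one=plus_one))
    return pd.concat(pieces, ignore_index=True)


def identification_report(
    merged: pd.DataFrame,
    fdr_grid: Sequence[float] = (0.001, 0.005, 0.01, 0.02, 0.05),
    noncanonical_label: str = "expanded",
) -> pd.DataFrame:
    """Peptide/PSM counts and noncanonical fraction at each FDR threshold.

    Decoys are excluded from the report; a PSM counts as noncanonical when
    its database label equals ``noncanonical_label``.
    """
    targets = merged[~merged["is_decoy"]]
    rows = []
    for alpha in fdr_grid:
        accepted = targets[targets["q_value"] <= alpha]
        n_psms = len(accepted)
        rows.append(
            {
                "fdr_threshold": alpha,
                "n_psms": n_psms,
                "n_peptides": accepted["sequence"].nunique(),
                "fraction_noncanonical": (
                    (accepted["database_label"] == noncanonical_label).mean()
                    if n_psms
                    else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def peptide_rollup(psms: pd.DataFrame) -> pd.DataFrame:
    """Peptide-level view: best (lowest q, then highest score) PSM per sequence."""
    return (
        psms.sort_values(["q_value", "score"], ascending=[True, False], kind="stable")
        .drop_duplicates("sequence", keep="first")
        .reset_index(drop=True)
    )


def simulate_psm_scores(
    n_true: int,
    n_false: int,
    rng: np.random.Generator,
    true_loc: float = 3.0,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Synthetic PSM benchmark with known ground truth.

    False targets and decoys are drawn i.i.d. from N(0, scale) (the
    target-decoy assumption), true targets from N(true_loc, scale); the
    ``is_true`` column enables empirical-FDR evaluation of the estimator.
    """
    scores = np.concatenate(
        [
            rng.normal(true_loc, scale, n_true),
            rng.normal(0.0, scale, n_false),
            rng.normal(0.0, scale, n_true + n_false),
        ]
    )
    is_decoy = np.concatenate(
        [
            np.zeros(n_true + n_false, dtype=bool),
            np.ones(n_true + n_false, dtype=bool),
        ]
    )
    is_true = np.concatenate(
        [
            np.ones(n_true, dtype=bool),
            np.zeros(n_false + n_true + n_false, dtype=bool),
        ]
    )
    return pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(len(scores))],
            "sequence": [f"PEP{i}" for i in range(len(scores))],
            "score": scores,
            "is_decoy": is_decoy,
            "is_true": is_true,
            "database_label": "expanded",
            "group": "sim",
        }
    )
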