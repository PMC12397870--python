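"""In-silico digestion: tryptic and nonspecific peptide generation.

Peptides carry their origin coordinates so that downstream multimapping
analysis and decoy symmetry checks can always recover where a sequence
came from.  Long substrates are split into overlapping chunks so that
generation jobs stay bounded in memory; with an overlap of at least
N_max + Imax no peptide (spliced or not) is lost across a chunk boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

AMBIGUOUS_RESIDUE = "X"


@dataclass(frozen=True)
class PeptideRecord:
    """A generated peptide with its origin.

    ``start``/``end`` are 1-based inclusive residue positions in the
    origin; for spliced records they bound the full span and
    ``sr_coords`` holds the (i, j, k, n) splice-reactant positions.
    """

    sequence: str
    origin_id: str
    start: int
    end: int
    rule: str  # tryptic | nonspecific | cis_spliced | trans_spliced
    sr_coords: Optional[tuple] = None
    intervening: Optional[int] = None


@dataclass(frozen=True)
class ProteinChunk:
    chunk_id: str
    origin_id: str
    offset: int  # 0-based residue offset of the chunk within the origin
    sequence: str


def _keep(seq: str, length_range: tuple[int, int], drop_ambiguous: bool) -> bool:
    lo, hi = length_range
    if not lo <= len(seq) <= hi:
        return False
    if drop_ambiguous and AMBIGUOUS_RESIDUE in seq:
        return False
    return True


def tryptic_digest(
    protein: str,
    origin_id: str = "protein",
    length_range: tuple[int, int] = (5, 30),
    max_missed: Optional[int] = None,
    proline_rule: bool = False,
    drop_ambiguous: bool = True,
) -> list[PeptideRecord]:
    """Fully tryptic peptides (cleavage after K/R).

    ``max_missed=None`` allows any number of internal K/R within the
    length cap — the exhaustive-search-space default.  ``proline_rule``
    suppresses cleavage before P when set; off by default.
    """
    if not protein:
        raise ValueError("empty protein")
    # cut positions: residue index after which the backbone is cleaved
    cuts = [0]
    for idx, res in enumerate(protein[:-1]):
        if res in "KR" and not (proline_rule and protein[idx + 1] == "P"):
            cuts.append(idx + 1)
    cuts.append(len(protein))
    records = []
    for a_pos, a in enumerate(cuts[:-1]):
        for b in cuts[a_pos + 1 :]:
            seq = protein[a:b]
            if len(seq) > length_range[1]:
                break
            missed = sum(1 for r in seq[:-1] if r in "KR")
            if max_missed is not None and missed > max_missed:
                break
            if _keep(seq, length_range, drop_ambiguous):
                records.append(
                    PeptideRecord(seq, origin_id, a + 1, b, "tryptic")
                )
    return records


def nonspecific_windows(
    protein: str,
    origin_id: str = "protein",
    length_range: tuple[int, int] = (8, 15),
    drop_ambiguous: bool = True,
) -> list[PeptideRecord]:
    """Every substring of each length in range: L - N + 1 windows per length."""
    L = len(protein)
    records = []
    for N in range(length_range[0], length_range[1] + 1):
        for start in range(L - N + 1):
            seq = protein[start : start + N]
            if not drop_ambiguous or AMBIGUOUS_RESIDUE not in seq:
                records.append(
                    PeptideRecord(seq, origin_id, start + 1, start + N, "nonspecific")
                )
    return records


def chunk_protein(
    protein: str, max_len: int, overlap: int, origin_id: str = "protein"
) -> list[ProteinChunk]:
    """Split a protein into chunks of <= max_len sharing ``overlap`` residues.

    Consecutive chunks advance by max_len - overlap, so every substring of
    length <= overlap is wholly contained in at least one chunk.
    """
    if overlap >= max_len:
        raise ValueError("overlap must be smaller than max_len")
    L = len(protein)
    if L <= max_len:
        return [ProteinChunk(f"{origin_id}.0", origin_id, 0, protein)]
    step = max_len - overlap
    chunks = []
    offset = 0
    while True:
        seq = protein[offset : offset + max_len]
        chunks.append(ProteinChunk(f"{origin_id}.{offset}", origin_id, offset, seq))
        if offset + max_len >= L:
            break
        offset += step
    return chunks


def dedup_peptides(
    records: Iterable[PeptideRecord],
) -> tuple[set[str], pd.DataFrame]:
    """Unique sequence set plus the full peptide-to-origin mapping table.

    Every (sequence, origin, coordinates) tuple is preserved in the
    mapping; identical duplicate rows (e.g. the same event reached via
    two overlapping chunks) collapse to one.
    """
    rows = [
        {
            "sequence": r.sequence,
            "origin_id": r.origin_id,
            "start": r.start,
            "end": r.end,
            "rule": r.rule,
            "sr_coords": str(r.sr_coords) if r.sr_coords else "",
            "intervening": -1 if r.intervening is None else r.intervening,
        }
        for r in records
    ]
    if not rows:
        return set(), pd.DataFrame(
            columns=[
                "sequence", "origin_id", "start", "end", "rule",
                "sr_coords", "intervening",
            ]
        )
    table = pd.DataFrame(rows).drop_duplicates(ignore_index=True)
    return set(table["sequence"]), table


def partition_key(record: PeptideRecord) -> tuple[str, int, str]:
    """Storage partition key: rule, length and sequence prefix.

    One leading residue for tryptic peptides, two for nonspecific and
    spliced ones (finer fan-out where the space is larger).
    """
    width = 1 if record.rule == "tryptic" else 2
    return record.rule, len(record.sequence), record.sequence[:width]
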