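"""Generation of proteasome-spliced peptides via splice-reactant indices.

A spliced peptide is the ligation of two contiguous substrate fragments
(splice reactants).  Generation is expressed as two substring operations
driven by a precomputed index of coordinate 4-tuples (i, j, k, n), where
(i, j) bounds the first reactant (the peptide's N-terminal part) and
(k, n) the second, both 1-based inclusive in substrate coordinates.  The
index is computed once for the longest substrate and reused for shorter
ones by filtering out-of-range tuples.

Forward cis tuples keep substrate order (k > j, gap k-j-1 in [1, Imax]);
reverse cis tuples invert it (i > n, gap i-n-1 in [0, Imax]).  Reactant
intervals are always disjoint: one substrate molecule cannot reuse its
residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .digestion import PeptideRecord

INF = math.inf


@dataclass(frozen=True)
class SpliceIndex:
    """Precomputed splice-reactant coordinates for substrates up to length L.

    ``tuples`` holds (i, j, k, n) 1-based inclusive coordinates satisfying
    the direction's gap constraint; filtering by max(j, n) adapts the
    index to shorter substrates.
    """

    L: int
    N: int
    Lext: int
    Imax: float
    direction: str
    tuples: tuple = field(repr=False, default=())

    def for_length(self, length: int) -> Iterable[tuple]:
        """Tuples valid for a substrate of ``length`` <= L."""
        if length > self.L:
            raise ValueError(
                f"substrate length {length} exceeds index length {self.L}"
            )
        return (t for t in self.tuples if t[1] <= length and t[3] <= length)


def intervening_length(sr_coords: tuple, direction: str) -> int:
    """Residues between the two splice reactants.

    Forward: k - j - 1; reverse: i - n - 1.  Raises on overlapping
    reactant intervals (negative gap).
    """
    i, j, k, n = sr_coords
    if direction == "forward":
        gap = k - j - 1
    elif direction == "reverse":
        gap = i - n - 1
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if gap < 0:
        raise ValueError(f"overlapping splice reactants in {sr_coords}")
    return gap


def build_splice_index(
    L: int, N: int, Lext: int = 1, Imax: float = INF, direction: str = "forward"
) -> SpliceIndex:
    """All (i, j, k, n) tuples for substrates of length L, peptide length N.

    Returns an empty index when N < 2*Lext (no valid split of N into two
    reactants of length >= Lext).
    """
    if direction not in {"forward", "reverse"}:
        raise ValueError(f"unknown direction {direction!r}")
    tuples = []
    for a in range(Lext, N - Lext + 1):  # first-reactant length
        b = N - a
        if direction == "forward":
            # [i..j] then gap >= 1 then [k..n]
            for i in range(1, L - a + 2):
                j = i + a - 1
                k_hi = L - b + 1
                if Imax != INF:
                    k_hi = min(k_hi, j + 1 + int(Imax))
                for k in range(j + 2, k_hi + 1):
                    tuples.append((i, j, k, k + b - 1))
        else:
            # [k..n] then gap >= 0 then [i..j]; peptide is [i..j] + [k..n]
            for k in range(1, L - b + 2):
                n = k + b - 1
                i_hi = L - a + 1
                if Imax != INF:
                    i_hi = min(i_hi, n + 1 + int(Imax))
                for i in range(n + 1, i_hi + 1):
                    tuples.append((i, i + a - 1, k, n))
    return SpliceIndex(L, N, Lext, Imax, direction, tuple(tuples))


def generate_cis_spliced(
    protein: str,
    N: int,
    Lext: int = 1,
    Imax: float = INF,
    direction: str = "forward",
    origin_id: str = "protein",
    index: Optional[SpliceIndex] = None,
) -> list[PeptideRecord]:
    """One record per valid splice event on ``protein``.

    The sequence is substrate[i..j] + substrate[k..n]; records carry the
    splice-reactant coordinates and the intervening length.  A
    previously built (longer) index may be supplied for reuse.
    """
    L = len(protein)
    if index is None:
        index = build_splice_index(L, N, Lext, Imax, direction)
    elif (index.N, index.Lext, index.Imax, index.direction) != (
        N, Lext, Imax, direction,
    ):
        raise ValueError("supplied index parameters do not match request")
    records = []
    for i, j, k, n in index.for_length(L):
        seq = protein[i - 1 : j] + protein[k - 1 : n]
        records.append(
            PeptideRecord(
                sequence=seq,
                origin_id=origin_id,
                start=min(i, k),
                end=max(j, n),
                rule="cis_spliced",
                sr_coords=(i, j, k, n),
                intervening=intervening_length((i, j, k, n), direction),
            )
        )
    return records


def generate_cis_both(
    protein: str,
    N: int,
    Lext: int = 1,
    Imax: float = INF,
    origin_id: str = "protein",
) -> list[PeptideRecord]:
    """Forward plus reverse cis-spliced records for one substrate."""
    return generate_cis_spliced(
        protein, N, Lext, Imax, "forward", origin_id
    ) + generate_cis_spliced(protein, N, Lext, Imax, "reverse", origin_id)


def generate_trans_spliced(
    protein_a: str,
    protein_b: str,
    N: int,
    Lext: int = 1,
    origin_a: str = "proteinA",
    origin_b: str = "proteinB",
) -> list[PeptideRecord]:
    """Pairwise trans-spliced peptides: reactant 1 from A, reactant 2 from B.

    Provided for counting and testing; the pipeline treats trans events
    analytically only.
    """
    if origin_a == origin_b:
        raise ValueError("trans splicing requires distinct origin identifiers")
    L1, L2 = len(protein_a), len(protein_b)
    records = []
    sr1_min = max(Lext, N - L2)
    sr1_max = min(L1, N - Lext)
    for a in range(sr1_min, sr1_max + 1):
        b = N - a
        for i in range(1, L1 - a + 2):
            frag_a = protein_a[i - 1 : i + a - 1]
            for k in range(1, L2 - b + 2):
                records.append(
                    PeptideRecord(
                        sequence=frag_a + protein_b[k - 1 : k + b - 1],
                        origin_id=f"{origin_a}+{origin_b}",
                        start=i,
                        end=k + b - 1,
                        rule="trans_spliced",
                        sr_coords=(i, i + a - 1, k, k + b - 1),
                        intervening=None,
                    )
                )
    return records
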