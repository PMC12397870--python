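"""Monoisotopic masses and combinatorial PTM expansion.

Residue monoisotopic masses come from :mod:`pyteomics.mass`; water and
proton constants are centralised here.  Variable-PTM expansion assigns at
most one modification per site (terminus or residue position), up to a
configurable number of variable modifications per peptide (default 2,
the usual search-engine setting).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

WATER_MONO = 18.0105646863
PROTON_MASS = 1.00727646688
RESIDUE_MASSES = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class PTMDefinition:
    """One modification: a target residue letter or terminus and a mass delta."""

    name: str
    target: str  # residue letter or N-term / C-term
    delta_mass: float
    fixed: bool = False

    def __post_init__(self) -> None:
        valid = set(RESIDUE_MASSES) | {N_TERM, C_TERM}
        if self.target not in valid:
            raise ValueError(f"invalid PTM target {self.target!r}")
        if not self.delta_mass == self.delta_mass:  # NaN guard
            raise ValueError("delta_mass must be finite")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with site-resolved modifications and its monoisotopic mass.

    ``modifications`` is a tuple of (site, PTMDefinition) where site is a
    0-based residue index or a terminus label.
    """

    base_sequence: str
    modifications: tuple
    mass: float


# The eight common PTMs used for variable-modification searches.
COMMON_PTMS = (
    PTMDefinition("Acetyl", N_TERM, 42.010565),
    PTMDefinition("Carbamidomethyl", "C", 57.021464),
    PTMDefinition("Deamidated", "N", 0.984016),
    PTMDefinition("Deamidated", "Q", 0.984016),
    PTMDefinition("Oxidation", "M", 15.994915),
    PTMDefinition("Phospho", "S", 79.966331),
    PTMDefinition("Phospho", "T", 79.966331),
    PTMDefinition("Phospho", "Y", 79.966331),
)


def peptide_mass(
    sequence: str, fixed_mods: Sequence[PTMDefinition] = ()
) -> float:
    """Monoisotopic neutral mass: residue masses + water + fixed deltas.

    Fixed residue modifications are folded into the residue mass; fixed
    terminal modifications are added once when the relevant terminus
    exists (N-/C-term targets apply to every peptide; a terminal mod with
    a residue target would be modelled as a residue mod).  Sequences with
    X or other non-standard residues have no defined mass and raise.
    """
    if not sequence:
        raise ValueError("empty sequence has no mass")
    masses = dict(RESIDUE_MASSES)
    terminal_delta = 0.0
    for mod in fixed_mods:
        if not mod.fixed:
            raise ValueError(f"{mod.name} is not a fixed modification")
        if mod.target in (N_TERM, C_TERM):
            terminal_delta += mod.delta_mass
        else:
            masses[mod.target] = masses[mod.target] + mod.delta_mass
    total = WATER_MONO + terminal_delta
    for res in sequence:
        try:
            total += masses[res]
        except KeyError:
            raise ValueError(f"residue {res!r} has no defined mass") from None
    return total


def peptide_masses(sequences, fixed_mods: Sequence[PTMDefinition] = ()):
    """Vectorised :func:`peptide_mass` over many sequences.

    Same semantics (raises on residues without a defined mass); returns a
    float ndarray.
    """
    import numpy as np

    masses = dict(RESIDUE_MASSES)
    terminal_delta = 0.0
    for mod in fixed_mods:
        if not mod.fixed:
            raise ValueError(f"{mod.name} is not a fixed modification")
        if mod.target in (N_TERM, C_TERM):
            terminal_delta += mod.delta_mass
        else:
            masses[mod.target] += mod.delta_mass
    lookup = np.full(128, np.nan)
    for res, m in masses.items():
        lookup[ord(res)] = m
    out = np.empty(len(sequences))
    for idx, seq in enumerate(sequences):
        if not seq:
            raise ValueError("empty sequence has no mass")
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        total = lookup[codes].sum()
        if np.isnan(total):
            raise ValueError(f"sequence {seq!r} contains residues without mass")
        out[idx] = total + WATER_MONO + terminal_delta
    return out


def _eligible_sites(sequence: str, ptm: PTMDefinition):
    if ptm.target == N_TERM:
        return [N_TERM]
    if ptm.target == C_TERM:
        return [C_TERM]
    return [idx for idx, res in enumerate(sequence) if res == ptm.target]


def expand_variable_ptms(
    sequence: str,
    ptm_set: Sequence[PTMDefinition],
    max_mods: int = 2,
    fixed_mods: Sequence[PTMDefinition] = (),
) -> list[ModifiedPeptide]:
    """All assignments of 0..max_mods variable PTMs, <= 1 per site.

    The unmodified form is always included.  The terminus counts as a
    site distinct from residue position 0, so N-terminal acetylation can
    co-occur with a side-chain modification of the first residue.
    """
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    base = peptide_mass(sequence, fixed_mods)
    options = []  # (site, ptm) pairs
    for ptm in ptm_set:
        if ptm.fixed:
            continue
        for site in _eligible_sites(sequence, ptm):
            options.append((site, ptm))
    forms = [ModifiedPeptide(sequence, (), base)]
    for n_mods in range(1, max_mods + 1):
        for combo in combinations(options, n_mods):
            sites = [site for site, _ in combo]
            if len(set(sites)) != n_mods:
                continue  # one modification per site
            delta = sum(ptm.delta_mass for _, ptm in combo)
            forms.append(ModifiedPeptide(sequence, tuple(combo), base + delta))
    return forms


def count_modified_forms(
    sequence: str,
    ptm_set: Sequence[PTMDefinition],
    max_mods: int = 2,
    collapse_isomers: bool = False,
) -> int:
    """Number of modified forms of one peptide.

    ``collapse_isomers=False`` counts positional forms (distinct site
    assignments); ``True`` merges positional isomers, counting forms
    distinct in (sequence, multiset of PTM names+targets).
    """
    forms = expand_variable_ptms(sequence, ptm_set, max_mods)
    if not collapse_isomers:
        return len(forms)
    seen = {
        tuple(sorted((p.name, p.target) for _, p in f.modifications))
        for f in forms
    }
    return len(seen)


def load_ptm_table(stream, delimiter: str = "\t") -> list[PTMDefinition]:
    """Parse a delimited PTM table with columns name, target, delta_mass, fixed."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream, delimiter=delimiter)
    out: list[PTMDefinition] = []
    seen = set()
    for row in reader:
        key = (row["name"], row["target"])
        if key in seen:
            raise ValueError(f"duplicate PTM definition {key}")
        seen.add(key)
        try:
            delta = float(row["delta_mass"])
        except ValueError:
            raise ValueError(
                f"non-numeric delta_mass {row['delta_mass']!r} for {key}"
            ) from None
        fixed = str(row.get("fixed", "false")).strip().lower() in {
            "1", "true", "yes",
        }
        out.append(PTMDefinition(row["name"], row["target"], delta, fixed))
    return out


def ptm_inflation_ratio(
    proteins: Iterable[str],
    ptm_set: Sequence[PTMDefinition],
    length_range: tuple[int, int] = (8, 15),
    max_mods: int = 2,
    collapse_isomers: bool = False,
) -> float:
    """Ratio of PTM-expanded to unmodified nonspecific search-space size.

    Reporting utility over a user-provided protein sample: generates the
    nonspecific windows of each protein and counts modified forms per
    peptide.  Multiplying this ratio by an exhaustive unmodified stratum
    size extrapolates the PTM-expanded size.
    """
    from .digestion import nonspecific_windows

    unmodified = 0
    expanded = 0
    for idx, protein in enumerate(proteins):
        for rec in nonspecific_windows(protein, origin_id=str(idx), length_range=length_range):
            unmodified += 1
            expanded += count_modified_forms(
                rec.sequence, ptm_set, max_mods, collapse_isomers
            )
    if unmodified == 0:
        raise ValueError("no peptides generated from the protein sample")
    return expanded / unmodified
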