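"""Data-driven pre-filters: precursor mass, retention time, HLA binding.

A generated peptide is worth searching only if some MS1 observation could
explain it.  The MW filter keeps peptides whose monoisotopic mass falls
within the ppm window of at least one observed neutral precursor mass;
the MW+RT filter additionally requires the *same* observation's retention
time to lie within the calibrated prediction-error window; the HLA filter
keeps 8-15-mers predicted to bind at least one allele below an IC50
threshold.  Decoy databases are built by protein reversal so that every
downstream step applies symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ptm import PROTON_MASS

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PrecursorObservation:
    """One MS1 precursor: m/z, charge, retention time (minutes)."""

    mz: float
    charge: int
    rt: float
    source_run: str = ""

    @property
    def neutral_mass(self) -> float:
        return neutral_mass(self.mz, self.charge)


def neutral_mass(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from m/z and charge: z*mz - z*m_proton."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return charge * mz - charge * PROTON_MASS


def load_observations(path_or_buf, delimiter: str = "\t") -> pd.DataFrame:
    """Read an observation table (columns mz, charge, rt_minutes).

    Returns a DataFrame with derived neutral_mass, deduplicated on
    (neutral_mass, rt) rounded to (1e-5 Da, 1e-3 min) — duplicate
    detections carry no additional filtering information.
    """
    table = pd.read_csv(path_or_buf, sep=delimiter)
    table["neutral_mass"] = [
        neutral_mass(mz, z) for mz, z in zip(table["mz"], table["charge"])
    ]
    table["rt"] = table["rt_minutes"]
    table = table.assign(
        _m=table["neutral_mass"].round(5), _r=table["rt"].round(3)
    ).drop_duplicates(["_m", "_r"]).drop(columns=["_m", "_r"])
    return table.reset_index(drop=True)


def mw_filter(
    peptide_masses: Sequence[float],
    observed_masses: Sequence[float],
    ppm: float = 5.0,
) -> np.ndarray:
    """Keep mask: any observation within ppm of the peptide mass.

    The tolerance window is +/- ppm * 1e-6 * observed neutral mass,
    centred on each observation.  Implemented as a sorted interval join;
    equivalent to the all-pairs brute force.
    """
    if ppm <= 0:
        raise ValueError("ppm must be > 0")
    masses = np.asarray(peptide_masses, dtype=float)
    obs = np.sort(np.asarray(observed_masses, dtype=float))
    if obs.size == 0:
        return np.zeros(masses.shape, dtype=bool)
    tol = ppm * 1e-6 * obs
    lo, hi = obs - tol, obs + tol
    # both endpoints are monotone in obs, so the rightmost interval whose
    # lower bound is below the mass is the only candidate to check
    idx = np.searchsorted(lo, masses, side="right") - 1
    return (idx >= 0) & (masses <= hi[np.clip(idx, 0, None)])


@dataclass
class RTModel:
    """Additive retention-time model: RT = intercept + sum of residue coefficients.

    ``error_threshold`` is the calibrated absolute-error cut-off (minutes),
    the mean across CV folds of the chosen quantile of held-out absolute
    residuals.  Prediction is defined only for sequences over the trained
    residue set.
    """

    coefficients: dict
    intercept: float
    error_threshold: float
    trained_residues: frozenset
    fold_thresholds: tuple = ()

    def predict(self, sequence: str) -> float:
        missing = set(sequence) - self.trained_residues
        if missing:
            raise KeyError(
                f"residues {sorted(missing)} not observed during calibration"
            )
        return self.intercept + sum(self.coefficients[res] for res in sequence)

    def predict_many(self, sequences: Sequence[str]) -> np.ndarray:
        """Vector of predictions; NaN flags sequences with untrained residues."""
        out = np.full(len(sequences), np.nan)
        for idx, seq in enumerate(sequences):
            try:
                out[idx] = self.predict(seq)
            except KeyError:
                pass
        return out


def _composition_matrix(sequences: Sequence[str]) -> np.ndarray:
    X = np.zeros((len(sequences), len(AA_ORDER) + 1))
    col = {aa: i for i, aa in enumerate(AA_ORDER)}
    for row, seq in enumerate(sequences):
        for res in seq:
            X[row, col[res]] += 1
        X[row, -1] = 1.0  # intercept
    return X


def fit_rt_model(
    calibration: pd.DataFrame,
    folds: int = 5,
    quantile: float = 0.99,
    seed: int = 0,
) -> RTModel:
    """Calibrate the additive RT model on identified peptides.

    ``calibration`` needs columns sequence and rt_minutes.  Duplicate
    sequences are averaged; the CV split is on unique sequences (seeded
    shuffle) so no sequence leaks across folds.  The error threshold is
    the mean across folds of the ``quantile`` of held-out |residuals|.
    Residues present in no calibration sequence are excluded from the
    trained set; peptides carrying them are later flagged rather than
    predicted.
    """
    table = (
        calibration.groupby("sequence", as_index=False)["rt_minutes"].mean()
    )
    sequences = table["sequence"].tolist()
    if len(sequences) < 20:
        raise ValueError(
            f"need >= 20 distinct calibration sequences, got {len(sequences)}"
        )
    rts = table["rt_minutes"].to_numpy(float)
    X = _composition_matrix(sequences)
    present = X[:, :-1].sum(axis=0) > 0
    keep_cols = np.append(present, True)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    fold_of = np.empty(len(sequences), dtype=int)
    fold_of[order] = np.arange(len(sequences)) % folds
    logger.info("RT CV fold sizes: %s", np.bincount(fold_of, minlength=folds))

    thresholds = []
    for fold in range(folds):
        test = fold_of == fold
        beta, *_ = np.linalg.lstsq(X[~test][:, keep_cols], rts[~test], rcond=None)
        resid = np.abs(X[test][:, keep_cols] @ beta - rts[test])
        thresholds.append(float(np.quantile(resid, quantile)))

    beta, *_ = np.linalg.lstsq(X[:, keep_cols], rts, rcond=None)
    trained = [aa for aa, p in zip(AA_ORDER, present) if p]
    coeffs = dict(zip(trained, beta[:-1]))
    return RTModel(
        coefficients=coeffs,
        intercept=float(beta[-1]),
        error_threshold=float(np.mean(thresholds)),
        trained_residues=frozenset(trained),
        fold_thresholds=tuple(thresholds),
    )


def mw_rt_filter(
    sequences: Sequence[str],
    peptide_masses: Sequence[float],
    observations: pd.DataFrame,
    model: RTModel,
    ppm: float = 5.0,
    joint: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep mask for the joint MW+RT filter, plus an RT-evaluated mask.

    A peptide is kept iff a single observation satisfies both the ppm
    mass window and |predicted RT - observed RT| <= model.error_threshold
    (``joint=False`` relaxes to independent conditions).  Peptides whose
    RT cannot be predicted (untrained residues; variable-PTM forms are
    never RT-filtered by design) fall back to MW-only and are flagged
    False in the second mask.
    """
    masses = np.asarray(peptide_masses, dtype=float)
    obs_mass = observations["neutral_mass"].to_numpy(float)
    obs_rt = observations["rt"].to_numpy(float)
    preds = model.predict_many(sequences)
    evaluated = ~np.isnan(preds)

    keep = np.zeros(len(masses), dtype=bool)
    if obs_mass.size:
        order = np.argsort(obs_mass)
        obs_mass, obs_rt = obs_mass[order], obs_rt[order]
        tol = ppm * 1e-6 * obs_mass
        lo_all = obs_mass - tol
        hi_all = obs_mass + tol
        if joint:
            # observations matching a mass form the contiguous index range
            # [first hi >= m, last lo <= m] (endpoints monotone in obs mass)
            first = np.searchsorted(hi_all, masses, side="left")
            last = np.searchsorted(lo_all, masses, side="right")
            for idx in range(len(masses)):
                window = slice(first[idx], last[idx])
                if window.start >= window.stop:
                    continue
                if not evaluated[idx]:
                    keep[idx] = True
                else:
                    keep[idx] = bool(
                        (
                            np.abs(preds[idx] - obs_rt[window])
                            <= model.error_threshold
                        ).any()
                    )
        else:
            mw_ok = mw_filter(masses, obs_mass, ppm)
            rt_ok = np.zeros(len(masses), dtype=bool)
            for idx in range(len(masses)):
                if evaluated[idx]:
                    rt_ok[idx] = bool(
                        (np.abs(preds[idx] - obs_rt) <= model.error_threshold).any()
                    )
            keep = mw_ok & np.where(evaluated, rt_ok, True)
    return keep, evaluated


def hla_filter(
    sequences: Sequence[str],
    predictor: Callable[[str, str], float],
    alleles: Sequence[str],
    ic50_threshold: float = 5000.0,
    length_range: tuple[int, int] = (8, 15),
) -> tuple[np.ndarray, np.ndarray]:
    """Keep mask by predicted HLA-I binding, plus an evaluated mask.

    Peptides within the length range are kept iff the minimum predicted
    IC50 over alleles is <= threshold (nM, lower = stronger binder);
    peptides outside the range pass through unevaluated.
    """
    keep = np.ones(len(sequences), dtype=bool)
    evaluated = np.zeros(len(sequences), dtype=bool)
    lo, hi = length_range
    for idx, seq in enumerate(sequences):
        if not lo <= len(seq) <= hi:
            continue
        evaluated[idx] = True
        try:
            best = min(predictor(seq, allele) for allele in alleles)
        except Exception as exc:  # noqa: BLE001 - annotate peptide context
            raise RuntimeError(f"HLA predictor failed on {seq!r}") from exc
        keep[idx] = best <= ic50_threshold
    return keep, evaluated


def make_decoys(proteins: dict[str, str], suffix: str = "_decoy") -> dict[str, str]:
    """Reversed-sequence decoy database; ids suffixed.

    Reversal preserves amino-acid composition, so per-protein nonspecific
    event counts and mass multisets match the targets exactly — the basis
    of decoy-symmetric FDR estimation.
    """
    return {pid + suffix: seq[::-1] for pid, seq in proteins.items()}


class ToyHLAPredictor:
    """Position-weight-matrix IC50-like scorer for tests and examples.

    Synthetic stand-in for an external binding predictor: scores anchor
    positions 2 and C-terminus against an allele-specific residue
    preference and maps the score monotonically onto (0, 50000] nM.  Not
    a trained model.
    """

    _ANCHORS = {
        "A*02:01": {1: "LMIV", -1: "VLI"},
        "B*07:02": {1: "P", -1: "LF"},
    }

    def __init__(self, alleles: Optional[Iterable[str]] = None):
        self.alleles = list(alleles or self._ANCHORS)

    def __call__(self, sequence: str, allele: str) -> float:
        prefs = self._ANCHORS.get(allele)
        if prefs is None:
            raise KeyError(f"unknown allele {allele!r}")
        score = 0.0
        for pos, favoured in prefs.items():
            res = sequence[pos]
            if res in favoured:
                score += 1.0
            elif res in "ACDEFGHIKLMNPQRSTVWY":
                score += 0.1
        # score in [0.2, 2] -> IC50 in (0, 50000], monotone decreasing
        return 50000.0 * np.exp(-3.0 * score)
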