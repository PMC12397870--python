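"""Shared fixtures and independent brute-force oracles.

Oracles here are deliberately naive (quadruple loops, all-pairs scans,
substring enumeration) and never share code with the implementation
paths they validate.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pepspace import synthetic, workflow

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --- brute-force oracles ---------------------------------------------------

def splice_quad_loop(L, N, Lext, Imax, direction):
    """Literal quadruple-loop count of valid (i, j, k, n) tuples."""
    count = 0
    for i in range(1, L + 1):
        for j in range(i, L + 1):
            for k in range(1, L + 1):
                for n in range(k, L + 1):
                    a, b = j - i + 1, n - k + 1
                    if a < Lext or b < Lext or a + b != N:
                        continue
                    gap = (k - j - 1) if direction == "forward" else (i - n - 1)
                    if direction == "forward" and gap < 1:
                        continue
                    if direction == "reverse" and gap < 0:
                        continue
                    if gap > Imax:
                        continue
                    count += 1
    return count


def orf_scan_brute(nt_seq, start_codons, min_aa, stop_pred, include_no_stop=True):
    """Enumerate every start, extend to the stop, group by stop, keep the
    longest (most upstream start) per stop per frame."""
    nt_seq = nt_seq.upper()
    per_stop = {}
    for start in range(len(nt_seq) - 2):
        if nt_seq[start : start + 3] not in start_codons:
            continue
        pos = start
        stop_at = None
        while pos + 3 <= len(nt_seq):
            if stop_pred(nt_seq[pos : pos + 3]):
                stop_at = pos
                break
            pos += 3
        if stop_at is None:
            if not include_no_stop:
                continue
            end = start + 3 * ((len(nt_seq) - start) // 3)
            key = ("nostop", start % 3)
        else:
            end = stop_at
            key = ("stop", stop_at)
        if (end - start) // 3 < min_aa:
            continue
        if key not in per_stop or start < per_stop[key][0]:
            per_stop[key] = (start, end)
    return sorted(per_stop.values())


def tryptic_brute(protein, length_range, max_missed):
    """All substrings with valid tryptic termini and missed-cleavage count."""
    L = len(protein)
    out = set()
    for a in range(L):
        for b in range(a + 1, L + 1):
            if not length_range[0] <= b - a <= length_range[1]:
                continue
            nterm_ok = a == 0 or protein[a - 1] in "KR"
            cterm_ok = b == L or protein[b - 1] in "KR"
            if not (nterm_ok and cterm_ok):
                continue
            missed = sum(1 for r in protein[a : b - 1] if r in "KR")
            if max_missed is not None and missed > max_missed:
                continue
            out.add((a + 1, b, protein[a:b]))
    return out


def mw_brute(masses, obs, ppm):
    """All-pairs MW filter."""
    masses = np.asarray(masses)[:, None]
    obs = np.asarray(obs)[None, :]
    if obs.size == 0:
        return np.zeros(masses.shape[0], dtype=bool)
    return (np.abs(masses - obs) <= ppm * 1e-6 * obs).any(axis=1)


def mw_rt_brute(masses, preds, obs_mass, obs_rt, ppm, threshold):
    """All-pairs joint MW+RT filter; NaN prediction falls back to MW-only."""
    keep = np.zeros(len(masses), dtype=bool)
    for idx in range(len(masses)):
        for m, r in zip(obs_mass, obs_rt):
            if abs(masses[idx] - m) > ppm * 1e-6 * m:
                continue
            if np.isnan(preds[idx]) or abs(preds[idx] - r) <= threshold:
                keep[idx] = True
                break
    return keep


def edit_distance_dp(a, b):
    """Textbook dynamic-programming Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def qvalues_brute(scores, is_decoy):
    """Reference q-value assignment by explicit threshold scan."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    qs = np.empty(len(scores))
    thresholds = np.sort(np.unique(scores))
    fdr_at = {}
    for t in thresholds:
        sel = scores >= t
        fdr_at[t] = sel[is_decoy].sum() / max(1, sel[~is_decoy].sum())
    for idx, s in enumerate(scores):
        qs[idx] = min(fdr_at[t] for t in thresholds if t <= s)
    return np.clip(qs, 0, 1)


# --- shared fixtures -------------------------------------------------------

@pytest.fixture(scope="session")
def toy_fixtures():
    return synthetic.generate_fixtures(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(toy_fixtures):
    """One full end-to-end run shared across tests (deterministic, seed 1)."""
    config = workflow.PipelineConfig(seed=1, hla_alleles=("A*02:01", "B*07:02"))
    return workflow.run_pipeline(
        genome=toy_fixtures["genome"],
        gtf=toy_fixtures["gtf"],
        observations=toy_fixtures["observations"],
        calibration=toy_fixtures["calibration"],
        expression=toy_fixtures["expression"],
        config=config,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
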