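"""MW / RT / HLA pre-filters against all-pairs oracles; decoy symmetry."""

import numpy as np
import pandas as pd
import pytest
from pyteomics import achrom

from pepspace import digestion, filters, ptm, synthetic

from conftest import mw_brute, mw_rt_brute


class TestNeutralMass:
    def test_formula(self):
        assert filters.neutral_mass(500.0, 2) == pytest.approx(997.98545, abs=1e-5)

    def test_singly_charged_identity(self):
        m = 1234.5678
        assert filters.neutral_mass(m + ptm.PROTON_MASS, 1) == pytest.approx(m, abs=1e-9)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            filters.neutral_mass(500.0, 0)


class TestMWFilter:
    def test_boundary_arithmetic(self):
        keep = filters.mw_filter([1000.000, 1000.000], [1000.004], ppm=5)
        assert keep.tolist() == [True, True]
        assert not filters.mw_filter([1000.000], [1000.006], ppm=5)[0]

    def test_empty_observations_drop_all(self):
        assert not filters.mw_filter([500.0, 900.0], [], ppm=5).any()

    def test_matches_all_pairs_brute_force(self, rng):
        masses = rng.uniform(800, 1600, size=3000)
        obs = rng.uniform(800, 1600, size=400)
        # plant exact near-matches so both branches are exercised
        obs[:50] = masses[:50] * (1 + rng.uniform(-4e-6, 4e-6, 50))
        got = filters.mw_filter(masses, obs, ppm=5)
        assert (got == mw_brute(masses, obs, 5)).all()

    def test_invalid_ppm(self):
        with pytest.raises(ValueError):
            filters.mw_filter([1.0], [1.0], ppm=0)


class TestRTModel:
    @staticmethod
    def _calibration(rng, n, sigma):
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(8, 16))))
            for _ in range(n)
        ]
        rts = np.array([synthetic.true_rt(s) for s in seqs]) + rng.normal(0, sigma, n)
        return pd.DataFrame({"sequence": seqs, "rt_minutes": rts})

    def test_exact_recovery_without_noise(self, rng):
        table = self._calibration(rng, 300, 0.0)
        model = filters.fit_rt_model(table, folds=5)
        preds = model.predict_many(table["sequence"].tolist())
        assert np.max(np.abs(preds - table["rt_minutes"].to_numpy())) < 1e-6
        assert model.error_threshold < 1e-6

    def test_noise_quantile_threshold(self, rng):
        """0.99 quantile of |N(0, 0.5)| is about 2.576 * 0.5 = 1.288 min."""
        table = self._calibration(rng, 2000, 0.5)
        model = filters.fit_rt_model(table, folds=5, quantile=0.99)
        assert model.error_threshold == pytest.approx(1.288, rel=0.15)

    def test_coefficient_error_shrinks_with_n(self, rng):
        errors = []
        for n in (200, 2000):
            model = filters.fit_rt_model(self._calibration(rng, n, 0.5))
            truth = synthetic.TRUE_RT_COEFFICIENTS
            # additive models are identifiable up to a constant per residue;
            # compare centred coefficients
            diffs = np.array([model.coefficients[aa] - truth[aa] for aa in truth])
            errors.append(np.mean(np.abs(diffs - diffs.mean())))
        assert errors[1] < errors[0]

    def test_insufficient_calibration_raises(self):
        table = pd.DataFrame({"sequence": ["PEPTIDEK"] * 30, "rt_minutes": [10.0] * 30})
        with pytest.raises(ValueError, match="20"):
            filters.fit_rt_model(table)

    def test_untrained_residue_flagged(self, rng):
        table = self._calibration(rng, 100, 0.1)
        table["sequence"] = table["sequence"].str.replace("W", "A")
        model = filters.fit_rt_model(table)
        assert "W" not in model.trained_residues
        with pytest.raises(KeyError):
            model.predict("WAAAAAAA")
        assert np.isnan(model.predict_many(["WAAAAAAA"]))[0]

    def test_agrees_with_achrom_additive_model(self, rng):
        """Independent cross-check: pyteomics' additive achrom fit predicts
        the same RTs on noiseless additive data."""
        table = self._calibration(rng, 300, 0.0)
        model = filters.fit_rt_model(table)
        # lcp=0: plain additive model, no length correction
        rcs = achrom.get_RCs(
            table["sequence"].tolist(), table["rt_minutes"].to_numpy(), lcp=0.0
        )
        for seq in table["sequence"][:50]:
            ref = achrom.calculate_RT(seq, rcs)
            assert model.predict(seq) == pytest.approx(ref, abs=1e-4)


class TestMWRTFilter:
    @staticmethod
    def _model():
        return filters.RTModel(
            coefficients={aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"},
            intercept=10.0,
            error_threshold=1.0,
            trained_residues=frozenset("ACDEFGHIKLMNPQRSTVWY"),
        )

    def test_joint_condition_requires_single_observation(self):
        # obs A matches on mass only, obs B on RT only -> drop under joint
        obs = pd.DataFrame(
            {"neutral_mass": [1000.0, 2000.0], "rt": [50.0, 10.0]}
        )
        model = self._model()  # predicts rt 10 for everything
        keep, _ = filters.mw_rt_filter(["AAAAAAAA"], [1000.0], obs, model, ppm=5)
        assert not keep[0]
        keep, _ = filters.mw_rt_filter(
            ["AAAAAAAA"], [1000.0], obs, model, ppm=5, joint=False
        )
        assert keep[0]

    def test_joint_match_kept(self):
        obs = pd.DataFrame({"neutral_mass": [1000.0], "rt": [10.5]})
        keep, evaluated = filters.mw_rt_filter(
            ["AAAAAAAA"], [1000.0], obs, self._model(), ppm=5
        )
        assert keep[0] and evaluated[0]

    def test_unpredictable_peptide_falls_back_to_mw(self):
        model = filters.RTModel(
            coefficients={"A": 1.0}, intercept=0.0, error_threshold=1.0,
            trained_residues=frozenset("A"),
        )
        obs = pd.DataFrame({"neutral_mass": [1000.0], "rt": [50.0]})
        keep, evaluated = filters.mw_rt_filter(
            ["WWWWWWWW"], [1000.0], obs, model, ppm=5
        )
        assert keep[0] and not evaluated[0]

    def test_matches_all_pairs_brute_force(self, rng):
        masses = rng.uniform(800, 1600, 1500)
        seqs = ["A" * 8] * 1500  # prediction constant; RT window decided by obs
        obs = pd.DataFrame(
            {
                "neutral_mass": np.concatenate(
                    [masses[:200] * (1 + rng.uniform(-4e-6, 4e-6, 200)),
                     rng.uniform(800, 1600, 300)]
                ),
                "rt": rng.uniform(5, 15, 500),
            }
        )
        model = self._model()
        keep, _ = filters.mw_rt_filter(seqs, masses, obs, model, ppm=5)
        preds = np.full(len(masses), 10.0)
        expected = mw_rt_brute(
            masses, preds, obs["neutral_mass"].to_numpy(), obs["rt"].to_numpy(),
            5, model.error_threshold,
        )
        assert (keep == expected).all()

    def test_stage_containment(self, rng):
        masses = rng.uniform(800, 1600, 500)
        obs = pd.DataFrame(
            {"neutral_mass": rng.uniform(800, 1600, 200), "rt": rng.uniform(5, 15, 200)}
        )
        mw_keep = filters.mw_filter(masses, obs["neutral_mass"].to_numpy(), 20)
        mwrt_keep, _ = filters.mw_rt_filter(
            ["A" * 8] * 500, masses, obs, self._model(), ppm=20
        )
        assert not (mwrt_keep & ~mw_keep).any()


class TestHLAFilter:
    def test_threshold_boundary(self):
        keep, evaluated = filters.hla_filter(
            ["AAAAAAAAA"], lambda s, a: 4999.0, ["X"], ic50_threshold=5000
        )
        assert keep[0] and evaluated[0]
        keep, _ = filters.hla_filter(
            ["AAAAAAAAA"], lambda s, a: 5001.0, ["X"], ic50_threshold=5000
        )
        assert not keep[0]

    def test_out_of_range_passes_unevaluated(self):
        keep, evaluated = filters.hla_filter(
            ["A" * 16], lambda s, a: 1e9, ["X"], length_range=(8, 15)
        )
        assert keep[0] and not evaluated[0]

    def test_min_over_alleles(self):
        ic50 = {"A1": 9000.0, "A2": 100.0}
        keep, _ = filters.hla_filter(
            ["AAAAAAAAA"], lambda s, a: ic50[a], ["A1", "A2"]
        )
        assert keep[0]

    def test_predictor_failure_reports_peptide(self):
        def broken(s, a):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="AAAAAAAAA"):
            filters.hla_filter(["AAAAAAAAA"], broken, ["X"])

    def test_toy_predictor_prefers_anchor_residues(self):
        predictor = filters.ToyHLAPredictor()
        strong = predictor("KLIDLVSSV", "A*02:01")  # L at P2, V at C-term
        weak = predictor("KDIDEDSSE", "A*02:01")
        assert strong < weak


class TestDecoys:
    def test_reversal_and_suffix(self):
        decoys = filters.make_decoys({"p1": "ACDE"})
        assert decoys == {"p1_decoy": "EDCA"}

    def test_composition_preserved(self, rng):
        proteins = {
            f"p{i}": synthetic.random_protein(rng, int(rng.integers(20, 60)))
            for i in range(20)
        }
        decoys = filters.make_decoys(proteins)
        for pid, seq in proteins.items():
            assert sorted(decoys[pid + "_decoy"]) == sorted(seq)

    def test_nonspecific_event_counts_and_mass_multisets_symmetric(self, rng):
        proteins = {
            f"p{i}": synthetic.random_protein(rng, int(rng.integers(15, 50)))
            for i in range(30)
        }
        decoys = filters.make_decoys(proteins)
        for pid, seq in proteins.items():
            target = digestion.nonspecific_windows(seq, length_range=(8, 12))
            decoy = digestion.nonspecific_windows(
                decoys[pid + "_decoy"], length_range=(8, 12)
            )
            assert len(target) == len(decoy)
            t_masses = sorted(ptm.peptide_mass(r.sequence) for r in target)
            d_masses = sorted(ptm.peptide_mass(r.sequence) for r in decoy)
            assert np.allclose(t_masses, d_masses, atol=1e-9)


def test_load_observations_dedups(tmp_path):
    path = tmp_path / "obs.tsv"
    pd.DataFrame(
        {"mz": [500.0, 500.0, 600.0], "charge": [2, 2, 2],
         "rt_minutes": [10.0, 10.0, 12.0]}
    ).to_csv(path, sep="\t", index=False)
    obs = filters.load_observations(path)
    assert len(obs) == 2
    assert obs["neutral_mass"].iloc[0] == pytest.approx(997.98545, abs=1e-5)
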