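"""DP4 stereoisomer ranking: probabilities, invariances, benchmarks."""

import numpy as np
import pytest
from rdkit import Chem
from scipy import stats

from spinsys.dp4 import (
    DP4Params,
    dp4_probability,
    enumerate_stereoisomers,
    identification_benchmark,
    rank_candidates,
)


class TestEnumeration:
    def test_achiral_single_candidate(self):
        assert len(enumerate_stereoisomers(Chem.MolFromSmiles("CCO"))) == 1

    def test_two_stereocenters_four_candidates(self):
        mol = Chem.MolFromSmiles("C[C@H](F)[C@@H](Cl)C")
        assert len(enumerate_stereoisomers(mol)) == 4

    def test_three_plus_centers_capped_at_eight(self):
        mol = Chem.MolFromSmiles("C[C@H](F)[C@@H](Cl)[C@H](N)[C@@H](O)C")
        cands = enumerate_stereoisomers(mol, max_candidates=8)
        assert len(cands) == 8

    def test_input_structure_first_and_deterministic(self):
        mol = Chem.MolFromSmiles("C[C@H](F)[C@@H](Cl)C")
        a = [Chem.MolToSmiles(m) for m in enumerate_stereoisomers(mol)]
        b = [Chem.MolToSmiles(m) for m in enumerate_stereoisomers(mol)]
        assert a == b
        assert a[0] == Chem.MolToSmiles(mol)
        assert len(set(a)) == len(a)


def _brute_dp4(predicted, reference, params):
    """Independent oracle: plain product of t tail probabilities."""
    liks = []
    for cand in predicted:
        lik = 1.0
        for cls, ref in reference.items():
            pred = np.asarray(cand[cls], float)
            ref = np.asarray(ref, float)
            if params.correction == "linear-rescale" and pred.size >= 2:
                slope, intercept = np.polyfit(ref, pred, 1)
                pred = (pred - intercept) / slope
            for e in np.abs(pred - ref):
                lik *= 1.0 - stats.t.cdf(e / params.sigma[cls], df=params.nu[cls])
        liks.append(lik)
    liks = np.array(liks)
    return liks / liks.sum()


class TestProbabilities:
    def test_single_candidate_probability_one(self):
        p = dp4_probability(
            [{"1H": np.array([1.0, 2.0])}], {"1H": np.array([1.1, 2.2])}
        )
        assert p == pytest.approx([1.0])

    def test_identical_candidates_uniform(self):
        cand = {"1H": np.array([1.0, 2.0, 3.0])}
        p = dp4_probability([cand, dict(cand)], {"1H": np.array([1.2, 2.1, 2.9])})
        assert p == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        ref = {"1H": rng.normal(2, 1, 5), "13C": rng.normal(60, 20, 4)}
        cands = [
            {"1H": ref["1H"] + rng.normal(0, 0.3, 5),
             "13C": ref["13C"] + rng.normal(0, 2, 4)}
            for _ in range(6)
        ]
        p = dp4_probability(cands, ref)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)

    @pytest.mark.parametrize("correction", ["none", "linear-rescale"])
    def test_matches_independent_t_density_oracle(self, correction, rng):
        params = DP4Params(correction=correction)
        ref = {"1H": np.array([1.0, 2.5, 4.0]), "13C": np.array([20.0, 75.0])}
        cands = [
            {"1H": np.array([1.2, 2.4, 4.4]), "13C": np.array([22.0, 73.0])},
            {"1H": np.array([0.5, 3.0, 3.6]), "13C": np.array([30.0, 70.0])},
        ]
        p = dp4_probability(cands, ref, params)
        brute = _brute_dp4(cands, ref, params)
        assert p == pytest.approx(brute, abs=1e-9)

    def test_mismatched_atom_counts_rejected(self):
        with pytest.raises(ValueError):
            dp4_probability(
                [{"1H": np.ones(3)}], {"1H": np.ones(4)}
            )

    def test_invariant_to_candidate_ordering(self, rng):
        ref = {"1H": rng.normal(2, 1, 6)}
        cands = [{"1H": ref["1H"] + rng.normal(0, 0.3, 6)} for _ in range(4)]
        p = dp4_probability(cands, ref)
        p_rev = dp4_probability(cands[::-1], ref)
        assert np.allclose(p, p_rev[::-1], atol=1e-12)

    def test_common_offset_does_not_change_ranking_with_rescale(self, rng):
        params = DP4Params(correction="linear-rescale")
        ref = {"1H": rng.normal(2, 1, 8)}
        cands = [{"1H": ref["1H"] + rng.normal(0, 0.2, 8)} for _ in range(4)]
        p0 = dp4_probability(cands, ref, params)
        shifted = [{"1H": c["1H"] + 0.7} for c in cands]
        p1 = dp4_probability(shifted, ref, params)
        assert np.array_equal(np.argsort(p0), np.argsort(p1))


class TestBenchmarks:
    def test_oracle_predictor_perfect_top1(self, rng):
        # the "model" returns the reference itself for the true candidate
        mols = [
            Chem.MolFromSmiles(s)
            for s in (
                "C[C@H](F)[C@@H](Cl)C",
                "C[C@H](O)[C@@H](F)C",
                "C[C@H](N)[C@@H](Cl)C",
            )
        ]
        refs = []
        predictions = {}
        for mol in mols:
            ref = {"1H": rng.normal(2, 1, 8)}
            refs.append(ref)
            cands = enumerate_stereoisomers(mol)
            for k, c in enumerate(cands):
                smi = Chem.MolToSmiles(c)
                if k == 0:
                    predictions[smi] = ref["1H"]
                else:
                    predictions[smi] = ref["1H"] + rng.normal(0, 1.0, 8)

        def predict(mol):
            return {"1H": predictions[Chem.MolToSmiles(mol)]}

        result = identification_benchmark(predict, mols, refs)
        assert result["top1"] == 1.0
        assert 4 in result["by_candidate_count"]

    def test_random_predictor_uniform_over_eight(self, rng):
        # Monte Carlo over the probability function alone: with iid random
        # predictions per candidate, each of 8 candidates wins ~1/8
        n_trials, hits = 5000, 0
        ref = {"1H": np.zeros(6)}
        params = DP4Params(correction="none")
        for _ in range(n_trials):
            cands = [{"1H": rng.normal(0, 1, 6)} for _ in range(8)]
            p = dp4_probability(cands, ref, params)
            hits += int(np.argmax(p) == 0)
        assert abs(hits / n_trials - 0.125) < 0.02

    def test_noisy_oracle_beats_random(self, rng):
        # small perturbation of the truth: top-1 well above the 1/4 baseline
        mols = [Chem.MolFromSmiles("C[C@H](F)[C@@H](Cl)C") for _ in range(40)]
        refs, predictions = [], {}
        for i, mol in enumerate(mols):
            local = np.random.default_rng(i)
            base = local.normal(2, 1, 8)
            refs.append({"1H": base})
            for k, c in enumerate(enumerate_stereoisomers(mol)):
                smi = (i, Chem.MolToSmiles(c))
                truth = base if k == 0 else base + local.normal(0, 1.5, 8)
                predictions[smi] = truth + local.normal(0, 0.05, 8)
        hits = 0
        for i, (mol, ref) in enumerate(zip(mols, refs)):
            cands = enumerate_stereoisomers(mol)
            preds = [{"1H": predictions[(i, Chem.MolToSmiles(c))]} for c in cands]
            p = dp4_probability(preds, ref, DP4Params(correction="none"))
            hits += int(np.argmax(p) == 0)
        assert hits / len(mols) > 0.5  # far above the 0.25 random baseline

    def test_rank_candidates_reports_true_rank(self, rng):
        ref = {"1H": np.array([1.0, 2.0, 3.0])}
        good = {"1H": np.array([1.05, 2.0, 3.1])}
        bad = {"1H": np.array([2.0, 0.5, 4.5])}
        report = rank_candidates(["a", "b"], [bad, good], ref,
                                 DP4Params(correction="none"), true_index=1)
        assert report.true_rank == 1
        assert report.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
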