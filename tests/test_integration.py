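import numpy as np
import pandas as pd
import pytest

from sasangdx.integration import (
    IntegrationModel,
    classify,
    diagnose,
    fit_integration,
    margin,
    sweep_cutoff,
    tscore,
    tscore_fixed,
    tscores,
    typicality_filter,
)
from sasangdx.lasso import SC_TYPES, LinearFit

MODS = ("face", "body", "questionnaire", "voice")


def manual_model(weights, intercepts=(0.0, 0.0, 0.0), tau=0.1):
    """IntegrationModel with hand-set w_jr (dict type -> 4 weights)."""
    fits = {}
    for j, t in enumerate(SC_TYPES):
        w = np.asarray(weights[t], dtype=float)
        fits[t] = LinearFit(coef=w, intercept=float(intercepts[j]), lam=0.0,
                            feature_means=np.zeros(4), feature_sds=np.ones(4))
    return IntegrationModel(modalities=MODS, fits=fits, tau=tau)


def random_blocks(rng, n=30):
    idx = pd.Index([f"S{i}" for i in range(n)])
    return {m: pd.DataFrame(rng.standard_normal((n, 3)), index=idx,
                            columns=list(SC_TYPES)) for m in MODS}


class TestTscore:
    def test_zero_weights_give_intercepts(self, rng):
        model = manual_model({t: [0, 0, 0, 0] for t in SC_TYPES},
                             intercepts=(0.2, 0.5, -0.1))
        blocks = random_blocks(rng)
        ts = tscores(model, blocks)
        np.testing.assert_allclose(ts["TE"], 0.2)
        np.testing.assert_allclose(ts["SE"], 0.5)
        np.testing.assert_allclose(ts["SY"], -0.1)

    def test_quarter_weights_reduce_to_plain_modality_mean(self, rng):
        model = manual_model({t: [0.25] * 4 for t in SC_TYPES})
        blocks = random_blocks(rng)
        ts = tscores(model, blocks)
        manual = sum(blocks[m].to_numpy() for m in MODS) / 4
        np.testing.assert_allclose(ts.to_numpy(), manual, atol=1e-12)
        # equivalently the historical equal fixed-weight form
        fixed = tscore_fixed(blocks, {m: 0.25 for m in MODS})
        np.testing.assert_allclose(ts.to_numpy(), fixed.to_numpy(), atol=1e-12)

    def test_matches_dot_product_oracle(self, rng):
        weights = {t: rng.standard_normal(4) for t in SC_TYPES}
        icepts = rng.standard_normal(3)
        model = manual_model(weights, icepts)
        pi_row = {m: {t: float(rng.standard_normal()) for t in SC_TYPES}
                  for m in MODS}
        got = tscore(pi_row, model)
        for j, t in enumerate(SC_TYPES):
            expected = icepts[j] + sum(
                weights[t][r] * pi_row[m][t] for r, m in enumerate(MODS))
            assert got[j] == pytest.approx(expected, abs=1e-10)

    def test_missing_modality_is_an_error(self, rng):
        model = manual_model({t: [1, 1, 1, 1] for t in SC_TYPES})
        with pytest.raises(ValueError, match="common samples"):
            tscore({"face": {t: 0.1 for t in SC_TYPES}}, model)

    def test_affine_shift_of_one_types_inputs(self, rng):
        """Adding c to every modality's type-j score shifts TSCORE_j by
        c * sum_r w_jr and leaves the other types untouched."""
        weights = {t: rng.standard_normal(4) for t in SC_TYPES}
        model = manual_model(weights)
        blocks = random_blocks(rng, n=10)
        base = tscores(model, blocks)
        c = 0.7
        shifted = {m: b.assign(SE=b["SE"] + c) for m, b in blocks.items()}
        out = tscores(model, shifted)
        np.testing.assert_allclose(out["SE"], base["SE"] + c * weights["SE"].sum(),
                                   atol=1e-10)
        np.testing.assert_allclose(out["TE"], base["TE"], atol=1e-12)
        np.testing.assert_allclose(out["SY"], base["SY"], atol=1e-12)


class TestClassify:
    def test_argmax_and_tie_break(self):
        assert classify((0.5, 0.3, 0.2)) == "TE"
        assert classify((0.4, 0.4, 0.1)) == "TE"   # documented tie-break order
        assert classify((0.1, 0.4, 0.4)) == "SE"

    def test_permutation_equivariance(self, rng):
        """Permuting the score triple permutes the predicted label the
        same way (away from exact ties)."""
        for _ in range(100):
            s = rng.standard_normal(3)
            if len(set(np.round(s, 6))) < 3:
                continue
            perm = rng.permutation(3)
            before = SC_TYPES.index(classify(s))
            after = SC_TYPES.index(classify(s[perm]))
            assert perm[after] == before

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify((0.1, float("nan"), 0.2))

    def test_invariant_under_increasing_affine_transform(self, rng):
        for _ in range(50):
            s = rng.standard_normal(3)
            a, b = rng.uniform(0.1, 5), rng.uniform(-3, 3)
            assert classify(s) == classify(a * s + b)


class TestTypicality:
    def test_margin_examples(self):
        assert margin((0.6, 0.3, 0.1)) == pytest.approx(0.3)
        assert margin((0.4, 0.4, 0.1)) == pytest.approx(0.0)

    def test_tie_excluded_for_positive_tau(self, rng):
        model = manual_model({t: [0.25] * 4 for t in SC_TYPES})
        blocks = random_blocks(rng, n=5)
        for m in MODS:  # force an exact two-way tie for subject 0
            blocks[m].iloc[0] = [1.0, 1.0, 0.0]
        diag = diagnose(model, blocks)
        assert diag.iloc[0]["margin"] == pytest.approx(0.0)
        assert typicality_filter(diag, 0.01).index[0] != diag.index[0] \
            or len(typicality_filter(diag, 0.01)) < len(diag)
        assert diag.index[0] not in typicality_filter(diag, 1e-9).index

    def test_retained_size_monotone_in_tau(self, rng):
        model = manual_model({t: list(rng.standard_normal(4)) for t in SC_TYPES})
        diag = diagnose(model, random_blocks(rng, n=200))
        sizes = [len(typicality_filter(diag, t))
                 for t in (0.0, 0.05, 0.1, 0.2, 0.5, 1.0)]
        assert sizes[0] == 200
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_negative_tau_rejected(self, rng):
        model = manual_model({t: [0.25] * 4 for t in SC_TYPES})
        diag = diagnose(model, random_blocks(rng, n=3))
        with pytest.raises(ValueError):
            typicality_filter(diag, -0.1)


class TestFitIntegration:
    def _blocks_with_oracle_modality(self, rng, n=600, noise=0.05):
        labels = np.array(SC_TYPES)[rng.choice(3, n, p=[0.4, 0.27, 0.33])]
        idx = pd.Index([f"S{i}" for i in range(n)])
        onehot = pd.DataFrame(
            {t: (labels == t).astype(float) for t in SC_TYPES}, index=idx)
        blocks = {m: pd.DataFrame(rng.standard_normal((n, 3)) * 0.5,
                                  index=idx, columns=list(SC_TYPES))
                  for m in MODS}
        blocks["voice"] = onehot + rng.standard_normal((n, 3)) * noise
        return blocks, labels

    def test_oracle_modality_dominates_weights_and_accuracy(self, rng):
        blocks, labels = self._blocks_with_oracle_modality(rng)
        tr = pd.Index([f"S{i}" for i in range(400)])
        te = pd.Index([f"S{i}" for i in range(400, 600)])
        model = fit_integration({m: b.loc[tr] for m, b in blocks.items()},
                                labels[:400], seed=0, folds=5)
        W = model.weights()
        for t in SC_TYPES:
            assert W.loc[t].abs().idxmax() == "voice"
        diag = diagnose(model, {m: b.loc[te] for m, b in blocks.items()})
        assert (diag["predicted"].to_numpy() == labels[400:]).mean() >= 0.95

    def test_identical_blocks_match_single_block_predictions(self, rng):
        """Duplicating one probability block across all four modalities
        leaves the stacked predictions equal to the single-block fit
        (the L1 penalty is indifferent to how weight splits among exact
        duplicates)."""
        labels = np.array(SC_TYPES)[rng.choice(3, 300, p=[0.4, 0.27, 0.33])]
        idx = pd.Index([f"S{i}" for i in range(300)])
        A = pd.DataFrame({t: (labels == t) + rng.standard_normal(300) * 0.4
                          for t in SC_TYPES}, index=idx)
        blocks4 = {m: A for m in MODS}
        m4 = fit_integration(blocks4, labels, seed=1, folds=5)
        m1 = fit_integration({"face": A}, labels, modalities=("face",),
                             seed=1, folds=5)
        np.testing.assert_allclose(tscores(m4, blocks4).to_numpy(),
                                   tscores(m1, {"face": A}).to_numpy(),
                                   atol=1e-6)

    def test_single_class_rejected(self, rng):
        blocks = random_blocks(rng, n=20)
        with pytest.raises(ValueError):
            fit_integration(blocks, np.array(["TE"] * 20), seed=0)

    def test_misaligned_blocks_rejected(self, rng):
        blocks = random_blocks(rng, n=20)
        blocks["voice"] = blocks["voice"].iloc[::-1]
        with pytest.raises(ValueError, match="aligned"):
            fit_integration(blocks, np.array(["TE", "SE", "SY", "TE"] * 5), seed=0)

    def test_serialization_round_trip(self, rng):
        blocks, labels = self._blocks_with_oracle_modality(rng, n=200)
        model = fit_integration(blocks, labels, seed=2, folds=5)
        clone = IntegrationModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(tscores(clone, blocks).to_numpy(),
                                      tscores(model, blocks).to_numpy())


class TestSweepCutoff:
    def test_sweep_reports_monotone_retention(self, rng):
        model = manual_model({t: list(rng.standard_normal(4)) for t in SC_TYPES})
        blocks = random_blocks(rng, n=100)
        diag = diagnose(model, blocks)
        truth = pd.Series(np.array(SC_TYPES)[rng.choice(3, 100)],
                          index=diag.index)
        table = sweep_cutoff(diag, truth, [0.0, 0.1, 0.3])
        assert table["retained_fraction"].is_monotonic_decreasing
        assert table.loc[0, "retained_fraction"] == 1.0
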