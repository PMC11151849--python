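"""Repeated k-fold cross-validation machinery and the width search."""

import numpy as np
import pandas as pd
import pytest

from mycorun import CVPlan, SimConfig, TrainConfig, cross_validate, fit_surrogate, make_folds
from mycorun.model_selection import search_hidden_neurons
from mycorun.pipeline import dataset_xy
from mycorun.preprocess import fit_boxcox
from mycorun.simulate import generate_rl_dataset


class MeanModel:
    def __init__(self, mean):
        self.mean = mean

    def predict(self, X):
        return np.full(len(X), self.mean)


class TestMakeFolds:
    def test_each_repeat_partitions_rows_into_balanced_folds(self):
        plan = CVPlan(k=8, repeats=10, seed=0)
        folds = make_folds(2048, plan)
        assert folds.shape == (10, 2048)
        for rep in range(10):
            sizes = np.bincount(folds[rep], minlength=8)
            assert sizes.tolist() == [256] * 8

    def test_uneven_rows_differ_by_at_most_one(self):
        folds = make_folds(30, CVPlan(k=8, repeats=2, seed=0))
        for rep in range(2):
            sizes = np.bincount(folds[rep], minlength=8)
            assert sizes.max() - sizes.min() <= 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, CVPlan(k=8, repeats=1))

    def test_grouped_folds_keep_groups_together(self):
        groups = np.repeat(np.arange(32), 8)
        folds = make_folds(256, CVPlan(k=8, repeats=3, seed=1), groups=groups)
        for rep in range(3):
            df = pd.DataFrame({"g": groups, "f": folds[rep]})
            assert (df.groupby("g")["f"].nunique() == 1).all()


class TestCrossValidate:
    def test_split_count_is_k_times_repeats(self, rr_xy):
        X, y, _ = rr_xy
        res = cross_validate(lambda Xt, yt: MeanModel(yt.mean()), X, y, CVPlan(k=8, repeats=10, seed=0))
        assert res.n_splits == 80
        assert len(res.split_test) == 80

    def test_mean_predictor_has_zero_pooled_r2(self, rr_xy):
        X, y, _ = rr_xy
        res = cross_validate(lambda Xt, yt: MeanModel(yt.mean()), X, y, CVPlan(k=8, repeats=2, seed=0))
        assert abs(res.pooled_test.r2) <= 0.02

    def test_oracle_predictor_hits_the_noise_ceiling(self, tables):
        """Predicting the exact generator mean leaves only replicate noise:
        pooled R² must match 1 − E[noise²]/Var(y) computed in closed form."""
        sim = SimConfig(seed=21)
        rl = generate_rl_dataset(tables, sim)
        X, y, _ = dataset_xy(rl, "rl")

        frame = tables.frame.set_index(["bagasse_pct", "wheatbran_pct", "beechsawdust_pct"])

        class OracleModel:
            def predict(self, Xq):
                out = np.empty(len(Xq))
                for i, (b, w, s, t) in enumerate(Xq):
                    row = frame.loc[(b, w, s)]
                    day = row["days_to_highest"]
                    out[i] = 0.0 if pd.isna(day) else row["rl_mean_cm"] * min(t, day) / day
                return out

        res = cross_validate(lambda Xt, yt: OracleModel(), X, y, CVPlan(k=8, repeats=2, seed=3))
        # noise sd at (substrate, t) is noise_sd * min(t, day)/day, independent of plateau
        days = frame["days_to_highest"].astype(float).to_numpy()
        ratios = [
            min(t, d) / d
            for d in days if not np.isnan(d)
            for t in (5, 10, 15, 20, 25, 30, 35, 40)
        ]
        noise_var = sim.noise_sd_cm**2 * np.mean(np.square(ratios)) * (63 * 32) / 2048
        ceiling = 1 - noise_var / y.var()
        assert res.pooled_test.r2 == pytest.approx(ceiling, abs=0.02)


class TestWidthSearch:
    @staticmethod
    def _factory_for_width(feats, lmbda, seed, max_epochs=400, patience=80):
        def factory_for(n_hidden):
            def factory(Xtr, ytr):
                return fit_surrogate(
                    Xtr, ytr, n_hidden,
                    TrainConfig(seed=seed, max_epochs=max_epochs, patience=patience),
                    feature_names=feats, boxcox_lmbda=lmbda,
                )
            return factory
        return factory_for

    def test_search_equals_exhaustive_sweep_and_caches(self, rr_xy):
        X, y, feats = rr_xy
        bc = fit_boxcox(y, offset=1.0)
        from mycorun import GAConfig

        ga = GAConfig(bounds=((1, 6),), seed=2, encoding="integer", generations=25)
        best, cache, outcome = search_hidden_neurons(
            X, y, self._factory_for_width(feats, bc.lmbda, seed=5),
            CVPlan(k=8, repeats=1, seed=9), gene_range=(1, 6), ga_config=ga,
        )
        assert set(cache) <= set(range(1, 7))
        assert best == max(cache, key=cache.get)  # GA returns the cached argmax
        # fitness was evaluated once per distinct width despite 25 x 50 GA evaluations
        assert len(cache) <= 6
        assert int(outcome.best_chromosome[0]) == best

    def test_linear_truth_prefers_small_widths(self, rng):
        X = rng.uniform(0, 1, size=(300, 3))
        y = X @ [2.0, -1.0, 0.5] + 3.0 + rng.normal(0, 0.02, 300)
        from mycorun import GAConfig

        ga = GAConfig(bounds=((1, 5),), seed=0, encoding="integer", generations=15)
        best, cache, _ = search_hidden_neurons(
            X, y, self._factory_for_width(("a", "b", "c"), 1.0, seed=1, max_epochs=2500, patience=400),
            CVPlan(k=8, repeats=1, seed=1), gene_range=(1, 5), ga_config=ga,
        )
        rmses = {k: -v for k, v in cache.items()}
        # a small network wins or ties within a whisker on a linear truth
        assert rmses[best] <= min(rmses.values()) + 1e-12
        assert min(rmses[k] for k in rmses if k <= 3) <= 1.5 * min(rmses.values())
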