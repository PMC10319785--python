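"""Curation pipeline, splitting, fitting, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import graphccs as g
from graphccs.errors import EmptyEvaluationError
from graphccs.gnn import ModelConfig


def _rec(identifier, smiles, adduct, ccs=None, mz=None):
    return g.CCSRecord(identifier=identifier, smiles=smiles, adduct=adduct,
                       ccs=ccs, mz=mz)


def ten_row_fixture():
    """Hand-derived curation ledger: 10 -> 9 -> 7 -> 5 -> 5 -> 5.

    One bad SMILES, two [M+K]+ entries, and three duplicates of one
    (smiles, adduct) key with CCS {100, 110, 150} collapsing to 110.
    """
    return [
        _rec("d1", "CCO", "[M+H]+", 100.0),
        _rec("d2", "CCO", "[M+H]+", 110.0),
        _rec("d3", "CCO", "[M+H]+", 150.0),
        _rec("bad", "not_a_smiles", "[M+H]+", 120.0),
        _rec("k1", "CC(=O)O", "[M+K]+", 130.0),
        _rec("k2", "c1ccccc1", "[M+K]+", 140.0),
        _rec("b1", "c1ccccc1", "[M+H]+", 115.0),
        _rec("n1", "CCN", "[M+Na]+", 125.0),
        _rec("p1", "CCC", "[M-H]-", 105.0),
        _rec("m1", "CO", "[M+H]+", 95.0),
    ]


class TestCurate:
    def test_fixture_counts_per_step(self):
        curated, report = g.curate(ten_row_fixture(), seed=1)
        assert report.counts() == [10, 9, 7, 5, 5, 5]
        assert len(curated) == 5

    def test_median_collapse_of_duplicates(self):
        curated, _ = g.curate(ten_row_fixture(), seed=1)
        cco = [r for r in curated if r.smiles == "CCO"]
        assert len(cco) == 1
        assert cco[0].ccs == 110.0

    def test_drop_reasons_recorded(self):
        _, report = g.curate(ten_row_fixture(), seed=1)
        reasons = {ident: reason for ident, reason in report.dropped}
        assert reasons["bad"] == "invalid_smiles"
        assert reasons["k1"] == "unsupported_adduct"
        assert reasons["d2"] == "duplicate_entry"

    def test_empty_input(self):
        curated, report = g.curate([], seed=1)
        assert curated == []
        assert report.counts() == [0, 0, 0, 0, 0, 0]

    def test_idempotent(self):
        once, _ = g.curate(ten_row_fixture(), seed=1)
        twice, report = g.curate(list(once), seed=1)
        assert [(r.smiles, r.adduct, r.ccs) for r in twice] == \
               [(r.smiles, r.adduct, r.ccs) for r in once]

    def test_outlier_removal_on_planted_outlier(self):
        """A CCS far off the per-adduct mass trend is dropped in step 5."""
        rng = np.random.default_rng(0)
        smiles = ["C" * k for k in range(1, 13)]   # alkane ladder
        records = []
        for i, s in enumerate(smiles):
            mz = 16.0 + 14.0 * i
            records.append(_rec(f"a{i}", s, "[M+H]+",
                                ccs=40 + 2.0 * mz + rng.normal(0, 0.5),
                                mz=mz))
        records.append(_rec("outlier", "CCCCCCCCCCCCC", "[M+H]+",
                            ccs=5000.0, mz=200.0))
        curated, report = g.curate(records, seed=2)
        reasons = {i: r for i, r in report.dropped}
        assert reasons.get("outlier") == "ccs_outlier"
        assert len(curated) == len(smiles)


class TestSplit:
    def _records(self, n=100):
        return [_rec(f"r{i}", "CCO", "[M+H]+", 100.0 + i) for i in range(n)]

    def test_sizes_and_disjoint(self):
        train, test = g.split(self._records(), (0.9, 0.1), seed=5)
        assert len(train) == 90 and len(test) == 10
        assert {r.identifier for r in train}.isdisjoint(
            {r.identifier for r in test})

    def test_deterministic(self):
        a = g.split(self._records(), (0.9, 0.1), seed=5)
        b = g.split(self._records(), (0.9, 0.1), seed=5)
        assert [r.identifier for r in a[0]] == [r.identifier for r in b[0]]

    def test_molecule_level_keeps_smiles_together(self):
        records = [
            _rec(f"r{i}{a}", f"{'C' * (i + 1)}O", a, 100.0)
            for i in range(30)
            for a in ("[M+H]+", "[M+Na]+")
        ]
        train, test = g.split(records, (0.8, 0.2), seed=3, level="molecule")
        assert {r.smiles for r in train}.isdisjoint({r.smiles for r in test})

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            g.split(self._records(), (0.9, 0.2), seed=1)


class TestFit:
    def _toy_records(self, target=100.0, n=10):
        smiles = ["C", "CC", "CCC", "CCO", "CCN", "CO", "CN", "CCCC",
                  "CC(C)C", "CCCO"]
        return [
            _rec(f"t{i}", s, "[M+H]+", ccs=target)
            for i, s in enumerate(smiles[:n])
        ]

    def _config(self, seed=0, epochs=60):
        return ModelConfig.scaled(seed=seed, epochs=epochs, batch_size=5,
                                  patience=epochs)

    def test_constant_target_is_learned(self):
        records = self._toy_records()
        model, log = g.fit(records, records[:3], self._config())
        metrics = g.evaluate(records, model)
        assert metrics["rmse"] < 1.0        # targets all 100 Å²

    def test_log_is_finite_and_validation_improves(self):
        records = self._toy_records()
        model, log = g.fit(records, records[:3], self._config())
        losses = [e["val_loss"] for e in log]
        assert all(np.isfinite(e["train_loss"]) for e in log)
        assert min(losses) <= losses[0]

    def test_same_seed_reproduces_loss(self):
        records = self._toy_records()
        cfg = self._config(seed=4, epochs=25)
        _, log_a = g.fit(records, records[:3], cfg)
        _, log_b = g.fit(records, records[:3], self._config(seed=4, epochs=25))
        assert abs(log_a[-1]["train_loss"] - log_b[-1]["train_loss"]) < 1e-6

    def test_end_to_end_learnability(self, trained_model, synthetic_split):
        """Scaled network trained on 400 synthetic molecules generalizes to
        the 100 held-out molecules."""
        _, test = synthetic_split
        metrics = g.evaluate(test, trained_model)
        assert metrics["r2"] >= 0.8
        assert metrics["median_re"] <= 10.0


class TestMetrics:
    def test_perfect_fit(self):
        obs = np.array([100.0, 150.0, 200.0])
        assert g.r_squared(obs, obs) == 1.0
        assert g.median_relative_error(obs, obs) == 0.0
        assert g.rmse(obs, obs) == 0.0

    def test_hand_case(self):
        obs = np.array([100.0, 200.0])
        pred = np.array([110.0, 200.0])
        assert g.median_relative_error(obs, pred) == pytest.approx(5.0)
        assert g.rmse(obs, pred) == pytest.approx(np.sqrt(50.0))

    def test_mean_predictor_has_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.full(4, obs.mean())
        assert g.r_squared(obs, pred) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_metrics_agree_with_naive_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(50, 300, size=64)
        pred = obs + rng.normal(0, 10, size=64)
        naive_r2 = 1 - ((obs - pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum()
        naive_med = float(np.median(np.abs(pred - obs) / obs)) * 100
        naive_rmse = float(np.sqrt(((pred - obs) ** 2).mean()))
        assert abs(g.r_squared(obs, pred) - naive_r2) < 1e-10
        assert abs(g.median_relative_error(obs, pred) - naive_med) < 1e-10
        assert abs(g.rmse(obs, pred) - naive_rmse) < 1e-10

    def test_empty_evaluation_raises(self, trained_model):
        with pytest.raises(EmptyEvaluationError):
            g.evaluate([], trained_model)
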