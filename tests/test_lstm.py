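import numpy as np
import pytest

from ovascreen import Cohort, GeneratorConfig, LSTMClassifier, LSTMConfig, \
    VisitSeries, auc, generate_cohort
from ovascreen.rnn.cells import (ChannelWeights, backward_sequence,
                                 forward_padded, forward_sequence, lstm_step,
                                 sigmoid)
from ovascreen.rnn.model import Scaler, cross_entropy, tune


def _scalar_step_oracle(h_prev, c_prev, y, w):
    """Element-by-element evaluation of the gate equations."""
    H = w.H
    h, c = np.empty(H), np.empty(H)
    for n in range(H):
        a_c = sum(h_prev[m] * w.Uc[m, n] for m in range(H)) + y * w.Wc[n] + w.bc[n]
        a_i = sum(h_prev[m] * w.Ui[m, n] for m in range(H)) + y * w.Wi[n] + w.bi[n]
        a_f = sum(h_prev[m] * w.Uf[m, n] for m in range(H)) + y * w.Wf[n] + w.bf[n]
        a_o = sum(h_prev[m] * w.Uo[m, n] for m in range(H)) + y * w.Wo[n] + w.bo[n]
        ct = np.tanh(a_c)
        gi = 1 / (1 + np.exp(-a_i))
        gf = 1 / (1 + np.exp(-a_f))
        go = 1 / (1 + np.exp(-a_o))
        c[n] = gf * c_prev[n] + gi * ct
        h[n] = go * np.tanh(c[n])
    return h, c


class TestCell:
    def test_zero_weights_closed_form(self):
        """All weights zero: every gate is 1/2, the candidate vanishes, so
        c = c_prev/2 and h = tanh(c_prev/2)/2."""
        H = 3
        w = ChannelWeights.zeros(H)
        c_prev = np.array([0.4, -1.0, 2.0])
        h, c, _ = lstm_step(np.ones(H), c_prev, 5.0, w)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)
        h0, c0, _ = lstm_step(np.zeros(H), np.zeros(H), -3.0, w)
        np.testing.assert_allclose(h0, 0.0)
        np.testing.assert_allclose(c0, 0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = ChannelWeights.initialize(2, rng)
        h_prev = rng.standard_normal(2)
        c_prev = rng.standard_normal(2)
        y = float(rng.standard_normal())
        h, c, _ = lstm_step(h_prev, c_prev, y, w)
        h_ref, c_ref = _scalar_step_oracle(h_prev, c_prev, y, w)
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)

    def test_two_step_sequence_matches_oracle(self):
        rng = np.random.default_rng(3)
        w = ChannelWeights.initialize(2, rng)
        seq = [0.7, -1.2]
        h_T, _ = forward_sequence(seq, w)
        h, c = np.zeros(2), np.zeros(2)
        for y in seq:
            h, c = _scalar_step_oracle(h, c, y, w)
        np.testing.assert_allclose(h_T, h, atol=1e-10)

    def test_masked_padding_is_inert(self):
        rng = np.random.default_rng(4)
        w = ChannelWeights.initialize(3, rng)
        seq = [0.5, -0.3, 1.1]
        h_ref, _ = forward_sequence(seq, w)
        padded = np.array(seq + [99.0, -99.0])
        mask = np.array([True, True, True, False, False])
        np.testing.assert_array_equal(forward_padded(padded, mask, w), h_ref)


class TestLoss:
    def test_half_risk_gives_log2(self):
        assert cross_entropy([1, 0, 1], [0.5, 0.5, 0.5]) == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_arithmetic_example(self):
        expected = -0.5 * (np.log(0.9) + np.log(0.8))
        assert cross_entropy([1, 0], [0.9, 0.2]) == pytest.approx(expected,
                                                                  abs=1e-12)
        assert expected == pytest.approx(0.16425, abs=1e-5)

    def test_perfect_prediction_tends_to_zero(self):
        assert cross_entropy([1, 0], [0.999999, 0.000001]) < 1e-5

    def test_degenerate_risks_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            val = cross_entropy([1, 0], [1.0, 0.0])
        assert np.isfinite(val)


def _toy_model(markers=("CA125",), hidden=3, seed=0, dropout=0.0):
    cohort, _ = generate_cohort(GeneratorConfig(n_controls=8, n_cases=6,
                                                seed=5))
    clf = LSTMClassifier(cohort, markers=list(markers),
                         config=LSTMConfig(hidden=hidden, dropout=dropout,
                                           epochs=1, learning_rate=1e-3))
    return clf


class TestForward:
    def test_zero_weights_give_half_risk(self):
        clf = _toy_model()
        res = clf.fit(seed=0)
        net = res.network
        for ch in net.channels:
            z = ChannelWeights.zeros(net.weights[ch].H)
            for name in z.names():
                setattr(net.weights[ch], name, getattr(z, name))
        net.We = np.zeros_like(net.We)
        net.be = 0.0
        p = res.predict_proba(clf.cohort.patients[0])
        assert p == pytest.approx(0.5, abs=1e-15)

    def test_eval_mode_is_pure(self):
        clf = _toy_model(dropout=0.4)
        res = clf.fit(seed=1)
        p = clf.cohort.patients[3]
        vals = {res.predict_proba(p) for _ in range(5)}
        assert len(vals) == 1

    def test_identical_patients_identical_risks(self):
        clf = _toy_model()
        res = clf.fit(seed=2)
        p = clf.cohort.patients[0]
        q = VisitSeries("copy", p.status, ages=p.ages.copy(),
                        levels={k: v.copy() for k, v in p.levels.items()},
                        diagnosis_age=p.diagnosis_age)
        assert res.predict_proba(p) == res.predict_proba(q)

    def test_too_few_visits_rejected(self):
        clf = _toy_model()
        res = clf.fit(seed=0)
        with pytest.raises(ValueError):
            res.predict_proba(clf.cohort.patients[0], n_visits=1)

    def test_full_model_matches_hand_rolled_computation(self):
        """H=1, one marker + age channel, 2 visits: the whole pipeline
        (standardize -> two LSTMs -> concatenate -> sigmoid head) agrees
        with a hand evaluation of the gate equations."""
        clf = _toy_model(hidden=1)
        res = clf.fit(seed=3)
        p = clf.cohort.patients[1]
        risk = res.predict_proba(p, n_visits=2)
        h_parts = []
        for ch in res.channels:
            seq = res.scaler.transform(p, ch, n_visits=2)
            h = np.zeros(1)
            c = np.zeros(1)
            for y in seq:
                h, c = _scalar_step_oracle(h, c, float(y),
                                           res.network.weights[ch])
            h_parts.append(h)
        z = np.concatenate(h_parts) @ res.network.We + res.network.be
        assert risk == pytest.approx(float(sigmoid(z)), abs=1e-10)


class TestGradients:
    def test_numerical_gradient_agreement(self):
        """Analytic BPTT gradients vs central finite differences, 1e-4
        relative, over every weight of a tiny two-channel network."""
        clf = _toy_model(hidden=2)
        res = clf.fit(seed=4)
        net = res.network
        batch = clf._training_batch(res.scaler)[:4]

        def total_loss():
            risks = [net.forward(seqs)[0] for seqs, _ in batch]
            labels = [lab for _, lab in batch]
            return cross_entropy(labels, risks)

        # analytic
        grads = {}
        N = len(batch)
        for seqs, label in batch:
            risk, cache = net.forward(seqs)
            dz = (risk - label) / N
            for k, g in net.backward(cache, dz).items():
                grads[k] = grads.get(k, 0.0) + g
        eps = 1e-6
        rng = np.random.default_rng(0)
        for key, value in list(net.param_items()):
            g_analytic = np.atleast_1d(np.asarray(grads[key], dtype=float))
            flat_val = np.atleast_1d(np.asarray(value, dtype=float))
            # probe a subset of coordinates per parameter
            n_probe = min(4, flat_val.size)
            coords = rng.choice(flat_val.size, size=n_probe, replace=False)
            for c in coords:
                idx = np.unravel_index(c, flat_val.shape)
                orig = flat_val[idx]
                flat_val[idx] = orig + eps
                net.set_param(key, flat_val.reshape(np.shape(value))
                              if np.ndim(value) else float(flat_val[0]))
                up = total_loss()
                flat_val[idx] = orig - eps
                net.set_param(key, flat_val.reshape(np.shape(value))
                              if np.ndim(value) else float(flat_val[0]))
                down = total_loss()
                flat_val[idx] = orig
                net.set_param(key, flat_val.reshape(np.shape(value))
                              if np.ndim(value) else float(flat_val[0]))
                numeric = (up - down) / (2 * eps)
                scale = max(abs(numeric), abs(g_analytic.reshape(-1)[c]), 1e-8)
                assert abs(numeric - g_analytic.reshape(-1)[c]) / scale < 1e-4


class TestTraining:
    def test_learns_separable_cohort(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_controls=30, n_cases=20,
                                                    seed=13))
        clf = LSTMClassifier(cohort, config=LSTMConfig(
            hidden=8, dropout=0.0, epochs=60, learning_rate=0.02))
        res = clf.fit(seed=0)
        losses = np.array(res.loss_history)
        assert losses[10] < losses[0]          # early descent
        scores = np.array([res.predict_proba(p) for p in cohort.patients])
        assert auc(cohort.labels, scores) > 0.95

    def test_determinism(self):
        clf = _toy_model(dropout=0.2)
        a = clf.fit(seed=9).loss_history
        b = clf.fit(seed=9).loss_history
        assert a == b

    def test_one_class_rejected(self, small_cohort):
        cohort, _ = small_cohort
        controls = cohort.subset_patients([p.patient_id
                                           for p in cohort.controls])
        with pytest.raises(ValueError):
            LSTMClassifier(controls).fit(seed=0)

    def test_scaler_computed_on_training_split_only(self, small_cohort):
        cohort, _ = small_cohort
        half = cohort.subset_patients(cohort.ids[::2])
        s_half = Scaler.fit(half, cohort.biomarker_names)
        s_full = Scaler.fit(cohort, cohort.biomarker_names)
        assert any(s_half.mean[m] != s_full.mean[m]
                   for m in cohort.biomarker_names)


class TestTune:
    def test_single_point_grid_returned(self, small_cohort):
        cohort, _ = small_cohort
        cfg = tune(cohort, grid={"hidden": [4], "dropout": [0.1]},
                   base_config=LSTMConfig(epochs=2), inner_k=3, inner_reps=1,
                   seed=0)
        assert cfg.hidden == 4 and cfg.dropout == 0.1

    def test_selection_matches_exhaustive_rerun(self, small_cohort):
        """The tuner's winner equals an independent re-run of the same grid
        with the same folds and seeds."""
        from sklearn.model_selection import RepeatedStratifiedKFold
        from dataclasses import replace as dc_replace

        cohort, _ = small_cohort
        grid = {"hidden": [2, 6], "dropout": [0.0]}
        base = LSTMConfig(epochs=4, learning_rate=0.02)
        chosen = tune(cohort, grid=grid, base_config=base, inner_k=3,
                      inner_reps=1, seed=1)

        ids = np.array(cohort.ids)
        labels = cohort.labels
        splitter = RepeatedStratifiedKFold(n_splits=3, n_repeats=1,
                                           random_state=1)
        means = {}
        for hidden in grid["hidden"]:
            vals = []
            for fold_i, (tr, va) in enumerate(splitter.split(ids, labels)):
                train = cohort.subset_patients(ids[tr])
                res = LSTMClassifier(
                    train, config=dc_replace(base, hidden=hidden, dropout=0.0)
                ).fit(seed=1 + fold_i)
                y = [cohort[p].status for p in ids[va]]
                s = [res.predict_proba(cohort[p]) for p in ids[va]]
                if len(set(y)) == 2:
                    vals.append(auc(np.array(y), np.array(s)))
            means[hidden] = np.mean(vals)
        best_hidden = max(grid["hidden"],
                          key=lambda h: (means[h], -h))
        assert chosen.hidden == best_hidden
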