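"""Per-marker LSTM classifier of longitudinal screening series.

One scalar-input LSTM per selected biomarker plus one for the screening
age (the age channel is always included); the last hidden states are
concatenated, dropout is applied to the concatenated vector at train time,
and a sigmoid head maps it to a risk of ovarian cancer.  Training minimises
cross-entropy by full-batch gradient descent with Adam; recurrent kernels
start orthogonal, input weights Glorot-uniform, biases zero.

Standardization statistics (per-channel mean/sd pooled over visits) are
computed on the training split only and reapplied at evaluation.

``LSTMClassifier`` / ``LSTMResults`` mirror the package's Model/Results
convention; ``tune`` runs the inner repeated-stratified-CV hyperparameter
search over hidden size and dropout rate.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from ..cohort import Cohort, VisitSeries
from .cells import ChannelWeights, backward_sequence, forward_sequence, sigmoid

__all__ = ["LSTMConfig", "Scaler", "LSTMClassifier", "LSTMResults",
           "cross_entropy", "tune"]

AGE_CHANNEL = "age"
RISK_EPS = 1e-7


@dataclass(frozen=True)
class LSTMConfig:
    """Architecture and training settings.

    ``hidden`` and ``dropout`` are the tuned hyperparameters; learning rate
    and epoch count are fixed meta-parameters.
    """

    hidden: int = 8              # hidden neurons per channel
    dropout: float = 0.2         # rate on the concatenated hidden vector
    learning_rate: float = 1e-3
    epochs: int = 100
    age_hidden: int | None = None   # defaults to ``hidden``

    def __post_init__(self):
        if self.hidden < 1:
            raise ValueError("hidden size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("invalid training meta-parameters")

    def hidden_for(self, channel: str) -> int:
        if channel == AGE_CHANNEL and self.age_hidden is not None:
            return self.age_hidden
        return self.hidden


@dataclass
class Scaler:
    """Per-channel standardization (mean/sd pooled over all visits)."""

    mean: dict
    sd: dict

    @classmethod
    def fit(cls, cohort: Cohort, markers, min_visits: int = 2) -> "Scaler":
        mean, sd = {}, {}
        usable = [p for p in cohort.patients if p.n_visits >= min_visits]
        for m in markers:
            vals = np.concatenate([p.transformed(m) for p in usable])
            mean[m], sd[m] = float(vals.mean()), float(vals.std())
        ages = np.concatenate([p.ages for p in usable])
        mean[AGE_CHANNEL], sd[AGE_CHANNEL] = float(ages.mean()), float(ages.std())
        for c, s in sd.items():
            if s == 0.0:
                sd[c] = 1.0
        return cls(mean=mean, sd=sd)

    def transform(self, series: VisitSeries, channel: str,
                  n_visits: int | None = None) -> np.ndarray:
        if channel == AGE_CHANNEL:
            vals = np.asarray(series.ages, dtype=float)
        else:
            vals = series.transformed(channel)
        if n_visits is not None:
            vals = vals[:n_visits]
        return (vals - self.mean[channel]) / self.sd[channel]


def cross_entropy(labels, risks) -> float:
    """Mean binary cross-entropy; risks at exactly 0/1 are clipped with a warning."""
    labels = np.asarray(labels, dtype=float)
    risks = np.asarray(risks, dtype=float)
    if np.any((risks <= 0.0) | (risks >= 1.0)):
        warnings.warn(f"risks clipped into ({RISK_EPS}, 1-{RISK_EPS})",
                      stacklevel=2)
        risks = np.clip(risks, RISK_EPS, 1.0 - RISK_EPS)
    return float(-np.mean(labels * np.log(risks)
                          + (1.0 - labels) * np.log(1.0 - risks)))


# ---------------------------------------------------------------- the network

class _Network:
    """Weights of the full model: one ChannelWeights per channel + head."""

    def __init__(self, channels, config: LSTMConfig, rng):
        self.channels = list(channels)
        self.config = config
        self.weights = {
            ch: ChannelWeights.initialize(config.hidden_for(ch), rng)
            for ch in self.channels
        }
        total = sum(config.hidden_for(ch) for ch in self.channels)
        limit = np.sqrt(6.0 / (total + 1))
        self.We = rng.uniform(-limit, limit, size=total)
        self.be = 0.0

    def param_items(self):
        for ch in self.channels:
            w = self.weights[ch]
            for name in w.names():
                yield (ch, name), getattr(w, name)
        yield ("head", "We"), self.We
        yield ("head", "be"), self.be

    def set_param(self, key, value):
        ch, name = key
        if ch == "head":
            if name == "We":
                self.We = value
            else:
                self.be = float(value)
        else:
            setattr(self.weights[ch], name, value)

    def forward(self, seqs: dict, dropout_mask: np.ndarray | None = None):
        """Risk for one patient; ``seqs`` maps channel -> standardized series.

        ``dropout_mask`` is a pre-scaled (inverted-dropout) multiplier on
        the concatenated hidden vector; ``None`` means evaluation mode.
        """
        h_parts, caches = [], {}
        for ch in self.channels:
            h, cache = forward_sequence(seqs[ch], self.weights[ch])
            h_parts.append(h)
            caches[ch] = cache
        h_cat = np.concatenate(h_parts)
        h_drop = h_cat if dropout_mask is None else h_cat * dropout_mask
        z = float(h_drop @ self.We + self.be)
        risk = float(sigmoid(z))
        return risk, (caches, h_drop, dropout_mask)

    def backward(self, fwd_cache, dz: float):
        """Gradients of the loss given d(loss)/dz at the head input."""
        caches, h_drop, dropout_mask = fwd_cache
        grads = {("head", "We"): dz * h_drop, ("head", "be"): dz}
        dh_cat = dz * self.We
        if dropout_mask is not None:
            dh_cat = dh_cat * dropout_mask
        offset = 0
        for ch in self.channels:
            H = self.weights[ch].H
            g = backward_sequence(caches[ch], self.weights[ch],
                                  dh_cat[offset:offset + H])
            for name, val in g.items():
                grads[(ch, name)] = val
            offset += H
        return grads


class _Adam:
    def __init__(self, keys, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, net: _Network, grads: dict):
        self.t += 1
        for key, value in list(net.param_items()):
            g = grads[key]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * np.square(g)
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            net.set_param(key, value - self.lr * mhat / (np.sqrt(vhat) + self.eps))


# ------------------------------------------------------------- Model / Results

class LSTMClassifier:
    """LSTM screening classifier over a marker subset (age always included)."""

    def __init__(self, cohort: Cohort, markers=None,
                 config: LSTMConfig | None = None):
        self.cohort = cohort
        self.markers = list(markers) if markers is not None \
            else list(cohort.biomarker_names)
        unknown = set(self.markers) - set(cohort.biomarker_names)
        if unknown:
            raise KeyError(f"unknown markers {unknown}")
        self.config = config if config is not None else LSTMConfig()
        self.channels = self.markers + [AGE_CHANNEL]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, markers=None,
                       config: LSTMConfig | None = None):
        return cls(Cohort.from_frame(df), markers=markers, config=config)

    def _training_batch(self, scaler: Scaler):
        batch = []
        for p in self.cohort.patients:
            if p.n_visits < 2:
                warnings.warn(f"patient {p.patient_id} has <2 visits; skipped",
                              stacklevel=2)
                continue
            seqs = {ch: scaler.transform(p, ch) for ch in self.channels}
            batch.append((seqs, float(p.status)))
        return batch

    def fit(self, seed: int = 0) -> "LSTMResults":
        labels = self.cohort.labels
        if labels.min() == labels.max():
            raise ValueError("training cohort must contain both classes")
        rng = np.random.default_rng(seed)
        scaler = Scaler.fit(self.cohort, self.markers)
        batch = self._training_batch(scaler)
        net = _Network(self.channels, self.config, rng)
        keys = [k for k, _ in net.param_items()]
        adam = _Adam(keys, lr=self.config.learning_rate)
        keep = 1.0 - self.config.dropout
        n_cat = net.We.size
        loss_history = []
        N = len(batch)
        for _ in range(self.config.epochs):
            total_loss = 0.0
            grad_acc = {k: 0.0 for k in keys}
            for seqs, label in batch:
                if keep < 1.0:
                    mask = (rng.uniform(size=n_cat) < keep) / keep
                else:
                    mask = None
                risk, cache = net.forward(seqs, dropout_mask=mask)
                r = min(max(risk, RISK_EPS), 1.0 - RISK_EPS)
                total_loss += -(label * np.log(r) + (1 - label) * np.log(1 - r))
                dz = (r - label) / N       # d(mean CE)/dz through the sigmoid
                for k, g in net.backward(cache, dz).items():
                    grad_acc[k] = grad_acc[k] + g
            loss = total_loss / N
            if not np.isfinite(loss):
                raise RuntimeError("non-finite training loss; aborting")
            loss_history.append(float(loss))
            adam.step(net, grad_acc)
        return LSTMResults(model=self, network=net, scaler=scaler,
                           loss_history=loss_history, seed=seed)


class LSTMResults:
    """Trained weights, the training-split scaler, and risk scoring."""

    def __init__(self, model: LSTMClassifier | None, network: _Network,
                 scaler: Scaler, loss_history, seed: int):
        self.model = model
        self.network = network
        self.scaler = scaler
        self.loss_history = list(loss_history)
        self.seed = seed

    @property
    def channels(self):
        return self.network.channels

    def predict_proba(self, series: VisitSeries,
                      n_visits: int | None = None) -> float:
        """Evaluation-mode risk (dropout off; deterministic)."""
        n = series.n_visits if n_visits is None else n_visits
        if n < 2:
            raise ValueError("need at least two visits to score a patient")
        seqs = {ch: self.scaler.transform(series, ch, n_visits=n)
                for ch in self.channels}
        risk, _ = self.network.forward(seqs, dropout_mask=None)
        return risk

    def risk_trajectory(self, series: VisitSeries,
                        min_visits: int = 2) -> pd.DataFrame:
        rows = []
        for j in range(min_visits, series.n_visits + 1):
            rows.append({
                "patient_id": series.patient_id,
                "visit_index": j - 1,
                "age_years": float(series.ages[j - 1]),
                "risk": self.predict_proba(series, n_visits=j),
                "model": "rnn",
            })
        return pd.DataFrame(rows)

    def score_cohort(self, cohort: Cohort, min_visits: int = 2) -> pd.DataFrame:
        frames = []
        for p in cohort.patients:
            if p.n_visits < min_visits:
                warnings.warn(f"patient {p.patient_id} has <{min_visits} "
                              "visits; skipped", stacklevel=2)
                continue
            frames.append(self.risk_trajectory(p, min_visits=min_visits))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        cfg = self.model.config if self.model else None
        rows = [{
            "channels": ",".join(self.channels),
            "hidden": cfg.hidden if cfg else None,
            "dropout": cfg.dropout if cfg else None,
            "epochs": len(self.loss_history),
            "final_loss": self.loss_history[-1] if self.loss_history else None,
            "seed": self.seed,
        }]
        return pd.DataFrame(rows)

    # ------------------------------------------------------------- persistence

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for (ch, name), val in self.network.param_items():
            arrays[f"{ch}__{name}"] = np.asarray(val)
        np.savez_compressed(directory / "weights.npz", **arrays)
        cfg = self.model.config if self.model else LSTMConfig()
        manifest = {
            "channels": self.channels,
            "hidden": cfg.hidden, "dropout": cfg.dropout,
            "learning_rate": cfg.learning_rate, "epochs": cfg.epochs,
            "age_hidden": cfg.age_hidden,
            "scaler_mean": self.scaler.mean, "scaler_sd": self.scaler.sd,
            "seed": self.seed, "loss_history": self.loss_history,
        }
        (directory / "model.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "LSTMResults":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        config = LSTMConfig(hidden=manifest["hidden"],
                            dropout=manifest["dropout"],
                            learning_rate=manifest["learning_rate"],
                            epochs=manifest["epochs"],
                            age_hidden=manifest["age_hidden"])
        channels = manifest["channels"]
        net = _Network(channels, config, np.random.default_rng(0))
        with np.load(directory / "weights.npz") as z:
            for key in z.files:
                ch, name = key.split("__")
                val = z[key]
                net.set_param((ch, name),
                              float(val) if name == "be" else val)
        scaler = Scaler(mean=manifest["scaler_mean"], sd=manifest["scaler_sd"])
        return cls(model=None, network=net, scaler=scaler,
                   loss_history=manifest["loss_history"], seed=manifest["seed"])


# ------------------------------------------------------------------ tuning

DEFAULT_GRID = {"hidden": (4, 8, 16), "dropout": (0.0, 0.2, 0.4)}


def tune(cohort: Cohort, markers=None, grid: dict | None = None,
         base_config: LSTMConfig | None = None, inner_k: int = 10,
         inner_reps: int = 3, seed: int = 0, metric=None) -> LSTMConfig:
    """Inner-loop hyperparameter selection by repeated stratified CV.

    Scores every (hidden, dropout) combination by the mean inner-validation
    AUC (configurable via ``metric(labels, scores)``); ties break toward the
    smaller hidden size, then the lower dropout rate.
    """
    from ..evaluation import auc as auc_metric

    grid = dict(DEFAULT_GRID if grid is None else grid)
    if not grid.get("hidden") or grid.get("dropout") is None:
        raise ValueError("grid needs non-empty 'hidden' and 'dropout' entries")
    metric = metric if metric is not None else auc_metric
    base = base_config if base_config is not None else LSTMConfig()
    labels = cohort.labels
    ids = np.array(cohort.ids)
    splitter = RepeatedStratifiedKFold(n_splits=inner_k, n_repeats=inner_reps,
                                       random_state=seed)
    combos = sorted(itertools.product(grid["hidden"], grid["dropout"]))
    scores = {combo: [] for combo in combos}
    for fold_i, (tr, va) in enumerate(splitter.split(ids, labels)):
        train = cohort.subset_patients(ids[tr])
        valid_ids = ids[va]
        for combo in combos:
            hidden, dropout = combo
            cfg = replace(base, hidden=hidden, dropout=dropout)
            res = LSTMClassifier(train, markers=_resolve_markers(markers, cohort),
                                 config=cfg).fit(seed=seed + fold_i)
            y, s = [], []
            for pid in valid_ids:
                p = cohort[pid]
                if p.n_visits < 2:
                    continue
                y.append(p.status)
                s.append(res.predict_proba(p))
            if len(set(y)) == 2:
                scores[combo].append(metric(np.array(y), np.array(s)))
    means = {combo: np.mean(vals) if vals else -np.inf
             for combo, vals in scores.items()}
    best = max(combos, key=lambda c: (means[c], -c[0], -c[1]))
    return replace(base, hidden=best[0], dropout=best[1])


def _resolve_markers(markers, cohort):
    return list(markers) if markers is not None else list(cohort.biomarker_names)
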