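"""Pseudopopulation decoding of stimulus frequency from spike counts.

Units recorded non-simultaneously are pooled into pseudopopulations of 50
units (sampled with replacement from the responsive pool, trials paired by
repetition index), and an 11-class frequency decoder is trained on the
trials x units spike-count matrix irrespective of SPL.  The decoder is a
one-versus-one error-correcting-output-codes ensemble of linear
maximum-margin (SVM) binary learners; a test observation is assigned the
class minimizing the average binary hinge loss over the learners involving
that class (loss-weighted decoding).  The regularization constant is tuned
by a seeded random search over a log-spaced range with a fixed evaluation
budget.  Shuffled-label runs provide the chance baseline (1/11 ~ 9.1%),
and cross-condition runs (train on one stimulus kind, test on the other)
measure the generalization of the frequency representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .stimuli import StimulusGrid

DEFAULT_WINDOW_MS = (0.0, 50.0)
EARLY_WINDOW_MS = (0.0, 25.0)


def response_tensor(spikes: pd.DataFrame, grid: StimulusGrid, unit_ids: np.ndarray,
                    kind: str, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
                    ) -> np.ndarray:
    """Spike counts per (unit, frequency, SPL, trial) in the decoding window."""
    freqs = np.asarray(grid.center_frequencies)
    spls = np.asarray(grid.spl_levels)
    n_t = grid.repetitions
    uidx = {u: i for i, u in enumerate(unit_ids)}
    fidx = {f: i for i, f in enumerate(freqs)}
    sidx = {s: i for i, s in enumerate(spls)}
    sub = spikes[(spikes["kind"] == kind) & spikes["unit_id"].isin(unit_ids)
                 & (spikes["spike_ms"] >= window_ms[0])
                 & (spikes["spike_ms"] < window_ms[1])]
    tensor = np.zeros((len(unit_ids), len(freqs), len(spls), n_t))
    counts = sub.groupby(["unit_id", "freq_hz", "spl_db", "trial"]).size()
    for (u, f, s, t), c in counts.items():
        if t < n_t:
            tensor[uidx[u], fidx[f], sidx[s], int(t)] = c
    return tensor


@dataclass
class PopulationResponses:
    X: np.ndarray          # (n_trials, n_units) spike counts
    y_freq: np.ndarray     # frequency class per trial (0..n_freq-1)
    y_amp: np.ndarray      # SPL per trial


@dataclass
class Pseudopopulation:
    population_id: int
    unit_rows: np.ndarray                     # sampled row indices into the pool
    unit_ids: np.ndarray                      # corresponding unit identifiers
    kind_data: dict                           # kind -> PopulationResponses
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS


def build_pseudopopulations(tensors: dict, pool_unit_ids: dict,
                            size: int = 50, n_pops: int = 10, seed: int = 0,
                            window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
                            ) -> list[Pseudopopulation]:
    """Sample pseudopopulations of ``size`` units with replacement.

    ``tensors`` maps kind -> (n_pool, n_freq, n_spl, n_trials) count arrays
    (pools may differ between kinds unless cross-condition decoding is
    intended, in which case pass identical pools).  Unit selection is
    unconstrained by CF or C50.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    kinds = list(tensors)
    pool_sizes = {k: tensors[k].shape[0] for k in kinds}
    if any(v == 0 for v in pool_sizes.values()):
        raise ValueError("empty responsive pool")
    shared_pool = all(np.array_equal(pool_unit_ids[k], pool_unit_ids[kinds[0]])
                      for k in kinds)
    pops = []
    for p in range(n_pops):
        if shared_pool:
            draw = rng.integers(0, pool_sizes[kinds[0]], size=size)
            rows = {k: draw for k in kinds}
        else:
            rows = {k: rng.integers(0, pool_sizes[k], size=size) for k in kinds}
        kind_data = {}
        for k in kinds:
            t = tensors[k][rows[k]]                       # (size, n_f, n_s, n_t)
            n_u, n_f, n_s, n_t = t.shape
            X = t.reshape(n_u, -1).T                      # trials x units
            f_lab = np.repeat(np.arange(n_f), n_s * n_t)
            a_lab = np.tile(np.repeat(np.arange(n_s), n_t), n_f)
            kind_data[k] = PopulationResponses(X=X, y_freq=f_lab, y_amp=a_lab)
        first = kinds[0]
        pops.append(Pseudopopulation(
            population_id=p, unit_rows=rows[first],
            unit_ids=np.asarray(pool_unit_ids[first])[rows[first]],
            kind_data=kind_data, window_ms=window_ms))
    return pops


class ECOCLinearSVM:
    """One-vs-one error-correcting-output-codes ensemble of linear SVMs.

    Prediction assigns the class minimizing the average binary hinge loss
    over the learners whose code involves that class (loss-weighted
    decoding), rather than majority voting.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 3000, random_state: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ECOCLinearSVM":
        self.classes_ = np.unique(y)
        self.pairs_ = list(combinations(range(len(self.classes_)), 2))
        self.learners_ = []
        for a, b in self.pairs_:
            mask = (y == self.classes_[a]) | (y == self.classes_[b])
            yb = np.where(y[mask] == self.classes_[b], 1, -1)
            clf = LinearSVC(C=self.C, max_iter=self.max_iter, tol=1e-3,
                            random_state=self.random_state)
            clf.fit(X[mask], yb)
            self.learners_.append(clf)
        return self

    def _losses(self, X: np.ndarray) -> np.ndarray:
        n_classes = len(self.classes_)
        margins = np.column_stack([clf.decision_function(X) for clf in self.learners_])
        loss = np.zeros((X.shape[0], n_classes))
        involved = np.zeros(n_classes)
        for l, (a, b) in enumerate(self.pairs_):
            # hinge loss of the binary score under each class's code (+1 for b, -1 for a)
            loss[:, b] += np.maximum(0.0, 1.0 - margins[:, l]) / 2.0
            loss[:, a] += np.maximum(0.0, 1.0 + margins[:, l]) / 2.0
            involved[a] += 1
            involved[b] += 1
        return loss / involved

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmin(self._losses(X), axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))


def tune_regularization(X: np.ndarray, y: np.ndarray, seed: int = 0,
                        budget: int = 20, c_range: tuple[float, float] = (1e-3, 1e2),
                        val_fraction: float = 0.25) -> float:
    """Seeded random search for the SVM regularization constant."""
    rng = np.random.default_rng(seed)
    cs = 10.0 ** rng.uniform(np.log10(c_range[0]), np.log10(c_range[1]), budget)
    Xtr, Xva, ytr, yva = train_test_split(
        X, y, test_size=val_fraction, stratify=y,
        random_state=int(rng.integers(2**31 - 1)))
    best_c, best_acc = cs[0], -1.0
    for c in cs:
        acc = ECOCLinearSVM(C=c).fit(Xtr, ytr).score(Xva, yva)
        if acc > best_acc:
            best_acc, best_c = acc, c
    return float(best_c)


@dataclass
class DecodingResult:
    population_id: int
    kind: str
    window_ms: tuple[float, float]
    accuracy: float
    per_frequency: pd.Series
    per_frequency_amplitude: pd.DataFrame
    shuffled: bool
    n_test: int
    C: float
    train_kind: str | None = None
    test_kind: str | None = None
    within_cv_accuracy: float | None = None


def decode_frequency(pop: Pseudopopulation, kind: str,
                     test_fraction: float = 1.0 / 3.0, shuffle: bool = False,
                     seed: int = 0, tuning_budget: int = 20) -> DecodingResult:
    """Train/test the 11-class frequency decoder on one pseudopopulation.

    Two-thirds of the trials (stratified by frequency x amplitude) train the
    classifier; accuracy is reported on the held-out third, overall, per
    frequency and per frequency x amplitude.  ``shuffle=True`` permutes the
    frequency labels before splitting, yielding the chance baseline.
    """
    data = pop.kind_data[kind]
    rng = np.random.default_rng(seed)
    y = data.y_freq.copy()
    if shuffle:
        y = rng.permutation(y)
    strat = np.char.add(y.astype(str), np.char.add("_", data.y_amp.astype(str)))
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=strat,
                              random_state=int(rng.integers(2**31 - 1)))
    for split_name, split in (("training", tr), ("test", te)):
        counts = np.bincount(y[split], minlength=len(np.unique(data.y_freq)))
        if (counts < 2).any():
            raise ValueError(f"a frequency class has < 2 trials in the {split_name} split")
    c = tune_regularization(data.X[tr], y[tr], seed=int(rng.integers(2**31 - 1)),
                            budget=tuning_budget)
    clf = ECOCLinearSVM(C=c).fit(data.X[tr], y[tr])
    pred = clf.predict(data.X[te])
    correct = pred == y[te]
    per_freq = pd.Series(correct).groupby(y[te]).mean()
    pfa = (pd.DataFrame({"freq": y[te], "amp": data.y_amp[te], "ok": correct})
           .groupby(["freq", "amp"])["ok"].mean().reset_index()
           .rename(columns={"ok": "accuracy"}))
    return DecodingResult(population_id=pop.population_id, kind=kind,
                          window_ms=pop.window_ms, accuracy=float(correct.mean()),
                          per_frequency=per_freq, per_frequency_amplitude=pfa,
                          shuffled=shuffle, n_test=len(te), C=c)


def cross_condition_decode(pop: Pseudopopulation, train_kind: str, test_kind: str,
                           seed: int = 0, tuning_budget: int = 20,
                           n_folds: int = 5) -> DecodingResult:
    """Train on all trials of one stimulus kind, test on the other.

    Hyperparameters are tuned first on the training condition; the
    within-condition accuracy comes from stratified k-fold cross-validation
    on the training data, and the cross-condition accuracy from applying
    the final model to every trial of the other kind.  Requires a
    pseudopopulation built from units responsive to both kinds on matched
    condition grids.
    """
    if train_kind not in pop.kind_data or test_kind not in pop.kind_data:
        raise ValueError("pseudopopulation lacks one of the requested kinds")
    tr = pop.kind_data[train_kind]
    te = pop.kind_data[test_kind]
    if tr.X.shape != te.X.shape:
        raise ValueError("condition grids are not matched across kinds")
    rng = np.random.default_rng(seed)
    c = tune_regularization(tr.X, tr.y_freq, seed=int(rng.integers(2**31 - 1)),
                            budget=tuning_budget)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    cv_acc = [ECOCLinearSVM(C=c).fit(tr.X[i], tr.y_freq[i]).score(tr.X[j], tr.y_freq[j])
              for i, j in skf.split(tr.X, tr.y_freq)]
    clf = ECOCLinearSVM(C=c).fit(tr.X, tr.y_freq)
    pred = clf.predict(te.X)
    correct = pred == te.y_freq
    per_freq = pd.Series(correct).groupby(te.y_freq).mean()
    pfa = (pd.DataFrame({"freq": te.y_freq, "amp": te.y_amp, "ok": correct})
           .groupby(["freq", "amp"])["ok"].mean().reset_index()
           .rename(columns={"ok": "accuracy"}))
    return DecodingResult(population_id=pop.population_id, kind=test_kind,
                          window_ms=pop.window_ms, accuracy=float(correct.mean()),
                          per_frequency=per_freq, per_frequency_amplitude=pfa,
                          shuffled=False, n_test=int(te.X.shape[0]), C=c,
                          train_kind=train_kind, test_kind=test_kind,
                          within_cv_accuracy=float(np.mean(cv_acc)))
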