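"""Training loop, evaluation protocols and comparator baselines.

Covers: the cross-entropy objective and its Adam minimisation, the
personality-first (PF) per-cluster training scheme, k-fold (pooled,
non-cross-subject) and leave-one-subject-out (LOSO, cross-subject)
protocols, SVM / gradient-boosting baselines on the flattened band
features, and the per-cluster attention report.

Median-split label thresholds are always computed from training-split
ratings only and then applied to the held-out ratings — no test-label
leakage anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import network
from ._autodiff import Tensor, backward
from .clustering import PersonalityProfile, assign_cluster, fit_kmeans
from .preprocessing import (DEFAULT_BANDS, BandSet, FeatureSample, WindowSpec,
                            binarize_labels, build_samples, condition_signal,
                            trial_de_units)

__all__ = [
    "PrepConfig",
    "TrainConfig",
    "EvalResult",
    "FeatureDataset",
    "featurize_dataset",
    "cross_entropy_loss",
    "train_model",
    "evaluate_kfold",
    "evaluate_loso",
    "run_experiment_grid",
    "attention_report",
    "METHODS",
]

PROB_FLOOR = 1e-12

#: method grid of the results tables: two baselines, the network without
#: the channel-weight layer ("-C" ablation) and the full network.
METHODS = ("svm", "gbt", "net_noattn", "net")


@dataclass(frozen=True)
class PrepConfig:
    hp_hz: float = 1.0
    lp_hz: float = 16.0
    window_s: float = 1.0
    step_s: float | None = None      # None -> non-overlapping (= window_s)
    bands: BandSet = DEFAULT_BANDS
    segments_per_sample: int = 9


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    lr: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.0
    patience: int = 25               # early stop on training-loss plateau
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("epochs/batch_size must be >= 1 and lr > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class EvalResult:
    protocol: str                    # "kfold" | "loso"
    axis: str                        # "valence" | "arousal"
    method: str
    pf: bool
    fold_accuracies: list[float]
    mean_accuracy: float
    per_cluster: dict[int, float] | None = None
    n_test: int = 0
    seed: int = 0


@dataclass
class FeatureDataset:
    """Feature samples plus subject metadata, ready for either protocol."""

    samples: list[FeatureSample]
    personalities: dict[str, tuple]
    n_bands: int
    n_channels: int
    n_segments: int

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.personalities)

    def profiles(self, subject_ids=None):
        ids = self.subject_ids if subject_ids is None else subject_ids
        return [PersonalityProfile(s, self.personalities[s]) for s in ids]


def featurize_dataset(recordings, personalities, ratings,
                      prep: PrepConfig = PrepConfig()) -> FeatureDataset:
    """Run every recording through conditioning -> windows -> DE -> samples."""
    samples: list[FeatureSample] = []
    step = prep.step_s if prep.step_s is not None else prep.window_s
    for rec in recordings:
        spec = WindowSpec(width=int(round(prep.window_s * rec.fs)),
                          step=int(round(step * rec.fs)))
        conditioned = condition_signal(rec, prep.hp_hz, prep.lp_hz)
        de_units = trial_de_units(conditioned, spec, prep.bands)
        v, a = ratings[(rec.subject_id, rec.trial_id)]
        samples.extend(build_samples(
            de_units, prep.segments_per_sample,
            subject_id=rec.subject_id, trial_id=rec.trial_id,
            valence=v, arousal=a))
    if not samples:
        raise ValueError("no feature samples produced")
    return FeatureDataset(
        samples=samples,
        personalities=dict(personalities),
        n_bands=len(prep.bands),
        n_channels=samples[0].X.shape[1],
        n_segments=prep.segments_per_sample,
    )


# ----------------------------------------------------------------------- loss

def cross_entropy_loss(probs, labels):
    """Mean negative log-probability of the true class.

    ``probs``: Tensor or array of shape (batch, T), rows summing to 1;
    ``labels``: int array (batch,).  Probabilities below 1e-12 at the
    true class are clamped (with a warning) to keep the loss finite.
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    labels = np.asarray(labels, dtype=int)
    picked = probs[np.arange(len(labels)), labels]
    if np.any(picked.data < PROB_FLOOR):
        warnings.warn("probability at true class below 1e-12; clamped", RuntimeWarning)
    return -(picked.clamp_min(PROB_FLOOR).log().mean())


class _Adam:
    def __init__(self, params: network.ModelParams, lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params: network.ModelParams, lr: float, weight_decay: float = 0.0):
        self.params, self.lr, self.wd = params, lr, weight_decay

    def step(self):
        for p in self.params.values():
            if p.grad is not None:
                p.data -= self.lr * (p.grad + self.wd * p.data)


def train_model(X: np.ndarray, y: np.ndarray, train_config: TrainConfig,
                model_config: network.ModelConfig):
    """Mini-batch gradient descent on the cross-entropy objective.

    ``X``: (n, F, M, N) stacked samples, ``y``: (n,) int labels.
    Returns ``(params, loss_trace)`` with one mean-loss entry per epoch.
    Deterministic given the two seeds (init and shuffling).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set has a single class")
    params = network.init_params(model_config)
    opt_cls = _Adam if train_config.optimizer == "adam" else _SGD
    opt = opt_cls(params, train_config.lr, train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    n = len(y)
    trace: list[float] = []
    best, since_best = np.inf, 0
    for _ in range(train_config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            params.zero_grad()
            _, probs, _ = network.forward_batch(X[idx], params, model_config)
            loss = cross_entropy_loss(probs, y[idx])
            backward(loss)
            opt.step()
            losses.append(float(loss.data) * len(idx))
        epoch_loss = float(np.sum(losses) / n)
        trace.append(epoch_loss)
        if epoch_loss < best - 1e-5:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break
    return params, trace


# ------------------------------------------------------------------ fitting

def _stack_samples(samples, axis: str, threshold: float):
    X = np.stack([s.X for s in samples])
    ratings = np.array([getattr(s, axis) for s in samples])
    y, _ = binarize_labels(ratings, threshold=threshold)
    return X, y


def _train_threshold(samples, axis: str) -> float:
    ratings = np.array([getattr(s, axis) for s in samples])
    _, thr = binarize_labels(ratings)
    return thr


def _fit_predict(method: str, train_samples, test_samples, axis: str,
                 train_config: TrainConfig, model_config: network.ModelConfig):
    """Train one method and predict the test samples.

    Returns ``(y_true, y_pred, artifacts)``; the median threshold comes
    from the training ratings only.
    """
    thr = _train_threshold(train_samples, axis)
    Xtr, ytr = _stack_samples(train_samples, axis, thr)
    Xte, yte = _stack_samples(test_samples, axis, thr)
    artifacts: dict = {"threshold": thr}
    if method in ("net", "net_noattn"):
        cfg = replace(model_config, use_channel_attention=(method == "net"))
        params, trace = train_model(Xtr, ytr, train_config, cfg)
        probs = network.predict_proba(Xte, params, cfg)
        pred = probs.argmax(axis=1)
        artifacts.update(params=params, config=cfg, loss_trace=trace)
    elif method in ("svm", "gbt"):
        Ftr = Xtr.reshape(len(Xtr), -1)
        Fte = Xte.reshape(len(Xte), -1)
        if method == "svm":
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler
            from sklearn.svm import SVC
            clf = make_pipeline(StandardScaler(), SVC(random_state=train_config.seed))
        else:
            # gradient-boosted trees: stand-in for the XGBoost comparator
            from sklearn.ensemble import HistGradientBoostingClassifier
            clf = HistGradientBoostingClassifier(random_state=train_config.seed,
                                                 max_iter=60)
        clf.fit(Ftr, ytr)
        pred = clf.predict(Fte)
        artifacts["clf"] = clf
    else:
        raise ValueError(f"unknown method {method!r}")
    return yte, np.asarray(pred), artifacts


def _accuracy(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


# --------------------------------------------------------------- k-fold (CV)

def evaluate_kfold(fdata: FeatureDataset, axis: str, method: str, k: int = 10,
                   pf: bool = False, n_clusters: int = 5,
                   train_config: TrainConfig = TrainConfig(),
                   model_config: network.ModelConfig | None = None,
                   seed: int = 0, subject_stratified: bool = False) -> EvalResult:
    """Pooled-sample k-fold CV (the non-cross-subject protocol).

    PF mode clusters the subjects' personalities once (every subject has
    training samples in every round of this protocol), trains one model
    per cluster on that cluster's training-fold samples and scores each
    test sample with its subject's cluster model; the fold accuracy is
    the subject-group average.
    """
    model_config = model_config or _default_model_config(fdata, seed)
    samples = fdata.samples
    n = len(samples)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    rng = np.random.default_rng(seed)
    if subject_stratified:
        subjects = fdata.subject_ids
        perm = rng.permutation(len(subjects))
        fold_of_subject = {subjects[p]: i % k for i, p in enumerate(perm)}
        fold_idx = [[i for i, s in enumerate(samples)
                     if fold_of_subject[s.subject_id] == f] for f in range(k)]
    else:
        fold_idx = [list(part) for part in np.array_split(rng.permutation(n), k)]

    cluster_of = None
    if pf:
        cfit = fit_kmeans(fdata.profiles(), n_clusters, seed=seed)
        cluster_of = cfit.assignment

    accs: list[float] = []
    cluster_hits: dict[int, list[float]] = {}
    n_test = 0
    for f in range(k):
        test_i = set(fold_idx[f])
        train = [s for i, s in enumerate(samples) if i not in test_i]
        test = [samples[i] for i in sorted(test_i)]
        if not test:
            continue
        n_test += len(test)
        if not pf:
            yt, yp, _ = _fit_predict(method, train, test, axis, train_config, model_config)
            accs.append(_accuracy(yt, yp))
            continue
        group_accs = []
        for c in sorted(set(cluster_of.values())):
            tr_c = [s for s in train if cluster_of[s.subject_id] == c]
            te_c = [s for s in test if cluster_of[s.subject_id] == c]
            if not te_c:
                continue
            if not tr_c:
                warnings.warn(f"cluster {c} has no training samples in fold {f}; "
                              "falling back to pooled training set", RuntimeWarning)
                tr_c = train
            yt, yp, _ = _fit_predict(method, tr_c, te_c, axis, train_config, model_config)
            acc = _accuracy(yt, yp)
            group_accs.append(acc)
            cluster_hits.setdefault(c, []).append(acc)
        accs.append(float(np.mean(group_accs)))
    return EvalResult(
        protocol="kfold", axis=axis, method=method, pf=pf,
        fold_accuracies=accs, mean_accuracy=float(np.mean(accs)),
        per_cluster={c: float(np.mean(v)) for c, v in cluster_hits.items()} or None,
        n_test=n_test, seed=seed)


# ---------------------------------------------------------------------- LOSO

def evaluate_loso(fdata: FeatureDataset, axis: str, method: str,
                  pf: bool = False, n_clusters: int = 5,
                  train_config: TrainConfig = TrainConfig(),
                  model_config: network.ModelConfig | None = None,
                  seed: int = 0, collect_models: bool = False) -> EvalResult:
    """Leave-one-subject-out (the cross-subject protocol).

    PF mode, per held-out subject: k-means is fitted on the remaining
    subjects' personalities only, the held-out subject is routed to its
    nearest centroid, and a model trained on that cluster's subjects
    scores it.  A routed cluster with no training subjects falls back to
    the pooled model with a warning.
    """
    model_config = model_config or _default_model_config(fdata, seed)
    subjects = fdata.subject_ids
    if pf:
        by_cluster_count = len(subjects) - 1
        if n_clusters > by_cluster_count:
            raise ValueError("n_clusters exceeds training subjects in LOSO round")
    per_subject: list[float] = []
    cluster_hits: dict[int, list[float]] = {}
    models: list[dict] = []
    n_test = 0
    for held_out in subjects:
        test = [s for s in fdata.samples if s.subject_id == held_out]
        train = [s for s in fdata.samples if s.subject_id != held_out]
        if not test:
            continue
        n_test += len(test)
        routed = None
        if pf:
            train_ids = [s for s in subjects if s != held_out]
            cfit = fit_kmeans(fdata.profiles(train_ids), n_clusters, seed=seed)
            routed = assign_cluster(
                cfit, PersonalityProfile(held_out, fdata.personalities[held_out]))
            cluster_train = [s for s in train if cfit.assignment[s.subject_id] == routed]
            if not cluster_train:
                warnings.warn(
                    f"routed cluster {routed} empty for {held_out}; "
                    "falling back to pooled model", RuntimeWarning)
            else:
                train = cluster_train
        yt, yp, art = _fit_predict(method, train, test, axis, train_config, model_config)
        acc = _accuracy(yt, yp)
        per_subject.append(acc)
        if routed is not None:
            cluster_hits.setdefault(routed, []).append(acc)
        if collect_models:
            models.append({"subject": held_out, "cluster": routed, **art})
    result = EvalResult(
        protocol="loso", axis=axis, method=method, pf=pf,
        fold_accuracies=per_subject, mean_accuracy=float(np.mean(per_subject)),
        per_cluster={c: float(np.mean(v)) for c, v in cluster_hits.items()} or None,
        n_test=n_test, seed=seed)
    if collect_models:
        result.models = models  # type: ignore[attr-defined]
    return result


def _default_model_config(fdata: FeatureDataset, seed: int) -> network.ModelConfig:
    return network.ModelConfig(
        n_bands=fdata.n_bands, n_channels=fdata.n_channels,
        n_segments=fdata.n_segments, seed=seed)


# ----------------------------------------------------------------- the grid

def run_experiment_grid(fdata: FeatureDataset, protocol: str,
                        methods=METHODS, pf_modes=(False, True),
                        axes=("valence", "arousal"), k: int = 10,
                        n_clusters: int = 5,
                        train_config: TrainConfig = TrainConfig(),
                        model_config: network.ModelConfig | None = None,
                        seed: int = 0):
    """Run the full methods x PF grid for both axes on one protocol.

    Returns a list of EvalResult (or error records); a failing cell is
    recorded and skipped, it does not abort the grid.
    """
    results = []
    for axis in axes:
        for pf in pf_modes:
            for method in methods:
                try:
                    if protocol == "kfold":
                        res = evaluate_kfold(
                            fdata, axis, method, k=k, pf=pf, n_clusters=n_clusters,
                            train_config=train_config, model_config=model_config,
                            seed=seed)
                    elif protocol == "loso":
                        res = evaluate_loso(
                            fdata, axis, method, pf=pf, n_clusters=n_clusters,
                            train_config=train_config, model_config=model_config,
                            seed=seed)
                    else:
                        raise ValueError(f"unknown protocol {protocol!r}")
                    results.append(res)
                except Exception as exc:  # record, keep the rest of the grid
                    results.append({"protocol": protocol, "axis": axis,
                                    "method": method, "pf": pf, "error": repr(exc)})
    return results


def results_table(results):
    """Tables-2/3-shaped DataFrame: rows = axis, columns = (pf, method)."""
    import pandas as pd

    rows = {}
    for res in results:
        if isinstance(res, dict):
            axis, key, val = res["axis"], (res["pf"], res["method"]), np.nan
        else:
            axis, key, val = res.axis, (res.pf, res.method), res.mean_accuracy * 100
        rows.setdefault(axis, {})[key] = val
    cols = [(pf, m) for pf in (False, True) for m in METHODS]
    table = pd.DataFrame(
        {("PF" if pf else "noPF", m): {a: rows.get(a, {}).get((pf, m), np.nan)
                                       for a in rows}
         for pf, m in cols})
    return table


# ------------------------------------------------------------- attention

def attention_report(models: list[dict], probe_samples_by_cluster: dict):
    """Mean attention matrix and channel importance per cluster.

    ``models``: records with keys cluster/params/config (as collected by
    ``evaluate_loso(..., collect_models=True)``).  Probe samples are run
    through each cluster's models; W is averaged over samples, segments
    and models.  Channel importance is the mean total weight a channel's
    embedding receives across output slots (row mass of W, scaled by
    1/M).  Raises on no-attention models.
    """
    by_cluster: dict[int, list] = {}
    for rec in models:
        cfg = rec.get("config")
        if cfg is None or "params" not in rec:
            raise ValueError("attention_report needs network models with parameters")
        if not cfg.use_channel_attention:
            raise ValueError("attention_report is undefined for no-attention models")
        by_cluster.setdefault(rec["cluster"], []).append(rec)

    report = {}
    for c, recs in sorted(by_cluster.items()):
        probes = probe_samples_by_cluster.get(c)
        if not probes:
            continue
        X = np.stack([s.X for s in probes])
        Ws = []
        for rec in recs:
            _, W = network.predict_proba(X, rec["params"], rec["config"],
                                         return_attention=True)
            Ws.append(W.reshape(-1, W.shape[-2], W.shape[-1]))
        mean_W = np.concatenate(Ws).mean(axis=0)
        importance = mean_W.mean(axis=1)  # row mass / M
        report[c] = {"mean_W": mean_W, "importance": importance}
    return report
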