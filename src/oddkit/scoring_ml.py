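"""Reproducible scoring-function machinery.

Model kinds: multiple linear regression (exact least squares), partial least
squares, random forests, support vector machines, and single/multi-layer
neural networks (sklearn backends for the latter four). Every stochastic
kind takes a mandatory seed and retraining with identical inputs and seed
reproduces predictions exactly. Trained models persist to a versioned,
checksummed container and refuse descriptor vectors that do not match their
training descriptors.

Virtual-screening metrics: Pearson r, ROC AUC (rank-statistic form with tie
correction), semi-log ROC AUC (area under TPR vs log10 FPR over [λ, 1],
normalized so a perfect ranking scores 1), and the enrichment factor at a
fraction of the ranked list. k-fold and leave-one-out cross-validation use a
seeded shuffle and report per-fold correlation mean and spread.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import ConfigError, DescriptorMismatchError, IntegrityError, VersionError

__all__ = [
    "ModelSpec",
    "ScoringModel",
    "EvalReport",
    "train",
    "predict",
    "save_model",
    "load_model",
    "kfold_cv",
    "pearson_r",
    "roc_auc",
    "semilog_roc_auc",
    "enrichment_factor",
]

MODEL_KINDS = ("mlr", "pls", "rf", "svm", "nn_single", "nn_multi")
_STOCHASTIC = {"rf", "nn_single", "nn_multi"}
_MIN_ROWS = {"mlr": 2, "pls": 3, "rf": 2, "svm": 2, "nn_single": 5, "nn_multi": 5}

FORMAT_MAGIC = b"ODDKITSF"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    seed: int | None = None
    task: str = "regress"            # regress | classify
    hyperparameters: tuple = ()      # sorted (name, value) pairs

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.kind!r}")
        if self.task not in ("regress", "classify"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.kind in _STOCHASTIC and self.seed is None:
            raise ConfigError(f"kind {self.kind!r} is stochastic: seed is mandatory")
        _validate_hp(self.kind, dict(self.hyperparameters))

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)

    @classmethod
    def make(cls, kind: str, seed: int | None = None, task: str = "regress",
             **hyperparameters) -> "ModelSpec":
        return cls(kind=kind, seed=seed, task=task,
                   hyperparameters=tuple(sorted(hyperparameters.items())))


_HP_ALLOWED = {
    "mlr": set(),
    "pls": {"components"},
    "rf": {"trees", "max_depth"},
    "svm": {"c", "epsilon", "gamma"},
    "nn_single": {"hidden", "alpha", "max_iter"},
    "nn_multi": {"hidden_sizes", "alpha", "max_iter"},
}


def _validate_hp(kind: str, hp: dict) -> None:
    unknown = set(hp) - _HP_ALLOWED[kind]
    if unknown:
        raise ConfigError(f"hyperparameters {sorted(unknown)} not valid for {kind!r}")
    if kind == "pls" and hp.get("components", 2) < 1:
        raise ConfigError("pls needs components >= 1")
    if kind == "rf" and hp.get("trees", 100) < 1:
        raise ConfigError("rf needs trees >= 1")


class _MLRModel:
    """Minimum-norm least squares with classic coefficient standard errors."""

    def __init__(self):
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0
        self.stderr_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        A = np.hstack([X, np.ones((n, 1))])
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p + 1:
            warnings.warn("rank-deficient design: minimum-norm solution used",
                          stacklevel=2)
        self.coef_ = beta[:-1]
        self.intercept_ = float(beta[-1])
        resid = y - A @ beta
        dof = max(n - rank, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.pinv(A.T @ A)
        self.stderr_ = np.sqrt(np.diag(cov))[:-1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_ + self.intercept_


def _build_backend(spec: ModelSpec):
    hp = spec.hp
    kind, task = spec.kind, spec.task
    if kind == "mlr":
        return _MLRModel()
    if kind == "pls":
        return PLSRegression(n_components=hp.get("components", 2))
    if kind == "rf":
        cls = RandomForestClassifier if task == "classify" else RandomForestRegressor
        return cls(n_estimators=hp.get("trees", 100),
                   max_depth=hp.get("max_depth"), random_state=spec.seed, n_jobs=1)
    # SVM and neural nets are scale-sensitive: descriptors are standardized
    # inside the model so contact counts (mean ~20) train as well as bits.
    if kind == "svm":
        if task == "classify":
            est = SVC(C=hp.get("c", 1.0), gamma=hp.get("gamma", "scale"))
        else:
            est = SVR(C=hp.get("c", 1.0), epsilon=hp.get("epsilon", 0.1),
                      gamma=hp.get("gamma", "scale"))
        return make_pipeline(StandardScaler(), est)
    if kind == "nn_single":
        cls = MLPClassifier if task == "classify" else MLPRegressor
        est = cls(hidden_layer_sizes=(hp.get("hidden", 64),),
                  alpha=hp.get("alpha", 1e-4), max_iter=hp.get("max_iter", 2000),
                  solver="lbfgs", random_state=spec.seed)
        return make_pipeline(StandardScaler(), est)
    if kind == "nn_multi":
        cls = MLPClassifier if task == "classify" else MLPRegressor
        est = cls(hidden_layer_sizes=tuple(hp.get("hidden_sizes", (64, 32))),
                  alpha=hp.get("alpha", 1e-4), max_iter=hp.get("max_iter", 2000),
                  solver="lbfgs", random_state=spec.seed)
        return make_pipeline(StandardScaler(), est)
    raise ConfigError(f"unknown kind {kind!r}")


@dataclass
class ScoringModel:
    spec: ModelSpec
    backend: object
    descriptor_generator: str
    n_features: int
    training_meta: dict = field(default_factory=dict)

    def predict(self, X, generator_id: str | None = None) -> np.ndarray:
        return predict(self, X, generator_id=generator_id)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def train(spec: ModelSpec, X, y, descriptor_generator: str = "custom") -> ScoringModel:
    """Fit a scoring model; identical inputs + seed reproduce it exactly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ConfigError("X must be 2-D with one row per target")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ConfigError("non-finite values in training data")
    if X.shape[0] < _MIN_ROWS[spec.kind]:
        raise ConfigError(f"{spec.kind} needs at least {_MIN_ROWS[spec.kind]} rows")
    backend = _build_backend(spec)
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        if spec.task == "classify":
            backend.fit(X, y.astype(int))
        else:
            backend.fit(X, y)
    return ScoringModel(spec=spec, backend=backend,
                        descriptor_generator=descriptor_generator,
                        n_features=X.shape[1],
                        training_meta={"n": int(X.shape[0]),
                                       "data_hash": _data_hash(X, y)})


def predict(model: ScoringModel, X, generator_id: str | None = None) -> np.ndarray:
    """Deterministic scores for a descriptor matrix matching the training one."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.n_features:
        raise DescriptorMismatchError(
            f"model was trained on {model.n_features} features "
            f"({model.descriptor_generator}); got {X.shape[1]}")
    if generator_id is not None and generator_id != model.descriptor_generator:
        raise DescriptorMismatchError(
            f"model expects descriptors from {model.descriptor_generator!r}, "
            f"got {generator_id!r}")
    out = model.backend.predict(X)
    return np.asarray(out, dtype=float).reshape(-1)


# ---------------------------------------------------------------------------
# Persistence: magic + version + schema-checked JSON header + checksummed body
# ---------------------------------------------------------------------------

def save_model(model: ScoringModel, path) -> None:
    payload = pickle.dumps(model.backend, protocol=4)
    header = {
        "format_version": FORMAT_VERSION,
        "spec": {"kind": model.spec.kind, "seed": model.spec.seed,
                 "task": model.spec.task,
                 "hyperparameters": list(model.spec.hyperparameters)},
        "descriptor_generator": model.descriptor_generator,
        "n_features": model.n_features,
        "training_meta": model.training_meta,
        "payload_sha256": hashlib.sha256(payload).hexdigest(),
    }
    hdr = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(FORMAT_MAGIC)
        fh.write(struct.pack("<I", len(hdr)))
        fh.write(hdr)
        fh.write(payload)


def load_model(path) -> ScoringModel:
    """Load a persisted model; corrupt or truncated files never yield a
    partial model, and a newer format version raises :class:`VersionError`."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < len(FORMAT_MAGIC) + 4 or not blob.startswith(FORMAT_MAGIC):
        raise IntegrityError("not a scoring-model file (bad magic)")
    (hdr_len,) = struct.unpack_from("<I", blob, len(FORMAT_MAGIC))
    off = len(FORMAT_MAGIC) + 4
    if off + hdr_len > len(blob):
        raise IntegrityError("truncated model file header")
    try:
        header = json.loads(blob[off:off + hdr_len])
    except json.JSONDecodeError as e:
        raise IntegrityError(f"corrupt model header: {e}") from None
    required = {"format_version", "spec", "descriptor_generator", "n_features",
                "payload_sha256"}
    if not required <= set(header):
        raise IntegrityError(f"model header missing fields {sorted(required - set(header))}")
    if header["format_version"] > FORMAT_VERSION:
        raise VersionError(f"model format version {header['format_version']} "
                           f"is newer than supported {FORMAT_VERSION}")
    payload = blob[off + hdr_len:]
    if hashlib.sha256(payload).hexdigest() != header["payload_sha256"]:
        raise IntegrityError("model payload checksum mismatch")
    try:
        backend = pickle.loads(payload)
    except Exception as e:  # corrupt but checksum-valid payloads are impossible
        raise IntegrityError(f"cannot deserialize model payload: {e}") from None
    s = header["spec"]
    spec = ModelSpec(kind=s["kind"], seed=s["seed"], task=s["task"],
                     hyperparameters=tuple((k, _detuple(v)) for k, v in s["hyperparameters"]))
    return ScoringModel(spec=spec, backend=backend,
                        descriptor_generator=header["descriptor_generator"],
                        n_features=header["n_features"],
                        training_meta=header.get("training_meta", {}))


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def pearson_r(a, b) -> float:
    """Pearson correlation; 0 (with a warning) when either side is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("correlation undefined for constant input; reporting 0",
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    pos = int(labels.sum())
    neg = len(labels) - pos
    if pos == 0 or neg == 0:
        raise ConfigError("need at least one positive and one negative label")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """ROC AUC as the rank statistic P(s+ > s-) + ½ P(tie).

    Computed from midranks (Mann–Whitney form), which handles ties exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = _check_labels(labels)
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - pos * (pos + 1) / 2
    return float(u / (pos * neg))


def _roc_curve(scores: np.ndarray, labels: np.ndarray):
    """Step-ROC points (fpr, tpr) at every distinct threshold, ties grouped."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(l)[idx]
    fp = (idx + 1) - tp
    pos = labels.sum()
    neg = len(labels) - pos
    fpr = np.r_[0.0, fp / neg]
    tpr = np.r_[0.0, tp / pos]
    return fpr, tpr


def semilog_roc_auc(scores, labels, lam: float = 0.001) -> float:
    """Early-recognition AUC: ∫ TPR d(log10 FPR) over [λ, 1] / (−log10 λ).

    The empirical ROC is interpolated at λ and integrated trapezoidally on
    the log-FPR axis; a perfect ranking scores exactly 1.
    """
    if not 0 < lam < 1:
        raise ConfigError("lambda must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    fpr, tpr = _roc_curve(scores, labels)
    # interpolate TPR at λ and clip the curve to [λ, 1]
    tpr_lam = float(np.interp(lam, fpr, tpr))
    keep = fpr > lam
    fx = np.r_[lam, fpr[keep]]
    fy = np.r_[tpr_lam, tpr[keep]]
    if fx[-1] < 1.0:
        fx = np.r_[fx, 1.0]
        fy = np.r_[fy, 1.0]
    area = np.trapezoid(fy, np.log10(fx))
    return float(area / -np.log10(lam))


def enrichment_factor(scores, labels, fraction: float) -> float:
    """EF@x: (actives in the top ceil(x·n)) / (top size) ÷ (actives / n).

    The top set is taken from a descending stable sort, so tied scores break
    by input order — the documented tie policy.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(scores)
    n_act = int(labels.sum())
    if n_act == 0:
        raise ConfigError("no actives in label set")
    top = int(np.ceil(fraction * n))
    order = np.argsort(-scores, kind="stable")
    hits = int(labels[order[:top]].sum())
    return float((hits / top) / (n_act / n))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    r_mean: float
    r_sd: float
    per_fold_r: list[float]
    fold_sizes: list[int]
    predictions: np.ndarray
    seed: int

    def __post_init__(self):
        assert -1.0 - 1e-12 <= self.r_mean <= 1.0 + 1e-12


def kfold_cv(spec: ModelSpec, X, y, k: int, seed: int,
             descriptor_generator: str = "custom") -> EvalReport:
    """Seeded k-fold cross-validation; ``k = n`` reduces to leave-one-out.

    Rows are shuffled once with the seed, split into folds whose sizes differ
    by at most one, and each row is predicted exactly once by a model trained
    on the other folds. Per-fold Pearson r (0 for degenerate single-row or
    constant folds) is summarized as mean and standard deviation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ConfigError(f"k={k} must satisfy 2 <= k <= n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    preds = np.empty(n, dtype=float)
    per_fold_r = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = train(spec, X[mask], y[mask], descriptor_generator=descriptor_generator)
        p = predict(model, X[fold])
        preds[fold] = p
        if len(fold) >= 2 and np.std(y[fold]) > 0 and np.std(p) > 0:
            per_fold_r.append(pearson_r(p, y[fold]))
        else:
            per_fold_r.append(0.0)
    return EvalReport(r_mean=float(np.mean(per_fold_r)),
                      r_sd=float(np.std(per_fold_r)),
                      per_fold_r=per_fold_r,
                      fold_sizes=[len(f) for f in folds],
                      predictions=preds, seed=seed)
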