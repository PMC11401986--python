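"""Two-layer confidence scoring of single-cell genotype calls (RF-GDA).

The scorer assigns every genotype call a posterior probability of being
correct, from its MA intensity features alone:

1. **First layer — random forest.**  An ensemble trained on labelled calls
   (here: simulated batches with known ground truth) predicts, per call,
   the probability that the called genotype matches the template.

2. **Second layer — per-individual Gaussian discriminant analysis.**  For
   each individual separately, calls the forest is confident about
   (probability >= ``p_hi`` as positives, <= ``p_lo`` as negatives) seed a
   two-class generative model: one full-covariance Gaussian per class over
   the feature vector, priors from the seed counts.  The final score is
   the posterior

       rfgda_score = pi+ N(f | mu+, S+) / sum_k pi_k N(f | mu_k, S_k)

   Fitting per individual rather than on the pooled batch keeps one
   outlier-ridden cell from biasing everyone else's scoring function;
   individuals with too few confident calls in either class fall back to
   a pooled layer fitted on all individuals together (flagged in the
   model's provenance).

Covariances are maximum-likelihood estimates regularized as S + ridge*I.
All randomness sits behind one seed; scoring is fully deterministic.
No-call records receive a score for diagnostics but are never converted
back into a called genotype.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.ensemble import RandomForestClassifier

from .errors import ModelError, ParameterError

DEFAULT_FEATURES = ("m", "a", "m_raw", "a_raw")

_MODEL_MAGIC = b"RFGDA"
_MODEL_VERSION = 1


@dataclass
class RFLayer:
    """Trained random-forest first layer."""

    forest: RandomForestClassifier
    features: tuple[str, ...]
    seed: int

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Probability each call is correct, in [0, 1]."""
        X = _feature_matrix(table, self.features)
        # column of the True class
        idx = int(np.where(self.forest.classes_)[0][0])
        return self.forest.predict_proba(X)[:, idx]


@dataclass
class GaussianClass:
    mean: np.ndarray
    cov: np.ndarray
    prior: float

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        return multivariate_normal(self.mean, self.cov).logpdf(X)


@dataclass
class GDALayer:
    """Two-class (correct vs error) Gaussian discriminant for one individual."""

    pos: GaussianClass
    neg: GaussianClass
    pooled: bool = False  # True when this is the shared fallback layer

    def posterior(self, X: np.ndarray) -> np.ndarray:
        lp = np.log(self.pos.prior) + self.pos.logpdf(X)
        ln = np.log(self.neg.prior) + self.neg.logpdf(X)
        lp = np.atleast_1d(lp)
        ln = np.atleast_1d(ln)
        return np.exp(lp - logsumexp(np.stack([lp, ln]), axis=0))


@dataclass
class RFGDAModel:
    """First-layer forest plus the per-individual second layers."""

    rf: RFLayer
    gda: dict[str, GDALayer]
    pooled: GDALayer | None
    features: tuple[str, ...]
    provenance: dict = field(default_factory=dict)


def _feature_matrix(table: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ParameterError(f"table missing feature columns {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ParameterError("non-finite values in feature columns")
    return X


def train_rf(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    n_estimators: int = 100,
    max_depth: int | None = 12,
    seed: int = 0,
) -> RFLayer:
    """Fit the first-layer forest on labelled calls.

    ``labels`` is a boolean vector aligned to ``table`` rows: True when the
    called genotype equals the (known) template genotype.
    """
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(table):
        raise ParameterError("labels length does not match table")
    if len(np.unique(y)) < 2:
        raise ModelError("training labels contain a single class")
    X = _feature_matrix(table, features)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        random_state=seed, n_jobs=1,
    )
    forest.fit(X, y)
    return RFLayer(forest, tuple(features), seed)


def _fit_class(X: np.ndarray, ridge: float) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    centred = X - mean
    cov = centred.T @ centred / len(X)  # ML estimate (divide by n)
    cov += ridge * np.eye(cov.shape[0])
    return mean, cov


def fit_gda(
    table: pd.DataFrame,
    rf_prob: np.ndarray,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    p_hi: float = 0.9,
    p_lo: float = 0.15,
    ridge: float = 1e-6,
    min_count: int = 200,
) -> tuple[dict[str, GDALayer], GDALayer | None, list[str]]:
    """Fit the per-individual second layers from forest-confident calls.

    Returns ``(layers, pooled_layer, fallback_individuals)``.  Individuals
    whose positive or negative seed set is smaller than ``min_count`` map
    to the pooled layer; if even the pooled seed sets are too small a
    :class:`ModelError` is raised.
    """
    if not p_lo < p_hi:
        raise ParameterError(f"need p_lo < p_hi, got {p_lo} >= {p_hi}")
    if "individual" not in table.columns:
        raise ParameterError("table missing 'individual' column")
    rf_prob = np.asarray(rf_prob, dtype=float)
    if len(rf_prob) != len(table):
        raise ParameterError("rf_prob length does not match table")

    X = _feature_matrix(table, features)
    pos_mask = rf_prob >= p_hi
    neg_mask = rf_prob <= p_lo
    individuals = table["individual"].to_numpy()

    def _layer(sel_pos: np.ndarray, sel_neg: np.ndarray,
               pooled: bool) -> GDALayer | None:
        n_pos, n_neg = int(sel_pos.sum()), int(sel_neg.sum())
        if n_pos < min_count or n_neg < min_count:
            return None
        mu_p, cov_p = _fit_class(X[sel_pos], ridge)
        mu_n, cov_n = _fit_class(X[sel_neg], ridge)
        total = n_pos + n_neg
        return GDALayer(
            GaussianClass(mu_p, cov_p, n_pos / total),
            GaussianClass(mu_n, cov_n, n_neg / total),
            pooled=pooled,
        )

    pooled = _layer(pos_mask, neg_mask, pooled=True)
    layers: dict[str, GDALayer] = {}
    fallbacks: list[str] = []
    for ind in pd.unique(individuals):
        sel = individuals == ind
        layer = _layer(pos_mask & sel, neg_mask & sel, pooled=False)
        if layer is None:
            if pooled is None:
                raise ModelError(
                    f"individual {ind!r} lacks {min_count} confident calls "
                    "per class and no pooled fallback could be fitted"
                )
            fallbacks.append(str(ind))
            layer = pooled
        layers[str(ind)] = layer
    if pooled is None and not layers:
        raise ModelError("no individual produced enough confident calls")
    return layers, pooled, fallbacks


def train_model(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    n_estimators: int = 100,
    max_depth: int | None = 12,
    p_hi: float = 0.9,
    p_lo: float = 0.15,
    ridge: float = 1e-6,
    min_count: int = 200,
    seed: int = 0,
) -> RFGDAModel:
    """End-to-end training: forest on labelled calls, then per-individual GDA."""
    rf = train_rf(table, labels, features, n_estimators, max_depth, seed)
    prob = rf.predict_proba(table)
    layers, pooled, fallbacks = fit_gda(
        table, prob, features, p_hi, p_lo, ridge, min_count
    )
    return RFGDAModel(
        rf=rf, gda=layers, pooled=pooled, features=tuple(features),
        provenance={
            "seed": seed, "p_hi": p_hi, "p_lo": p_lo, "ridge": ridge,
            "min_count": min_count, "n_estimators": n_estimators,
            "max_depth": max_depth, "pooled_fallback_individuals": fallbacks,
        },
    )


def refit_gda(model: RFGDAModel, table: pd.DataFrame) -> RFGDAModel:
    """Fit fresh per-individual second layers for a new batch, reusing the
    trained first-layer forest.

    This is the deployment path: the forest generalizes across batches,
    while the Gaussian layers are always estimated on the batch being
    scored so they adapt to its individuals.
    """
    prob = model.rf.predict_proba(table)
    p = model.provenance
    layers, pooled, fallbacks = fit_gda(
        table, prob, model.features,
        p.get("p_hi", 0.9), p.get("p_lo", 0.15),
        p.get("ridge", 1e-6), p.get("min_count", 200),
    )
    prov = dict(p)
    prov["pooled_fallback_individuals"] = fallbacks
    return RFGDAModel(model.rf, layers, pooled, model.features, prov)


def score(table: pd.DataFrame, model: RFGDAModel) -> pd.DataFrame:
    """Append the ``rfgda_score`` posterior column.

    Every row is scored, no-calls included; individuals unseen at fit time
    use the pooled layer when available.
    """
    X = _feature_matrix(table, model.features)
    out = table.copy()
    scores = np.empty(len(table), dtype=float)
    individuals = table["individual"].to_numpy()
    for ind in pd.unique(individuals):
        layer = model.gda.get(str(ind), model.pooled)
        if layer is None:
            raise ModelError(
                f"individual {ind!r} has no fitted layer and no pooled fallback"
            )
        sel = individuals == ind
        scores[sel] = layer.posterior(X[sel])
    out["rfgda_score"] = scores
    return out


def save_model(model: RFGDAModel, path: str | Path) -> Path:
    """Serialize a model (magic + version byte + pickle payload)."""
    payload = pickle.dumps({
        "features": model.features,
        "rf": model.rf,
        "gda": model.gda,
        "pooled": model.pooled,
        "provenance": model.provenance,
    })
    path = Path(path)
    path.write_bytes(_MODEL_MAGIC + bytes([_MODEL_VERSION]) + payload)
    return path


def load_model(path: str | Path) -> RFGDAModel:
    buf = Path(path).read_bytes()
    if buf[:5] != _MODEL_MAGIC:
        raise ModelError(f"{path}: not an RF-GDA model file")
    if buf[5] != _MODEL_VERSION:
        raise ModelError(
            f"{path}: model format version {buf[5]} is incompatible with "
            f"this release (expected {_MODEL_VERSION})"
        )
    try:
        d = pickle.loads(buf[6:])
        return RFGDAModel(
            rf=d["rf"], gda=d["gda"], pooled=d["pooled"],
            features=tuple(d["features"]), provenance=d["provenance"],
        )
    except ModelError:
        raise
    except Exception as e:
        raise ModelError(f"{path}: corrupted model file ({e})") from e
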