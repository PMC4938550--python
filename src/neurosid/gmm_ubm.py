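"""Diagonal-covariance GMM-UBM classifier.

A universal background model (UBM) is fitted by EM on the pooled training
features of all enrolled speakers; each speaker's model is then derived by
MAP adaptation of the component means only (weights and variances are
shared with the UBM). Identification picks the speaker model with the
maximum total log-likelihood of the test feature matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


@dataclass
class GMMModel:
    """A diagonal-covariance Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < 0).any():
            raise ValueError("weights must be a probability simplex")
        if (self.variances <= 0).any():
            raise ValueError("variances must be strictly positive")
        if not (self.weights.shape[0] == self.means.shape[0] == self.variances.shape[0]):
            raise ValueError("component counts disagree")

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class SpeakerModelSet:
    """A UBM plus per-speaker MAP-adapted models (means-only adaptation)."""

    ubm: GMMModel
    speakers: list  # ordered (speaker_id, GMMModel) pairs
    relevance: float = 16.0


def _log_component_liks(model: GMMModel, data: np.ndarray) -> np.ndarray:
    """(n_frames, M) matrix of log w_k + log N(x_t; mu_k, diag sigma2_k)."""
    d = model.dim
    const = -0.5 * (d * np.log(2 * np.pi) + np.sum(np.log(model.variances), axis=1))
    diff = data[:, None, :] - model.means[None, :, :]
    mahal = np.sum(diff**2 / model.variances[None, :, :], axis=2)
    return np.log(model.weights)[None, :] + const[None, :] - 0.5 * mahal


def loglik(model: GMMModel, data: np.ndarray) -> float:
    """Total log-likelihood (nats) of ``data`` under the mixture,
    computed with log-sum-exp stabilisation."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[1] != model.dim:
        raise ValueError("feature dimension mismatch")
    return float(np.sum(logsumexp(_log_component_liks(model, data), axis=1)))


def em_fit(data: np.ndarray, n_components: int = 128, seed: int = 0,
           max_iter: int = 100, rel_tol: float = 1e-4,
           var_floor_frac: float = 1e-3) -> GMMModel:
    """Fit a diagonal GMM by EM from a seeded k-means++ initialisation.

    Iterates until the relative total log-likelihood gain drops below
    ``rel_tol`` or ``max_iter`` iterations. Per-dimension variances are
    floored at ``var_floor_frac`` times the global data variance, which
    protects low-variance neurogram dimensions from component collapse.
    The per-iteration log-likelihood history is stored in
    ``model.meta['loglik_history']`` and is non-decreasing.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n, d = data.shape
    if n == 0:
        raise ValueError("empty training data")
    if n < 10 * n_components:
        warnings.warn(
            f"only {n} frames for {n_components} components; "
            "estimates may be poor"
        )
    global_var = data.var(axis=0)
    floor = var_floor_frac * np.maximum(global_var, np.finfo(float).tiny)

    km = KMeans(n_clusters=n_components, init="k-means++", n_init=1,
                random_state=seed).fit(data)
    means = km.cluster_centers_.copy()
    variances = np.tile(np.maximum(global_var, floor), (n_components, 1))
    counts = np.bincount(km.labels_, minlength=n_components).astype(float)
    weights = np.maximum(counts, 1.0)
    weights /= weights.sum()
    model = GMMModel(weights, means, variances)

    history: list[float] = []
    for _ in range(max_iter):
        logp = _log_component_liks(model, data)
        per_frame = logsumexp(logp, axis=1)
        total = float(per_frame.sum())
        history.append(total)
        if len(history) > 1:
            prev = history[-2]
            if abs(total - prev) < rel_tol * abs(prev):
                break
        resp = np.exp(logp - per_frame[:, None])
        nk = resp.sum(axis=0)
        nk_safe = np.maximum(nk, np.finfo(float).tiny)
        means = (resp.T @ data) / nk_safe[:, None]
        sq = (resp.T @ data**2) / nk_safe[:, None]
        variances = sq - means**2
        collapsed = variances < floor[None, :]
        if collapsed.any():
            log.debug("variance floor applied to %d entries", collapsed.sum())
        variances = np.maximum(variances, floor[None, :])
        weights = nk / nk.sum()
        model = GMMModel(weights, means, variances)

    model.meta["loglik_history"] = history
    model.meta["seed"] = seed
    return model


def map_adapt(ubm: GMMModel, data: np.ndarray, relevance: float = 16.0) -> GMMModel:
    """MAP mean adaptation of a UBM toward speaker data.

    ``mu_k <- (n_k x_bar_k + r mu_k^ubm) / (n_k + r)`` with ``n_k`` the soft
    counts of the data under the UBM. Weights and variances are copied from
    the UBM unchanged.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[0] == 0:
        raise ValueError("empty adaptation data")
    if data.shape[1] != ubm.dim:
        raise ValueError("feature dimension mismatch")
    logp = _log_component_liks(ubm, data)
    resp = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    nk = resp.sum(axis=0)
    ex = resp.T @ data  # n_k * x_bar_k
    if np.isinf(relevance):
        means = ubm.means.copy()
    else:
        denom = nk + relevance
        means = np.where(
            denom[:, None] > 0,
            (ex + relevance * ubm.means) / np.maximum(denom, np.finfo(float).tiny)[:, None],
            ubm.means,  # unoccupied component at relevance 0: keep the prior
        )
    return GMMModel(ubm.weights.copy(), means, ubm.variances.copy(),
                    meta={"adapted": True, "relevance": relevance})


def train_speaker_models(features_by_speaker: dict, n_components: int = 128,
                         seed: int = 0, relevance: float = 16.0,
                         **em_kw) -> SpeakerModelSet:
    """Closed-set enrolment: UBM on pooled data, MAP-adapt per speaker."""
    pooled = np.vstack(list(features_by_speaker.values()))
    ubm = em_fit(pooled, n_components=n_components, seed=seed, **em_kw)
    speakers = [
        (sid, map_adapt(ubm, feats, relevance=relevance))
        for sid, feats in features_by_speaker.items()
    ]
    return SpeakerModelSet(ubm, speakers, relevance=relevance)


def _model_to_dict(m: GMMModel) -> dict:
    return {
        "weights": m.weights.tolist(),
        "means": m.means.tolist(),
        "variances": m.variances.tolist(),
        "meta": {k: v for k, v in m.meta.items()
                 if isinstance(v, (int, float, str, bool, list))},
    }


def _model_from_dict(d: dict) -> GMMModel:
    return GMMModel(np.array(d["weights"]), np.array(d["means"]),
                    np.array(d["variances"]), meta=dict(d.get("meta", {})))


def save_models(models: SpeakerModelSet, path) -> None:
    """Persist a speaker model set as JSON (weights, means, variances,
    relevance factor and provenance metadata)."""
    payload = {
        "format": "neurosid-gmm-ubm-v1",
        "relevance": models.relevance,
        "ubm": _model_to_dict(models.ubm),
        "speakers": [{"id": sid, "model": _model_to_dict(m)}
                     for sid, m in models.speakers],
    }
    Path(path).write_text(json.dumps(payload))


def load_models(path) -> SpeakerModelSet:
    """Load a speaker model set written by :func:`save_models`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "neurosid-gmm-ubm-v1":
        raise ValueError(f"unrecognised model container in {path!r}")
    return SpeakerModelSet(
        _model_from_dict(payload["ubm"]),
        [(s["id"], _model_from_dict(s["model"])) for s in payload["speakers"]],
        relevance=payload["relevance"],
    )


def identify(models: SpeakerModelSet, test_features: np.ndarray):
    """Max-likelihood identification.

    Returns ``(speaker_id, margin)`` where the margin is the per-frame
    average gap between the best and second-best speaker log-likelihoods
    (+inf with a single enrolled speaker). Ties break to the earlier
    speaker in enrolment order, with a warning.
    """
    if not models.speakers:
        raise ValueError("empty speaker model set")
    test_features = np.atleast_2d(np.asarray(test_features, dtype=np.float64))
    if test_features.shape[0] == 0:
        raise ValueError("empty test feature matrix")
    scores = np.array([loglik(m, test_features) for _, m in models.speakers])
    best = int(np.argmax(scores))  # argmax takes the first maximum: tie rule
    if (scores == scores[best]).sum() > 1:
        warnings.warn("tied speaker scores; breaking tie by enrolment order")
    if scores.size == 1:
        return models.speakers[0][0], np.inf
    second = np.partition(scores, -2)[-2]
    margin = (scores[best] - second) / test_features.shape[0]
    return models.speakers[best][0], float(margin)
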