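"""Sticky autoregressive HMM segmentation of pose dynamics into syllables.

A weak-limit finite sticky HMM with vector-autoregressive (VAR) emissions in
a low-dimensional latent space, in the spirit of keypoint-based motion
sequencing: keypoint coordinates are projected to a 3-D latent by principal
components, each hidden state carries its own VAR(ar_order) dynamics, and a
stickiness weight kappa inflates self-transitions so states persist long
enough to read as behavioral syllables.

Fitting follows the two-phase protocol: an AR-only phase (50 iterations,
kappa 1e9) that learns per-state dynamics under a near-degenerate sticky
prior, then a full phase (500 iterations, kappa 1e8) jointly refining
dynamics and segmentation.  Inference is Gibbs-style blocked sampling
(forward-filter backward-sample state sequences alternating with closed-form
AR/transition updates) with a deterministic Viterbi decode producing the
reported sequence, so a fixed seed reproduces the output exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ARHMMModel",
    "SyllableSequence",
    "latent_projection",
    "fit_ar_only",
    "fit_full",
    "fit_syllables",
    "decode",
    "one_step_prediction_error",
    "syllable_statistics",
    "syllable_dendrogram",
]


@dataclass
class ARHMMModel:
    """Sticky AR-HMM parameters.

    ``weights`` holds per-state AR coefficient matrices and bias stacked as
    (n_states, d, d*ar_order + 1): the last column is the bias.  ``sigma`` is
    the per-state innovation covariance; ``trans`` rows sum to 1.
    """

    n_states: int
    latent_dim: int
    ar_order: int
    weights: np.ndarray
    sigma: np.ndarray
    trans: np.ndarray
    kappa: float
    loglik_trace: list = field(default_factory=list)

    def ar_matrix(self, state: int, lag: int = 1) -> np.ndarray:
        """(d, d) AR coefficient block of ``state`` at the given lag (1-based)."""
        d = self.latent_dim
        return self.weights[state][:, (lag - 1) * d : lag * d]

    def validate(self) -> None:
        if not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        for k in range(self.n_states):
            np.linalg.cholesky(self.sigma[k])  # raises if not PD


@dataclass
class SyllableSequence:
    """Per-frame discrete syllable IDs with bout and usage summaries.

    State IDs are relabeled 0..S-1 by descending usage, making reports
    invariant to the sampler's internal state labels; empty states are
    dropped.
    """

    states: np.ndarray  # (T,) int

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def n_syllables(self) -> int:
        return len(np.unique(self.states))

    def bouts(self) -> list[tuple[int, int, int]]:
        """(state, start_frame, length) runs partitioning the frame range."""
        s = self.states
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [len(s)]])
        return [(int(s[a]), int(a), int(b - a)) for a, b in zip(starts, stops)]

    @property
    def durations(self) -> np.ndarray:
        return np.array([ln for _, _, ln in self.bouts()], dtype=int)

    @property
    def usage(self) -> dict[int, int]:
        vals, counts = np.unique(self.states, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


# ---------------------------------------------------------------------------
# Latent projection
# ---------------------------------------------------------------------------

def latent_projection(series, latent_dim: int = 3) -> tuple[np.ndarray, PCA]:
    """Project flattened keypoint coordinates onto ``latent_dim`` principal
    components, each scaled to unit variance.

    ``series`` may be a KeypointSeries or a (T, D) array.
    """
    if hasattr(series, "coords"):
        data = series.coords().reshape(series.n_frames, -1)
    else:
        data = np.asarray(series, dtype=float)
    if data.shape[0] <= latent_dim:
        raise ValueError("need more frames than latent dimensions")
    pca = PCA(n_components=latent_dim, whiten=True, random_state=0)
    latents = pca.fit_transform(data)
    return latents, pca


# ---------------------------------------------------------------------------
# Core inference machinery
# ---------------------------------------------------------------------------

def _design(latents: np.ndarray, ar_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix X (N, d*r+1 incl. bias) and targets Z (N, d)."""
    T, d = latents.shape
    r = ar_order
    if T <= r:
        raise ValueError("need more frames than the AR order")
    cols = [latents[r - lag : T - lag] for lag in range(1, r + 1)]
    X = np.concatenate(cols + [np.ones((T - r, 1))], axis=1)
    return X, latents[r:]


def _fit_ar_state(X: np.ndarray, Z: np.ndarray, ridge: float = 1e-8):
    p = X.shape[1]
    G = X.T @ X + ridge * np.eye(p)
    W = np.linalg.solve(G, X.T @ Z).T  # (d, p)
    resid = Z - X @ W.T
    sigma = resid.T @ resid / max(len(Z), 1) + 1e-6 * np.eye(Z.shape[1])
    return W, sigma

def _state_logliks(model: ARHMMModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """(N, K) Gaussian log-densities of each target under each state's VAR."""
    N, d = Z.shape
    out = np.empty((N, model.n_states))
    for k in range(model.n_states):
        resid = Z - X @ model.weights[k].T
        L = np.linalg.cholesky(model.sigma[k])
        sol = np.linalg.solve(L, resid.T)
        quad = (sol**2).sum(axis=0)
        logdet = 2 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (quad + logdet + d * np.log(2 * np.pi))
    return out


def _forward_filter(loglik: np.ndarray, trans: np.ndarray) -> tuple[np.ndarray, float]:
    """Scaled forward recursion; returns filtered probabilities and log-evidence."""
    N, K = loglik.shape
    alpha = np.empty((N, K))
    shift = loglik.max(axis=1)
    lik = np.exp(loglik - shift[:, None])
    a = lik[0] / K
    c0 = a.sum()
    alpha[0] = a / c0
    log_ev = np.log(c0) + shift[0]
    for t in range(1, N):
        a = (alpha[t - 1] @ trans) * lik[t]
        c = a.sum()
        if c <= 0 or not np.isfinite(c):
            a = np.full(K, 1.0 / K)
            c = 1.0
        alpha[t] = a / c
        log_ev += np.log(c) + shift[t]
    return alpha, float(log_ev)


def _backward_sample(
    alpha: np.ndarray, trans: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    N, K = alpha.shape
    states = np.empty(N, dtype=int)
    states[-1] = rng.choice(K, p=alpha[-1])
    for t in range(N - 2, -1, -1):
        w = alpha[t] * trans[:, states[t + 1]]
        s = w.sum()
        w = w / s if s > 0 else np.full(K, 1.0 / K)
        states[t] = rng.choice(K, p=w)
    return states


def _viterbi(loglik: np.ndarray, trans: np.ndarray) -> np.ndarray:
    N, K = loglik.shape
    log_trans = np.log(np.maximum(trans, 1e-300))
    delta = loglik[0] - np.log(K)
    back = np.empty((N, K), dtype=int)
    for t in range(1, N):
        cand = delta[:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + loglik[t]
    states = np.empty(N, dtype=int)
    states[-1] = int(delta.argmax())
    for t in range(N - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def _map_transitions(
    states: np.ndarray, n_states: int, kappa: float, alpha: float = 1.0
) -> np.ndarray:
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (states[:-1], states[1:]), 1.0)
    counts += alpha
    counts[np.diag_indices(n_states)] += kappa
    return counts / counts.sum(axis=1, keepdims=True)


def _update_ar_params(
    model: ARHMMModel, X: np.ndarray, Z: np.ndarray, states: np.ndarray
) -> None:
    p = X.shape[1]
    for k in range(model.n_states):
        rows = states == k
        if rows.sum() < p + 2:
            continue  # too few frames: keep previous parameters
        model.weights[k], model.sigma[k] = _fit_ar_state(X[rows], Z[rows])


def _gibbs_sweeps(
    model: ARHMMModel,
    X: np.ndarray,
    Z: np.ndarray,
    iters: int,
    kappa: float,
    rng: np.random.Generator,
) -> ARHMMModel:
    model.kappa = kappa
    for _ in range(iters):
        loglik = _state_logliks(model, X, Z)
        alpha, log_ev = _forward_filter(loglik, model.trans)
        states = _backward_sample(alpha, model.trans, rng)
        _update_ar_params(model, X, Z, states)
        model.trans = _map_transitions(states, model.n_states, kappa)
        model.loglik_trace.append(log_ev)
    return model


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def fit_ar_only(
    latents: np.ndarray,
    n_states: int = 20,
    ar_order: int = 3,
    iters: int = 50,
    kappa: float = 1e9,
    seed: int = 0,
) -> ARHMMModel:
    """AR-only fitting phase: learn per-state VAR dynamics under a
    near-degenerate sticky prior.

    States are initialized by K-means over the latent frames; ``iters=0``
    returns that initialization (AR fits per initial state) unchanged.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.std(axis=0).min() < 1e-12:
        raise np.linalg.LinAlgError(
            "degenerate (constant) latent dimension: covariance is singular"
        )
    rng = np.random.default_rng(seed)
    X, Z = _design(latents, ar_order)
    d, p = latents.shape[1], X.shape[1]

    km = KMeans(n_clusters=min(n_states, len(Z)), random_state=seed, n_init=5)
    init_states = km.fit_predict(Z)
    W0, S0 = _fit_ar_state(X, Z)  # global fallback parameters
    weights = np.tile(W0, (n_states, 1, 1))
    sigma = np.tile(S0, (n_states, 1, 1))
    model = ARHMMModel(
        n_states=n_states,
        latent_dim=d,
        ar_order=ar_order,
        weights=weights,
        sigma=sigma,
        trans=_map_transitions(init_states, n_states, kappa),
        kappa=kappa,
    )
    _update_ar_params(model, X, Z, init_states)
    if iters > 0:
        _gibbs_sweeps(model, X, Z, iters, kappa, rng)
    return model


def decode(model: ARHMMModel, latents: np.ndarray) -> np.ndarray:
    """Deterministic Viterbi state sequence (first ar_order frames take the
    state of the first decodable frame)."""
    X, Z = _design(np.asarray(latents, dtype=float), model.ar_order)
    loglik = _state_logliks(model, X, Z)
    core = _viterbi(loglik, model.trans)
    return np.concatenate([np.full(model.ar_order, core[0], dtype=int), core])


def fit_full(
    model: ARHMMModel,
    latents: np.ndarray,
    iters: int = 500,
    kappa: float = 1e8,
    seed: int = 0,
) -> tuple[ARHMMModel, SyllableSequence]:
    """Full fitting phase: joint refinement of AR parameters and segmentation.

    Blocked Gibbs updates (state resampling alternating with AR and
    transition updates) followed by a deterministic Viterbi decode.  The
    reported sequence drops empty states and relabels syllables by usage.
    """
    latents = np.asarray(latents, dtype=float)
    rng = np.random.default_rng(seed)
    X, Z = _design(latents, model.ar_order)
    _gibbs_sweeps(model, X, Z, iters, kappa, rng)
    states = decode(model, latents)
    if model.n_states > 1 and len(np.unique(states)) == 1:
        warnings.warn(
            "all frames decoded to a single state; kappa may be too high "
            "for this recording"
        )
    # relabel by descending usage: empty states vanish, reports become
    # invariant to the sampler's internal labels
    vals, counts = np.unique(states, return_counts=True)
    order = vals[np.argsort(-counts, kind="stable")]
    remap = {int(v): i for i, v in enumerate(order)}
    seq = SyllableSequence(states=np.array([remap[int(s)] for s in states]))
    model._state_relabel = remap  # type: ignore[attr-defined]
    return model, seq


def fit_syllables(
    series,
    latent_dim: int = 3,
    n_states: int = 20,
    ar_order: int = 3,
    iters_ar: int = 50,
    iters_full: int = 500,
    kappa_ar: float = 1e9,
    kappa_full: float = 1e8,
    seed: int = 0,
) -> tuple[ARHMMModel, SyllableSequence]:
    """Project keypoints to the latent space and run both fitting phases."""
    latents, _ = latent_projection(series, latent_dim=latent_dim)
    model = fit_ar_only(
        latents, n_states=n_states, ar_order=ar_order, iters=iters_ar,
        kappa=kappa_ar, seed=seed,
    )
    return fit_full(model, latents, iters=iters_full, kappa=kappa_full, seed=seed)


def one_step_prediction_error(model: ARHMMModel, latents: np.ndarray) -> float:
    """Mean squared one-step-ahead prediction error under the Viterbi path."""
    latents = np.asarray(latents, dtype=float)
    X, Z = _design(latents, model.ar_order)
    states = decode(model, latents)[model.ar_order :]
    pred = np.einsum("np,kdp->nkd", X, model.weights)
    chosen = pred[np.arange(len(Z)), states]
    return float(((Z - chosen) ** 2).mean())


# ---------------------------------------------------------------------------
# Syllable summaries
# ---------------------------------------------------------------------------

def syllable_statistics(
    seq: SyllableSequence,
    series,
    window: int = 30,
    min_frac: float = 0.005,
) -> dict:
    """Per-syllable mean trajectory vectors, speeds and counts.

    The trajectory vector of a syllable is the average flattened keypoint
    coordinate vector over a fixed ``window`` of frames from each bout onset
    (truncated at bout end).  Syllables using fewer than ``min_frac`` of all
    frames are excluded (listed under ``excluded``).
    """
    if hasattr(series, "coords"):
        data = series.coords().reshape(series.n_frames, -1)
        fps = series.fps
    else:
        data = np.asarray(series, dtype=float)
        fps = 1.0
    if len(data) != seq.n_frames:
        raise ValueError("sequence and series lengths differ")
    speed = np.zeros(len(data))
    if len(data) > 1:
        speed[1:] = np.linalg.norm(np.diff(data, axis=0), axis=1) * fps

    usage = seq.usage
    T = seq.n_frames
    keep = sorted(s for s, c in usage.items() if c / T >= min_frac)
    excluded = sorted(set(usage) - set(keep))

    vectors, rows = [], []
    for s in keep:
        onset_frames: list[np.ndarray] = []
        n_bouts = 0
        for state, start, length in seq.bouts():
            if state != s:
                continue
            n_bouts += 1
            onset_frames.append(data[start : start + min(window, length)])
        vec = np.concatenate(onset_frames, axis=0).mean(axis=0)
        vectors.append(vec)
        frames = seq.states == s
        rows.append(
            {
                "syllable": s,
                "n_frames": int(usage[s]),
                "n_bouts": n_bouts,
                "mean_speed": float(speed[frames].mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("syllable") if rows else pd.DataFrame()
    return {
        "table": table,
        "vectors": np.array(vectors) if vectors else np.empty((0, data.shape[1])),
        "syllables": keep,
        "excluded": excluded,
    }


def syllable_dendrogram(stats: dict) -> dict:
    """Average-linkage dendrogram over pairwise cosine distances between
    syllable trajectory vectors (distance 1 - cos; taller merges = more
    distinct syllables)."""
    vectors = np.asarray(stats["vectors"], dtype=float)
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 syllables for a dendrogram")
    norms = np.linalg.norm(vectors, axis=1)
    if (norms == 0).any():
        bad = [stats["syllables"][i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm trajectory vector(s) for syllables {bad}")
    distances = pdist(vectors, metric="cosine")
    return {
        "linkage": linkage(distances, method="average"),
        "distances": distances,
        "labels": list(stats["syllables"]),
        "mean_distance": float(distances.mean()),
    }
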