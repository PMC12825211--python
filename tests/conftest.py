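"""Shared fixtures: synthetic trials, switching-VAR data, oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import stimselect as ss


@pytest.fixture(scope="session")
def selective_trial():
    """8-configuration selective-regime trial (injective motif map)."""
    labels = list(range(1, 9))
    library = ss.make_motif_library(labels, regime="selective", seed=3)
    spec = ss.TrialSpec(n_configs=8, seed=3)
    series, epochs, truth = ss.generate_trial(spec, library)
    return library, spec, series, epochs, truth


@pytest.fixture(scope="session")
def selective_matrix(selective_trial):
    _, _, series, epochs, _ = selective_trial
    return ss.preprocess_series(series, epochs)


@pytest.fixture(scope="session")
def selective_embedding(selective_matrix):
    """Embedding + density clusters of the selective trial (UMAP is slow,
    so embed once per session)."""
    emb = ss.embed(selective_matrix, profile="custom", seed=42)
    labels = ss.cluster_density(emb.coords, profile="custom")
    return emb, labels


def make_switching_var(
    n_states: int = 3,
    T: int = 6000,
    dwell_frames: float = 60.0,
    noise: float = 0.3,
    seed: int = 7,
):
    """Ground-truth switching VAR(1) in 3 dims with known parameters.

    Mean dwell of ``dwell_frames`` (1 s at 60 fps by default).  Returns
    (latents, states, A_list, drive_list).
    """
    rng = np.random.default_rng(seed)

    def stable(rng):
        th = rng.uniform(0.1, 0.5)
        rho = rng.uniform(0.85, 0.95)
        A = np.zeros((3, 3))
        A[:2, :2] = rho * np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        )
        A[2, 2] = rng.uniform(0.7, 0.9)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        return Q @ A @ Q.T

    As = [stable(rng) for _ in range(n_states)]
    ds = [rng.normal(size=3) * 0.5 for _ in range(n_states)]
    z = np.zeros((T, 3))
    states = np.zeros(T, dtype=int)
    s = 0
    for t in range(1, T):
        if rng.random() < 1.0 / dwell_frames:
            s = int(rng.integers(n_states))
        states[t] = s
        z[t] = As[s] @ z[t - 1] + ds[s] + noise * rng.standard_normal(3)
    return z, states, As, ds


@pytest.fixture(scope="session")
def switching_var_data():
    return make_switching_var()


def ami_bruteforce(labels_a, labels_b) -> float:
    """Independent AMI: expected MI by direct summation over the
    hypergeometric permutation model (scipy.stats.hypergeom), arithmetic-mean
    normalization, natural log."""
    from scipy.stats import hypergeom

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    N = len(a)
    avals, acnt = np.unique(a, return_counts=True)
    bvals, bcnt = np.unique(b, return_counts=True)
    if len(avals) == len(bvals) == 1:
        return 1.0  # both partitions trivial: zero uncertainty on both sides

    # observed MI
    mi = 0.0
    for i, av in enumerate(avals):
        for j, bv in enumerate(bvals):
            nij = int(np.sum((a == av) & (b == bv)))
            if nij > 0:
                mi += (nij / N) * np.log(N * nij / (acnt[i] * bcnt[j]))

    # expected MI under random permutations of one labeling
    emi = 0.0
    for ai in acnt:
        for bj in bcnt:
            lo = max(0, ai + bj - N)
            hi = min(ai, bj)
            for nij in range(max(lo, 1), hi + 1):
                p = hypergeom.pmf(nij, N, ai, bj)
                emi += p * (nij / N) * np.log(N * nij / (ai * bj))

    h_a = -np.sum((acnt / N) * np.log(acnt / N))
    h_b = -np.sum((bcnt / N) * np.log(bcnt / N))
    denom = (h_a + h_b) / 2 - emi
    eps = np.finfo("float64").eps
    denom = min(denom, -eps) if denom < 0 else max(denom, eps)
    return float((mi - emi) / denom)


def align_accuracy(decoded: np.ndarray, truth: np.ndarray) -> float:
    """Best state-sequence accuracy over all label permutations."""
    from itertools import permutations

    decoded = np.asarray(decoded)
    truth = np.asarray(truth)
    k = max(int(decoded.max()), int(truth.max())) + 1
    best = 0.0
    for perm in permutations(range(k)):
        mapped = np.array([perm[d] for d in decoded])
        best = max(best, float(np.mean(mapped == truth)))
    return best
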