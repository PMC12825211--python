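"""Entropy-based selectivity scoring and group statistics.

For each electrode configuration i, the syllables evoked during its
stimulation-ON frames give a distribution p_ij; its Shannon entropy
H_i = -sum_j p_ij ln p_ij measures how spread the evoked movements are, and

    selectivity_i = 1 - H_i / ln(N)

(with N the total number of distinct syllables in the trial) maps to [0, 1]:
1 when a configuration evokes a single syllable, 0 when it spreads uniformly
over all N.  The score is invariant to the logarithm base.

Group comparison between stimulation types follows the published protocol:
bootstrap resampling of scores (resample size 100, 1000 iterations) with
95% percentile intervals, beta regression of scores on stimulation type
(logit mean link), a two-sided Mann-Whitney U test, Cohen's d and Cliff's
delta.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import mannwhitneyu
from statsmodels.base.model import GenericLikelihoodModel

__all__ = [
    "syllable_config_table",
    "shannon_entropy",
    "selectivity_score",
    "selectivity_table",
    "bootstrap_means",
    "smithson_verkuilen",
    "beta_regression",
    "nonparametric_effects",
    "cliffs_delta",
    "cohens_d",
]


# ---------------------------------------------------------------------------
# Syllable-by-configuration table and the score
# ---------------------------------------------------------------------------

def syllable_config_table(
    states: np.ndarray, epochs: pd.DataFrame, by_bout: bool = False
) -> pd.DataFrame:
    """Counts of each syllable during each retained configuration's ON frames.

    ``states`` is the per-frame syllable sequence.  Configurations whose
    ``retained`` flag is False (movement gate) are absent; configurations
    with zero ON frames after gating are excluded with a note.  With
    ``by_bout=True`` occurrences are counted per bout onset instead of per
    frame.  N (total distinct syllables across all configurations of the
    trial) is stored in ``attrs['n_total_syllables']``.
    """
    states = np.asarray(states)
    rows = {}
    excluded = []
    use = epochs
    if "retained" in epochs.columns:
        use = epochs[epochs["retained"]]
    for row in use.itertuples(index=False):
        span = states[int(row.on_start) : int(row.on_stop)]
        if span.size == 0:
            excluded.append(row.label)
            continue
        if by_bout:
            onsets = np.concatenate([[True], np.diff(span) != 0])
            span = span[onsets]
        vals, counts = np.unique(span, return_counts=True)
        rows[row.label] = dict(zip(vals.tolist(), counts.tolist()))
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    table = table.sort_index().sort_index(axis=1)
    table.index.name = "configuration"
    table.columns.name = "syllable"
    table.attrs["n_total_syllables"] = int(table.shape[1])
    table.attrs["excluded_zero_on"] = excluded
    if excluded:
        warnings.warn(f"configurations with zero ON frames excluded: {excluded}")
    return table


def shannon_entropy(p: np.ndarray) -> float:
    """H = -sum p ln p with the 0*ln(0) = 0 convention (nats)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def selectivity_score(table: pd.DataFrame, n_total: int | None = None) -> pd.Series:
    """Per-configuration selectivity 1 - H_i / ln(N).

    N defaults to the total number of distinct syllables across all
    configurations of the trial (the table's column count).  N = 1 means a
    trial with zero syllable uncertainty anywhere: every score is defined as
    1 with a warning (ln N = 0 is guarded).
    """
    if n_total is None:
        n_total = table.attrs.get("n_total_syllables", table.shape[1])
    counts = table.to_numpy(dtype=float)
    p = counts / counts.sum(axis=1, keepdims=True)
    H = np.array([shannon_entropy(row) for row in p])
    if n_total < 2:
        warnings.warn("single syllable in the whole trial: scores defined as 1")
        scores = np.ones(len(H))
    else:
        scores = 1.0 - H / np.log(n_total)
    return pd.Series(scores, index=table.index, name="selectivity")


def selectivity_table(
    states: np.ndarray,
    epochs: pd.DataFrame,
    stim_type: str = "TIS",
    subject_id: str | None = None,
    by_bout: bool = False,
) -> pd.DataFrame:
    """Long-form per-configuration table: counts -> entropy -> score."""
    table = syllable_config_table(states, epochs, by_bout=by_bout)
    scores = selectivity_score(table)
    counts = table.to_numpy(dtype=float)
    p = counts / counts.sum(axis=1, keepdims=True)
    out = pd.DataFrame(
        {
            "configuration": table.index,
            "entropy_nats": [shannon_entropy(row) for row in p],
            "selectivity": scores.to_numpy(),
            "n_on_frames": counts.sum(axis=1).astype(int),
            "stim_type": stim_type,
        }
    )
    if subject_id is None and "subject_id" in epochs.columns and len(epochs):
        subject_id = str(epochs["subject_id"].iloc[0])
    out["subject_id"] = subject_id or "subject01"
    out.attrs.update(table.attrs)
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_means(
    scores_by_group: dict[str, np.ndarray],
    m: int = 100,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap distribution of group means (resample size m, B iterations).

    For each group, draws B resamples of size m with replacement and reports
    the mean of resample means with the 2.5/97.5 percentile interval, plus a
    pairwise CI-overlap flag.
    """
    if m < 1 or B < 1:
        raise ValueError("m and B must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict = {"groups": {}, "m": m, "B": B}
    for name, scores in scores_by_group.items():
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValueError(f"group {name!r} is empty")
        means = rng.choice(scores, size=(B, m), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        out["groups"][name] = {
            "mean": float(means.mean()),
            "ci95": (float(lo), float(hi)),
            "n": int(scores.size),
        }
    names = list(scores_by_group)
    overlaps = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            lo_a, hi_a = out["groups"][a]["ci95"]
            lo_b, hi_b = out["groups"][b]["ci95"]
            overlaps[f"{a}|{b}"] = bool(max(lo_a, lo_b) <= min(hi_a, hi_b))
    out["ci_overlap"] = overlaps
    return out


# ---------------------------------------------------------------------------
# Beta regression (logit mean link, constant precision)
# ---------------------------------------------------------------------------

def smithson_verkuilen(y: np.ndarray) -> np.ndarray:
    """Compress [0, 1] scores into (0, 1): y' = (y*(n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


class _BetaReg(GenericLikelihoodModel):
    """Beta regression: y ~ Beta(mu*phi, (1-mu)*phi), logit(mu) = X b."""

    def nloglikeobs(self, params):
        # cap log-phi: degenerate samples (all scores equal) otherwise send
        # the precision to infinity and the optimizer never terminates
        beta, phi = params[:-1], np.exp(min(params[-1], 30.0))
        mu = expit(self.exog @ beta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        y = self.endog
        a, b = mu * phi, (1 - mu) * phi
        ll = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1) * np.log(y)
            + (b - 1) * np.log(1 - y)
        )
        return -ll


def beta_regression(
    data: pd.DataFrame,
    response: str = "selectivity",
    predictors: tuple[str, ...] = ("stim_type",),
    reference: dict[str, str] | None = None,
) -> dict:
    """Maximum-likelihood beta regression of a bounded score on categorical
    predictors (stimulation type, electrode configuration, subject).

    Scores are first compressed off the boundary with the
    Smithson-Verkuilen transform.  The mean uses a logit link; precision phi
    is a free scalar (log parameterization).  Returns coefficient estimates
    with Wald standard errors, p-values and 95% CIs.
    """
    y = smithson_verkuilen(data[response].to_numpy())
    design = [np.ones(len(y))]
    names = ["intercept"]
    for pred in predictors:
        col = data[pred]
        if col.dtype.kind in "ifu" and col.nunique() > 12:
            design.append(col.to_numpy(dtype=float))
            names.append(pred)
            continue
        levels = sorted(col.astype(str).unique())
        ref = (reference or {}).get(pred, levels[0])
        for lvl in levels:
            if lvl == ref:
                continue
            design.append((col.astype(str) == lvl).to_numpy(dtype=float))
            names.append(f"{pred}[{lvl}]")
    X = np.column_stack(design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (perfect collinearity)")

    if np.ptp(y) < 1e-10:
        # degenerate response: every score identical.  The mean model fits
        # exactly and the precision is unbounded, so return the exact
        # solution rather than chasing an optimizer along a flat ridge.
        warnings.warn("all scores equal: beta-regression precision is unbounded")
        eta = float(np.log(y[0] / (1 - y[0])))
        beta_exact = np.linalg.lstsq(X, np.full(len(y), eta), rcond=None)[0]
        coef = pd.DataFrame(
            {
                "coef": beta_exact,
                "se": np.nan,
                "p": np.nan,
                "ci_lo": np.nan,
                "ci_hi": np.nan,
            },
            index=names,
        )
        return {
            "coefficients": coef,
            "phi": float("inf"),
            "loglik": float("inf"),
            "converged": True,
            "n": int(len(y)),
        }

    model = _BetaReg(y, X)
    # moment-based start: logit-linear LS for beta, method-of-moments phi
    eta = np.log(y / (1 - y))
    beta0 = np.linalg.lstsq(X, eta, rcond=None)[0]
    mu0 = expit(X @ beta0)
    var0 = max(float(np.var(y - mu0)), 1e-6)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / var0 - 1), 1.0)
    start = np.concatenate([beta0, [np.log(phi0)]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=False)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=start, method="nm", maxiter=5000, disp=False)
            res = model.fit(
                start_params=res.params, method="bfgs", maxiter=500, disp=False
            )
    if not res.mle_retvals.get("converged", False):
        # BFGS reports precision loss on flat likelihoods (e.g. degenerate
        # all-equal scores at the phi cap); accept genuine stationary points
        grad = model.score(res.params)
        if not np.all(np.abs(grad[: X.shape[1]]) < 1e-4 * max(len(y), 1)):
            raise RuntimeError(
                f"beta regression did not converge: {res.mle_retvals}"
            )
    coef = pd.DataFrame(
        {
            "coef": res.params[:-1],
            "se": res.bse[:-1],
            "p": res.pvalues[:-1],
            "ci_lo": res.params[:-1] - 1.959963984540054 * res.bse[:-1],
            "ci_hi": res.params[:-1] + 1.959963984540054 * res.bse[:-1],
        },
        index=names,
    )
    return {
        "coefficients": coef,
        "phi": float(np.exp(res.params[-1])),
        "loglik": float(res.llf),
        "converged": True,
        "n": int(len(y)),
    }


# ---------------------------------------------------------------------------
# Nonparametric effects
# ---------------------------------------------------------------------------

def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d (no small-sample correction)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / sp)


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross-group pairs.

    Computed with sorted-array rank counting, O((n+m) log(n+m)).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left").sum()
    less = (len(b) - np.searchsorted(bs, a, side="right")).sum()
    return float((greater - less) / (len(a) * len(b)))


def nonparametric_effects(scores_a: np.ndarray, scores_b: np.ndarray) -> dict:
    """Mann-Whitney U (two-sided, tie-corrected), Cohen's d, Cliff's delta."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 scores")
    u = mannwhitneyu(a, b, alternative="two-sided")
    return {
        "U": float(u.statistic),
        "p": float(u.pvalue),
        "cohens_d": cohens_d(a, b),
        "cliffs_delta": cliffs_delta(a, b),
    }
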