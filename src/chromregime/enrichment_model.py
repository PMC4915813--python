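"""Two-component binomial mixture for ChIP vs control counts, and the
regularized, normalized log-enrichment statistic derived from it.

Model
-----
For region *i* with ChIP count s_i and control count r_i, condition on the
total n_i = s_i + r_i and model the ChIP fraction as a mixture:

    s_i | n_i  ~  pi_bg * Binom(n_i, theta_bg) + pi_sig * Binom(n_i, theta_sig)

One component is chromatin background (reads split between ChIP and control
at the library-size ratio), the other genuine enrichment. The fit is by EM,
restarted from several initializations, with components relabelled so that
theta_bg <= theta_sig.

Statistic
---------
Pseudo counts are derived from the background component,

    alpha_s = c * theta_bg,     alpha_r = c * (1 - theta_bg),

so that a region whose counts sit exactly at the background ratio scores
zero, and low-count regions are shrunk towards zero. The raw regularized
log enrichment is

    e*_i = ln( (s_i + alpha_s) / (r_i + alpha_r) * alpha_r / alpha_s )

and the normalized enrichment divides by the average log enrichment of the
signal component, ln<f> (posterior-weighted mean of e*):

    e_i = e*_i / ln<f>

so background regions score ~0 and a typical signal region scores ~1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

_THETA_EPS = 1e-12


class FitError(RuntimeError):
    """The mixture cannot be fitted to the given counts."""


@dataclass
class MixtureFit:
    """Converged two-component binomial mixture (components: bg, sig)."""

    theta_bg: float
    theta_sig: float
    pi_bg: float
    posterior: np.ndarray  # P(signal | s_i, n_i) per region
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    degenerate: bool = False
    alpha_s: float | None = None
    alpha_r: float | None = None
    ln_f: float | None = None

    @property
    def pi_sig(self) -> float:
        return 1.0 - self.pi_bg


def _as_counts(counts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a (region_id, s, r) DataFrame or a pair of arrays."""
    if isinstance(counts, pd.DataFrame):
        ids = counts["region_id"].to_numpy()
        s = counts["s"].to_numpy(dtype=np.int64)
        r = counts["r"].to_numpy(dtype=np.int64)
    else:
        s, r = counts
        s = np.asarray(s, dtype=np.int64)
        r = np.asarray(r, dtype=np.int64)
        ids = np.array([f"region_{i}" for i in range(len(s))])
    if len(s) == 0:
        raise FitError("no regions supplied")
    if (s < 0).any() or (r < 0).any():
        raise ValueError("counts must be non-negative")
    return ids, s, r


def _log_binom_pmf(s, n, log_coef, theta: float) -> np.ndarray:
    theta = float(np.clip(theta, _THETA_EPS, 1.0 - _THETA_EPS))
    return log_coef + s * np.log(theta) + (n - s) * np.log1p(-theta)


def mixture_loglik(
    s: np.ndarray,
    r: np.ndarray,
    theta_bg: float,
    theta_sig: float,
    pi_bg: float,
    weights: np.ndarray | None = None,
) -> float:
    """Full-data log-likelihood (binomial coefficients included)."""
    n = s + r
    log_coef = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    lp = np.stack(
        [
            np.log(max(pi_bg, _THETA_EPS)) + _log_binom_pmf(s, n, log_coef, theta_bg),
            np.log(max(1.0 - pi_bg, _THETA_EPS))
            + _log_binom_pmf(s, n, log_coef, theta_sig),
        ]
    )
    per_region = logsumexp(lp, axis=0)
    if weights is None:
        return float(per_region.sum())
    return float(np.dot(weights, per_region))


def _em_run(
    s: np.ndarray,
    r: np.ndarray,
    w: np.ndarray,
    theta0: tuple[float, float],
    pi_bg0: float,
    tol: float,
    max_iter: int,
) -> tuple[float, float, float, np.ndarray, list[float], bool, int]:
    """One EM run on aggregated (s, r) rows with multiplicities ``w``."""
    n = s + r
    log_coef = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    th_bg, th_sig = theta0
    pi_bg = pi_bg0
    trace: list[float] = []
    gamma_sig = np.full(len(s), 1.0 - pi_bg)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        lp_bg = np.log(max(pi_bg, _THETA_EPS)) + _log_binom_pmf(s, n, log_coef, th_bg)
        lp_sig = np.log(max(1.0 - pi_bg, _THETA_EPS)) + _log_binom_pmf(
            s, n, log_coef, th_sig
        )
        norm = np.logaddexp(lp_bg, lp_sig)
        ll = float(np.dot(w, norm))
        if not np.isfinite(ll):
            raise FitError(f"non-finite likelihood at EM iteration {it}")
        gamma_sig = np.exp(lp_sig - norm)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # M step (weighted by multiplicities)
        w_sig = w * gamma_sig
        w_bg = w * (1.0 - gamma_sig)
        tot_sig, tot_bg = w_sig.sum(), w_bg.sum()
        pi_bg = float(np.clip(tot_bg / w.sum(), _THETA_EPS, 1 - _THETA_EPS))
        if tot_bg > 0 and np.dot(w_bg, n) > 0:
            th_bg = float(np.dot(w_bg, s) / np.dot(w_bg, n))
        if tot_sig > 0 and np.dot(w_sig, n) > 0:
            th_sig = float(np.dot(w_sig, s) / np.dot(w_sig, n))
        th_bg = float(np.clip(th_bg, _THETA_EPS, 1 - _THETA_EPS))
        th_sig = float(np.clip(th_sig, _THETA_EPS, 1 - _THETA_EPS))
    return th_bg, th_sig, pi_bg, gamma_sig, trace, converged, it


def fit_binomial_mixture(
    counts,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit the two-component binomial mixture by EM.

    ``counts`` is a (region_id, s, r) DataFrame or an ``(s, r)`` array pair.
    The first initialization places the component fractions at the 0.4/0.6
    quantiles of the observed s/(s+r); the remaining ``restarts - 1`` are
    random but derived from ``seed``. The best converged log-likelihood
    wins (ties: first). Components are relabelled so theta_bg <= theta_sig.

    Identical (s, r) rows are aggregated before EM, so runtime scales with
    the number of distinct count pairs rather than the number of regions.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    _, s_all, r_all = _as_counts(counts)
    n_all = s_all + r_all
    if not (n_all > 0).any():
        raise FitError("no informative regions: every region has s + r == 0")

    rows = np.stack([s_all, r_all], axis=1)
    uniq, inverse, w = np.unique(rows, axis=0, return_inverse=True, return_counts=True)
    s, r = uniq[:, 0], uniq[:, 1]
    w = w.astype(float)

    informative = n_all > 0
    frac = s_all[informative] / n_all[informative]
    q40, q60 = np.quantile(frac, [0.4, 0.6])
    inits: list[tuple[tuple[float, float], float]] = [
        ((float(np.clip(q40, 0.02, 0.98)), float(np.clip(q60, 0.02, 0.98))), 0.5)
    ]
    rng = np.random.default_rng(seed)
    for _ in range(restarts - 1):
        th = np.sort(rng.uniform(0.05, 0.95, size=2))
        inits.append(((float(th[0]), float(th[1])), float(rng.uniform(0.2, 0.95))))

    best = None
    for theta0, pi0 in inits:
        th_bg, th_sig, pi_bg, gamma_sig, trace, converged, it = _em_run(
            s, r, w, theta0, pi0, tol, max_iter
        )
        if best is None or trace[-1] > best[4][-1] + 1e-12:
            best = (th_bg, th_sig, pi_bg, gamma_sig, trace, converged, it)
    th_bg, th_sig, pi_bg, gamma_sig, trace, converged, it = best

    if th_bg > th_sig:  # relabel so the background is the low-fraction component
        th_bg, th_sig = th_sig, th_bg
        pi_bg = 1.0 - pi_bg
        gamma_sig = 1.0 - gamma_sig

    degenerate = len(s_all) < 2 or abs(th_sig - th_bg) < 1e-6
    if degenerate:
        warnings.warn(
            "degenerate mixture fit: components are indistinguishable or "
            "too few regions were supplied",
            RuntimeWarning,
            stacklevel=2,
        )
    posterior = np.clip(gamma_sig[inverse], 0.0, 1.0)
    return MixtureFit(
        theta_bg=th_bg,
        theta_sig=th_sig,
        pi_bg=pi_bg,
        posterior=posterior,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        degenerate=degenerate,
    )


def estimate_pseudo_counts(fit: MixtureFit, c: float = 1.0) -> tuple[float, float]:
    """Background-derived pseudo counts: alpha_s = c*theta_bg, alpha_r = c*(1-theta_bg).

    The ratio alpha_r/alpha_s equals the background control/ChIP ratio, so
    a region sitting exactly at that ratio has e* -> 0 as counts grow, and
    empty regions score exactly 0. ``c`` sets the regularization mass.
    """
    if c <= 0:
        raise ValueError("regularization mass c must be positive")
    if not (0.0 < fit.theta_bg < 1.0):
        raise FitError(
            f"pseudo counts undefined for theta_bg = {fit.theta_bg}"
        )
    fit.alpha_s = c * fit.theta_bg
    fit.alpha_r = c * (1.0 - fit.theta_bg)
    return fit.alpha_s, fit.alpha_r


def raw_enrichment(counts, alpha_s: float, alpha_r: float) -> np.ndarray:
    """e*_i = ln((s_i + alpha_s)/(r_i + alpha_r) * alpha_r/alpha_s); finite everywhere."""
    if alpha_s <= 0 or alpha_r <= 0:
        raise ValueError("pseudo counts must be positive")
    _, s, r = _as_counts(counts)
    return np.log((s + alpha_s) / (r + alpha_r) * (alpha_r / alpha_s))


def normalize_enrichment(
    e_star: np.ndarray,
    fit: MixtureFit,
    region_ids=None,
    mode: str = "divide",
    average: str = "log",
) -> pd.DataFrame:
    """Normalize e* by the signal component's average log enrichment ln<f>.

    ln<f> is the posterior-weighted mean of e* over the signal component
    (``average='log'``; ``average='fold'`` takes the log of the weighted
    mean fold enrichment instead). ``mode='divide'`` (default) returns
    e = e*/ln<f>; ``mode='multiply'`` returns e = e* * ln<f>.

    Raises if ln<f> <= 0 — the "signal" component is then not enriched over
    the control, which usually means treatment and control are swapped.
    """
    e_star = np.asarray(e_star, dtype=float)
    post = np.asarray(fit.posterior, dtype=float)
    if e_star.shape != post.shape:
        raise ValueError("e_star and fit posteriors are misaligned")
    total = post.sum()
    if total <= 0:
        raise FitError("signal component has zero posterior mass")
    if average == "log":
        ln_f = float(np.dot(post, e_star) / total)
    elif average == "fold":
        ln_f = float(np.log(np.dot(post, np.exp(e_star)) / total))
    else:
        raise ValueError(f"unknown average {average!r}")
    if ln_f <= 0:
        raise FitError(
            f"ln<f> = {ln_f:.4g} <= 0: signal component is not enriched over "
            "the control; check whether treatment and control are swapped"
        )
    fit.ln_f = ln_f
    if mode == "divide":
        e = e_star / ln_f
    elif mode == "multiply":
        e = e_star * ln_f
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if region_ids is None:
        region_ids = [f"region_{i}" for i in range(len(e_star))]
    return pd.DataFrame(
        {"region_id": region_ids, "e_star": e_star, "e": e, "posterior": post}
    )


def posterior_labels(fit: MixtureFit, threshold: float = 0.5) -> np.ndarray:
    """Per-region 'bg'/'sig' labels: sig iff posterior >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return np.where(fit.posterior >= threshold, "sig", "bg")


def enrichment_scores(
    counts,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    pseudo_mass: float = 1.0,
) -> tuple[pd.DataFrame, MixtureFit]:
    """Convenience: fit the mixture, then compute normalized enrichment.

    Returns ``(scores, fit)`` where scores has columns
    (region_id, e_star, e, posterior).
    """
    ids, s, r = _as_counts(counts)
    fit = fit_binomial_mixture(
        counts, tol=tol, max_iter=max_iter, restarts=restarts, seed=seed
    )
    alpha_s, alpha_r = estimate_pseudo_counts(fit, c=pseudo_mass)
    e_star = raw_enrichment((s, r), alpha_s, alpha_r)
    return normalize_enrichment(e_star, fit, region_ids=ids), fit
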