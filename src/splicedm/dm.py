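"""Two-category Dirichlet-multinomial (beta-binomial) model for replicate
path counts, with maximum-likelihood fits and the likelihood-ratio test.

For an event with per-sample counts (x1, x2) supporting its two paths, the
model places a Beta(s*pi, s*(1-pi)) prior on the per-replicate path-1
proportion, giving the beta-binomial mass

    P(x1 | n, pi, s) = C(n, x1) * B(x1 + s*pi, x2 + s*(1-pi)) / B(s*pi, s*(1-pi))

with n = x1 + x2.  ``pi`` is the population path-1 proportion and ``s`` the
precision: large s approaches the binomial (no replicate overdispersion),
small s allows strong between-replicate variability.

The null model shares (pi, s) across both conditions; the alternative
allows condition-specific proportions with a shared precision, so the test
has one degree of freedom and isolates the splicing-proportion change.

Dispersion handling matters with two replicates per condition: a precision
re-estimated per event from four samples is strongly biased (incidental
proportion parameters), which makes the chi-square reference liberal.  The
pipeline therefore estimates one precision shared across all events by a
method of moments on within-condition replicate scatter
(:func:`estimate_dispersion_mom`) and holds it fixed while profiling the
proportions; :func:`fit_dm_null`/:func:`fit_dm_alt` also expose the
per-event free-precision maximum-likelihood fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

PI_EPS = 1e-6
S_MIN = 1e-3
S_MAX = 1e6
_LOGIT_LO = np.log(PI_EPS) - np.log1p(-PI_EPS)
_LOGIT_HI = -_LOGIT_LO


@dataclass
class DMFit:
    pi: float
    s: float
    loglik: float
    converged: bool


@dataclass
class AltFit:
    fit_mut: DMFit
    fit_ctrl: DMFit
    s: float
    loglik: float
    converged: bool


@dataclass
class LRTResult:
    stat: float
    df: int
    pval: float


def dm_log_pmf(x1, x2, pi, s):
    """Log-mass of the two-category Dirichlet-multinomial.

    Vectorized over counts; ``pi`` must lie in (0, 1) and ``s`` be positive.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("counts must be non-negative")
    if np.any(x1 + x2 == 0):
        raise ValueError("x1 and x2 must not both be zero")
    pi = float(pi)
    s = float(s)
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0,1), got {pi}")
    if s <= 0.0:
        raise ValueError(f"s must be positive, got {s}")
    n = x1 + x2
    a = s * pi
    b = s * (1.0 - pi)
    out = (
        special.gammaln(n + 1)
        - special.gammaln(x1 + 1)
        - special.gammaln(x2 + 1)
        + special.betaln(x1 + a, x2 + b)
        - special.betaln(a, b)
    )
    return out if out.ndim else float(out)


def _loglik_arrays(x1: np.ndarray, x2: np.ndarray, pi: float, s: float) -> float:
    return float(np.sum(dm_log_pmf(x1, x2, pi, s)))


def _clamp_pi(pi: float) -> float:
    return float(min(max(pi, PI_EPS), 1.0 - PI_EPS))


def _expit(z: float) -> float:
    return float(special.expit(z))


_N_COARSE_S = 49


def _profile_over_s(groups) -> tuple[float, float]:
    """Maximize sum of per-group pi-profiled log-likelihoods over s.

    Coarse scan over log s followed by bounded Brent refinement around the
    best cell; each evaluation profiles the proportion of every group by a
    bounded 1-D search.  Returns (s_hat, loglik).  Deterministic.
    """

    def prof(ls: float) -> float:
        s = float(np.exp(ls))
        return sum(_fit_pi_fixed_s(x1, x2, s).loglik for x1, x2 in groups)

    coarse = np.linspace(np.log(S_MIN), np.log(S_MAX), _N_COARSE_S)
    vals = np.array([prof(ls) for ls in coarse])
    i = int(np.argmax(vals))
    lo = coarse[max(0, i - 1)]
    hi = coarse[min(len(coarse) - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda ls: -prof(ls), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    ls_best, ll_best = float(res.x), -float(res.fun)
    if vals[i] > ll_best:
        ls_best, ll_best = float(coarse[i]), float(vals[i])
    return float(np.exp(ls_best)), ll_best


def _fit_pi_fixed_s(x1: np.ndarray, x2: np.ndarray, s: float) -> DMFit:
    """Profile the proportion at a fixed precision (bounded 1-D search)."""
    res = optimize.minimize_scalar(
        lambda lp: -_loglik_arrays(x1, x2, _clamp_pi(_expit(lp)), s),
        bounds=(_LOGIT_LO, _LOGIT_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    pi = _clamp_pi(_expit(float(res.x)))
    # the bounded search can stall a hair short of the boundary on
    # separated data; accept the boundary when it is better
    ll = -float(res.fun)
    for pb in (PI_EPS, 1.0 - PI_EPS):
        llb = _loglik_arrays(x1, x2, pb, s)
        if llb > ll:
            pi, ll = pb, llb
    return DMFit(pi=pi, s=float(s), loglik=ll, converged=bool(res.success))


def fit_dm_null(x1, x2, s_fixed: float | None = None) -> DMFit:
    """Shared-(pi, s) maximum-likelihood fit over all samples pooled.

    With ``s_fixed`` the precision is held and only the proportion is
    profiled; otherwise the precision is profiled out by a coarse scan over
    log s with Brent refinement, with the proportion re-profiled at each
    precision.  Deterministic given the data.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if s_fixed is not None:
        return _fit_pi_fixed_s(x1, x2, float(s_fixed))
    s_hat, loglik = _profile_over_s([(x1, x2)])
    fit = _fit_pi_fixed_s(x1, x2, s_hat)
    return DMFit(pi=fit.pi, s=s_hat, loglik=max(loglik, fit.loglik), converged=True)


def fit_dm_alt(x1_mut, x2_mut, x1_ctrl, x2_ctrl, s_fixed: float | None = None) -> AltFit:
    """Condition-specific proportions with a shared precision.

    Maximizes the joint likelihood over (pi_mut, pi_ctrl, s) — or over the
    two proportions alone when ``s_fixed`` is given; the shared dispersion
    makes the proportion difference the single tested parameter.
    """
    x1m = np.asarray(x1_mut, dtype=float)
    x2m = np.asarray(x2_mut, dtype=float)
    x1c = np.asarray(x1_ctrl, dtype=float)
    x2c = np.asarray(x2_ctrl, dtype=float)
    if s_fixed is not None:
        fm = _fit_pi_fixed_s(x1m, x2m, float(s_fixed))
        fc = _fit_pi_fixed_s(x1c, x2c, float(s_fixed))
        return AltFit(
            fit_mut=fm, fit_ctrl=fc, s=float(s_fixed),
            loglik=fm.loglik + fc.loglik,
            converged=fm.converged and fc.converged,
        )
    s_hat, _ = _profile_over_s([(x1m, x2m), (x1c, x2c)])
    fm = _fit_pi_fixed_s(x1m, x2m, s_hat)
    fc = _fit_pi_fixed_s(x1c, x2c, s_hat)
    return AltFit(
        fit_mut=fm, fit_ctrl=fc, s=s_hat,
        loglik=fm.loglik + fc.loglik, converged=True,
    )


def estimate_dispersion_mom(units) -> float:
    """Shared precision s from within-condition replicate scatter.

    ``units`` is an iterable of (x1, x2) count arrays, one per
    event-condition group with >= 2 informative replicates.  For replicate
    proportions p_j = x_j/n_j the pairwise expectation
    E[(p_j - p_k)^2 / 2] = v(pi) * (rho + (1 - rho) * (1/n_j + 1/n_k)/2)
    with v(pi) = pi(1-pi) and rho = 1/(s+1) identifies rho by a ratio of
    sums across units; the plug-in v(pi_hat) is bias-corrected and the
    solve iterated.  Unbiased for the group proportions (no incidental-
    parameter bias), unaffected by true between-condition differences.
    """
    prepared = []
    for x1, x2 in units:
        x1 = np.asarray(x1, dtype=float)
        n = x1 + np.asarray(x2, dtype=float)
        keep = n > 0
        if keep.sum() < 2:
            continue
        prepared.append((x1[keep], n[keep]))
    if not prepared:
        return S_MAX
    rho = 0.0
    for _ in range(3):
        num = den = 0.0
        for x1, n in prepared:
            p = x1 / n
            big_n = n.sum()
            pi = x1.sum() / big_n
            v = pi * (1.0 - pi)
            # E[v(pi_hat)] = v(pi) * (1 - c): undo the plug-in shrinkage
            c = rho * np.sum(n**2) / big_n**2 + (1.0 - rho) / big_n
            v = v / max(1.0 - c, 1e-6)
            t_sum = h_sum = 0.0
            m = 0
            r = len(n)
            for j in range(r):
                for k in range(j + 1, r):
                    t_sum += (p[j] - p[k]) ** 2 / 2.0
                    h_sum += (1.0 / n[j] + 1.0 / n[k]) / 2.0
                    m += 1
            t_bar, h_bar = t_sum / m, h_sum / m
            num += t_bar - v * h_bar
            den += v * (1.0 - h_bar)
        rho = num / den if den > 0 else 0.0
        rho = float(min(max(rho, 0.0), 1.0))
    if rho <= 1.0 / (S_MAX + 1.0):
        return S_MAX
    if rho >= 1.0 / (S_MIN + 1.0):
        return S_MIN
    return 1.0 / rho - 1.0


def likelihood_ratio_test(
    x1_mut, x2_mut, x1_ctrl, x2_ctrl, s_fixed: float | None = None
) -> tuple[LRTResult, DMFit, AltFit]:
    """LRT of condition-specific vs shared splicing proportion (df = 1).

    With ``s_fixed`` (the pipeline default passes the shared
    across-events precision) only the proportions are profiled; without it
    both models re-estimate the precision per event.  Small negative
    statistics from numerical error are clamped to zero.
    """
    x1 = np.concatenate([np.atleast_1d(x1_mut), np.atleast_1d(x1_ctrl)])
    x2 = np.concatenate([np.atleast_1d(x2_mut), np.atleast_1d(x2_ctrl)])
    null = fit_dm_null(x1, x2, s_fixed=s_fixed)
    alt = fit_dm_alt(x1_mut, x2_mut, x1_ctrl, x2_ctrl, s_fixed=s_fixed)
    stat = 2.0 * (alt.loglik - null.loglik)
    if stat < 0.0:
        stat = 0.0
    pval = float(stats.chi2.sf(stat, df=1))
    return LRTResult(stat=stat, df=1, pval=pval), null, alt
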