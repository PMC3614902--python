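"""Mismatch distributions and sudden-expansion demography.

The observed mismatch distribution is the histogram of pairwise
mutational-step differences over all C(n,2) individual pairs.  Under the
sudden-expansion model a population at scaled (mutational) size theta0
grows instantaneously to theta1 at mutational time tau before present; the
expected mismatch spectrum has the closed form

    F_j = Fhat_j(theta1)
          + exp(-tau (theta1 + 1)/theta1)
            * sum_{m<=j} tau^(j-m)/(j-m)! [Fhat_m(theta0) - Fhat_m(theta1)]

with ``Fhat_j(theta) = theta^j / (theta+1)^(j+1)`` the equilibrium
spectrum.  Fitting minimizes the sum of squared deviations (SSD) between
observed and expected spectra; goodness of fit (SSD and Harpending's
raggedness index) is assessed by parametric bootstrap with coalescent
simulation under the fitted model, and the expansion parameter converts to
calendar time through ``T = tau / (2 u)`` with ``u = mu * k * g``.

Raggedness convention: the spectrum is padded with a zero class on both
ends and ``r = sum (x_i - x_{i-1})^2`` over successive classes, so a
one-class spike has r = 2 and a flat spectrum contributes only its two
boundary terms.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .haplotypes import StepDistanceMatrix

__all__ = [
    "MismatchFit",
    "mismatch_distribution",
    "expected_mismatch",
    "fit_sudden_expansion",
    "raggedness",
    "parametric_bootstrap",
    "expansion_time",
    "simulate_mismatch_spectrum",
]

FIT_PAD = 5  # fitted support extends this many classes past the observed max
TAU_MAX = 50.0  # numerical bounds for the optimizer
THETA_MAX = 1e4


@dataclass
class MismatchFit:
    """Observed spectrum with fitted sudden-expansion parameters."""

    F_obs: np.ndarray
    n: int
    tau: float
    theta0: float
    theta1: float
    SSD: float
    raggedness: float
    P_SSD: float | None = None
    P_rag: float | None = None
    n_bootstrap: int | None = None
    expansion: dict[str, float] = field(default_factory=dict)


def mismatch_distribution(
    individuals: Sequence[str] | Mapping[str, int],
    d: StepDistanceMatrix,
) -> np.ndarray:
    """Relative frequencies of pairwise differences, classes 0..max.

    *individuals* is either a sequence of haplotype labels (one per
    individual) or a mapping of haplotype label to count.
    """
    if isinstance(individuals, Mapping):
        counts = dict(individuals)
    else:
        counts = {}
        for h in individuals:
            counts[h] = counts.get(h, 0) + 1
    labels = sorted(counts)
    n = sum(counts.values())
    if n < 2:
        raise ValueError("need at least two individuals")
    sub = d.submatrix(labels).matrix
    c = np.asarray([counts[h] for h in labels], dtype=float)
    dmax = int(sub.max()) if len(labels) > 1 else 0
    spec = np.zeros(dmax + 1)
    for i in range(len(labels)):
        spec[0] += c[i] * (c[i] - 1) / 2.0
        for j in range(i + 1, len(labels)):
            spec[sub[i, j]] += c[i] * c[j]
    return spec / spec.sum()


def _equilibrium(theta: float, j: np.ndarray) -> np.ndarray:
    if theta <= 0:
        out = np.zeros_like(j, dtype=float)
        out[j == 0] = 1.0
        return out
    return np.exp(j * np.log(theta) - (j + 1.0) * np.log(theta + 1.0))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_classes: int
) -> np.ndarray:
    """Model mismatch spectrum over classes 0..n_classes-1, renormalized."""
    if tau < 0 or theta0 < 0 or theta1 < theta0:
        raise ValueError("require tau >= 0 and 0 <= theta0 <= theta1")
    j = np.arange(n_classes)
    f1 = _equilibrium(theta1, j)
    if theta1 <= 0:
        return f1  # both sizes zero: all pairs identical
    diff = _equilibrium(theta0, j) - f1
    logw = -tau * (theta1 + 1.0) / theta1
    if tau == 0:
        pois = np.zeros(n_classes)
        pois[0] = 1.0
    else:
        pois = np.exp(j * np.log(tau) - gammaln(j + 1.0))
    conv = np.convolve(pois, diff)[:n_classes]
    F = f1 + np.exp(logw) * conv
    F = np.clip(F, 0.0, None)
    s = F.sum()
    if s <= 0:
        raise ValueError("degenerate model spectrum")
    return F / s


def fit_sudden_expansion(
    F_obs: np.ndarray, n: int | None = None
) -> MismatchFit:
    """Least-squares fit of the sudden-expansion model to a spectrum.

    Coarse grid over (tau, theta0, theta1) followed by Nelder-Mead
    refinement of the SSD; deterministic for fixed input.  The fitted
    support covers the observed classes plus a small zero-padded tail.
    """
    F = np.asarray(F_obs, dtype=float)
    if F.ndim != 1 or F.size < 1 or (F < 0).any():
        raise ValueError("invalid observed spectrum")
    F = F / F.sum()
    K = F.size + FIT_PAD
    Fpad = np.concatenate([F, np.zeros(FIT_PAD)])
    j = np.arange(K)

    def clipped(params: np.ndarray) -> tuple[float, float, float]:
        tau, th0, dth = np.abs(params)
        return min(tau, TAU_MAX), min(th0, THETA_MAX), min(th0 + dth, THETA_MAX)

    def ssd(params: np.ndarray) -> float:
        tau, th0, th1 = clipped(params)
        try:
            model = expected_mismatch(tau, th0, max(th0, th1), K)
        except ValueError:
            return np.inf
        return float(np.sum((Fpad - model) ** 2))

    params, models = _grid_models(K)
    vals = np.sum((models - Fpad) ** 2, axis=1)
    b = int(np.argmin(vals))
    if not np.isfinite(vals[b]):
        raise RuntimeError("sudden-expansion fit failed to initialize")
    best = tuple(params[b])
    x0 = np.array([best[0], best[1], best[2] - best[1]])
    res = minimize(
        ssd, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-11, "maxiter": 250},
    )
    tau, th0, th1 = clipped(res.x)
    dth = max(th1 - th0, 0.0)
    fit_ssd = ssd(res.x)
    if not np.isfinite(fit_ssd):
        raise RuntimeError("sudden-expansion fit did not converge")
    return MismatchFit(
        F_obs=F,
        n=int(n) if n else 0,
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th0 + dth),
        SSD=float(fit_ssd),
        raggedness=raggedness(F),
    )


@lru_cache(maxsize=64)
def _grid_models(K: int):
    """Coarse-grid model spectra for the SSD fit, cached per support size.

    Grid: tau in [0, 20] (41 steps), theta0 in {0, 0.1, 0.3, 1, 3, 10},
    theta1 log-spaced in [0.5, 1000]; returns (params (M, 3), spectra (M, K)).
    """
    taus = np.linspace(0.0, 20.0, 41)
    th0s = np.array([0.0, 0.1, 0.3, 1.0, 3.0, 10.0])
    th1s = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
    j = np.arange(K)
    with np.errstate(divide="ignore"):
        logtau = np.where(taus > 0, np.log(taus), 0.0)
    pois = np.exp(np.outer(logtau, j) - gammaln(j + 1.0))
    pois[taus == 0] = 0.0
    pois[taus == 0, 0] = 1.0
    params, spectra = [], []
    for th0 in th0s:
        f0 = _equilibrium(th0, j)
        for th1 in th1s:
            if th1 < th0:
                continue
            f1 = _equilibrium(th1, j)
            diff = f0 - f1
            toep = np.zeros((K, K))
            for m in range(K):
                toep[m, m:] = diff[: K - m]
            models = f1 + np.exp(-taus * (th1 + 1.0) / th1)[:, None] * (pois @ toep)
            models = np.clip(models, 0.0, None)
            sums = models.sum(axis=1)
            with np.errstate(invalid="ignore"):
                models = np.where(sums[:, None] > 0, models / sums[:, None], np.inf)
            for t_i, tau in enumerate(taus):
                params.append((tau, th0, th1))
                spectra.append(models[t_i])
    return np.asarray(params), np.asarray(spectra)


def raggedness(F_obs: np.ndarray) -> float:
    """Harpending's raggedness index with zero padding on both ends."""
    F = np.asarray(F_obs, dtype=float)
    x = np.concatenate([[0.0], F, [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def simulate_mismatch_spectrum(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One coalescent sample's mismatch spectrum under sudden expansion.

    Kingman coalescent in mutational (pairwise) time: coalescence rate
    C(k,2)/theta with theta = theta1 more recently than tau and theta0
    before; infinite-sites mutations at rate 1/2 per lineage.  Returns
    relative class frequencies.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise ValueError("invalid coalescent parameters")
    acc = np.zeros(n)  # mutations from each leaf up to its current lineage
    born = np.zeros(n)
    lineages: list[np.ndarray] = [np.array([i]) for i in range(n)]
    t = 0.0
    spectrum: dict[int, float] = {}
    TINY = 1e-12
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0
        if t < tau:
            wait = rng.exponential(theta1 / rate)
            if t + wait > tau:
                t = tau
                continue
            t += wait
        else:
            if theta0 <= TINY:
                wait = 0.0
            else:
                wait = rng.exponential(theta0 / rate)
            t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        # mutations on the two merging branches
        for leafset in (a, b):
            length = t - born[leafset[0]]  # all leaves in a lineage share born time
            m = rng.poisson(0.5 * length) if length > 0 else 0
            if m:
                acc[leafset] += m
        # cross pairs coalesce here: record their differences
        sums = np.add.outer(acc[a], acc[b]).ravel()
        for val, cnt in zip(*np.unique(sums, return_counts=True)):
            spectrum[int(val)] = spectrum.get(int(val), 0.0) + float(cnt)
        merged = np.concatenate([a, b])
        born_new = t
        for leaf in merged:
            born[leaf] = born_new
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    dmax = max(spectrum)
    spec = np.zeros(dmax + 1)
    for k_, v in spectrum.items():
        spec[k_] = v
    return spec / spec.sum()


def parametric_bootstrap(
    fit: MismatchFit,
    n: int | None = None,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> MismatchFit:
    """Goodness-of-fit p-values for SSD and raggedness by parametric bootstrap.

    B coalescent samples of size n are simulated under the fitted
    (tau, theta0, theta1), each refitted, and P = fraction of simulated
    statistics at least the observed (with +1 smoothing).  Returns the fit
    with ``P_SSD`` and ``P_rag`` filled in.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = n or fit.n
    if not n or n < 2:
        raise ValueError("sample size required for the parametric bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta1 = max(fit.theta1, 1e-6)
    hits_ssd = hits_rag = 0
    used = 0
    for _ in range(B):
        spec = simulate_mismatch_spectrum(n, fit.tau, fit.theta0, theta1, rng)
        try:
            refit = fit_sudden_expansion(spec, n)
        except RuntimeError:
            continue
        used += 1
        if refit.SSD >= fit.SSD - 1e-15:
            hits_ssd += 1
        if refit.raggedness >= fit.raggedness - 1e-15:
            hits_rag += 1
    if used == 0:
        raise RuntimeError("all bootstrap refits failed")
    fit.P_SSD = (hits_ssd + 1.0) / (used + 1.0)
    fit.P_rag = (hits_rag + 1.0) / (used + 1.0)
    fit.n_bootstrap = used
    return fit


def expansion_time(tau: float, mu: float, k: float, g: float) -> dict[str, float]:
    """Convert the expansion parameter tau to time since expansion.

    ``u = mu * k * g`` is the per-sequence per-generation mutation rate
    (mu in substitutions/site/year, k the sequence length, g the generation
    time in years); ``T = tau / (2 u)`` generations.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if mu <= 0 or k <= 0 or g <= 0:
        raise ValueError("mu, k and g must be positive")
    u = mu * k * g
    T = tau / (2.0 * u)
    return {
        "u": u,
        "generations": T,
        "years": T * g,
        "Myr": T * g / 1e6,
    }
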