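"""Two-state (telegraph) promoter model: stationary law and per-gene inference.

The telegraph model describes a promoter switching OFF->ON at rate ``alpha``
and ON->OFF at rate ``beta``, transcribing at rate ``gamma`` while ON, with
mRNA degrading at unit rate (all rates are expressed in units of the mRNA
degradation rate).  The stationary mRNA count is Poisson-Beta distributed:

    X ~ Poisson(gamma * u),   u ~ Beta(alpha, beta)

Derived burst parameters use the identity-consistent convention

    burst size      s = gamma / beta
    burst frequency f = alpha * beta / (alpha + beta)

so that the stationary mean equals ``s * f = gamma * alpha / (alpha + beta)``
exactly.

Inference is a two-stage scheme: closed-form inversion of the first three
factorial moments (``fit_moments``) followed by maximum likelihood in
log-parameter space (``fit_mle``).  Genes whose empirical moments admit no
positive-rate solution are assigned a flagged Poisson fallback (burst size
-> 0 at matched mean) so downstream gene universes stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "TelegraphParams",
    "TelegraphFit",
    "poisson_beta_logpmf",
    "poisson_beta_pmf",
    "fit_moments",
    "fit_mle",
    "fit_gene_table",
    "differential_burst",
    "regression_decomposition",
]

# switching-rate scale of the flagged Poisson fallback: with alpha = beta
# this large the Poisson-Beta law collapses onto a Poisson at the same mean
# in the frequent-tiny-burst limit (s -> 0).
_POISSON_ALPHA = 1.0e4


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic rates of the two-state promoter, in mRNA-degradation units."""

    alpha: float  # OFF -> ON activation rate
    beta: float   # ON -> OFF inactivation rate
    gamma: float  # transcription rate while ON

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"switching rates must be positive, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.gamma < 0:
            raise ValueError(f"transcription rate must be >= 0, got gamma={self.gamma}")

    @property
    def mean(self) -> float:
        """Stationary mean, gamma * alpha / (alpha + beta)."""
        return self.gamma * self.alpha / (self.alpha + self.beta)

    @property
    def burst_size(self) -> float:
        """Expected mRNA output per burst, s = gamma / beta."""
        return self.gamma / self.beta

    @property
    def burst_frequency(self) -> float:
        """Rate of productive promoter activations, f = alpha*beta/(alpha+beta)."""
        return self.alpha * self.beta / (self.alpha + self.beta)


@dataclass
class TelegraphFit:
    """Result of fitting the telegraph model to one gene in one condition."""

    params: TelegraphParams
    loglik: float
    method: str                    # "moments" | "mle"
    converged: bool
    feasible: bool = True          # False => flagged Poisson fallback
    near_poisson: bool = False     # fit indistinguishable from Poisson at this mean
    gene_id: str | None = None
    condition: str | None = None
    n_cells: int = 0

    @property
    def burst_size(self) -> float:
        return self.params.burst_size

    @property
    def burst_frequency(self) -> float:
        return self.params.burst_frequency

    @property
    def mean(self) -> float:
        return self.params.mean


# ---------------------------------------------------------------------------
# Stationary pmf
# ---------------------------------------------------------------------------

def _log_hyp1f1_series(a: float, b: np.ndarray, x: float) -> np.ndarray:
    """log 1F1(a; b; x) for x >= 0 by term-wise logsumexp of the Kummer series.

    All series terms are positive for x >= 0, so the log-space sum is exact to
    floating accuracy and never overflows, unlike scipy's hyp1f1 at large x.
    ``b`` may be a vector (one entry per count value).
    """
    if x == 0.0:
        return np.zeros_like(b, dtype=float)
    # terms: (a)_j / (b)_j * x^j / j!;  truncate once past the mode at j ~ x
    j_max = int(np.ceil(x + 12.0 * np.sqrt(x + 1.0) + 60.0))
    j = np.arange(j_max + 1, dtype=float)
    out = np.empty(len(b), dtype=float)
    # chunk over b to keep the (len(b) x j_max) term matrix bounded
    chunk = max(1, int(5e6) // (j_max + 1))
    for lo in range(0, len(b), chunk):
        bb = b[lo:lo + chunk, None]
        log_terms = (
            special.gammaln(a + j)
            - special.gammaln(a)
            + special.gammaln(bb)
            - special.gammaln(bb + j)
            + j * np.log(x)
            - special.gammaln(j + 1.0)
        )
        out[lo:lo + chunk] = special.logsumexp(log_terms, axis=1)
    return out


def poisson_beta_logpmf(k, params: TelegraphParams) -> np.ndarray:
    """Log stationary pmf of the telegraph model at counts ``k``.

    Uses the confluent-hypergeometric representation with the Kummer
    transformation applied, so the 1F1 argument is positive and the series
    is a sum of positive terms evaluated in log space:

        P(k) = gamma^k/k! * B(alpha+k, beta)/B(alpha, beta)
               * exp(-gamma) * 1F1(beta; alpha+beta+k; gamma)
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("counts must be non-negative integers")
    a, b, g = params.alpha, params.beta, params.gamma
    if g == 0.0:
        out = np.where(k == 0, 0.0, -np.inf)
        return out
    log1f1 = _log_hyp1f1_series(b, a + b + k, g)
    return (
        k * np.log(g)
        - special.gammaln(k + 1.0)
        + special.betaln(a + k, b)
        - special.betaln(a, b)
        - g
        + log1f1
    )


def poisson_beta_pmf(k, params: TelegraphParams) -> np.ndarray:
    """Stationary pmf P(X = k); vectorized over ``k``."""
    return np.exp(poisson_beta_logpmf(k, params))


def pmf_support(params: TelegraphParams, tail_mass: float = 1e-10) -> int:
    """Upper count K such that P(X > K) <= tail_mass (conservative bound).

    X is stochastically dominated by Poisson(gamma), so a Poisson tail bound
    on gamma suffices.
    """
    g = params.gamma
    if g == 0:
        return 0
    k = int(np.ceil(g + 10.0 * np.sqrt(g) + 20.0))
    while stats.poisson.sf(k, g) > tail_mass:
        k = int(k * 1.5) + 10
    return k


# ---------------------------------------------------------------------------
# Moment-based fitting
# ---------------------------------------------------------------------------

def _poisson_loglik(counts: np.ndarray) -> float:
    return float(np.sum(stats.poisson.logpmf(counts, counts.mean())))


def _is_near_poisson(loglik: float, counts: np.ndarray, margin: float = 2.0) -> bool:
    """True when the telegraph fit barely improves on a Poisson at the mean.

    On the near-Poisson likelihood ridge the burst parameters are not
    identifiable; callers should not interpret s and f quantitatively there.
    """
    return loglik - _poisson_loglik(counts) < margin


def _factorial_moments(counts: np.ndarray) -> tuple[float, float, float]:
    x = counts.astype(float)
    m1 = x.mean()
    m2 = (x * (x - 1)).mean()
    m3 = (x * (x - 1) * (x - 2)).mean()
    return m1, m2, m3


def _invert_moments(m1: float, m2: float, m3: float) -> TelegraphParams | None:
    """Closed-form inversion of the first three factorial moments.

    For the Poisson-Beta law, E[X(X-1)...(X-j+1)] = gamma^j (alpha)_j/(alpha+beta)_j.
    With r1 = m1, r2 = m2/m1, r3 = m3/m2 the rates are recovered exactly;
    returns None when the data moments admit no positive solution.
    """
    if m1 <= 0 or m2 <= 0 or m3 <= 0:
        return None
    r1, r2, r3 = m1, m2 / m1, m3 / m2
    denom_g = r1 - 2.0 * r2 + r3
    denom_a = r1 * r2 - 2.0 * r1 * r3 + r2 * r3
    if denom_g == 0.0 or denom_a == 0.0:
        return None
    gamma = (2.0 * r1 * r3 - r1 * r2 - r2 * r3) / denom_g
    alpha = 2.0 * r1 * (r3 - r2) / denom_a
    if not (np.isfinite(alpha) and np.isfinite(gamma)) or alpha <= 0 or gamma <= r1:
        return None
    beta = alpha * (gamma - r1) / r1
    if not np.isfinite(beta) or beta <= 0:
        return None
    return TelegraphParams(alpha=alpha, beta=beta, gamma=gamma)


def _poisson_fallback(mean: float) -> TelegraphParams:
    """Flagged near-Poisson parameterization at the requested mean.

    Large, equal switching rates put the promoter in the frequent-tiny-burst
    limit: u ~ Beta(a, a) concentrates at 1/2, X -> Poisson(mean), with
    burst size s = gamma/beta -> 0 and frequency f -> large.
    """
    alpha = beta = _POISSON_ALPHA
    gamma = max(mean, 1e-12) * (alpha + beta) / alpha
    return TelegraphParams(alpha=alpha, beta=beta, gamma=gamma)


def fit_moments(counts) -> TelegraphFit:
    """Method-of-moments telegraph fit from a vector of integer counts.

    Solves the three-factorial-moment system in closed form.  When the system
    has no positive-rate solution (common for weakly expressed or
    Poisson-like genes) the fit falls back to a flagged Poisson
    parameterization matching the empirical mean, with ``feasible=False``.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 3:
        raise ValueError("need a 1-D vector of at least 3 counts")
    if np.unique(counts).size < 3:
        params = _poisson_fallback(float(np.mean(counts)))
        ll = float(np.sum(poisson_beta_logpmf(counts, params)))
        return TelegraphFit(params, ll, "moments", converged=True, feasible=False,
                            near_poisson=True, n_cells=counts.size)
    m1, m2, m3 = _factorial_moments(counts)
    params = _invert_moments(m1, m2, m3)
    feasible = params is not None
    if params is None:
        params = _poisson_fallback(m1)
    ll = float(np.sum(poisson_beta_logpmf(counts, params)))
    return TelegraphFit(params, ll, "moments", converged=True, feasible=feasible,
                        near_poisson=_is_near_poisson(ll, counts),
                        n_cells=counts.size)


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

# optimizer search domain: rates within [1e-4, 1e4] degradation units, ample
# for UMI-scale data while keeping the pmf series short
_LOG_BOUND = np.log(1.0e4)


def fit_mle(counts, init: TelegraphParams | TelegraphFit | None = None,
            tol: float = 1e-6, max_iter: int = 500) -> TelegraphFit:
    """Maximum-likelihood telegraph fit, optimizing in log-parameter space.

    Deterministic: starts from ``init`` (default: the moment fit) and runs
    Nelder-Mead on (log alpha, log beta, log gamma).  Returns the initial fit
    with ``converged=False`` if the optimizer fails to improve the likelihood.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 3:
        raise ValueError("need a 1-D vector of at least 3 counts")
    if init is None:
        init = fit_moments(counts)
    init_params = init.params if isinstance(init, TelegraphFit) else init
    feasible = init.feasible if isinstance(init, TelegraphFit) else True
    n = counts.size

    values, weights = np.unique(counts, return_counts=True)

    def nll(log_theta: np.ndarray) -> float:
        if np.any(np.abs(log_theta) > _LOG_BOUND):
            return np.inf
        p = TelegraphParams(*np.exp(log_theta))
        lp = poisson_beta_logpmf(values, p)
        return -float(np.dot(weights, lp))

    x0 = np.log([init_params.alpha, init_params.beta, init_params.gamma])
    ll0 = float(np.sum(poisson_beta_logpmf(counts, init_params)))
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": max_iter},
    )
    if not np.isfinite(res.fun) or -res.fun < ll0:
        return TelegraphFit(init_params, ll0, "mle", converged=False,
                            feasible=feasible,
                            near_poisson=_is_near_poisson(ll0, counts), n_cells=n)
    params = TelegraphParams(*np.exp(res.x))
    ll = -float(res.fun)
    return TelegraphFit(params, ll, "mle", converged=bool(res.success),
                        feasible=feasible,
                        near_poisson=_is_near_poisson(ll, counts), n_cells=n)


# ---------------------------------------------------------------------------
# Per-gene tables and condition contrasts
# ---------------------------------------------------------------------------

def fit_gene_table(matrix, condition: str | None = None, method: str = "moments",
                   normalize: bool = True) -> pd.DataFrame:
    """Fit the telegraph model to every gene of a CountMatrix.

    Parameters
    ----------
    matrix : CountMatrix
        Filtered counts (genes x cells).
    condition : str, optional
        Restrict to cells of this condition; default uses all cells.
    method : {"moments", "mle"}
        "mle" runs moment initialization + maximum likelihood per gene.
    normalize : bool
        Depth-normalize cells to the median library size and round back to
        integers before fitting (renormalizing within whatever cell subset is
        passed, so cluster-restricted runs get cluster-specific normalization).
    """
    from .qc_filtering import CountMatrix  # local import to avoid cycle

    if not isinstance(matrix, CountMatrix):
        raise TypeError("matrix must be a CountMatrix")
    if condition is not None:
        matrix = matrix.subset_cells(matrix.condition == condition)
    counts = matrix.to_dense()
    if normalize:
        counts = depth_normalize(counts)
    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        fit = fit_moments(counts[i])
        if method == "mle":
            fit = fit_mle(counts[i], init=fit)
        rows.append({
            "gene_id": gene,
            "condition": condition if condition is not None else "all",
            "alpha": fit.params.alpha,
            "beta": fit.params.beta,
            "gamma": fit.params.gamma,
            "burst_size": fit.burst_size,
            "burst_frequency": fit.burst_frequency,
            "mean": fit.mean,
            "loglik": fit.loglik,
            "method": fit.method,
            "converged": fit.converged,
            "feasible": fit.feasible,
            "near_poisson": fit.near_poisson,
        })
    return pd.DataFrame(rows)


def depth_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale each cell's counts to the median library size; round to int.

    Rounding keeps the data in the integer count family the stationary law
    describes.  Cells with zero total are left at zero.
    """
    counts = np.asarray(counts)
    libsize = counts.sum(axis=0).astype(float)
    med = np.median(libsize[libsize > 0])
    factors = np.where(libsize > 0, med / np.where(libsize > 0, libsize, 1.0), 0.0)
    return np.rint(counts * factors[None, :]).astype(np.int64)


def differential_burst(fits_wt: pd.DataFrame, fits_ko: pd.DataFrame) -> dict:
    """Per-gene burst differentials between conditions plus genotype-level tests.

    Returns a dict with a per-gene table (Fburst = (f_KO - f_WT)/f_WT and the
    analogous size differential), KS tests on the genotype-level distributions
    of burst frequency and burst size, and the KO - WT median differences.
    """
    wt = fits_wt.set_index("gene_id")
    ko = fits_ko.set_index("gene_id")
    shared = wt.index.intersection(ko.index)
    n_dropped = len(wt.index.union(ko.index)) - len(shared)
    f_wt = wt.loc[shared, "burst_frequency"].to_numpy()
    f_ko = ko.loc[shared, "burst_frequency"].to_numpy()
    s_wt = wt.loc[shared, "burst_size"].to_numpy()
    s_ko = ko.loc[shared, "burst_size"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fburst = np.where(f_wt > 0, (f_ko - f_wt) / f_wt, np.nan)
        fsize = np.where(s_wt > 0, (s_ko - s_wt) / s_wt, np.nan)
    if "feasible" in wt.columns and "feasible" in ko.columns:
        feasible = (wt.loc[shared, "feasible"] & ko.loc[shared, "feasible"]).to_numpy()
    else:
        feasible = np.ones(len(shared), dtype=bool)
    table = pd.DataFrame({
        "gene_id": shared,
        "f_WT": f_wt, "f_KO": f_ko, "s_WT": s_wt, "s_KO": s_ko,
        "Fburst": fburst, "size_differential": fsize,
        "feasible_both": feasible,
    })
    # distribution-level comparisons exclude flagged Poisson fallbacks: their
    # burst parameters are placeholder atoms, and including them turns the KS
    # into a test of the feasibility rate rather than of the fitted dynamics
    ks_f = stats.ks_2samp(f_wt[feasible], f_ko[feasible])
    ks_s = stats.ks_2samp(s_wt[feasible], s_ko[feasible])
    return {
        "table": table,
        "n_dropped": n_dropped,
        "n_feasible": int(feasible.sum()),
        "frequency_ks": (float(ks_f.statistic), float(ks_f.pvalue)),
        "size_ks": (float(ks_s.statistic), float(ks_s.pvalue)),
        "frequency_median_difference": float(
            np.median(f_ko[feasible]) - np.median(f_wt[feasible])),
        "size_median_difference": float(
            np.median(s_ko[feasible]) - np.median(s_wt[feasible])),
    }


def regression_decomposition(stats_table: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """OLS of log10 mean and log10 CV on log10 burst size and frequency.

    Quantifies how much each bursting parameter contributes to average
    expression versus expression noise.  Returns one row per
    (response, predictor) with coefficient, standard error and p-value, plus
    the intercept and R^2 of each model.
    """
    import statsmodels.api as sm

    left = stats_table[["gene_id", "mean", "cv"]].rename(columns={"mean": "mean_stat"})
    merged = left.merge(fits[["gene_id", "burst_size", "burst_frequency"]], on="gene_id")
    usable = merged[
        (merged["mean_stat"] > 0) & (merged["cv"] > 0)
        & (merged["burst_size"] > 0) & (merged["burst_frequency"] > 0)
    ]
    if len(usable) < 10:
        raise ValueError(f"only {len(usable)} usable genes; need >= 10 for regression")
    X = sm.add_constant(pd.DataFrame({
        "log_burst_size": np.log10(usable["burst_size"]),
        "log_burst_frequency": np.log10(usable["burst_frequency"]),
    }))
    rows = []
    for response, values in (("log_mean", np.log10(usable["mean_stat"])),
                             ("log_cv", np.log10(usable["cv"]))):
        model = sm.OLS(values.to_numpy(), X).fit()
        for name in X.columns:
            rows.append({
                "response": response,
                "predictor": name,
                "coef": model.params[name],
                "stderr": model.bse[name],
                "pvalue": model.pvalues[name],
                "r_squared": model.rsquared,
                "n_genes": int(len(usable)),
            })
    return pd.DataFrame(rows)
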