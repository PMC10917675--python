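"""Rank statistics, cross-validation, permutation inference and power.

All model validation in this package is non-parametric: Spearman rank
correlations relate model-based outcome estimates to empirical
improvements, and their significance comes from label permutation, not
from parametric null distributions.  The one parametric computation is
the "compromise" power analysis for a bivariate-normal correlation
test, in which the critical value is chosen so that the beta/alpha
ratio equals a stated constant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

__all__ = [
    "spearman",
    "spearman_map",
    "permutation_p",
    "kfold_cv",
    "CVReport",
    "cross_disorder_matrix",
    "SpecificityMatrix",
    "equality_of_proportions",
    "two_sample_ttest",
    "compromise_power",
    "PowerSpec",
]

# Exact permutation p-values are used below this sample size; the t
# approximation above it.
EXACT_P_MAX_N = 9
# Full enumeration cap (7! = 5040); larger small-n cases fall back to
# Monte-Carlo permutation.
ENUMERATION_CAP = 5040
MC_PERMUTATIONS = 10_000


def _check_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 4:
        raise ValueError(f"{name} needs at least 4 observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.ptp(arr) == 0:
        raise ValueError(f"{name} is constant; rank correlation undefined")
    return arr


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of pre-ranked vectors (= Spearman rho)."""
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    return float(cx @ cy) / denom


def spearman(x: Sequence[float], y: Sequence[float],
             seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  For n >= 10 the p-value uses the
    t-distribution approximation; below that an exact permutation
    distribution is enumerated (all n! orderings when n <= 7, otherwise
    10,000 seeded Monte-Carlo permutations).
    """
    xa = _check_vector(x, "x")
    ya = _check_vector(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    rx, ry = _rank(xa), _rank(ya)
    rho = _rank_corr(rx, ry)
    if n >= EXACT_P_MAX_N + 1:
        p = _t_pvalue(rho, n)
    else:
        p = _perm_pvalue(rx, ry, rho, seed)
    return rho, p


def _t_pvalue(rho: float | np.ndarray, n: int) -> float | np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum(p, 1.0)


def _perm_pvalue(rx: np.ndarray, ry: np.ndarray, rho: float, seed: int) -> float:
    n = rx.size
    if math.factorial(n) <= ENUMERATION_CAP:
        perms = np.array(list(itertools.permutations(range(n))))
        null = np.array([_rank_corr(rx, ry[p]) for p in perms])
        return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    rng = np.random.default_rng(seed)
    null = np.array([
        _rank_corr(rx, ry[rng.permutation(n)]) for _ in range(MC_PERMUTATIONS)
    ])
    return float((1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (1 + MC_PERMUTATIONS))


def spearman_map(X: np.ndarray, y: Sequence[float],
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman of an (n_obs, n_features) matrix against y.

    Vectorised mass-univariate version of :func:`spearman` with the same
    tie handling and p-value rules.  Constant columns yield rho = 0,
    p = 1 (a feature no field modulates carries no information).
    """
    X = np.asarray(X, dtype=float)
    ya = _check_vector(y, "y")
    n = X.shape[0]
    if n != ya.size:
        raise ValueError("X rows must match y length")
    const = np.ptp(X, axis=0) == 0
    rX = _rank(X, axis=0)
    ry = _rank(ya)
    cX = rX - rX.mean(axis=0)
    cy = ry - ry.mean()
    denom = np.sqrt(np.einsum("ij,ij->j", cX, cX) * float(cy @ cy))
    denom[denom == 0] = np.inf
    rho = (cy @ cX) / denom
    if n >= EXACT_P_MAX_N + 1:
        p = _t_pvalue(rho, n)
    else:
        p = _perm_pvalue_map(cX, ry, rho, seed)
    rho = np.where(const, 0.0, rho)
    p = np.where(const, 1.0, p)
    return rho, p


def _perm_pvalue_map(cX: np.ndarray, ry: np.ndarray, rho: np.ndarray,
                     seed: int) -> np.ndarray:
    n = cX.shape[0]
    if math.factorial(n) <= ENUMERATION_CAP:
        perm_idx = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perm_idx = np.array([rng.permutation(n) for _ in range(MC_PERMUTATIONS)])
    cy = ry[perm_idx] - ry.mean()  # (n_perm, n)
    sx = np.sqrt(np.einsum("ij,ij->j", cX, cX))
    sy = np.sqrt(np.einsum("ij,ij->i", cy, cy))
    sx[sx == 0] = np.inf
    p_out = np.empty(cX.shape[1])
    chunk = 4096
    for lo in range(0, cX.shape[1], chunk):
        hi = min(lo + chunk, cX.shape[1])
        null = (cy @ cX[:, lo:hi]) / (sy[:, None] * sx[None, lo:hi])
        exceed = np.abs(null) >= np.abs(rho[None, lo:hi]) - 1e-12
        if math.factorial(n) <= ENUMERATION_CAP:
            p_out[lo:hi] = exceed.mean(axis=0)
        else:
            p_out[lo:hi] = (1 + exceed.sum(axis=0)) / (1 + perm_idx.shape[0])
    return p_out


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

def permutation_p(estimates: Sequence[float], outcomes: Sequence[float],
                  n_iter: int = 5000, seed: int = 0) -> float:
    """Two-sided permutation p for spearman(estimates, outcomes).

    Outcomes are permuted ``n_iter`` times; the p-value uses the add-one
    rule p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_iter), which is
    never zero.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    est = _check_vector(estimates, "estimates")
    out = _check_vector(outcomes, "outcomes")
    rx, ry = _rank(est), _rank(out)
    rho_obs = _rank_corr(rx, ry)
    rng = np.random.default_rng(seed)
    n = rx.size
    cx = rx - rx.mean()
    sx = math.sqrt(float(cx @ cx))
    exceed = 0
    # permute in blocks, vectorised
    block = 1024
    done = 0
    while done < n_iter:
        m = min(block, n_iter - done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        ryp = ry[perms]
        cyp = ryp - ryp.mean(axis=1, keepdims=True)
        syp = np.sqrt(np.einsum("ij,ij->i", cyp, cyp))
        null = (cyp @ cx) / (syp * sx)
        exceed += int(np.sum(np.abs(null) >= abs(rho_obs) - 1e-12))
        done += m
    return (1 + exceed) / (1 + n_iter)


@dataclass
class CVReport:
    """Outcome of a k-fold cross-validation with permutation inference."""

    fold_of_patient: np.ndarray
    estimates: np.ndarray
    rho_obs: float
    p_perm: float
    n_permutations: int
    seed: int
    k: int

    def summary(self) -> str:
        lines = [
            "K-fold cross-validation",
            f"  folds:          {self.k}",
            f"  n patients:     {self.estimates.size}",
            f"  Spearman rho:   {self.rho_obs:+.3f}",
            f"  permutation p:  {self.p_perm:.4g}  ({self.n_permutations} iterations)",
            f"  seed:           {self.seed}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "rho_obs": self.rho_obs,
            "p_perm": self.p_perm,
            "fold_of_patient": self.fold_of_patient.tolist(),
            "estimates": self.estimates.tolist(),
        }


def kfold_cv(improvements: Sequence[float],
             fit: Callable[[np.ndarray, np.ndarray], object],
             score: Callable[[object, np.ndarray], np.ndarray],
             k: int = 5, seed: int = 0, n_permutations: int = 5000,
             refit: bool = False) -> CVReport:
    """Seeded k-fold cross-validation of a mapping model.

    ``fit(train_idx, improvements)`` must build the model from training
    patients only (coverage masks / candidate selection included — no
    leakage), and ``score(model, test_idx)`` returns estimates for the
    held-out patients.  The held-out estimates are then rank-correlated
    with the empirical improvements, with a permutation p-value.

    By default, permutations shuffle outcomes at the final correlation
    stage with the cross-validated estimates held fixed.  With
    ``refit=True`` the whole CV is repeated per permutation (slow).
    """
    y = _check_vector(improvements, "improvements")
    n = y.size
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    ss = np.random.SeedSequence(seed)
    fold_seed, perm_seed = ss.spawn(2)
    rng = np.random.default_rng(fold_seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    def run_cv(y_fit: np.ndarray) -> np.ndarray:
        est = np.empty(n)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            try:
                model = fit(train_idx, y_fit)
                est[test_idx] = score(model, test_idx)
            except Exception as exc:
                raise RuntimeError(f"cross-validation fold {f} failed: {exc}") from exc
        return est

    estimates = run_cv(y)
    fold_of_patient = np.empty(n, dtype=int)
    for f, test_idx in enumerate(folds):
        fold_of_patient[test_idx] = f

    rho_obs = _rank_corr(_rank(estimates), _rank(y))
    if refit:
        prng = np.random.default_rng(perm_seed)
        exceed = 0
        for _ in range(n_permutations):
            y_perm = prng.permutation(y)
            est_perm = run_cv(y_perm)
            rho_perm = _rank_corr(_rank(est_perm), _rank(y_perm))
            exceed += abs(rho_perm) >= abs(rho_obs) - 1e-12
        p_perm = (1 + exceed) / (1 + n_permutations)
    else:
        p_perm = permutation_p(estimates, y, n_iter=n_permutations,
                               seed=int(perm_seed.generate_state(1)[0] % 2**31))
    return CVReport(fold_of_patient=fold_of_patient, estimates=estimates,
                    rho_obs=rho_obs, p_perm=p_perm,
                    n_permutations=n_permutations, seed=seed, k=k)


# ---------------------------------------------------------------------------
# Cross-disorder specificity
# ---------------------------------------------------------------------------

@dataclass
class SpecificityMatrix:
    """Spearman rho / p for every (model disorder, cohort disorder) pair."""

    rho: pd.DataFrame
    p: pd.DataFrame

    def is_diagonally_dominant(self) -> bool:
        """True if each model fits its own disorder better than every
        other disorder (row-wise strict dominance of the diagonal)."""
        vals = self.rho.values
        for i in range(vals.shape[0]):
            off = np.delete(vals[i], i)
            if off.size and not np.all(vals[i, i] > off):
                return False
        return True

    def summary(self) -> str:
        return "Cross-disorder specificity (Spearman rho)\n" + self.rho.round(3).to_string()


def cross_disorder_matrix(models: Mapping[str, object],
                          cohorts: Mapping[str, object],
                          scorer: Callable[[object, object], np.ndarray],
                          ) -> SpecificityMatrix:
    """Score every disorder's model against every disorder's cohort.

    ``scorer(model, cohort)`` returns per-patient estimates; each cell
    holds spearman(estimates, cohort improvements).
    """
    if len(models) < 1 or len(cohorts) < 1:
        raise ValueError("need at least one model and one cohort")
    names_m = list(models)
    names_c = list(cohorts)
    rho = pd.DataFrame(index=names_m, columns=names_c, dtype=float)
    p = pd.DataFrame(index=names_m, columns=names_c, dtype=float)
    for m in names_m:
        for c in names_c:
            est = np.asarray(scorer(models[m], cohorts[c]), dtype=float)
            y = np.asarray(cohorts[c].improvements, dtype=float)
            r_mc, p_mc = spearman(est, y)
            rho.loc[m, c] = r_mc
            p.loc[m, c] = p_mc
    return SpecificityMatrix(rho=rho, p=p)


# ---------------------------------------------------------------------------
# Classical tests for placement controls
# ---------------------------------------------------------------------------

def equality_of_proportions(successes: Sequence[int], totals: Sequence[int],
                            correction: bool = False,
                            ) -> tuple[float, float, pd.DataFrame]:
    """k-sample chi-square test of equal proportions, plus pairwise table.

    Returns (chi2, p, pairwise) where ``pairwise`` lists chi2/p for every
    2x2 comparison.  Yates continuity correction is off by default.
    """
    s = np.asarray(successes, dtype=int)
    t = np.asarray(totals, dtype=int)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("successes and totals must be 1D and equal length")
    if np.any(t <= 0):
        raise ValueError("all totals must be positive")
    if np.any((s < 0) | (s > t)):
        raise ValueError("successes must lie in [0, total]")
    table = np.vstack([s, t - s])
    if np.ptp(s / t) == 0:
        chi2, p = 0.0, 1.0  # identical proportions: chi2 exactly 0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    rows = []
    for i in range(s.size):
        for j in range(i + 1, s.size):
            sub = table[:, [i, j]]
            if np.ptp(sub[0] / (sub.sum(axis=0))) == 0:
                c2, pp = 0.0, 1.0
            else:
                c2, pp, _, _ = stats.chi2_contingency(sub, correction=correction)
            rows.append({"group_a": i, "group_b": j, "chi2": c2, "p": pp})
    return float(chi2), float(p), pd.DataFrame(rows)


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     welch: bool = False) -> tuple[float, float]:
    """Independent two-sample t-test (pooled variance; Welch by flag)."""
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size < 2 or bb.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(aa)) and np.all(np.isfinite(bb))):
        raise ValueError("non-finite values in input")
    if np.ptp(aa) == 0 and np.ptp(bb) == 0:
        if aa.mean() == bb.mean():
            return 0.0, 1.0
        raise ValueError("both groups degenerate with unequal means")
    res = stats.ttest_ind(aa, bb, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Compromise power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Result of a compromise power analysis for a correlation test."""

    n: int
    rho1: float
    beta_alpha_ratio: float
    sided: str
    alpha: float
    power: float
    critical_r: float = field(default=float("nan"))
    method: str = "exact"

    def summary(self) -> str:
        return (
            f"Compromise power analysis (H0 rho=0 vs H1 rho={self.rho1}, "
            f"{self.sided}-sided, beta/alpha={self.beta_alpha_ratio})\n"
            f"  n:           {self.n}\n"
            f"  critical r:  {self.critical_r:.4f}\n"
            f"  alpha:       {self.alpha:.4f}\n"
            f"  power:       {self.power:.4f}\n"
            f"  method:      {self.method}"
        )


def _sample_corr_pdf(r: np.ndarray, n: int, rho: float) -> np.ndarray:
    """Exact density of the sample correlation coefficient for n
    bivariate-normal observations with population correlation rho."""
    log_c = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2 * math.pi)
        - special.gammaln(n - 0.5)
    )
    return (
        np.exp(log_c)
        * (1 - rho**2) ** ((n - 1) / 2)
        * (1 - np.asarray(r) ** 2) ** ((n - 4) / 2)
        * (1 - rho * np.asarray(r)) ** (1.5 - n)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * np.asarray(r)) / 2)
    )


def _sample_corr_cdf(rc: float, n: int, rho: float) -> float:
    val, _ = integrate.quad(_sample_corr_pdf, -1.0, rc, args=(n, rho), limit=200)
    return min(max(val, 0.0), 1.0)


def _null_sf(rc: float, n: int) -> float:
    """P(r > rc | rho = 0) via the exact t transform."""
    t = rc * math.sqrt((n - 2) / (1.0 - rc**2))
    return float(stats.t.sf(t, df=n - 2))


def compromise_power(n: int, rho1: float = 0.4, beta_alpha_ratio: float = 1.0,
                     sided: str = "one", method: str = "exact") -> PowerSpec:
    """Solve a compromise power analysis for testing rho=0 vs rho=rho1.

    The critical sample correlation r_c is chosen so that
    beta(r_c) / alpha(r_c) equals ``beta_alpha_ratio``, under a
    bivariate-normal model.  ``method="exact"`` integrates the exact
    sampling distribution of r under the alternative; ``method="fisher"``
    uses the bias-corrected Fisher-z approximation with mean
    atanh(rho1) + rho1 / (2 (n-1)) and variance 1 / (n-3).
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    if not 0 < rho1 < 1:
        raise ValueError("rho1 must lie in (0, 1)")
    if beta_alpha_ratio <= 0:
        raise ValueError("beta_alpha_ratio must be positive")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    tail = 1.0 if sided == "one" else 2.0

    if method == "exact":
        def alpha_f(rc: float) -> float:
            return tail * _null_sf(rc, n)

        def beta_f(rc: float) -> float:
            return _sample_corr_cdf(rc, n, rho1)
    elif method == "fisher":
        mu1 = math.atanh(rho1) + rho1 / (2 * (n - 1))
        sd = 1.0 / math.sqrt(n - 3)

        def alpha_f(rc: float) -> float:
            return tail * float(stats.norm.sf(math.atanh(rc) / sd))

        def beta_f(rc: float) -> float:
            return float(stats.norm.cdf((math.atanh(rc) - mu1) / sd))
    else:
        raise ValueError("method must be 'exact' or 'fisher'")

    def objective(rc: float) -> float:
        return beta_f(rc) - beta_alpha_ratio * alpha_f(rc)

    lo, hi = 1e-6, 1.0 - 1e-9
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"compromise_power failed to bracket a root: f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g}"
        )
    rc = optimize.brentq(objective, lo, hi, xtol=1e-10)
    alpha = alpha_f(rc)
    power = 1.0 - beta_f(rc)
    return PowerSpec(n=n, rho1=rho1, beta_alpha_ratio=beta_alpha_ratio,
                     sided=sided, alpha=alpha, power=power, critical_r=rc,
                     method=method)
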