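"""Neighborhood-model estimation of seed and pollen dispersal kernels.

The model treats every sampled offspring's multilocus genotype as arising
from a categorical mixture over its possible origins: with probability m_s
the seed immigrated from outside the plot (genotype drawn from a background
gene pool); otherwise a local mother j was the seed parent, chosen with
probability proportional to her fecundity exp(gamma * z_j) times the seed
kernel evaluated at her distance from the establishment point.  Given a
local mother, the pollen was immigrant with probability m_p, or came from a
local father k != j weighted by exp(gamma * z_k) times the pollen kernel at
the mother-father distance (selfing rate fixed at 0 via the k != j
exclusion).  z is standardized dbh.

Both kernels are two-dimensional exponential-power densities

    P(r) = b / (2 pi a^2 Gamma(2/b)) * exp(-(r/a)^b)

with scale a (m) and shape b; b = 2 is the Gaussian form and b < 1 fat-
tailed.  The mean dispersal distance is d = a * Gamma(3/b) / Gamma(2/b).

Genotype transition probabilities are computed on observed genotype classes,
marginalizing over true genotypes given per-locus null-allele frequencies:
a visible/null heterozygote reads as a visible homozygote, so an observed
parental homozygote A/A may truly be A/null, and an observed offspring
homozygote is matched by either an {A,A} or an {A,null} gamete pair.

``NeighborhoodModel`` follows the Model/Results convention: build it from
offspring and candidate-parent datasets, call :meth:`fit`, and read
estimates, standard errors (inverse observed information) and mean dispersal
distances off the returned :class:`NeighborhoodModelResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, psi

from .datasets import MISSING, AlleleFrequencyTable, DataError, GenotypeDataset

_B_BOUNDS = (0.05, 20.0)


# ---------------------------------------------------------------------------
# kernel primitives


def exp_power_logpdf(r, a: float, b: float):
    """Log of the 2-D exponential-power density at radial distance r (m)."""
    if a <= 0 or b <= 0:
        raise DataError(f"kernel parameters must be positive (a={a}, b={b})")
    r = np.asarray(r, dtype=float)
    return np.log(b) - np.log(2 * np.pi) - 2 * np.log(a) - gammaln(2.0 / b) - (r / a) ** b


def exp_power_pdf(r, a: float, b: float):
    """2-D exponential-power dispersal density (per m^2) at distance r."""
    return np.exp(exp_power_logpdf(r, a, b))


def mean_dispersal_distance(a: float, b: float) -> float:
    """Mean dispersal distance d = a * Gamma(3/b) / Gamma(2/b) in meters."""
    if a <= 0 or b <= 0:
        raise DataError(f"kernel parameters must be positive (a={a}, b={b})")
    return float(a * np.exp(gammaln(3.0 / b) - gammaln(2.0 / b)))


def sample_kernel_distance(a: float, b: float, size: int, rng: np.random.Generator):
    """Radial distances drawn from the 2-D kernel: r = a * G^(1/b), G ~ Gamma(2/b)."""
    g = rng.gamma(shape=2.0 / b, scale=1.0, size=size)
    return a * g ** (1.0 / b)


# ---------------------------------------------------------------------------
# genotype transition precomputation


def _gamete_matrix(genos: np.ndarray, codes: np.ndarray, bg: np.ndarray, nu: float):
    """Per-parent gamete probability matrix over (visible alleles..., null).

    Observed heterozygotes transmit each allele with probability 1/2; an
    observed homozygote A/A is truly A/A or A/null with posterior odds
    p_A : 2*nu (population frequencies), and a parent untyped at the locus
    transmits a population gamete.
    """
    n = len(genos)
    k = len(codes)
    g = np.zeros((n, k + 1))
    code_pos = {int(c): i for i, c in enumerate(codes)}
    for i in range(n):
        x, y = genos[i]
        if x == MISSING:
            g[i] = bg
            continue
        ix = code_pos[int(x)]
        if x != y:
            g[i, ix] += 0.5
            g[i, code_pos[int(y)]] += 0.5
        else:
            p_x = bg[ix]
            alpha = p_x / (p_x + 2 * nu) if (p_x + 2 * nu) > 0 else 1.0
            g[i, ix] = alpha + (1 - alpha) / 2
            g[i, k] = (1 - alpha) / 2
    return g


class _Transitions:
    """Parameter-independent genotype probabilities.

    B[o]          background-x-background genotype probability
    T_bg[o, j]    mother j x background-father probability
    T_pair[o,j,k] mother j x father k probability
    Products over typed offspring loci; missing offspring loci are skipped.
    """

    def __init__(
        self,
        offspring: GenotypeDataset,
        mature: GenotypeDataset,
        background: AlleleFrequencyTable,
        null_freqs: dict[str, float] | None,
    ) -> None:
        null_freqs = null_freqs or {}
        n_off, n_mat = offspring.n, mature.n
        self.B = np.ones(n_off)
        self.T_bg = np.ones((n_off, n_mat))
        self.T_pair = np.ones((n_off, n_mat, n_mat))
        names_m = [l.name for l in mature.loci]
        for li, locus in enumerate(offspring.loci):
            if locus.name not in background.freqs or locus.name not in names_m:
                continue
            nu = float(null_freqs.get(locus.name, 0.0))
            codes, q = background.arrays(locus.name)
            geno_o = offspring.genotypes[:, li, :]
            geno_m = mature.genotypes[:, names_m.index(locus.name), :]
            observed = np.unique(
                np.concatenate([geno_o[geno_o != MISSING], geno_m[geno_m != MISSING]])
            )
            extra = np.setdiff1d(observed, codes)
            if extra.size:
                codes = np.concatenate([codes, extra])
                q = np.concatenate([q, np.zeros(extra.size)])
            bg = np.append((1 - nu) * q, nu)  # joint background gamete probs
            G = _gamete_matrix(geno_m, codes, bg, nu)
            pos = {int(c): i for i, c in enumerate(codes)}
            k_null = len(codes)
            for o in range(n_off):
                x, y = geno_o[o]
                if x == MISSING:
                    continue
                ix = pos[int(x)]
                if x != y:
                    iy = pos[int(y)]
                    b_o = 2 * bg[ix] * bg[iy]
                    tbg = G[:, ix] * bg[iy] + G[:, iy] * bg[ix]
                    tp = np.outer(G[:, ix], G[:, iy]) + np.outer(G[:, iy], G[:, ix])
                else:
                    b_o = bg[ix] ** 2 + 2 * bg[ix] * bg[k_null]
                    tbg = G[:, ix] * (bg[ix] + bg[k_null]) + G[:, k_null] * bg[ix]
                    gx, gn = G[:, ix], G[:, k_null]
                    tp = np.outer(gx, gx) + np.outer(gx, gn) + np.outer(gn, gx)
                self.B[o] *= b_o
                self.T_bg[o] *= tbg
                self.T_pair[o] *= tp


# ---------------------------------------------------------------------------
# the model

_PARAM_NAMES = ("m_s", "m_p", "a_s", "b_s", "a_p", "b_p", "gamma")
_TRANSFORMED_NAMES = (
    "logit(m_s)", "logit(m_p)", "ln(a_s)", "ln(b_s)", "ln(a_p)", "ln(b_p)", "gamma"
)


def _unpack(theta: np.ndarray) -> dict[str, float]:
    return {
        "m_s": float(expit(theta[0])),
        "m_p": float(expit(theta[1])),
        "a_s": float(np.exp(theta[2])),
        "b_s": float(np.exp(theta[3])),
        "a_p": float(np.exp(theta[4])),
        "b_p": float(np.exp(theta[5])),
        "gamma": float(theta[6]),
    }


def _pack(params: dict[str, float]) -> np.ndarray:
    return np.array(
        [
            logit(params["m_s"]),
            logit(params["m_p"]),
            np.log(params["a_s"]),
            np.log(params["b_s"]),
            np.log(params["a_p"]),
            np.log(params["b_p"]),
            params["gamma"],
        ]
    )


class NeighborhoodModel:
    """Maximum-likelihood neighborhood model for seed and pollen dispersal.

    Parameters
    ----------
    offspring : GenotypeDataset
        Established offspring with coordinates (mothers unknown).
    mature : GenotypeDataset
        Candidate parents; must carry coordinates and dbh.
    background : AlleleFrequencyTable, optional
        Immigrant gene-pool frequencies; defaults to the mature-tree
        frequencies.
    null_freqs : mapping locus -> null frequency, optional
    """

    def __init__(
        self,
        offspring: GenotypeDataset,
        mature: GenotypeDataset,
        background: AlleleFrequencyTable | None = None,
        null_freqs: dict[str, float] | None = None,
    ) -> None:
        if offspring.n < 20:
            warnings.warn(f"only {offspring.n} offspring; estimates will be imprecise")
        if "dbh" not in mature.meta.columns or mature.meta["dbh"].isna().any():
            raise DataError("mature dataset must carry dbh for every individual")
        from .datasets import allele_frequencies

        self.offspring = offspring
        self.mature = mature
        self.background = background or allele_frequencies(mature)
        self.null_freqs = dict(null_freqs or {})
        dbh = mature.meta["dbh"].to_numpy(dtype=float)
        sd = dbh.std()
        self.z = (dbh - dbh.mean()) / (sd if sd > 0 else 1.0)
        diff = offspring.coords[:, None, :] - mature.coords[None, :, :]
        self.d_om = np.sqrt((diff**2).sum(axis=2))
        diff = mature.coords[:, None, :] - mature.coords[None, :, :]
        self.d_mm = np.sqrt((diff**2).sum(axis=2))
        self._trans = _Transitions(offspring, mature, self.background, self.null_freqs)

    # -- likelihood ------------------------------------------------------

    def loglike(self, params: dict[str, float] | np.ndarray) -> float:
        """Total log-likelihood of the offspring genotypes."""
        if not isinstance(params, dict):
            params = _unpack(np.asarray(params, dtype=float))
        m_s, m_p = params["m_s"], params["m_p"]
        gamma = params["gamma"]
        t = self._trans

        def row_weights(log_k):
            w = gamma * self.z[None, :] + log_k
            w = w - w.max(axis=1, keepdims=True)
            w = np.exp(w)
            return w / w.sum(axis=1, keepdims=True)

        psi_w = row_weights(exp_power_logpdf(self.d_om, params["a_s"], params["b_s"]))
        log_kp = exp_power_logpdf(self.d_mm, params["a_p"], params["b_p"])
        np.fill_diagonal(log_kp, -np.inf)  # selfing excluded
        phi_w = row_weights(log_kp)

        inner = m_p * t.T_bg + (1 - m_p) * np.einsum("ojk,jk->oj", t.T_pair, phi_w)
        lik = m_s * t.B + (1 - m_s) * np.sum(psi_w * inner, axis=1)
        if np.any(lik <= 0):
            return -np.inf
        return float(np.sum(np.log(lik)))

    def _neg_loglike(self, theta: np.ndarray) -> float:
        ll = self.loglike(theta)
        return 1e12 if not np.isfinite(ll) else -ll

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        start_params: dict[str, float] | None = None,
        n_starts: int = 6,
        rng: np.random.Generator | int | None = None,
        maxiter: int = 400,
    ) -> "NeighborhoodModelResults":
        """Maximize the likelihood from multiple jittered starting points.

        Optimization runs on transformed coordinates (logit immigration
        rates, log kernel parameters) so every iterate is feasible.
        """
        rng = np.random.default_rng(rng)
        extent = float(np.hypot(*self.offspring.plot_extent))
        base = {
            "m_s": 0.5, "m_p": 0.5,
            "a_s": extent / 15, "b_s": 1.0,
            "a_p": extent / 5, "b_p": 1.0,
            "gamma": 0.0,
        }
        if start_params:
            base.update(start_params)
        starts = [_pack(base)]
        for _ in range(n_starts - 1):
            jitter = rng.normal(scale=[0.8, 0.8, 0.7, 0.3, 0.7, 0.3, 0.5])
            starts.append(_pack(base) + jitter)
        bounds = [
            (-8.0, 8.0), (-8.0, 8.0),
            (np.log(1e-3), np.log(1e4)), (np.log(_B_BOUNDS[0]), np.log(_B_BOUNDS[1])),
            (np.log(1e-3), np.log(1e4)), (np.log(_B_BOUNDS[0]), np.log(_B_BOUNDS[1])),
            (-10.0, 10.0),
        ]
        best = None
        any_converged = False
        for theta0 in starts:
            theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(
                self._neg_loglike, theta0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise DataError("neighborhood-model optimization failed from every start")
        theta = np.asarray(best.x)
        cov = self._observed_information_cov(theta)
        return NeighborhoodModelResults(
            model=self, theta=theta, cov_theta=cov, llf=-float(best.fun),
            converged=any_converged, n_starts=len(starts),
        )

    def _observed_information_cov(self, theta: np.ndarray) -> np.ndarray:
        """Covariance from the inverse observed information (central FD Hessian)."""
        k = len(theta)
        h = 1e-3 * np.maximum(1.0, np.abs(theta))
        hess = np.zeros((k, k))
        f0 = self._neg_loglike(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    val = (
                        self._neg_loglike(theta + ei)
                        - 2 * f0
                        + self._neg_loglike(theta - ei)
                    ) / h[i] ** 2
                else:
                    val = (
                        self._neg_loglike(theta + ei + ej)
                        - self._neg_loglike(theta + ei - ej)
                        - self._neg_loglike(theta - ei + ej)
                        + self._neg_loglike(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        try:
            cov = np.linalg.pinv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        return cov


@dataclass
class NeighborhoodModelResults:
    """Fitted neighborhood-model parameters and their uncertainties."""

    model: NeighborhoodModel
    theta: np.ndarray  # transformed-scale estimates
    cov_theta: np.ndarray
    llf: float
    converged: bool
    n_starts: int

    @property
    def params(self) -> pd.Series:
        """Natural-scale estimates, plus the fixed selfing rate and mean distances."""
        p = _unpack(self.theta)
        p["s"] = 0.0
        p["d_s"] = mean_dispersal_distance(p["a_s"], p["b_s"])
        p["d_p"] = mean_dispersal_distance(p["a_p"], p["b_p"])
        return pd.Series(p)

    @property
    def bse(self) -> pd.Series:
        """Natural-scale standard errors (delta method from the transformed scale)."""
        se_t = np.sqrt(np.maximum(np.diag(self.cov_theta), 0.0))
        p = _unpack(self.theta)
        out = {
            "m_s": se_t[0] * p["m_s"] * (1 - p["m_s"]),
            "m_p": se_t[1] * p["m_p"] * (1 - p["m_p"]),
            "a_s": se_t[2] * p["a_s"],
            "b_s": se_t[3] * p["b_s"],
            "a_p": se_t[4] * p["a_p"],
            "b_p": se_t[5] * p["b_p"],
            "gamma": se_t[6],
            "s": 0.0,
            "d_s": self._mean_distance_se("s"),
            "d_p": self._mean_distance_se("p"),
        }
        return pd.Series(out)

    def _mean_distance_se(self, which: str) -> float:
        ia, ib = (2, 3) if which == "s" else (4, 5)
        p = _unpack(self.theta)
        a, b = p[f"a_{which}"], p[f"b_{which}"]
        # d(ln d)/d(ln a) = 1; d(ln d)/d(ln b) = (2 psi(2/b) - 3 psi(3/b)) / b
        grad_lnb = (2.0 * psi(2.0 / b) - 3.0 * psi(3.0 / b)) / b
        g = np.zeros(len(self.theta))
        g[ia], g[ib] = 1.0, grad_lnb
        var_lnd = float(g @ self.cov_theta @ g)
        return mean_dispersal_distance(a, b) * np.sqrt(max(var_lnd, 0.0))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals on the transformed scale (logit m, ln a, ln b, gamma)."""
        from scipy.stats import norm

        zq = norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.maximum(np.diag(self.cov_theta), 0.0))
        return pd.DataFrame(
            {"lower": self.theta - zq * se, "upper": self.theta + zq * se},
            index=list(_TRANSFORMED_NAMES),
        )

    @property
    def boundary_flags(self) -> dict[str, bool]:
        """Immigration rates pinned near 0 or 1 (kernel then unidentified)."""
        p = _unpack(self.theta)
        return {
            "m_s": p["m_s"] < 1e-3 or p["m_s"] > 1 - 1e-3,
            "m_p": p["m_p"] < 1e-3 or p["m_p"] > 1 - 1e-3,
        }

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Neighborhood dispersal model (exponential-power kernels)",
            f"  offspring n = {self.model.offspring.n}, candidate parents = "
            f"{self.model.mature.n}, log-likelihood = {self.llf:.3f}",
            f"  converged: {self.converged} ({self.n_starts} starts)",
            "",
            f"  {'Parameter':<14}{'Seed':>12}{'(SE)':>12}{'Pollen':>12}{'(SE)':>12}",
        ]
        rows = [
            ("a", "a_s", "a_p"),
            ("b", "b_s", "b_p"),
            ("s", "s", "s"),
            ("d", "d_s", "d_p"),
            ("m", "m_s", "m_p"),
            ("Sigma (dbh)", "gamma", "gamma"),
        ]
        for label, ks, kp in rows:
            lines.append(
                f"  {label:<14}{p[ks]:>12.3f}{se[ks]:>12.3f}{p[kp]:>12.3f}{se[kp]:>12.3f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Kernel-parameter table: one row per parameter, seed and pollen columns."""
        p, se = self.params, self.bse
        return pd.DataFrame(
            {
                "seed": [p["a_s"], p["b_s"], p["s"], p["d_s"], p["m_s"], p["gamma"]],
                "seed_se": [se["a_s"], se["b_s"], np.nan, se["d_s"], se["m_s"], se["gamma"]],
                "pollen": [p["a_p"], p["b_p"], p["s"], p["d_p"], p["m_p"], p["gamma"]],
                "pollen_se": [se["a_p"], se["b_p"], np.nan, se["d_p"], se["m_p"], se["gamma"]],
            },
            index=["a", "b", "s", "d", "m", "Sigma (dbh)"],
        )


def nm_offspring_loglik(
    offspring: GenotypeDataset,
    mature: GenotypeDataset,
    params: dict[str, float],
    background: AlleleFrequencyTable | None = None,
    null_freqs: dict[str, float] | None = None,
) -> float:
    """Neighborhood-model log-likelihood at fixed parameters."""
    return NeighborhoodModel(offspring, mature, background, null_freqs).loglike(params)


def fit_neighborhood_model(
    offspring: GenotypeDataset,
    mature: GenotypeDataset,
    background: AlleleFrequencyTable | None = None,
    null_freqs: dict[str, float] | None = None,
    start_params: dict[str, float] | None = None,
    n_starts: int = 6,
    rng_seed: int | None = None,
) -> NeighborhoodModelResults:
    """Convenience wrapper: build a :class:`NeighborhoodModel` and fit it."""
    model = NeighborhoodModel(offspring, mature, background, null_freqs)
    return model.fit(start_params=start_params, n_starts=n_starts, rng=rng_seed)
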