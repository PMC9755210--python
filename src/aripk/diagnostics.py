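"""Model qualification: goodness-of-fit residuals, visual predictive check
and normalized prediction distribution errors.

* GOF: population predictions (eta = 0), individual predictions (eta at the
  conditional mode) and FOCE conditional weighted residuals, where each
  subject's residual vector is decorrelated by the Cholesky factor of the
  linearised marginal covariance ``C_i = G Omega G' + diag(sigma^2 IPRED^2)``.
* VPC: the design (doses, sampling times, covariates) is re-simulated
  ``n_sim`` times under the fitted model; observed 5th/50th/95th percentiles
  per time-after-dose bin are compared with the 90% prediction band of the
  same percentiles across replicates.  Binning is equal-count (default 6
  bins); observed percentiles depend only on the data, never on the seed.
* NPDE: per subject, observed and simulated vectors are decorrelated by the
  Cholesky factor of the simulated covariance, prediction discrepancies are
  computed as uniform-jittered ranks ``(k + u) / (n_sim + 1)`` (exactly
  uniform under the null) and mapped through the inverse normal CDF.  The
  test battery is a mean t-test, a Fisher variance test (chi-square on the
  sample variance against 1) and a Shapiro-Wilk normality test, combined
  into a global test by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .model import PopPKResults

__all__ = ["gof_residuals", "VpcResult", "vpc", "NpdeResult", "npde",
           "simulate_observation_matrix"]


def gof_residuals(results: PopPKResults) -> pd.DataFrame:
    """GOF table: one row per observation with DV, PRED, IPRED and CWRES.

    A numerically singular per-subject covariance is ridge-stabilised with
    a jitter proportional to its trace (reported in the ``ridged`` column).
    """
    eng = results.model.engine
    eng.set_model(results.params)
    k = eng.k
    eta = results.eta_hat if results.eta_hat.shape == (eng.n_subjects, k) \
        else eng.inner_map()
    pred_pop = eng.predict(np.zeros((eng.n_subjects, k)))
    ipred, G, v, r = eng.linearization(eta)
    cwres = np.empty(eng.n_obs)
    ridged = np.zeros(eng.n_obs, dtype=bool)
    omega = np.diag(eng.omega_var) if k else np.zeros((0, 0))
    for i in range(eng.n_subjects):
        idx = np.flatnonzero(eng.obs_subj == i)
        if idx.size == 0:
            continue
        Gi = G[idx]
        Ci = Gi @ omega @ Gi.T + np.diag(v[idx])
        try:
            L = np.linalg.cholesky(Ci)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * max(np.trace(Ci), 1.0)
            L = np.linalg.cholesky(Ci + jitter * np.eye(idx.size))
            ridged[idx] = True
        cwres[idx] = solve_triangular(L, r[idx], lower=True)
    obs = results.model.dataset.observations()
    return pd.DataFrame({
        "id": obs["id"].to_numpy(),
        "time": eng.obs_time,
        "analyte": np.where(eng.obs_is_dari, "DARI", "ARI"),
        "dv": eng.y,
        "pred": pred_pop,
        "ipred": ipred,
        "cwres": cwres,
        "ridged": ridged,
    })


def simulate_observation_matrix(
    results: PopPKResults,
    n_sim: int,
    seed=None,
    residual_error: bool = True,
) -> np.ndarray:
    """(n_sim, n_obs) matrix of design-replicated simulated observations.

    Redraws the random effects (and, optionally, proportional residual
    error) under the fitted model while keeping doses, sampling times and
    covariates exactly as observed.
    """
    eng = results.model.engine
    eng.set_model(results.params)
    rng = np.random.default_rng(seed)
    k = eng.k
    sd = np.sqrt(eng.omega_var) if k else np.zeros(0)
    out = np.empty((n_sim, eng.n_obs))
    for rep in range(n_sim):
        eta = rng.standard_normal((eng.n_subjects, k)) * sd if k else \
            np.zeros((eng.n_subjects, 0))
        pred = eng.predict(eta)
        if residual_error:
            eps = rng.standard_normal(eng.n_obs) * eng.sigma_obs
            eps = np.maximum(eps, -0.999)
            pred = pred * (1.0 + eps)
        out[rep] = pred
    return out


@dataclass
class VpcResult:
    """Observed percentiles and simulated prediction bands per time bin."""

    observed: pd.DataFrame   # analyte, bin, t_mid, n, p5, p50, p95
    bands: pd.DataFrame      # analyte, bin, percentile, lower, upper, center
    bin_edges: np.ndarray
    n_sim: int

    def coverage(self) -> float:
        """Fraction of observed percentile points inside their 90% band."""
        obs = self.observed.melt(
            id_vars=["analyte", "bin"], value_vars=["p5", "p50", "p95"],
            var_name="percentile", value_name="observed_value",
        )
        obs["percentile"] = obs["percentile"].str.replace("p", "").astype(int)
        merged = obs.merge(self.bands, on=["analyte", "bin", "percentile"])
        inside = (merged["observed_value"] >= merged["lower"]) & (
            merged["observed_value"] <= merged["upper"])
        return float(inside.mean())


_PCTS = (5, 50, 95)


def _binned_percentiles(values, bins, analyte_mask):
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        for name, mask in analyte_mask.items():
            v = values[sel & mask]
            if v.size == 0:
                continue
            rows.append((name, int(b), v.size) + tuple(np.percentile(v, _PCTS)))
    return rows


def vpc(
    results: PopPKResults,
    n_sim: int = 1000,
    bins: int = 6,
    seed=None,
) -> VpcResult:
    """Visual predictive check of the fitted model against its own design."""
    eng = results.model.engine
    eng.set_model(results.params)
    # bin on time after the most recent dose when available, else raw time
    w = eng.obs_w if eng._fast else eng.obs_time
    edges = np.unique(np.quantile(w, np.linspace(0, 1, bins + 1)))
    bin_id = np.clip(np.searchsorted(edges, w, side="right") - 1, 0, len(edges) - 2)
    masks = {"ARI": ~eng.obs_is_dari, "DARI": eng.obs_is_dari}

    obs_rows = _binned_percentiles(eng.y, bin_id, masks)
    observed = pd.DataFrame(
        obs_rows, columns=["analyte", "bin", "n", "p5", "p50", "p95"])
    observed["t_mid"] = [
        float(np.median(w[(bin_id == b) & masks[a]]))
        for a, b in zip(observed["analyte"], observed["bin"])
    ]
    observed["low_count"] = observed["n"] < 5

    sims = simulate_observation_matrix(results, n_sim, seed=seed)
    per_rep: dict[tuple, list] = {}
    for rep in range(n_sim):
        for a, b, _n, p5, p50, p95 in _binned_percentiles(sims[rep], bin_id, masks):
            for pct, val in zip(_PCTS, (p5, p50, p95)):
                per_rep.setdefault((a, b, pct), []).append(val)
    band_rows = []
    for (a, b, pct), vals in per_rep.items():
        vals = np.asarray(vals)
        band_rows.append({
            "analyte": a, "bin": b, "percentile": pct,
            "lower": float(np.percentile(vals, 5)),
            "upper": float(np.percentile(vals, 95)),
            "center": float(np.percentile(vals, 50)),
        })
    return VpcResult(
        observed=observed,
        bands=pd.DataFrame(band_rows),
        bin_edges=edges,
        n_sim=n_sim,
    )


@dataclass
class NpdeResult:
    """Per-observation NPDE values with the four-test battery."""

    table: pd.DataFrame            # id, time, analyte, npde
    tests: dict[str, float]        # p-values: t_test, fisher_variance,
                                   # shapiro, global
    n_sim: int

    @property
    def normal(self) -> bool:
        """True when the global test does not reject at the 5% level."""
        return self.tests["global"] > 0.05


def npde(results: PopPKResults, n_sim: int = 1000, seed=None) -> NpdeResult:
    """Normalized prediction distribution errors with the test battery.

    Requires ``n_sim >= 100`` for a stable simulated covariance.  Rank ties
    are broken by seeded uniform jitter; the decorrelation uses the Cholesky
    factor of the per-subject simulated covariance (ridge-stabilised when
    needed).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100 for a stable covariance")
    eng = results.model.engine
    rng = np.random.default_rng(seed)
    sims = simulate_observation_matrix(results, n_sim, seed=rng)
    npde_vals = np.empty(eng.n_obs)
    for i in range(eng.n_subjects):
        idx = np.flatnonzero(eng.obs_subj == i)
        if idx.size == 0:
            continue
        S = sims[:, idx]                       # (n_sim, n_i)
        mean = S.mean(axis=0)
        cov = np.cov(S, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        ridge = 1e-10 * max(np.trace(cov), 1.0)
        for _ in range(8):
            try:
                L = np.linalg.cholesky(cov + ridge * np.eye(idx.size))
                break
            except np.linalg.LinAlgError:
                ridge *= 100
        y_dec = np.linalg.solve(L, eng.y[idx] - mean)
        s_dec = np.linalg.solve(L, (S - mean).T)   # (n_i, n_sim)
        k_below = (s_dec < y_dec[:, None]).sum(axis=1)
        u = rng.random(idx.size)
        pde = (k_below + u) / (n_sim + 1)
        npde_vals[idx] = stats.norm.ppf(pde)
    n = npde_vals.size
    if n >= 2:
        p_t = float(stats.ttest_1samp(npde_vals, 0.0).pvalue)
        var_stat = (n - 1) * npde_vals.var(ddof=1)
        p_var = float(2 * min(stats.chi2.cdf(var_stat, n - 1),
                              stats.chi2.sf(var_stat, n - 1)))
    else:
        p_t = p_var = float("nan")
    # Shapiro-Wilk needs a handful of points to mean anything
    p_sw = float(stats.shapiro(npde_vals).pvalue) if n >= 8 else float("nan")
    components = [p for p in (p_t, p_var, p_sw) if np.isfinite(p)]
    p_global = (float(min(1.0, len(components) * min(components)))
                if components else float("nan"))
    obs = results.model.dataset.observations()
    table = pd.DataFrame({
        "id": obs["id"].to_numpy(),
        "time": eng.obs_time,
        "analyte": np.where(eng.obs_is_dari, "DARI", "ARI"),
        "npde": npde_vals,
    })
    return NpdeResult(
        table=table,
        tests={"t_test": p_t, "fisher_variance": p_var, "shapiro": p_sw,
               "global": p_global},
        n_sim=n_sim,
    )
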