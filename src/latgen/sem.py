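"""Declarative threshold-structure SEM fitted by diagonally weighted least
squares (DWLS).

The data enter as first-stage polychoric statistics (thresholds and
correlations, ``PolyStats``).  A model is a declarative pattern of loadings,
structural regressions among latents, latent (co)variances and means,
item residual variances/covariances (theta parameterization: residual
variances fixed to 1 unless freed) and thresholds, any entry free, fixed,
or tied to an equality group.

Fitting minimizes the discrepancy sum_k w_k (s_k - sigma_k(theta))^2 with
w_k the inverse asymptotic variance of statistic k.  Because implied
thresholds are linear in the threshold parameters, those are profiled out
analytically each evaluation; only the nonlinear parameters are iterated.

The test statistic is the scaled-and-shifted (mean-and-variance adjusted)
form T* = a*T + b with a = sqrt(df / tr((U C)^2)) and b = df - a*tr(U C),
where U = W - W J (J'WJ)^{-1} J'W and C is the sampling covariance of the
statistics (full influence-function covariance when available, else its
diagonal); parameter standard errors use the corresponding sandwich.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .polychoric import PolyStats

__all__ = [
    "Param", "free", "fixed_at", "SemModelSpec", "FitResult",
    "fit_dwls", "fit_indices", "chi2_diff_test", "standardize",
    "IdentificationError", "parse_model_text",
]

VAR_FLOOR = 1e-4  # Heywood guard: variance parameters bounded below


class IdentificationError(ValueError):
    pass


@dataclass(frozen=True)
class Param:
    """One model-matrix entry: free (optionally labelled for equality
    constraints) or fixed at a value."""

    value: float | None = None
    fixed: bool = False
    label: str | None = None


def free(start: float | None = None, label: str | None = None) -> Param:
    return Param(value=start, fixed=False, label=label)


def fixed_at(value: float) -> Param:
    return Param(value=float(value), fixed=True)


_ROLE_START = {"loading": 0.5, "regression": 0.0, "psi_var": 1.0,
               "psi_cov": 0.0, "theta_var": 1.0, "theta_cov": 0.1,
               "threshold": 0.0, "mean": 0.0}
_ROLE_BOUNDS = {"loading": (-60.0, 60.0), "regression": (-10.0, 10.0),
                "psi_var": (VAR_FLOOR, 50.0), "psi_cov": (-10.0, 10.0),
                "theta_var": (VAR_FLOOR, 50.0), "theta_cov": (-5.0, 5.0),
                "threshold": (-8.0, 8.0), "mean": (-8.0, 8.0)}


@dataclass
class SemModelSpec:
    """Declarative model pattern.

    ``latents`` must be listed in causal (topological) order when
    regressions are present.  ``unit_variance`` lists endogenous factors
    whose *total* variance is constrained to 1 (their residual variance is
    derived, giving standardized structural scales); exogenous factors get
    a fixed psi diagonal instead.
    """

    observed: list[str]
    latents: list[str]
    loadings: dict = field(default_factory=dict)        # (obs, lat) -> Param
    regressions: dict = field(default_factory=dict)     # (out, pred) -> Param
    psi: dict = field(default_factory=dict)             # (lat_a, lat_b) -> Param
    alpha: dict = field(default_factory=dict)           # lat -> Param (zeta mean)
    theta: dict = field(default_factory=dict)           # obs -> Param (resid var)
    theta_cov: dict = field(default_factory=dict)       # (obs_a, obs_b) -> Param
    thresholds: dict = field(default_factory=dict)      # obs -> tuple[Param, ...]
    unit_variance: set = field(default_factory=set)

    def free_locations(self) -> set:
        locs = set()
        for table, name in ((self.loadings, "lam"), (self.regressions, "b"),
                            (self.psi, "psi"), (self.alpha, "alpha"),
                            (self.theta, "theta"), (self.theta_cov, "thcov")):
            for key, p in table.items():
                if not p.fixed:
                    locs.add((name, key))
        for obs, taus in self.thresholds.items():
            for c, p in enumerate(taus):
                if not p.fixed:
                    locs.add(("tau", obs, c))
        return locs


@dataclass
class FitResult:
    estimates: dict
    se: dict
    std_beta: dict
    chi2: float
    df: int
    pvalue: float
    scale_factors: tuple[float, float]
    rmsea: float
    cfi: float
    tli: float
    tli_gt1: bool
    converged: bool
    n: int
    heywood: bool = False
    baseline_chi2: float = 0.0
    baseline_df: int = 0
    # internals for difference testing / standardization
    _theta: np.ndarray = None
    _cov: np.ndarray = None
    _names: list = None
    _F_min: float = None
    _U: np.ndarray = None
    _cov_s: np.ndarray = None
    _s: np.ndarray = None
    _spec: SemModelSpec = None
    _model: "_Compiled" = None

    def param(self, name: str) -> tuple[float, float]:
        return self.estimates[name], self.se.get(name, np.nan)

    def to_frame(self):
        """Parameter table (estimate, SE, standardized value/SE where
        defined) as a DataFrame for text export."""
        import pandas as pd
        rows = []
        for name, est in self.estimates.items():
            std = self.std_beta.get("std_" + name, (np.nan, np.nan))
            rows.append({"parameter": name, "estimate": est,
                         "se": self.se.get(name, np.nan),
                         "std": std[0], "std_se": std[1]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

class _Compiled:
    def __init__(self, spec: SemModelSpec, stats: PolyStats):
        if list(stats.names) != list(spec.observed):
            raise ValueError("spec.observed must match the statistics' "
                             "variable order")
        self.spec = spec
        self.p = len(spec.observed)
        self.m = len(spec.latents)
        self.obs_idx = {v: i for i, v in enumerate(spec.observed)}
        self.lat_idx = {v: i for i, v in enumerate(spec.latents)}
        self.stats = stats
        self.n_thr = stats.n_thresholds
        self.pair_index = {pr: i for i, pr in enumerate(stats.pairs)}

        self.names: list[str] = []
        self.starts: list[float] = []
        self.roles: list[str] = []
        self._by_label: dict[str, int] = {}
        # entries: list of (array_name, key, param_index or fixed value, fixed?)
        self.entries: list[tuple] = []
        self.thr_param_stats: dict[int, list[int]] = {}

        def register(p: Param, role: str, default_name: str,
                     default_start: float | None = None) -> tuple[bool, float | int]:
            if p.fixed:
                return True, float(p.value)
            key = p.label or default_name
            if key in self._by_label:
                idx = self._by_label[key]
                return False, idx
            idx = len(self.names)
            self._by_label[key] = idx
            self.names.append(key)
            start = p.value
            if start is None:
                start = (default_start if default_start is not None
                         else _ROLE_START[role])
            self.starts.append(float(start))
            self.roles.append(role)
            return False, idx

        for (obs, lat), p in spec.loadings.items():
            fx, v = register(p, "loading", f"lam:{obs}~{lat}")
            self.entries.append(("lam", (self.obs_idx[obs], self.lat_idx[lat]),
                                 v, fx))
        for (out, pred), p in spec.regressions.items():
            fx, v = register(p, "regression", f"b:{out}~{pred}")
            self.entries.append(("B", (self.lat_idx[out], self.lat_idx[pred]),
                                 v, fx))
        for (a, b), p in spec.psi.items():
            role = "psi_var" if a == b else "psi_cov"
            fx, v = register(p, role, f"psi:{a},{b}")
            self.entries.append(("psi", (self.lat_idx[a], self.lat_idx[b]),
                                 v, fx))
        for lat, p in spec.alpha.items():
            fx, v = register(p, "mean", f"alpha:{lat}")
            self.entries.append(("alpha", (self.lat_idx[lat],), v, fx))
        for obs in spec.observed:
            p = spec.theta.get(obs, fixed_at(1.0))
            fx, v = register(p, "theta_var", f"theta:{obs}")
            self.entries.append(("theta", (self.obs_idx[obs],), v, fx))
        for (a, b), p in spec.theta_cov.items():
            fx, v = register(p, "theta_cov", f"thcov:{a},{b}")
            self.entries.append(("thcov", (self.obs_idx[a], self.obs_idx[b]),
                                 v, fx))
        # thresholds last: profiled analytically during optimization
        self.n_nonthr = len(self.names)
        thr_stat = 0
        for vi, obs in enumerate(spec.observed):
            n_tau = len(stats.thresholds[vi])
            taus = spec.thresholds.get(
                obs, tuple(free() for _ in range(n_tau)))
            if len(taus) != n_tau:
                raise ValueError(
                    f"{obs}: spec has {len(taus)} thresholds, data has {n_tau}")
            for c, p in enumerate(taus):
                fx, v = register(p, "threshold", f"tau:{obs}:{c}",
                                 default_start=float(stats.thresholds[vi][c]))
                self.entries.append(("tau", (vi, c, thr_stat), v, fx))
                if not fx:
                    self.thr_param_stats.setdefault(v, []).append(thr_stat)
                thr_stat += 1
        self.q = len(self.names)
        self._smart_starts(stats)
        self.thr_free = [i for i in range(self.n_nonthr, self.q)
                         if self.roles[i] == "threshold"]
        # any threshold param index < n_nonthr would mean a label shared with
        # a non-threshold param; disallow
        if any(self.roles[i] == "threshold" for i in range(self.n_nonthr)):
            raise ValueError("threshold labels may not be shared with "
                             "non-threshold parameters")
        self.m_stats = len(stats.s)
        self.df = self.m_stats - self.q
        if self.df < 0:
            raise IdentificationError(
                f"{self.q} free parameters exceed {self.m_stats} statistics")

        # vectorized assembly: templates hold fixed values; free entries are
        # written through precomputed flat positions
        p, m = self.p, self.m
        shapes = {"lam": (p, m), "B": (m, m), "psi": (m, m),
                  "alpha": (m,), "theta": (p,), "thcov": (p, p),
                  "tau": (self.n_thr,)}
        self._templates = {k: np.zeros(v) for k, v in shapes.items()}
        assign: dict[str, tuple[list, list]] = {k: ([], []) for k in shapes}
        for arr, key, v, fx in self.entries:
            if arr in ("psi", "thcov"):
                a, b = key
                cols = shapes[arr][1]
                flats = [a * cols + b] + ([b * cols + a] if a != b else [])
            elif arr == "lam":
                flats = [key[0] * m + key[1]]
            elif arr == "B":
                flats = [key[0] * m + key[1]]
            elif arr == "alpha":
                flats = [key[0]]
            elif arr == "theta":
                flats = [key[0]]
            else:  # tau
                flats = [key[2]]
            if fx:
                for f in flats:
                    self._templates[arr].flat[f] = v
            else:
                for f in flats:
                    assign[arr][0].append(f)
                    assign[arr][1].append(v)
        self._assign = {k: (np.asarray(pos, dtype=int),
                            np.asarray(idx, dtype=int))
                        for k, (pos, idx) in assign.items()}
        self._uv_idx = [self.lat_idx[f] for f in self.spec.latents
                        if f in self.spec.unit_variance]
        self.var_of_thr = np.empty(self.n_thr, dtype=int)
        pos = 0
        for vi in range(self.p):
            kk = len(stats.thresholds[vi])
            self.var_of_thr[pos:pos + kk] = vi
            pos += kk
        self._pi = np.array([pr[0] for pr in stats.pairs])
        self._pj = np.array([pr[1] for pr in stats.pairs])
        # observed-scale pairs (numeric covariates): the implied liability
        # correlation is attenuated by phi(tau)/sqrt(F(1-F)) per binary side
        self._obs_scale = (stats.observed_scale
                           if stats.observed_scale is not None else None)
        if self._obs_scale is not None and not self._obs_scale.any():
            self._obs_scale = None
        self._first_thr = np.full(self.p, -1, dtype=int)
        pos = 0
        for vi in range(self.p):
            kk = len(stats.thresholds[vi])
            if kk:
                self._first_thr[vi] = pos
            pos += kk
        if self._obs_scale is not None:
            flagged_vars = set(self._pi[self._obs_scale]) | set(
                self._pj[self._obs_scale])
            for vi in flagged_vars:
                if len(stats.thresholds[vi]) > 1:
                    raise ValueError(
                        "observed-scale correlations are supported only for "
                        "binary or numeric variables")

    def bounds(self):
        return [_ROLE_BOUNDS[r] for r in self.roles]

    def _smart_starts(self, stats: PolyStats) -> None:
        """Data-driven starting values: loadings from indicator triads,
        structural coefficients from attenuation-corrected correlations."""
        R = np.eye(self.p)
        for idx, (i, j) in enumerate(stats.pairs):
            R[i, j] = R[j, i] = stats.rho[idx]
        # indicator sets per latent (free or fixed loadings alike)
        ind: dict[int, list[int]] = {}
        load_par: dict[tuple[int, int], float] = {}
        for arr, key, v, fx in self.entries:
            if arr == "lam":
                oi, li = key
                ind.setdefault(li, []).append(oi)
        lam_hat = np.zeros(self.p)
        for li, obs in ind.items():
            for oi in obs:
                ests = []
                for a in obs:
                    for b in obs:
                        if len({oi, a, b}) == 3 and abs(R[a, b]) > 0.05:
                            v = R[oi, a] * R[oi, b] / R[a, b]
                            if v > 0:
                                ests.append(np.sqrt(min(v, 0.95)))
                lam_hat[oi] = np.clip(np.median(ests), 0.15, 0.95) if ests \
                    else 0.5
        for arr, key, v, fx in self.entries:
            if fx:
                continue
            if arr == "lam" and self.roles[v] == "loading":
                oi, li = key
                if lam_hat[oi] > 0:
                    # theta-scale loading: residual variance fixed at 1
                    r = min(lam_hat[oi], 0.99)
                    self.starts[v] = float(r / np.sqrt(1.0 - r * r))
            elif arr in ("B", "psi") and self.roles[v] in ("regression",
                                                           "psi_cov"):
                a, b = key
                oa = ind.get(a, [])
                ob = ind.get(b, [])
                vals = [R[i, j] / max(lam_hat[i] * lam_hat[j], 0.05)
                        for i in oa for j in ob if i != j]
                if vals:
                    self.starts[v] = float(np.clip(np.median(vals), -0.9, 0.9))

    # -- matrix assembly ----------------------------------------------------
    def _matrices(self, theta: np.ndarray):
        out = []
        for name in ("lam", "B", "psi", "alpha", "theta", "thcov", "tau"):
            arr = self._templates[name].copy()
            pos, idx = self._assign[name]
            if len(pos):
                arr.flat[pos] = theta[idx]
            out.append(arr)
        return tuple(out)

    def _structure(self, theta: np.ndarray):
        """Implied liability SDs, latent moments and correlation vector."""
        lam, B, psi_z, alpha, th, thcov, tau = self._matrices(theta)
        m = self.m
        A = np.linalg.solve(np.eye(m) - B, np.eye(m))
        for fi in self._uv_idx:
            psi_lat = A @ psi_z @ A.T
            psi_z[fi, fi] += (1.0 - psi_lat[fi, fi]) / (A[fi, fi] ** 2)
        psi_lat = A @ psi_z @ A.T
        mu_lat = A @ alpha
        lam_star = lam  # loadings act on latents directly
        sig_star = lam_star @ psi_lat @ lam_star.T + thcov
        diag = np.diag(sig_star) + th
        if np.any(diag <= 0):
            diag = np.maximum(diag, 1e-8)
        sigma = np.sqrt(diag)
        liab_mean = lam_star @ mu_lat
        return lam_star, psi_lat, mu_lat, sigma, sig_star, th, liab_mean, tau

    def implied(self, theta: np.ndarray) -> np.ndarray:
        (lam, psi_lat, mu_lat, sigma, sig_star, th, liab_mean,
         tau) = self._structure(theta)
        out = np.empty(self.m_stats)
        vot = self.var_of_thr
        out[:self.n_thr] = (tau - liab_mean[vot]) / sigma[vot]
        out[self.n_thr:] = (sig_star[self._pi, self._pj]
                            / (sigma[self._pi] * sigma[self._pj]))
        if self._obs_scale is not None:
            out[self.n_thr:] *= self._attenuation(out[:self.n_thr])
        return out

    def _attenuation(self, thr_std: np.ndarray) -> np.ndarray:
        """Per-pair multiplier mapping liability-scale to observed-scale
        correlations for flagged pairs (1 elsewhere)."""
        kv = np.ones(self.p)
        has = self._first_thr >= 0
        t = thr_std[self._first_thr[has]]
        F = norm.cdf(t)
        kv[has] = norm.pdf(t) / np.sqrt(np.clip(F * (1 - F), 1e-12, None))
        fac = np.ones(len(self._pi))
        fl = self._obs_scale
        fac[fl] = kv[self._pi[fl]] * kv[self._pj[fl]]
        return fac

    # -- profiled objective -------------------------------------------------
    def objective_factory(self, s: np.ndarray, w: np.ndarray):
        var_of_thr = self.var_of_thr
        thr_groups = [(pid, np.asarray(stat_idx))
                      for pid, stat_idx in self.thr_param_stats.items()]

        def split_eval(theta_full: np.ndarray):
            (lam, psi_lat, mu_lat, sigma, sig_star, th, liab_mean,
             tau) = self._structure(theta_full)
            # profile free threshold parameters: implied = (t - a_i)/sigma_i
            for pid, si in thr_groups:
                vi = var_of_thr[si]
                coef = 1.0 / sigma[vi]
                rhs = s[si] + liab_mean[vi] / sigma[vi]
                wk = w[si]
                t_opt = (wk * coef * rhs).sum() / (wk * coef ** 2).sum()
                theta_full[pid] = t_opt
                tau[si] = t_opt
            resid = np.empty(self.m_stats)
            resid[:self.n_thr] = (tau - liab_mean[var_of_thr]) / sigma[var_of_thr]
            resid[self.n_thr:] = (sig_star[self._pi, self._pj]
                                  / (sigma[self._pi] * sigma[self._pj]))
            if self._obs_scale is not None:
                resid[self.n_thr:] *= self._attenuation(resid[:self.n_thr])
            r = s - resid
            return float(np.sum(w * r * r))

        def fun(x_nonthr: np.ndarray, theta_full: np.ndarray) -> float:
            theta_full[:self.n_nonthr] = x_nonthr
            return split_eval(theta_full)

        return fun


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _canonicalize_signs(model: _Compiled, theta: np.ndarray) -> np.ndarray:
    """Resolve reflection indeterminacy: flip any group of latents (joined
    by shared loading parameters) whose summed loadings are negative.  The
    flip is an exact model-equivalent transformation (identical fit)."""
    lam, B, psi, alpha, *_ = model._matrices(theta)
    m = model.m
    # union latents sharing free loading parameters
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    par_lats: dict[int, list[int]] = {}
    for arr, key, v, fx in model.entries:
        if arr == "lam" and not fx:
            par_lats.setdefault(v, []).append(key[1])
    for lats in par_lats.values():
        for l in lats[1:]:
            union(lats[0], l)
    # also join latents linked by fixed nonzero structural paths
    # (e.g. wave2 = wave1 + change): they must flip together
    for arr, key, v, fx in model.entries:
        if arr == "B" and fx and v != 0.0:
            union(key[0], key[1])
    groups: dict[int, list[int]] = {}
    for l in range(m):
        groups.setdefault(find(l), []).append(l)

    theta = theta.copy()
    for members in groups.values():
        if sum(lam[:, l].sum() for l in members) >= 0:
            continue
        mem = set(members)
        flippable = True
        flip_idx = set()
        for arr, key, v, fx in model.entries:
            if arr == "lam":
                if key[1] in mem:
                    if fx and v != 0.0:
                        flippable = False
                    elif not fx:
                        flip_idx.add(v)
            elif arr in ("B", "psi"):
                a, b = key
                if (a in mem) != (b in mem):
                    if fx and v != 0.0:
                        flippable = False
                    elif not fx:
                        flip_idx.add(v)
            elif arr == "alpha" and key[0] in mem and not fx:
                flip_idx.add(v)
            elif arr == "alpha" and key[0] in mem and fx and v != 0.0:
                flippable = False
        if flippable:
            for idx in flip_idx:
                theta[idx] = -theta[idx]
    return theta


def _jacobian(model: _Compiled, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    J = np.empty((model.m_stats, model.q))
    for j in range(model.q):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        J[:, j] = (model.implied(tp) - model.implied(tm)) / (2 * h)
    return J


def _scaled_shifted(F_min, U, cov_s, df):
    UC = U @ cov_s
    tr1 = float(np.trace(UC))
    tr2 = float(np.trace(UC @ UC))
    if df <= 0 or tr2 <= 0:
        return max(F_min, 0.0), (1.0, 0.0)
    a = np.sqrt(df / tr2)
    b = df - a * tr1
    return max(a * F_min + b, 0.0), (a, b)


def fit_dwls(spec: SemModelSpec, stats: PolyStats, n: int | None = None,
             compute_baseline: bool = True, max_starts: int = 3,
             gtol: float = 5e-6,
             warm_start: dict | None = None) -> FitResult:
    """Fit a threshold-structure model to polychoric statistics by DWLS.

    ``n`` defaults to the analytic-sample size carried by ``stats``.
    ``warm_start`` maps parameter names (or equality-group labels) to
    starting values; unknown names are ignored.  Non-convergence after
    multi-start retries is reported via ``converged=False`` together with
    the last gradient norm in a warning.
    """
    n = n if n is not None else stats.n
    model = _Compiled(spec, stats)
    if warm_start:
        for name, value in warm_start.items():
            if name in model._by_label and np.isfinite(value):
                model.starts[model._by_label[name]] = float(value)
    s = stats.s
    w = 1.0 / np.maximum(stats.avar, 1e-12)
    fun = model.objective_factory(s, w)

    theta_full = np.array(model.starts)
    x0 = theta_full[:model.n_nonthr].copy()
    bounds = model.bounds()[:model.n_nonthr]
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(max_starts + 2):
        if attempt == 0:
            x_start = x0
        elif attempt <= 2 and best is not None:
            x_start = best.x.copy()  # restart resets the Hessian memory
        else:
            x_start = x0 + rng.normal(0, 0.2, len(x0))
        x_start = np.clip(x_start, [b[0] for b in bounds],
                          [b[1] for b in bounds])
        res = minimize(fun, x_start, args=(theta_full,), method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": 1000, "maxfun": 100000,
                                "ftol": 1e-13, "gtol": gtol})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
            best_theta = theta_full.copy()
            best_theta[:model.n_nonthr] = res.x
            fun(res.x, best_theta)  # refresh profiled thresholds
        if res.success or np.max(np.abs(res.jac)) < 1e-4:
            break
    converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-3)
    if not converged:
        warnings.warn(f"DWLS did not converge: |grad| = "
                      f"{np.max(np.abs(best.jac)):.2e}")
    theta = _canonicalize_signs(model, best_theta)
    F_min = float(best.fun)

    heywood = False
    for i in range(model.n_nonthr):
        if model.roles[i] in ("psi_var", "theta_var"):
            if theta[i] <= VAR_FLOOR * 1.01:
                heywood = True

    J = _jacobian(model, theta)
    W = np.diag(w)
    H = J.T @ (w[:, None] * J)
    try:
        Hinv = np.linalg.inv(H)
        rank_ok = True
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
        rank_ok = False
        warnings.warn("singular information matrix: model may be "
                      "under-identified")
    WJ = w[:, None] * J
    U = W - WJ @ Hinv @ WJ.T
    cov_s = stats.gamma if stats.gamma is not None else np.diag(stats.avar)
    df = model.df

    if df > 0:
        chi2, (a_c, b_c) = _scaled_shifted(F_min, U, cov_s, df)
        pvalue = float(chi2_dist.sf(chi2, df))
    else:
        chi2, (a_c, b_c) = max(F_min, 0.0), (1.0, 0.0)
        pvalue = 1.0

    cov_theta = Hinv @ (WJ.T @ cov_s @ WJ) @ Hinv
    ses = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))

    estimates = dict(zip(model.names, theta))
    se = dict(zip(model.names, ses))

    baseline_chi2, baseline_df = 0.0, 0
    rmsea = cfi = tli = np.nan
    tli_gt1 = False
    if compute_baseline and df > 0:
        corr = slice(model.n_thr, model.m_stats)
        F_b = float(np.sum(w[corr] * s[corr] ** 2))
        U_b = np.zeros_like(W)
        U_b[corr, corr] = w[corr]
        baseline_df = model.m_stats - model.n_thr
        baseline_chi2, _ = _scaled_shifted(F_b, U_b, cov_s, baseline_df)
        rmsea, cfi, tli = fit_indices(chi2, df, n, baseline_chi2, baseline_df)
        tli_gt1 = tli > 1

    fit = FitResult(
        estimates=estimates, se=se, std_beta={}, chi2=chi2, df=df,
        pvalue=pvalue, scale_factors=(a_c, b_c), rmsea=rmsea, cfi=cfi,
        tli=tli, tli_gt1=tli_gt1, converged=converged and rank_ok, n=n,
        heywood=heywood, baseline_chi2=baseline_chi2, baseline_df=baseline_df,
        _theta=theta, _cov=cov_theta, _names=model.names, _F_min=F_min,
        _U=U, _cov_s=cov_s, _s=s, _spec=spec, _model=model)
    fit.std_beta = standardize(fit, spec)
    return fit


def fit_indices(chi2: float, df: int, n: int, baseline_chi2: float,
                baseline_df: int) -> tuple[float, float, float]:
    """RMSEA / CFI / TLI from the model and baseline test statistics.

    rmsea = sqrt(max(0, (chi2 - df) / (df (n-1)))); TLI is returned
    untruncated (values > 1 are possible for well-fitting models).
    """
    if df <= 0:
        raise ValueError("fit indices undefined for a saturated model (df=0)")
    rmsea = float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))
    num = max(0.0, chi2 - df)
    den = max(num, baseline_chi2 - baseline_df)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rb = baseline_chi2 / baseline_df if baseline_df > 0 else np.inf
    rm = chi2 / df
    tli = (rb - rm) / (rb - 1.0) if rb != 1.0 else np.nan
    return rmsea, cfi, float(tli)


def chi2_diff_test(restricted: FitResult, free_fit: FitResult,
                   allow_reparameterized: bool = False
                   ) -> tuple[float, int, float]:
    """Scaled chi-square difference test for nested DWLS fits.

    The raw difference of discrepancy values is rescaled and shifted using
    the difference of the two residual-weight matrices against the sampling
    covariance of the shared statistics, the adjustment appropriate for
    mean-and-variance-adjusted statistics.

    Nesting is verified by requiring the restricted model's free locations
    to be a subset of the free model's.  Invariance ladders violate that
    literal check while remaining nested up to an identification
    reparameterization (equality constraints make wave-2 scale parameters
    estimable and conventionally freed); pass ``allow_reparameterized=True``
    to accept such pairs (df ordering is still enforced).
    """
    if restricted._s is None or free_fit._s is None:
        raise ValueError("fits lack stored statistics")
    if not np.allclose(restricted._s, free_fit._s):
        raise ValueError("difference test requires fits to the same "
                         "statistics")
    locs_r = restricted._spec.free_locations()
    locs_f = free_fit._spec.free_locations()
    if not locs_r.issubset(locs_f) and not allow_reparameterized:
        raise ValueError("models are not nested: restricted model frees "
                         f"locations absent from the free model: "
                         f"{sorted(locs_r - locs_f)[:4]}")
    df_diff = restricted.df - free_fit.df
    if df_diff < 0:
        raise ValueError("restricted model has fewer df than the free model")
    if df_diff == 0:
        return 0.0, 0, 1.0
    T_raw = max(restricted._F_min - free_fit._F_min, 0.0)
    U_d = restricted._U - free_fit._U
    stat, _ = _scaled_shifted(T_raw, U_d, restricted._cov_s, df_diff)
    p = float(chi2_dist.sf(stat, df_diff))
    return stat, df_diff, p


def standardize(fit: FitResult, spec: SemModelSpec) -> dict:
    """Fully standardized solution: loadings scaled by implied latent SD /
    liability SD, regressions by predictor SD / outcome SD."""
    model = fit._model
    theta = fit._theta

    def std_values(th):
        lam, psi_lat, mu_lat, sigma, *_ = model._structure(th)
        sd_lat = np.sqrt(np.maximum(np.diag(psi_lat), 1e-12))
        out = {}
        for (obs, lat), p in spec.loadings.items():
            oi, li = model.obs_idx[obs], model.lat_idx[lat]
            out[f"std_lam:{obs}~{lat}"] = lam[oi, li] * sd_lat[li] / sigma[oi]
        lamB, B, *_rest = model._matrices(th)
        for (outl, pred), p in spec.regressions.items():
            oi, pi = model.lat_idx[outl], model.lat_idx[pred]
            out[f"std_b:{outl}~{pred}"] = B[oi, pi] * sd_lat[pi] / sd_lat[oi]
        return out

    base = std_values(theta)
    # delta-method SEs
    h = 1e-6
    keys = list(base)
    grads = np.zeros((len(keys), model.q))
    for j in range(model.q):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        vp = std_values(tp)
        vm = std_values(tm)
        for ki, k in enumerate(keys):
            grads[ki, j] = (vp[k] - vm[k]) / (2 * h)
    cov = fit._cov
    result = {}
    for ki, k in enumerate(keys):
        var = float(grads[ki] @ cov @ grads[ki])
        result[k] = (float(base[k]), float(np.sqrt(max(var, 0.0))))
    return result


# ---------------------------------------------------------------------------
# compact model text syntax: "F by i1, i2; F on G; a with b"
# ---------------------------------------------------------------------------

def parse_model_text(text: str, observed: list[str]) -> SemModelSpec:
    """Parse a compact model description.

    Statements separated by ';' or newlines: ``F by a, b, c`` (loadings,
    free; ``name@v`` fixes at v; ``name=label`` joins an equality group),
    ``F on G`` (regression), ``a with b`` (covariance: latent pair -> psi,
    observed pair -> residual covariance).  Factors default to unit
    variance.
    """
    spec = SemModelSpec(observed=list(observed), latents=[])

    def parse_term(tok: str):
        tok = tok.strip()
        m = re.match(r"^([\w.]+)@(-?[\d.]+)$", tok)
        if m:
            return m.group(1), fixed_at(float(m.group(2)))
        m = re.match(r"^([\w.]+)=(\w+)$", tok)
        if m:
            return m.group(1), free(label=m.group(2))
        return tok, free()

    for stmt in re.split(r"[;\n]", text):
        stmt = stmt.strip()
        if not stmt:
            continue
        m = re.match(r"^(\w+)\s+by\s+(.+)$", stmt)
        if m:
            factor = m.group(1)
            if factor not in spec.latents:
                spec.latents.append(factor)
                spec.psi[(factor, factor)] = fixed_at(1.0)
            for tok in m.group(2).split(","):
                name, par = parse_term(tok)
                if name not in observed:
                    raise ValueError(f"unknown indicator {name!r}")
                spec.loadings[(name, factor)] = par
            continue
        m = re.match(r"^(\w+)\s+on\s+(.+)$", stmt)
        if m:
            outcome = m.group(1)
            for tok in m.group(2).split(","):
                name, par = parse_term(tok)
                spec.regressions[(outcome, name)] = par
            spec.psi.pop((outcome, outcome), None)
            spec.unit_variance.add(outcome)
            continue
        m = re.match(r"^([\w.]+)\s+with\s+([\w.]+)$", stmt)
        if m:
            a, b = m.group(1), m.group(2)
            if a in observed and b in observed:
                spec.theta_cov[(a, b)] = free()
            else:
                spec.psi[(a, b)] = free()
            continue
        raise ValueError(f"cannot parse model statement: {stmt!r}")
    return spec
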