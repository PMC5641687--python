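"""Tetrachoric / polychoric correlation estimation.

Two-stage maximum likelihood: thresholds from the univariate margins
(tau_c = Phi^{-1} of the cumulative proportion), then each correlation by
1-D maximization of the bivariate-normal likelihood of the contingency
table with thresholds held fixed.  Asymptotic variances -- and, when
complete cases permit, the full asymptotic covariance matrix of all
statistics -- are obtained from the influence functions of the two-stage
estimator, which is what a mean-and-variance-adjusted weighted
least-squares fit downstream needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._bvn import bvn_cdf, bvn_pdf

__all__ = [
    "ThresholdSet",
    "PairResult",
    "PolychoricMatrix",
    "PolyStats",
    "estimate_thresholds",
    "tetrachoric",
    "polychoric_pair",
    "polychoric_matrix",
    "compute_poly_stats",
    "compute_mixed_stats",
    "smooth_correlation",
]

RHO_BOUND = 0.999


class BoundaryError(ValueError):
    """A marginal category has zero count; collapse categories and retry."""


@dataclass
class ThresholdSet:
    """Ordered standard-normal thresholds per variable.

    One threshold for binary variables, K-1 for K ordered categories.
    """

    thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, var: str) -> np.ndarray:
        return self.thresholds[var]

    def __setitem__(self, var: str, tau: np.ndarray) -> None:
        tau = np.asarray(tau, dtype=float)
        if tau.size > 1 and np.any(np.diff(tau) <= 0):
            raise ValueError(f"thresholds for {var!r} must be strictly increasing")
        self.thresholds[var] = tau

    def __contains__(self, var: str) -> bool:
        return var in self.thresholds


class PairResult(NamedTuple):
    rho: float
    se: float
    n: int
    boundary: bool


def estimate_thresholds(proportions: Sequence[float]) -> np.ndarray:
    """Thresholds from category proportions: tau_j = Phi^{-1}(cum prop).

    ``proportions`` are the K category probabilities in ascending category
    order; K-1 thresholds are returned.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise BoundaryError(
            "zero-count (or saturated) category: collapse adjacent categories "
            "before threshold estimation"
        )
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("category proportions must sum to 1")
    return ndtri(np.cumsum(p)[:-1])


def _edges(tau: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], np.asarray(tau, float), [np.inf]))


def _cell_probs(tau_a: np.ndarray, tau_b: np.ndarray, rho: float) -> np.ndarray:
    """R x C matrix of bivariate-normal cell probabilities."""
    ea, eb = _edges(tau_a), _edges(tau_b)
    grid = bvn_cdf(ea[:, None], eb[None, :], rho)
    p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(p, 1e-300, 1.0)


def _cell_dprobs(tau_a: np.ndarray, tau_b: np.ndarray, rho: float) -> np.ndarray:
    """d(cell probability)/d(rho) via Plackett's identity."""
    ea, eb = _edges(tau_a), _edges(tau_b)
    grid = bvn_pdf(ea[:, None], eb[None, :], rho)
    return grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]


def _table_thresholds(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = table.sum()
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    return estimate_thresholds(pa), estimate_thresholds(pb)


def _fit_rho(table: np.ndarray, tau_a: np.ndarray, tau_b: np.ndarray) -> float:
    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(tau_a, tau_b, rho))))

    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-9})
    return float(res.x)


def _observed_info_se(table: np.ndarray, tau_a, tau_b, rho: float) -> float:
    """SE from the observed information of the profile likelihood in rho."""
    h = 1e-4

    def score(r):
        p = _cell_probs(tau_a, tau_b, r)
        dp = _cell_dprobs(tau_a, tau_b, r)
        return float(np.sum(table * dp / p))

    info = -(score(rho + h) - score(rho - h)) / (2 * h)
    if info <= 0:
        return np.inf
    return 1.0 / np.sqrt(info)


def _pair_from_table(table: np.ndarray) -> PairResult:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise BoundaryError("empty margin in contingency table")
    n = int(table.sum())
    tau_a, tau_b = _table_thresholds(table)
    rho = _fit_rho(table, tau_a, tau_b)
    boundary = bool(abs(rho) >= RHO_BOUND - 1e-6)
    se = _observed_info_se(table, tau_a, tau_b, rho)
    return PairResult(rho=rho, se=se, n=n, boundary=boundary)


def tetrachoric(table: np.ndarray) -> PairResult:
    """ML tetrachoric correlation of a 2x2 table (thresholds from margins).

    A table with an empty interior cell yields an estimate clipped at
    +/-0.999 with ``boundary=True``.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("tetrachoric requires a 2x2 table")
    return _pair_from_table(table)


def polychoric_pair(table: np.ndarray) -> PairResult:
    """ML polychoric correlation of an R x C table; reduces to tetrachoric
    for 2x2 input."""
    return _pair_from_table(np.asarray(table, dtype=float))


# ---------------------------------------------------------------------------
# matrix assembly and influence-function asymptotics
# ---------------------------------------------------------------------------

@dataclass
class PolychoricMatrix:
    names: list[str]
    rho: np.ndarray
    avar: np.ndarray           # sampling variance per correlation (NaN diagonal)
    n_pairwise: np.ndarray
    smoothed: bool = False

    def to_tsv(self, path) -> None:
        """Write the correlation matrix as tab-separated text."""
        pd.DataFrame(self.rho, index=self.names,
                     columns=self.names).to_csv(path, sep="\t")


@dataclass
class PolyStats:
    """First-stage statistics for a weighted least-squares structure fit.

    ``s`` stacks all thresholds (variable by variable) followed by the
    correlations for pairs ``(i, j), i < j`` in row-major order.  ``avar``
    holds the sampling variance of each element of ``s``; ``gamma`` is the
    full sampling covariance matrix of ``s`` when complete cases allowed its
    estimation (None otherwise).
    """

    names: list[str]
    categories: list[np.ndarray]
    thresholds: list[np.ndarray]
    pairs: list[tuple[int, int]]
    rho: np.ndarray
    s: np.ndarray
    avar: np.ndarray
    gamma: np.ndarray | None
    n: int
    boundary_pairs: list[tuple[int, int]] = field(default_factory=list)
    # per-variable: True if the column entered on its observed (numeric)
    # scale rather than as a categorized liability
    numeric_mask: np.ndarray | None = None
    # per-pair: True if the correlation is on the observed scale (any pair
    # involving a numeric variable)
    observed_scale: np.ndarray | None = None
    # complete-case influence matrix (internal; enables mixed-scale assembly)
    _infl: np.ndarray | None = None
    _complete: np.ndarray | None = None

    @property
    def n_thresholds(self) -> int:
        return int(sum(len(t) for t in self.thresholds))

    def threshold_set(self) -> ThresholdSet:
        ts = ThresholdSet()
        for name, tau in zip(self.names, self.thresholds):
            ts[name] = tau
        return ts

    def matrix(self) -> PolychoricMatrix:
        k = len(self.names)
        rho = np.eye(k)
        avar = np.full((k, k), np.nan)
        npair = np.zeros((k, k), dtype=int)
        off = self.n_thresholds
        for idx, (i, j) in enumerate(self.pairs):
            rho[i, j] = rho[j, i] = self.rho[idx]
            avar[i, j] = avar[j, i] = self.avar[off + idx]
        return PolychoricMatrix(names=list(self.names), rho=rho, avar=avar,
                                n_pairwise=npair)


def smooth_correlation(r: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip an indefinite correlation matrix and restore the unit
    diagonal; returns (matrix, was_smoothed)."""
    w, v = np.linalg.eigh(r)
    if w.min() >= 0:
        return r, False
    w = np.maximum(w, min_eig)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m, True


def _codes(col: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Map a categorical column to consecutive integer codes; NaN -> -1."""
    vals = col.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    cats = np.unique(vals[mask])
    codes = np.full(vals.shape, -1, dtype=int)
    codes[mask] = np.searchsorted(cats, vals[mask])
    return codes, cats


def _mean_score_fn(q: np.ndarray):
    """mean score in rho given observed cell proportions q."""

    def u(tau_a, tau_b, rho):
        p = _cell_probs(tau_a, tau_b, rho)
        dp = _cell_dprobs(tau_a, tau_b, rho)
        return float(np.sum(q * dp / p))

    return u


def _binary_poly_stats(codes: np.ndarray, names: list[str],
                       cats: list[np.ndarray], thresholds: list[np.ndarray],
                       n: int, full_gamma: bool, min_complete: int
                       ) -> PolyStats:
    """Vectorized all-binary path: every pairwise tetrachoric correlation is
    solved simultaneously by bisection on the ML score, with closed-form
    information and influence functions."""
    k = codes.shape[1]
    tau = np.array([t[0] for t in thresholds])
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    ia = np.array([p[0] for p in pairs])
    ja = np.array([p[1] for p in pairs])

    valid = codes >= 0
    A1 = ((codes == 1) & valid).astype(float)
    A0 = ((codes == 0) & valid).astype(float)
    N11 = A1.T @ A1
    N10 = A1.T @ A0
    N01 = A0.T @ A1
    N00 = A0.T @ A0
    n00 = N00[ia, ja]; n01 = N01[ia, ja]
    n10 = N10[ia, ja]; n11 = N11[ia, ja]
    npair = n00 + n01 + n10 + n11
    if np.any((n00 + n01) == 0) or np.any((n10 + n11) == 0) \
            or np.any((n00 + n10) == 0) or np.any((n01 + n11) == 0):
        bad = np.argmax((n00 + n01 == 0) | (n10 + n11 == 0)
                        | (n00 + n10 == 0) | (n01 + n11 == 0))
        raise BoundaryError(
            f"empty margin for pair ({names[ia[bad]]}, {names[ja[bad]]})")
    ta, tb = tau[ia], tau[ja]
    Fa, Fb = ndtr(ta), ndtr(tb)

    def cell_probs(rho):
        F2 = bvn_cdf(ta, tb, rho)
        p00 = np.clip(F2, 1e-12, 1.0)
        p01 = np.clip(Fa - F2, 1e-12, 1.0)
        p10 = np.clip(Fb - F2, 1e-12, 1.0)
        p11 = np.clip(1.0 - Fa - Fb + F2, 1e-12, 1.0)
        return p00, p01, p10, p11

    def g(rho):  # score / phi2: decreasing in rho
        p00, p01, p10, p11 = cell_probs(rho)
        return n00 / p00 - n01 / p01 - n10 / p10 + n11 / p11

    lo = np.full(len(pairs), -RHO_BOUND)
    hi = np.full(len(pairs), RHO_BOUND)
    for _ in range(46):
        mid = 0.5 * (lo + hi)
        above = g(mid) > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    rho = 0.5 * (lo + hi)
    boundary = np.abs(rho) >= RHO_BOUND - 1.5e-3
    rho = np.clip(rho, -RHO_BOUND, RHO_BOUND)

    p00, p01, p10, p11 = cell_probs(rho)
    phi2 = bvn_pdf(ta, tb, rho)
    info = phi2 ** 2 * (n00 / p00 ** 2 + n01 / p01 ** 2
                        + n10 / p10 ** 2 + n11 / p11 ** 2)
    pair_var = np.where(info > 0, 1.0 / np.maximum(info, 1e-12), np.inf)

    m = k + len(pairs)
    s = np.concatenate([tau, rho])
    avar = np.empty(m)
    gamma = None
    complete = valid.all(axis=1)
    n_cc = int(complete.sum())
    if full_gamma and n_cc >= min_complete:
        cc = codes[complete]
        # threshold influences
        psi_tau = ((cc == 0).astype(float) - ndtr(tau)[None, :]) / norm.pdf(tau)[None, :]
        # mean score derivatives (per complete-pair proportions)
        q00 = n00 / npair; q01 = n01 / npair
        q10 = n10 / npair; q11 = n11 / npair
        du_drho = -phi2 ** 2 * (q00 / p00 ** 2 + q01 / p01 ** 2
                                + q10 / p10 ** 2 + q11 / p11 ** 2)
        om = np.sqrt(1.0 - rho ** 2)
        d2a = norm.pdf(ta) * ndtr((tb - rho * ta) / om)   # dP00/dtau_a
        d2b = norm.pdf(tb) * ndtr((ta - rho * tb) / om)   # dP00/dtau_b
        pa = norm.pdf(ta); pb = norm.pdf(tb)
        # du/dtau = -phi2 * sum s_c q_c dp_c/dtau / p_c^2   (score term ~ 0)
        du_dta = -phi2 * (q00 * d2a / p00 ** 2 - q01 * (pa - d2a) / p01 ** 2
                          - q10 * (-d2a) / p10 ** 2 + q11 * (d2a - pa) / p11 ** 2)
        du_dtb = -phi2 * (q00 * d2b / p00 ** 2 - q10 * (pb - d2b) / p10 ** 2
                          - q01 * (-d2b) / p01 ** 2 + q11 * (d2b - pb) / p11 ** 2)
        # per-sample score: phi2 * s_c / p_c by cell
        lut = np.stack([phi2 / p00, -phi2 / p01, -phi2 / p10, phi2 / p11],
                       axis=1)  # cell order (0,0),(0,1),(1,0),(1,1)
        cell = cc[:, ia] * 2 + cc[:, ja]
        contrib = np.take_along_axis(
            lut[None, :, :].repeat(n_cc, axis=0),
            cell[:, :, None], axis=2)[:, :, 0]
        psi_rho = -(contrib + du_dta[None, :] * psi_tau[:, ia]
                    + du_dtb[None, :] * psi_tau[:, ja]) / du_drho[None, :]
        infl = np.concatenate([psi_tau, psi_rho], axis=1)
        gamma = np.cov(infl, rowvar=False, bias=True) / n_cc
        gamma = np.atleast_2d(gamma)
        avar = np.diag(gamma).copy()
        avar[avar <= 0] = 1e-12
    else:
        infl = None
        nj = valid.sum(axis=0)
        F = ndtr(tau)
        avar[:k] = F * (1 - F) / (nj * norm.pdf(tau) ** 2)
        avar[k:] = pair_var

    return PolyStats(names=names, categories=cats, thresholds=thresholds,
                     pairs=pairs, rho=rho, s=s, avar=avar, gamma=gamma, n=n,
                     boundary_pairs=[pairs[i] for i in np.flatnonzero(boundary)],
                     _infl=infl, _complete=complete)


def compute_poly_stats(data: pd.DataFrame, full_gamma: bool = True,
                       min_complete: int = 100) -> PolyStats:
    """Estimate thresholds and all pairwise polychoric correlations with
    influence-function asymptotics.

    Missing values (NaN) are handled by pairwise deletion for the point
    estimates; the covariance of the statistics is computed over listwise-
    complete rows (exact when there is no missingness, an MCAR approximation
    otherwise).  A variable observed in a single category raises ValueError.
    """
    names = list(data.columns)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 variables")
    n = len(data)

    codes = np.empty((n, k), dtype=int)
    cats: list[np.ndarray] = []
    thresholds: list[np.ndarray] = []
    degenerate = []
    for j, name in enumerate(names):
        cj, catj = _codes(data[name])
        if len(catj) < 2:
            degenerate.append(name)
            cats.append(catj)
            thresholds.append(np.array([]))
            codes[:, j] = cj
            continue
        codes[:, j] = cj
        cats.append(catj)
        obs = cj[cj >= 0]
        counts = np.bincount(obs, minlength=len(catj)).astype(float)
        thresholds.append(estimate_thresholds(counts / counts.sum()))
    if degenerate:
        raise ValueError(
            f"variables with a single observed category: {degenerate}")

    if all(len(c) == 2 for c in cats):
        return _binary_poly_stats(codes, names, cats, thresholds, n,
                                  full_gamma, min_complete)

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rhos = np.empty(len(pairs))
    pair_se = np.empty(len(pairs))
    boundary_pairs = []
    tables = []
    for idx, (i, j) in enumerate(pairs):
        ok = (codes[:, i] >= 0) & (codes[:, j] >= 0)
        tab = np.zeros((len(cats[i]), len(cats[j])))
        np.add.at(tab, (codes[ok, i], codes[ok, j]), 1.0)
        if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
            raise BoundaryError(
                f"empty margin for pair ({names[i]}, {names[j]})")
        rho = _fit_rho(tab, thresholds[i], thresholds[j])
        rhos[idx] = rho
        tables.append(tab)
        if abs(rho) >= RHO_BOUND - 1e-6:
            boundary_pairs.append((i, j))
        pair_se[idx] = _observed_info_se(tab, thresholds[i], thresholds[j], rho)

    t_off = np.concatenate(([0], np.cumsum([len(t) for t in thresholds])))
    m_thr = int(t_off[-1])
    m = m_thr + len(pairs)
    s = np.concatenate([np.concatenate(thresholds), rhos])

    complete = np.all(codes >= 0, axis=1)
    n_cc = int(complete.sum())

    avar = np.empty(m)
    gamma = None
    if full_gamma and n_cc >= min_complete:
        cc = codes[complete]
        infl = np.zeros((n_cc, m))
        # threshold influences: psi_tau_c(x) = (1{x <= c} - F_c) / phi(tau_c)
        psi_tau: list[np.ndarray] = []
        for j in range(k):
            tau = thresholds[j]
            F = ndtr(tau)
            ind = (cc[:, j][:, None] <= np.arange(len(tau))[None, :])
            pt = (ind - F[None, :]) / norm.pdf(tau)[None, :]
            psi_tau.append(pt)
            infl[:, t_off[j]:t_off[j + 1]] = pt
        # correlation influences with two-stage threshold correction
        h = 1e-5
        for idx, (i, j) in enumerate(pairs):
            tau_a, tau_b, rho = thresholds[i], thresholds[j], rhos[idx]
            tab = tables[idx]
            q = tab / tab.sum()
            u = _mean_score_fn(q)
            du_drho = (u(tau_a, tau_b, rho + h) - u(tau_a, tau_b, rho - h)) / (2 * h)
            if du_drho >= 0:
                du_drho = -1e-8
            p = _cell_probs(tau_a, tau_b, rho)
            dp = _cell_dprobs(tau_a, tau_b, rho)
            score_cell = dp / p
            contrib = score_cell[cc[:, i], cc[:, j]].astype(float)
            for c in range(len(tau_a)):
                ta = tau_a.copy(); ta[c] += h
                tb = tau_a.copy(); tb[c] -= h
                du_dt = (u(ta, tau_b, rho) - u(tb, tau_b, rho)) / (2 * h)
                contrib += du_dt * psi_tau[i][:, c]
            for c in range(len(tau_b)):
                ta = tau_b.copy(); ta[c] += h
                tb = tau_b.copy(); tb[c] -= h
                du_dt = (u(tau_a, ta, rho) - u(tau_a, tb, rho)) / (2 * h)
                contrib += du_dt * psi_tau[j][:, c]
            infl[:, m_thr + idx] = -contrib / du_drho
        gamma = np.cov(infl, rowvar=False, bias=True) / n_cc
        gamma = np.atleast_2d(gamma)
        avar = np.diag(gamma).copy()
        avar[avar <= 0] = 1e-12
    else:
        infl = None
        # diagonal fallback: margins + profile information per pair
        for j in range(k):
            tau = thresholds[j]
            nj = int((codes[:, j] >= 0).sum())
            F = ndtr(tau)
            avar[t_off[j]:t_off[j + 1]] = F * (1 - F) / (nj * norm.pdf(tau) ** 2)
        for idx in range(len(pairs)):
            avar[m_thr + idx] = pair_se[idx] ** 2

    return PolyStats(names=names, categories=cats, thresholds=thresholds,
                     pairs=pairs, rho=rhos, s=s, avar=avar, gamma=gamma,
                     n=n, boundary_pairs=boundary_pairs,
                     _infl=infl, _complete=complete)


def compute_mixed_stats(data: pd.DataFrame, numeric: Sequence[str],
                        full_gamma: bool = True) -> PolyStats:
    """Statistics for a mix of categorical columns (liability scale:
    thresholds + polychoric correlations) and numeric covariates (observed
    scale: Pearson correlations after standardization).

    Any pair involving a numeric column is a Pearson correlation of
    observed scores and is flagged in ``observed_scale``; a structure model
    must attenuate its implied liability-scale correlation accordingly.
    Rows with any missing value are dropped (listwise; mixed-scale
    statistics require a common sample).
    """
    numeric = list(numeric)
    if not numeric:
        return compute_poly_stats(data, full_gamma=full_gamma)
    names = list(data.columns)
    missing_cols = [c for c in numeric if c not in names]
    if missing_cols:
        raise ValueError(f"numeric columns not in data: {missing_cols}")
    df = data.dropna()
    n = len(df)
    if n < 30:
        raise ValueError("too few complete rows for mixed-scale statistics")
    is_num = np.array([c in numeric for c in names])
    ordinal_cols = [c for c in names if c not in numeric]
    if len(ordinal_cols) >= 2:
        sub = compute_poly_stats(df[ordinal_cols], full_gamma=full_gamma)
    elif len(ordinal_cols) == 1:
        # degenerate ordinal block: thresholds and their influences only
        col = ordinal_cols[0]
        codes, cats1 = _codes(df[col])
        counts = np.bincount(codes, minlength=len(cats1)).astype(float)
        if len(cats1) < 2:
            raise ValueError(
                f"variables with a single observed category: [{col!r}]")
        tau1 = estimate_thresholds(counts / counts.sum())
        psi = ((codes[:, None] <= np.arange(len(tau1))[None, :])
               - ndtr(tau1)[None, :]) / norm.pdf(tau1)[None, :]
        g1 = np.atleast_2d(np.cov(psi, rowvar=False, bias=True) / n)
        sub = PolyStats(names=[col], categories=[cats1],
                        thresholds=[tau1], pairs=[], rho=np.array([]),
                        s=tau1.copy(), avar=np.diag(g1).copy(), gamma=g1,
                        n=n, _infl=psi, _complete=np.ones(n, dtype=bool))
    else:
        sub = PolyStats(names=[], categories=[], thresholds=[], pairs=[],
                        rho=np.array([]), s=np.array([]),
                        avar=np.array([]), gamma=np.zeros((0, 0)), n=n,
                        _infl=np.zeros((n, 0)),
                        _complete=np.ones(n, dtype=bool))
    sub_idx = {c: i for i, c in enumerate(ordinal_cols)}
    sub_pair_idx = {pr: i for i, pr in enumerate(sub.pairs)}

    Z = np.column_stack([
        (df[c].to_numpy(float) - df[c].to_numpy(float).mean())
        / df[c].to_numpy(float).std() for c in names])

    k = len(names)
    cats, thresholds = [], []
    for c in names:
        if c in numeric:
            cats.append(np.array([]))
            thresholds.append(np.array([]))
        else:
            cats.append(sub.categories[sub_idx[c]])
            thresholds.append(sub.thresholds[sub_idx[c]])
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    obs_scale = np.array([is_num[i] or is_num[j] for i, j in pairs])
    rhos = np.empty(len(pairs))
    infl_cols = []
    for idx, (i, j) in enumerate(pairs):
        if obs_scale[idx]:
            x, y = Z[:, i], Z[:, j]
            r = float(np.mean(x * y))
            rhos[idx] = r
            infl_cols.append(x * y - 0.5 * r * (x * x + y * y))
        else:
            si = sub_pair_idx[tuple(sorted((sub_idx[names[i]],
                                            sub_idx[names[j]])))]
            rhos[idx] = sub.rho[si]
            if sub._infl is not None:
                infl_cols.append(sub._infl[:, sub.n_thresholds + si])
            else:
                infl_cols.append(None)

    t_off = np.concatenate(([0], np.cumsum([len(t) for t in thresholds])))
    m_thr = int(t_off[-1])
    s = np.concatenate([np.concatenate(thresholds) if m_thr else np.array([]),
                        rhos])
    gamma = None
    avar = np.empty(len(s))
    if full_gamma and sub._infl is not None:
        thr_infl = []
        for c in ordinal_cols:
            i0 = int(np.concatenate(
                ([0], np.cumsum([len(t) for t in sub.thresholds])))[sub_idx[c]])
            i1 = i0 + len(sub.thresholds[sub_idx[c]])
            thr_infl.append((c, sub._infl[:, i0:i1]))
        thr_map = dict(thr_infl)
        blocks = [thr_map[c] for c in names if c not in numeric]
        infl = np.column_stack(
            ([np.column_stack(blocks)] if blocks else [])
            + [np.column_stack(infl_cols)])
        gamma = np.atleast_2d(np.cov(infl, rowvar=False, bias=True) / n)
        avar = np.diag(gamma).copy()
        avar[avar <= 0] = 1e-12
    else:
        avar[:m_thr] = sub.avar[:sub.n_thresholds]
        for idx in range(len(pairs)):
            if obs_scale[idx]:
                avar[m_thr + idx] = (1 - rhos[idx] ** 2) ** 2 / n
            else:
                si = sub_pair_idx[tuple(sorted((sub_idx[names[pairs[idx][0]]],
                                                sub_idx[names[pairs[idx][1]]])))]
                avar[m_thr + idx] = sub.avar[sub.n_thresholds + si]

    return PolyStats(names=names, categories=cats, thresholds=thresholds,
                     pairs=pairs, rho=rhos, s=s, avar=avar, gamma=gamma, n=n,
                     boundary_pairs=[], numeric_mask=is_num,
                     observed_scale=obs_scale)


def polychoric_matrix(data: pd.DataFrame, smooth: bool = True,
                      full_gamma: bool = False) -> PolychoricMatrix:
    """Pairwise-complete polychoric correlation matrix with asymptotic
    variances; indefinite matrices are eigenvalue-smoothed and flagged."""
    stats = compute_poly_stats(data, full_gamma=full_gamma)
    pm = stats.matrix()
    npair = np.zeros_like(pm.n_pairwise)
    codes = np.column_stack([_codes(data[c])[0] for c in data.columns])
    for i in range(len(pm.names)):
        for j in range(len(pm.names)):
            npair[i, j] = int(((codes[:, i] >= 0) & (codes[:, j] >= 0)).sum())
    pm.n_pairwise = npair
    if smooth:
        pm.rho, pm.smoothed = smooth_correlation(pm.rho)
    return pm
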