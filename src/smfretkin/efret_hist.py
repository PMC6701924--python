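"""Time-resolved E_FRET distributions and constrained mixture fits.

Provides the 2D Gaussian-kernel density of pooled (time, E_FRET) points
with per-time-slice normalization, windowed 1D histograms with bootstrap
standard errors, and a global two-Gaussian maximum-likelihood fit with
component positions and widths shared across time windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess1

from smfretkin.preprocess import EfretRecord

_SIGMA_FLOOR = 1e-3


@dataclass
class Density2D:
    """Slice-normalized kernel density over (time since t0, E_FRET)."""

    t_grid: np.ndarray
    e_grid: np.ndarray
    density: np.ndarray  # shape (len(t_grid), len(e_grid)), slice-normalized
    raw_density: np.ndarray  # before per-slice normalization
    bw_t: float
    bw_e: float
    n_t: int  # measurements within the displayed range
    slice_width: float
    empty_slices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


@dataclass
class WindowHistogram:
    window: tuple[float, float]
    bin_edges: np.ndarray
    density: np.ndarray
    se: np.ndarray
    n_obs: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianMixtureFit:
    """Constrained two-component fit: means/SDs shared across windows,
    mixture weight free per window."""

    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    weights_low: np.ndarray  # per-window weight of the low component
    se_mu_low: float
    se_mu_high: float
    log_likelihood: float
    per_window_loglik: np.ndarray
    n_per_window: np.ndarray
    sigma_floored: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "window": j,
                "mu_low": self.mu_low,
                "mu_high": self.mu_high,
                "sigma_low": self.sigma_low,
                "sigma_high": self.sigma_high,
                "weight_low": w,
                "weight_high": 1.0 - w,
                "se_mu_low": self.se_mu_low,
                "se_mu_high": self.se_mu_high,
                "n": int(n),
                "loglik": ll,
            }
            for j, (w, n, ll) in enumerate(
                zip(self.weights_low, self.n_per_window, self.per_window_loglik)
            )
        ]
        return pd.DataFrame(rows)


def pooled_points(
    records: list[EfretRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Unmasked (t since t0, E_FRET) pairs pooled across records."""
    ts, es = [], []
    for r in records:
        keep = ~r.outlier_mask
        ts.append(r.times_since_t0[keep])
        es.append(r.efret[keep])
    if not ts:
        return np.zeros(0), np.zeros(0)
    return np.concatenate(ts), np.concatenate(es)


def kde2d_raw(
    t_pts: np.ndarray,
    e_pts: np.ndarray,
    t_grid: np.ndarray,
    e_grid: np.ndarray,
    bw_t: float,
    bw_e: float,
) -> np.ndarray:
    """Sum of product-Gaussian kernels over all data points at grid nodes.

    Direct O(N * G) summation — exactly the definition, so small-input
    checks against a naive double loop agree to machine precision.
    """
    kt = np.exp(-0.5 * ((t_grid[:, None] - t_pts[None, :]) / bw_t) ** 2) / (
        bw_t * np.sqrt(2 * np.pi)
    )
    ke = np.exp(-0.5 * ((e_grid[:, None] - e_pts[None, :]) / bw_e) ** 2) / (
        bw_e * np.sqrt(2 * np.pi)
    )
    return kt @ ke.T


def kde2d_density(
    records: list[EfretRecord],
    bw_t: float = 5.0,
    bw_e: float = 0.05,
    t_grid: np.ndarray | None = None,
    e_grid: np.ndarray | None = None,
    grid_dt: float = 1.0,
    grid_de: float = 0.01,
    e_range: tuple[float, float] = (-0.25, 0.85),
    slice_width: float = 2.67,
) -> Density2D:
    """Time-evolved E_FRET kernel density, each time slice renormalized to
    integrate to one over E_FRET.

    Empty slices (zero raw mass) are left at zero density and flagged.
    """
    t_pts, e_pts = pooled_points(records)
    if len(t_pts) == 0:
        raise ValueError("no unmasked measurements")
    if t_grid is None:
        t_grid = np.arange(0.0, t_pts.max() + grid_dt, grid_dt)
    if e_grid is None:
        e_grid = np.arange(e_range[0], e_range[1] + grid_de / 2, grid_de)
    raw = kde2d_raw(t_pts, e_pts, t_grid, e_grid, bw_t, bw_e)

    density = raw.copy()
    integrals = np.trapezoid(raw, e_grid, axis=1)
    empty = integrals <= 0.0
    nz = ~empty
    density[nz] = raw[nz] / integrals[nz, None]

    in_range = (
        (t_pts >= t_grid.min())
        & (t_pts <= t_grid.max())
        & (e_pts >= e_grid.min())
        & (e_pts <= e_grid.max())
    )
    return Density2D(
        t_grid=t_grid,
        e_grid=e_grid,
        density=density,
        raw_density=raw,
        bw_t=bw_t,
        bw_e=bw_e,
        n_t=int(in_range.sum()),
        slice_width=slice_width,
        empty_slices=empty,
    )


def window_values(records: list[EfretRecord], window: tuple[float, float]) -> list[np.ndarray]:
    """Per-record unmasked E_FRET values with t since t0 in [t_a, t_b)."""
    out = []
    for r in records:
        t = r.times_since_t0
        keep = ~r.outlier_mask & (t >= window[0]) & (t < window[1])
        if keep.any():
            out.append(r.efret[keep])
    return out


def window_histogram(
    records: list[EfretRecord],
    window: tuple[float, float],
    bin_edges: np.ndarray | None = None,
    n_bootstrap: int = 500,
    rng: np.random.Generator | int = 0,
) -> WindowHistogram:
    """Probability-density histogram of E_FRET within a time window, with
    per-bin standard errors from bootstrap resampling over records."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    per_record = window_values(records, window)
    if not per_record:
        raise ValueError(f"no measurements in window {window}")
    values = np.concatenate(per_record)
    if bin_edges is None:
        bin_edges = np.arange(-0.25, 0.8501, 0.05)
    dens, _ = np.histogram(values, bins=bin_edges, density=True)

    n_rec = len(per_record)
    boots = np.empty((n_bootstrap, len(bin_edges) - 1))
    for b in range(n_bootstrap):
        pick = rng.integers(0, n_rec, size=n_rec)
        sample = np.concatenate([per_record[i] for i in pick])
        boots[b], _ = np.histogram(sample, bins=bin_edges, density=True)
    return WindowHistogram(
        window=tuple(window),
        bin_edges=np.asarray(bin_edges, dtype=float),
        density=dens,
        se=boots.std(axis=0, ddof=1),
        n_obs=len(values),
    )


# ---------------------------------------------------------------------------
# constrained two-Gaussian global fit
# ---------------------------------------------------------------------------

def _mixture_loglik_per_window(values_per_window, mu, sigma, w_low):
    """Per-window log-likelihood for the 2-component mixture."""
    lls = np.empty(len(values_per_window))
    for j, x in enumerate(values_per_window):
        lp = np.stack(
            [
                np.log(w_low[j] + 1e-300)
                - 0.5 * ((x - mu[0]) / sigma[0]) ** 2
                - np.log(sigma[0] * np.sqrt(2 * np.pi)),
                np.log(1 - w_low[j] + 1e-300)
                - 0.5 * ((x - mu[1]) / sigma[1]) ** 2
                - np.log(sigma[1] * np.sqrt(2 * np.pi)),
            ]
        )
        lls[j] = logsumexp(lp, axis=0).sum()
    return lls


def _em_fit(values_per_window, mu0, sigma0, max_iter=2000, tol=1e-10):
    """EM with means/SDs pooled across windows, weights free per window."""
    J = len(values_per_window)
    mu = np.array(mu0, dtype=float)
    sigma = np.array(sigma0, dtype=float)
    w_low = np.full(J, 0.5)
    floored = False
    ll_old = -np.inf
    for _ in range(max_iter):
        tot = np.zeros(2)
        sx = np.zeros(2)
        sxx = np.zeros(2)
        for j, x in enumerate(values_per_window):
            lp = np.stack(
                [
                    np.log(w_low[j] + 1e-300)
                    - 0.5 * ((x - mu[0]) / sigma[0]) ** 2
                    - np.log(sigma[0]),
                    np.log(1 - w_low[j] + 1e-300)
                    - 0.5 * ((x - mu[1]) / sigma[1]) ** 2
                    - np.log(sigma[1]),
                ]
            )
            r = np.exp(lp - logsumexp(lp, axis=0))
            w_low[j] = r[0].mean()
            tot += r.sum(axis=1)
            sx += r @ x
            sxx += r @ (x ** 2)
        mu = sx / tot
        var = sxx / tot - mu ** 2
        sigma = np.sqrt(np.maximum(var, _SIGMA_FLOOR ** 2))
        if np.any(var < _SIGMA_FLOOR ** 2):
            floored = True
        ll = _mixture_loglik_per_window(values_per_window, mu, sigma, w_low).sum()
        if ll - ll_old < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    return mu, sigma, w_low, ll, floored


def fit_two_gaussians_global(
    values_per_window: list[np.ndarray],
    init_grid: list[tuple[float, float]] | None = None,
) -> GaussianMixtureFit:
    """Global MLE of a two-Gaussian mixture on raw E_FRET values with peak
    positions and widths shared across all windows.

    Deterministic multi-start over a fixed initialization grid; the best
    likelihood wins.  Output components are ordered mu_low < mu_high.
    Standard errors of the means come from the observed information.
    """
    if len(values_per_window) < 1:
        raise ValueError("need at least one window")
    values_per_window = [np.asarray(v, dtype=float) for v in values_per_window]
    pooled = np.concatenate(values_per_window)
    if init_grid is None:
        q = np.quantile(pooled, [0.1, 0.25, 0.75, 0.9])
        mean, std = pooled.mean(), pooled.std()
        init_grid = [
            (q[0], q[3]),
            (q[1], q[2]),
            (0.03, 0.6),
            (mean - std, mean + std),
            # single-component starts: second component far from the data so
            # its weight can vanish when the data are unimodal
            (mean, mean + 4 * std),
            (mean - 4 * std, mean),
        ]
    s0 = max(pooled.std() / 2, 2 * _SIGMA_FLOOR)
    candidates = [
        _em_fit(values_per_window, mu0, (s0, s0)) for mu0 in init_grid
    ]
    ll_best = max(c[3] for c in candidates)
    # likelihood ties (e.g. unimodal data, where a weight-split duplicate
    # component scores the same) break toward concentrated weights
    tol = 1e-6 * max(1.0, abs(ll_best))
    tied = [c for c in candidates if c[3] >= ll_best - tol]
    mu, sigma, w_low, ll, floored = max(
        tied, key=lambda c: np.minimum(c[2], 1 - c[2]).sum() * -1
    )

    # canonical order: low mean first
    if mu[0] > mu[1]:
        mu, sigma, w_low = mu[::-1], sigma[::-1], 1.0 - w_low

    se = _mean_standard_errors(values_per_window, mu, sigma, w_low)
    per_window = _mixture_loglik_per_window(values_per_window, mu, sigma, w_low)
    return GaussianMixtureFit(
        mu_low=float(mu[0]),
        mu_high=float(mu[1]),
        sigma_low=float(sigma[0]),
        sigma_high=float(sigma[1]),
        weights_low=w_low,
        se_mu_low=float(se[0]),
        se_mu_high=float(se[1]),
        log_likelihood=float(ll),
        per_window_loglik=per_window,
        n_per_window=np.array([len(v) for v in values_per_window]),
        sigma_floored=floored,
    )


def _mean_standard_errors(values_per_window, mu, sigma, w_low):
    """SEs of the component means from the observed information matrix.

    Parameters packed as (mu_low, mu_high, log sigma_low, log sigma_high,
    logit w_j ...); the Hessian of the negative log-likelihood is formed by
    finite differences and inverted.
    """
    J = len(values_per_window)
    w = np.clip(w_low, 1e-6, 1 - 1e-6)
    theta0 = np.concatenate([mu, np.log(sigma), np.log(w / (1 - w))])

    def nll(theta):
        m = theta[:2]
        s = np.exp(theta[2:4])
        ww = 1.0 / (1.0 + np.exp(-theta[4:]))
        return -_mixture_loglik_per_window(values_per_window, m, s, ww).sum()

    try:
        H = approx_hess1(theta0, nll)
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:2]
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(2, np.nan)
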