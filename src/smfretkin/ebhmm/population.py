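"""Population-level empirical-Bayes fitting and kinetic summaries.

Alternates per-trace variational inference with re-estimation of the shared
hyperparameters from pooled posterior statistics (mean-log matching for the
Dirichlet blocks, moment matching for the precision prior).  Rates come
from the pooled transition-count posterior scaled by the frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import beta as beta_dist

from smfretkin._types import StatePath
from smfretkin.ebhmm.priors import HMMPriors
from smfretkin.ebhmm.vb import (
    PackedRecords,
    VBState,
    _init_gamma_soft,
    dirichlet_eln,
    pack_records,
    seed_state,
    vb_iterate,
)
from smfretkin.preprocess import EfretRecord


# ---------------------------------------------------------------------------
# hyperparameter updates
# ---------------------------------------------------------------------------

def _inv_digamma(y: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Newton inversion of the digamma function (Minka's initialization)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(n_iter):
        x = x - (digamma(x) - y) / polygamma(1, x)
        x = np.maximum(x, 1e-8)
    return x


def dirichlet_from_meanlog(
    s: np.ndarray, u0: np.ndarray, n_iter: int = 200, tol: float = 1e-10
) -> np.ndarray:
    """Dirichlet parameters whose E[ln p] matches ``s`` (fixed point).

    ``s`` and ``u0`` share their last axis; the iteration
    u_k <- invpsi(psi(sum u) + s_k) converges to the maximum-likelihood
    hyperparameters given mean-log sufficient statistics.
    """
    u = np.maximum(np.asarray(u0, dtype=float).copy(), 1e-3)
    for _ in range(n_iter):
        u_new = _inv_digamma(digamma(u.sum(axis=-1, keepdims=True)) + s)
        u_new = np.clip(u_new, 1e-3, 1e7)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    return u


def _gamma_from_moments(mean_lam: np.ndarray, mean_lnlam: np.ndarray) -> tuple:
    """Gamma(a, b) matching E[lambda] and E[ln lambda] (Newton on shape)."""
    d = np.log(mean_lam) - mean_lnlam  # always > 0 by Jensen
    d = np.maximum(d, 1e-10)
    a = 0.5 / d  # classic starting point
    for _ in range(50):
        num = np.log(a) - digamma(a) - d
        den = 1.0 / a - polygamma(1, a)
        a = np.clip(a - num / den, 1e-3, 1e7)
    return a, a / mean_lam


def _pooled_emission(p: HMMPriors, state: VBState):
    """Normal-gamma posterior from pooled responsibilities under prior p."""
    N = state.Nk.sum(axis=0)
    Sx = state.Sx.sum(axis=0)
    Sx2 = state.Sx2.sum(axis=0)
    safe = np.maximum(N, 1e-12)
    xbar = np.where(N > 1e-12, Sx / safe, p.m)
    S = np.maximum(Sx2 - N * xbar ** 2, 0.0)
    beta_p = p.beta + N
    m_p = (p.beta * p.m + Sx) / beta_p
    a_p = p.a + N / 2.0
    b_p = p.b + 0.5 * (S + p.beta * N * (xbar - p.m) ** 2 / beta_p)
    return m_p, beta_p, a_p, b_p


def eb_update(
    priors_base: HMMPriors, state: VBState, mode: str = "pooled"
) -> HMMPriors:
    """Empirical-Bayes M-step: refit shared hyperparameters from the traces.

    ``mode='pooled'`` (default) moment-matches the hyperparameters to the
    pooled posterior sufficient statistics: Dirichlet blocks become the base
    counts plus the pooled expected transition/initial counts, and the
    emission block becomes the pooled normal-gamma posterior under the base
    prior.  This couples the per-trace fits strongly, which is what lets two
    states with identical emission means separate through their transition
    structure alone.

    ``mode='meanlog'`` is the gradient-exact alternative (hyperparameters
    maximizing the summed evidence bound given the per-trace posteriors);
    it guarantees a monotone evidence bound but couples traces only weakly.
    Pinned emission means/pseudo-counts are held fixed in both modes.
    """
    p = priors_base
    if mode == "meanlog":
        s_pi = dirichlet_eln(state.u_pi_hat).mean(axis=0)
        u_pi = dirichlet_from_meanlog(s_pi, p.u_pi)
        s_A = dirichlet_eln(state.u_A_hat).mean(axis=0)
        u_A = dirichlet_from_meanlog(s_A, p.u_A)
        mean_lam = (state.a_hat / state.b_hat).mean(axis=0)
        mean_lnlam = (digamma(state.a_hat) - np.log(state.b_hat)).mean(axis=0)
        a, b = _gamma_from_moments(mean_lam, mean_lnlam)
        if p.pin_emission:
            m, beta = p.m, p.beta
        else:
            Elam = state.a_hat / state.b_hat
            m = (state.m_hat * Elam).sum(axis=0) / Elam.sum(axis=0)
            inv_beta = (1.0 / state.beta_hat + Elam * (state.m_hat - m) ** 2).mean(axis=0)
            beta = np.clip(1.0 / inv_beta, 1e-3, 1e9)
    elif mode == "pooled":
        u_pi = p.u_pi + state.gamma[:, 0, :].sum(axis=0)
        u_A = p.u_A + state.xi_sum.sum(axis=0)
        m_p, beta_p, a_p, b_p = _pooled_emission(p, state)
        a, b = a_p, b_p
        if p.pin_emission:
            m, beta = p.m, p.beta
        else:
            m, beta = m_p, beta_p
    else:
        raise ValueError(f"unknown EB update mode {mode!r}")

    return HMMPriors(
        m=m, beta=beta, a=a, b=b, u_pi=u_pi, u_A=u_A,
        pin_emission=p.pin_emission,
    )


# ---------------------------------------------------------------------------
# population fit
# ---------------------------------------------------------------------------

@dataclass
class PopulationFit:
    """Fitted population-level kinetic model plus per-trace posteriors."""

    priors_initial: HMMPriors
    priors_final: HMMPriors
    state: VBState
    packed: PackedRecords
    evidence: float
    evidence_history: np.ndarray
    n_rounds: int
    restart_evidences: np.ndarray

    @property
    def n_states(self) -> int:
        return self.priors_final.n_states

    @property
    def frame_interval(self) -> float:
        return self.packed.frame_interval

    @property
    def n_records(self) -> int:
        return len(self.packed.L)

    def pooled_emission_posterior(self) -> tuple[np.ndarray, ...]:
        """Normal-gamma posterior from all pooled responsibilities under the
        initial (possibly pinned) emission prior: (m, beta, a, b)."""
        return _pooled_emission(self.priors_initial, self.state)

    @property
    def state_means(self) -> np.ndarray:
        return self.pooled_emission_posterior()[0]

    @property
    def state_sds(self) -> np.ndarray:
        _, _, a_p, b_p = self.pooled_emission_posterior()
        return np.sqrt(b_p / a_p)

    def decoded_paths(self) -> list["StatePath"]:
        """Viterbi paths for every record (cached)."""
        if not hasattr(self, "_decoded"):
            self._decoded = decode_states(self)
        return self._decoded

    def pooled_transition_counts(
        self, method: str = "decoded", base: float = 0.05
    ) -> np.ndarray:
        """Dirichlet posterior counts for a population-shared transition
        matrix: sparse base counts plus pooled transition counts.

        ``method='decoded'`` (default) counts hard transitions along the
        Viterbi paths; ``method='soft'`` uses the pooled expected transition
        counts from the responsibilities.  Soft counts carry residual blend
        mass between emission-degenerate states (a few spurious fractional
        transitions per cohort), which matters when testing whether rare
        rates differ from zero, so the decoded counts are the default for
        rate inference.
        """
        if method == "soft":
            return base + self.state.xi_sum.sum(axis=0)
        if method != "decoded":
            raise ValueError(f"unknown method {method!r}")
        K = self.n_states
        counts = np.zeros((K, K))
        for path in self.decoded_paths():
            s = path.states
            np.add.at(counts, (s[:-1], s[1:]), 1.0)
        return base + counts

    @property
    def transition_matrix(self) -> np.ndarray:
        c = self.pooled_transition_counts()
        return c / c.sum(axis=1, keepdims=True)


def eb_fit_population(
    records: list[EfretRecord],
    priors: HMMPriors,
    n_restarts: int = 5,
    seed: int = 0,
    max_rounds: int = 30,
    round_tol: float = 1e-5,
    vb_max_iter: int = 100,
    vb_tol: float = 1e-6,
    eb_mode: str = "pooled",
) -> PopulationFit:
    """Fit the hierarchical HMM to pooled records.

    Alternates (a) batched VB on every record under the current shared
    hyperparameters with (b) an EB refit of those hyperparameters from the
    pooled posterior statistics (recomputed from the caller's base priors
    every round, so counts never compound), until the summed evidence is
    stable.  Multi-start over a fixed seed list with jittered initial
    responsibilities; the best evidence wins, so the result is
    deterministic given data and seed.
    """
    if len(records) < 2:
        raise ValueError("population fit needs >= 2 records")
    packed = pack_records(records)
    n_unmasked = int(packed.OBS.sum())
    K = priors.n_states
    if n_unmasked < K * (K + 2):
        raise ValueError("fewer unmasked frames than model parameters")

    best = None
    restart_evs = []
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        gamma0 = _init_gamma_soft(packed, priors, rng, jitter=0.0 if r == 0 else 0.5)
        # prime the shared hyperparameters from the initial assignments so
        # the first E-step already sees population-level transition structure
        u = eb_update(priors, seed_state(packed, priors, gamma0), mode=eb_mode)
        st = vb_iterate(packed, u, gamma0, max_iter=vb_max_iter, tol=vb_tol)
        ev_hist = [st.elbo.sum()]
        for _ in range(max_rounds):
            u = eb_update(priors, st, mode=eb_mode)
            st = vb_iterate(
                packed, u, gamma_init=st.gamma, max_iter=vb_max_iter, tol=vb_tol
            )
            ev = st.elbo.sum()
            ev_hist.append(ev)
            if abs(ev - ev_hist[-2]) < round_tol * max(abs(ev), 1.0):
                break
        restart_evs.append(ev_hist[-1])
        if best is None or ev_hist[-1] > best[0]:
            best = (ev_hist[-1], u, st, np.array(ev_hist))

    ev, u, st, hist = best
    return PopulationFit(
        priors_initial=priors,
        priors_final=u,
        state=st,
        packed=packed,
        evidence=float(ev),
        evidence_history=hist,
        n_rounds=len(hist) - 1,
        restart_evidences=np.array(restart_evs),
    )


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def viterbi(
    ln_start: np.ndarray, ln_trans: np.ndarray, ln_obs: np.ndarray
) -> np.ndarray:
    """Most-probable state sequence; ties resolve to the lowest index."""
    T, K = ln_obs.shape
    delta = ln_start + ln_obs[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + ln_trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + ln_obs[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_states(fit: PopulationFit, index: int | None = None) -> list[StatePath]:
    """Viterbi decoding under per-trace posterior-mean parameters.

    Masked frames contribute no emission term and are bridged by the
    transition structure.  Returns one path per record (or a single-element
    list for a specific ``index``).
    """
    st, packed = fit.state, fit.packed
    idxs = range(fit.n_records) if index is None else [index]
    out = []
    for n in idxs:
        L = int(packed.L[n])
        pi = st.u_pi_hat[n] / st.u_pi_hat[n].sum()
        A = st.u_A_hat[n] / st.u_A_hat[n].sum(axis=1, keepdims=True)
        mean = st.m_hat[n]
        var = st.b_hat[n] / st.a_hat[n]
        x = packed.X[n, :L]
        obs = packed.OBS[n, :L]
        ln_obs = -0.5 * (
            np.log(2 * np.pi * var)[None, :] + (x[:, None] - mean[None, :]) ** 2 / var
        )
        ln_obs = np.where(obs[:, None], ln_obs, 0.0)
        path = viterbi(np.log(pi), np.log(A), ln_obs)
        out.append(
            StatePath(states=path, frame_interval=packed.frame_interval, t0=packed.t0[n])
        )
    return out


# ---------------------------------------------------------------------------
# rates and initial fractions
# ---------------------------------------------------------------------------

def transition_rates(
    fit: PopulationFit,
    frame_interval: float | None = None,
    significance_floor: float = 1e-4,
    ci_level: float = 0.95,
    use_matrix_log: bool = False,
    counts_method: str = "decoded",
    base_count: float = 0.05,
    min_row_counts: float = 3.0,
) -> pd.DataFrame:
    """Per-second rate constants with credible intervals and significance.

    k_ij = E[p_ij] / dt for i != j, with the credible interval from the
    marginal Beta posterior of each transition probability scaled by 1/dt
    (valid while k dt << 1).  ``use_matrix_log`` instead takes the matrix
    logarithm of E[P] for the point estimates.  A rate is flagged
    significant when the lower CI bound clears ``significance_floor`` and
    its source state carries at least ``min_row_counts`` counts of data —
    exit rates of an essentially unoccupied state are unidentifiable, not
    significant.
    """
    dt = fit.frame_interval if frame_interval is None else frame_interval
    if dt <= 0:
        raise ValueError("frame interval must be > 0")
    counts = fit.pooled_transition_counts(method=counts_method, base=base_count)
    K = counts.shape[0]
    row_data = counts.sum(axis=1) - K * base_count
    row = counts.sum(axis=1)
    p_mean = counts / row[:, None]
    k_linear = p_mean / dt
    if use_matrix_log:
        from scipy.linalg import logm

        Q = np.real(logm(p_mean)) / dt
        k_point = np.maximum(Q, 0.0)
    else:
        k_point = k_linear
    # credible bounds on p_ij from its marginal Beta posterior, mapped to
    # the rate scale by the same conversion as the point estimate
    scale = np.where(k_linear > 0, k_point / np.maximum(k_linear, 1e-300), 1.0)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            c_ij, c_rest = counts[i, j], row[i] - counts[i, j]
            ci_low = beta_dist.ppf(lo_q, c_ij, c_rest) / dt * scale[i, j]
            ci_high = beta_dist.ppf(hi_q, c_ij, c_rest) / dt * scale[i, j]
            rows.append(
                {
                    "from_state": i,
                    "to_state": j,
                    "k_per_s": k_point[i, j],
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "significant": bool(
                        ci_low > significance_floor and row_data[i] >= min_row_counts
                    ),
                }
            )
    return pd.DataFrame(rows)


def initial_fractions(
    fit: PopulationFit,
    n_bootstrap: int = 500,
    rng: np.random.Generator | int = 0,
    method: str = "responsibility",
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of records in each state at the time of second arrival.

    ``method='responsibility'``: mean of frame-zero responsibilities across
    records.  ``method='decoded'``: share of records whose decoded path is
    assigned to each state at the first time point (how the cohort counts
    are reported).  SE from bootstrap resampling over records.  Returns
    (IF, SE)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if method == "decoded":
        first = np.array([p.states[0] for p in decode_states(fit)])
        g0 = np.zeros((len(first), fit.n_states))
        g0[np.arange(len(first)), first] = 1.0
    elif method == "responsibility":
        g0 = fit.state.gamma[:, 0, :]
    else:
        raise ValueError(f"unknown method {method!r}")
    if_mean = g0.mean(axis=0)
    n = g0.shape[0]
    boots = np.empty((n_bootstrap, g0.shape[1]))
    for b in range(n_bootstrap):
        boots[b] = g0[rng.integers(0, n, size=n)].mean(axis=0)
    return if_mean, boots.std(axis=0, ddof=1)


def rate_matrix_table(fit: PopulationFit, **kwargs) -> pd.DataFrame:
    return transition_rates(fit, **kwargs)


def state_parameter_table(fit: PopulationFit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": np.arange(fit.n_states),
            "efret_mean": fit.state_means,
            "efret_sd": fit.state_sds,
        }
    )
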