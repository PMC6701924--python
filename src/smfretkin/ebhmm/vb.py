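"""Variational-Bayes inference for one or many E_FRET records.

Conjugate variational HMM with normal-gamma emissions and Dirichlet
transition/initial priors.  The E-step runs scaled forward-backward on the
geometric-mean ("tilde") parameterization of the variational posterior;
masked frames contribute no emission term but keep their transitions, so
dwell accounting stays on the true time base.  All records are processed in
a single padded batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from smfretkin.ebhmm.priors import HMMPriors
from smfretkin.preprocess import EfretRecord

_LN2PI = np.log(2.0 * np.pi)


@dataclass
class PackedRecords:
    """Records padded to a common length for batched inference."""

    X: np.ndarray  # (N, T) values, 0.0 in padding
    OBS: np.ndarray  # (N, T) True where an emission term applies
    L: np.ndarray  # (N,) record lengths in frames
    record_ids: list[str]
    frame_interval: float
    t0: np.ndarray  # (N,) absolute time of frame 0


def pack_records(records: list[EfretRecord]) -> PackedRecords:
    if not records:
        raise ValueError("no records to pack")
    dts = {r.frame_interval for r in records}
    if len(dts) != 1:
        raise ValueError(f"records mix frame intervals: {sorted(dts)}")
    L = np.array([len(r) for r in records])
    T = int(L.max())
    N = len(records)
    X = np.zeros((N, T))
    OBS = np.zeros((N, T), dtype=bool)
    for i, r in enumerate(records):
        good = ~r.outlier_mask
        X[i, : L[i]][good] = r.efret[good]
        OBS[i, : L[i]] = good
    return PackedRecords(
        X=X,
        OBS=OBS,
        L=L,
        record_ids=[r.record_id for r in records],
        frame_interval=dts.pop(),
        t0=np.array([r.t0 for r in records]),
    )


@dataclass
class VBState:
    """Per-trace variational posteriors and sufficient statistics."""

    u_pi_hat: np.ndarray  # (N, K)
    u_A_hat: np.ndarray  # (N, K, K)
    m_hat: np.ndarray  # (N, K)
    beta_hat: np.ndarray  # (N, K)
    a_hat: np.ndarray  # (N, K)
    b_hat: np.ndarray  # (N, K)
    gamma: np.ndarray  # (N, T, K) responsibilities, zero beyond record end
    xi_sum: np.ndarray  # (N, K, K) expected transition counts
    Nk: np.ndarray  # (N, K) responsibility mass on observed frames
    Sx: np.ndarray  # (N, K) weighted sum of values
    Sx2: np.ndarray  # (N, K) weighted sum of squared values
    ln_z: np.ndarray  # (N,)
    elbo: np.ndarray  # (N,)
    elbo_history: list[np.ndarray]
    converged: np.ndarray  # (N,) bool
    n_iter: int


@dataclass
class TracePosterior:
    """Variational posterior for a single record."""

    record_id: str
    gamma: np.ndarray  # (T, K)
    xi_sum: np.ndarray  # (K, K)
    u_pi_hat: np.ndarray
    u_A_hat: np.ndarray
    m_hat: np.ndarray
    beta_hat: np.ndarray
    a_hat: np.ndarray
    b_hat: np.ndarray
    elbo: float
    elbo_history: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------
# expected-log parameterization
# ---------------------------------------------------------------------------

def dirichlet_eln(u: np.ndarray) -> np.ndarray:
    """E[ln p] under Dirichlet(u) along the last axis."""
    return digamma(u) - digamma(u.sum(axis=-1, keepdims=True))


def expected_log_emission(
    X: np.ndarray, OBS: np.ndarray, m: np.ndarray, beta: np.ndarray,
    a: np.ndarray, b: np.ndarray,
) -> np.ndarray:
    """E_q[ln N(x_t | mu_k, 1/lambda_k)], zero on masked/padded frames."""
    Elam = a / b
    Elnlam = digamma(a) - np.log(b)
    diff = X[:, :, None] - m[:, None, :]
    lnp = 0.5 * (
        Elnlam[:, None, :] - _LN2PI - 1.0 / beta[:, None, :]
        - Elam[:, None, :] * diff ** 2
    )
    return np.where(OBS[:, :, None], lnp, 0.0)


def forward_backward_batch(
    ln_e: np.ndarray, ElnPi: np.ndarray, ElnA: np.ndarray, L: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward under the tilde parameterization.

    Frames beyond each record's length evolve under identity transitions
    and unit emissions, so they contribute nothing to any statistic.

    Returns (gamma, xi_sum, ln_z).
    """
    N, T, K = ln_e.shape
    Atil = np.exp(ElnA)
    pitil = np.exp(ElnPi)

    mx = ln_e.max(axis=2)
    e = np.exp(ln_e - mx[:, :, None])

    alpha = np.empty((N, T, K))
    c = np.ones((N, T))
    a0 = pitil * e[:, 0]
    c[:, 0] = a0.sum(axis=1)
    alpha[:, 0] = a0 / c[:, 0, None]
    for t in range(1, T):
        live = (t <= L - 1)[:, None]
        pred = np.einsum("nj,njk->nk", alpha[:, t - 1], Atil)
        pred = np.where(live, pred, alpha[:, t - 1])
        at = pred * e[:, t]
        c[:, t] = at.sum(axis=1)
        alpha[:, t] = at / c[:, t, None]

    ln_z = (np.log(c) + mx).sum(axis=1)

    gamma = np.empty((N, T, K))
    xi_sum = np.zeros((N, K, K))
    beta_v = np.ones((N, K))
    gamma[:, T - 1] = alpha[:, T - 1] * beta_v
    for t in range(T - 2, -1, -1):
        live = t + 1 <= L - 1  # (N,)
        tmp = e[:, t + 1] * beta_v
        xi = (
            alpha[:, t][:, :, None] * Atil * tmp[:, None, :]
            / c[:, t + 1][:, None, None]
        )
        xi_sum += np.where(live[:, None, None], xi, 0.0)
        newbeta = np.einsum("njk,nk->nj", Atil, tmp) / c[:, t + 1][:, None]
        beta_v = np.where(live[:, None], newbeta, beta_v)
        gamma[:, t] = alpha[:, t] * beta_v

    in_rec = np.arange(T)[None, :] < L[:, None]
    gamma *= in_rec[:, :, None]
    return gamma, xi_sum, ln_z


# ---------------------------------------------------------------------------
# KL divergences (per trace, summed over states)
# ---------------------------------------------------------------------------

def _kl_dirichlet(u_hat: np.ndarray, u: np.ndarray) -> np.ndarray:
    """KL(Dir(u_hat) || Dir(u)) along the last axis."""
    s_hat = u_hat.sum(axis=-1)
    return (
        gammaln(s_hat)
        - gammaln(u_hat).sum(axis=-1)
        - gammaln(u.sum(axis=-1))
        + gammaln(u).sum(axis=-1)
        + ((u_hat - u) * (digamma(u_hat) - digamma(s_hat)[..., None])).sum(axis=-1)
    )


def _kl_normal_gamma(m_hat, beta_hat, a_hat, b_hat, m, beta, a, b) -> np.ndarray:
    """KL between normal-gamma posteriors/priors, summed over states."""
    Elam = a_hat / b_hat
    kl_normal = 0.5 * (
        np.log(beta_hat / beta) - 1.0 + beta / beta_hat
        + beta * Elam * (m_hat - m) ** 2
    )
    kl_gamma = (
        (a_hat - a) * digamma(a_hat)
        - gammaln(a_hat)
        + gammaln(a)
        + a * (np.log(b_hat) - np.log(b))
        + a_hat * (b - b_hat) / b_hat
    )
    return (kl_normal + kl_gamma).sum(axis=-1)


# ---------------------------------------------------------------------------
# VB iteration
# ---------------------------------------------------------------------------

def _suffstats(packed: PackedRecords, gamma: np.ndarray):
    gobs = gamma * packed.OBS[:, :, None]
    Nk = gobs.sum(axis=1)
    Sx = np.einsum("ntk,nt->nk", gobs, packed.X)
    Sx2 = np.einsum("ntk,nt->nk", gobs, packed.X ** 2)
    return Nk, Sx, Sx2


def _mstep(packed: PackedRecords, priors: HMMPriors, gamma, xi_sum):
    Nk, Sx, Sx2 = _suffstats(packed, gamma)
    safe = np.maximum(Nk, 1e-12)
    xbar = np.where(Nk > 1e-12, Sx / safe, priors.m[None, :])
    Sxx = np.maximum(Sx2 - Nk * xbar ** 2, 0.0)

    beta_hat = priors.beta + Nk
    m_hat = (priors.beta * priors.m + Sx) / beta_hat
    a_hat = priors.a + Nk / 2.0
    b_hat = priors.b + 0.5 * (
        Sxx + priors.beta * Nk * (xbar - priors.m) ** 2 / beta_hat
    )
    u_pi_hat = priors.u_pi[None, :] + gamma[:, 0]
    u_A_hat = priors.u_A[None, :, :] + xi_sum
    return u_pi_hat, u_A_hat, m_hat, beta_hat, a_hat, b_hat


def _init_gamma_soft(
    packed: PackedRecords, priors: HMMPriors, rng: np.random.Generator | None,
    jitter: float = 0.0, hard: bool = True,
) -> np.ndarray:
    """Soft responsibilities from distance to prior means.

    States with (near-)equal prior means are disambiguated per record:
    records that ever visit the vicinity of the highest-mean state prefer
    the first member of the degenerate group, others the last — a
    deterministic symmetry break refined by the transition structure during
    fitting.
    """
    X, OBS, L = packed.X, packed.OBS, packed.L
    N, T = X.shape
    K = priors.n_states
    scale = 0.1
    lp = -0.5 * ((X[:, :, None] - priors.m[None, None, :]) / scale) ** 2
    g = np.exp(lp - lp.max(axis=2, keepdims=True))

    order = np.argsort(priors.m)
    groups: list[list[int]] = []
    for k in order:
        if groups and abs(priors.m[k] - priors.m[groups[-1][-1]]) < 0.02:
            groups[-1].append(int(k))
        else:
            groups.append([int(k)])
    mid = 0.5 * (priors.m.min() + priors.m.max())
    high_mask = (X > mid) & OBS  # (N, T)
    ever_high = high_mask.any(axis=1)
    idx = np.arange(T)[None, :]
    first_high = np.where(ever_high, np.argmax(high_mask, axis=1), T)
    last_high = np.where(
        ever_high, T - 1 - np.argmax(high_mask[:, ::-1], axis=1), -1
    )
    for grp in groups:
        if len(grp) < 2:
            continue
        # transient-low before the first high entry -> first group member;
        # long-lived low (never-high records, frames after the last high
        # segment) -> last member.  Mid-record low gaps stay transient-like.
        boost = np.zeros((N, T, K))
        transient = ever_high[:, None] & (idx <= last_high[:, None])
        boost[:, :, grp[0]] = np.where(transient, 8.0, 0.0)
        boost[:, :, grp[-1]] = np.where(~transient, 8.0, 0.0)
        g = g * (1.0 + boost)
    if jitter > 0 and rng is not None:
        g = g * rng.dirichlet(np.full(K, 1.0), size=g.shape[:2]) ** jitter
    if hard:
        # one-hot assignments: soft initial responsibilities would seed
        # spurious cross-transition counts between equal-mean states
        one = np.zeros_like(g)
        top = np.argmax(g, axis=2)
        one[np.arange(N)[:, None], np.arange(T)[None, :], top] = 1.0
        g = one
    else:
        g = g / g.sum(axis=2, keepdims=True)
    in_rec = np.arange(T)[None, :] < L[:, None]
    return g * in_rec[:, :, None]


def _xi_from_gamma(gamma: np.ndarray, L: np.ndarray) -> np.ndarray:
    N, T, K = gamma.shape
    valid = np.arange(T - 1)[None, :] < (L - 1)[:, None]
    g0 = gamma[:, :-1] * valid[:, :, None]
    return np.einsum("ntj,ntk->njk", g0, gamma[:, 1:])


def seed_state(
    packed: PackedRecords, priors: HMMPriors, gamma: np.ndarray
) -> VBState:
    """VB state built directly from initial responsibilities (one M-step,
    no E-step) — used to prime empirical-Bayes pooling before the first
    forward-backward pass."""
    xi_sum = _xi_from_gamma(gamma, packed.L)
    params = _mstep(packed, priors, gamma, xi_sum)
    Nk, Sx, Sx2 = _suffstats(packed, gamma)
    n = len(packed.L)
    return VBState(
        u_pi_hat=params[0], u_A_hat=params[1], m_hat=params[2],
        beta_hat=params[3], a_hat=params[4], b_hat=params[5],
        gamma=gamma, xi_sum=xi_sum, Nk=Nk, Sx=Sx, Sx2=Sx2,
        ln_z=np.full(n, -np.inf), elbo=np.full(n, -np.inf),
        elbo_history=[], converged=np.zeros(n, dtype=bool), n_iter=0,
    )


def vb_iterate(
    packed: PackedRecords,
    priors: HMMPriors,
    gamma_init: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> VBState:
    """Run batched VB-EM to ELBO convergence for every record."""
    if gamma_init is None:
        gamma_init = _init_gamma_soft(packed, priors, rng)
    gamma = gamma_init
    xi_sum = _xi_from_gamma(gamma, packed.L)
    params = _mstep(packed, priors, gamma, xi_sum)

    elbo_prev = np.full(len(packed.L), -np.inf)
    history: list[np.ndarray] = []
    converged = np.zeros(len(packed.L), dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        u_pi_hat, u_A_hat, m_hat, beta_hat, a_hat, b_hat = params
        ln_e = expected_log_emission(packed.X, packed.OBS, m_hat, beta_hat, a_hat, b_hat)
        gamma, xi_sum, ln_z = forward_backward_batch(
            ln_e, dirichlet_eln(u_pi_hat), dirichlet_eln(u_A_hat), packed.L
        )
        elbo = (
            ln_z
            - _kl_dirichlet(u_pi_hat, priors.u_pi[None, :])
            - _kl_dirichlet(u_A_hat, priors.u_A[None, :, :]).sum(axis=-1)
            - _kl_normal_gamma(
                m_hat, beta_hat, a_hat, b_hat,
                priors.m, priors.beta, priors.a, priors.b,
            )
        )
        history.append(elbo.copy())
        rel = np.abs(elbo - elbo_prev) / np.maximum(np.abs(elbo), 1.0)
        converged = rel < tol
        elbo_prev = elbo
        params = _mstep(packed, priors, gamma, xi_sum)
        if converged.all():
            break

    u_pi_hat, u_A_hat, m_hat, beta_hat, a_hat, b_hat = params
    Nk, Sx, Sx2 = _suffstats(packed, gamma)
    return VBState(
        u_pi_hat=u_pi_hat,
        u_A_hat=u_A_hat,
        m_hat=m_hat,
        beta_hat=beta_hat,
        a_hat=a_hat,
        b_hat=b_hat,
        gamma=gamma,
        xi_sum=xi_sum,
        Nk=Nk,
        Sx=Sx,
        Sx2=Sx2,
        ln_z=ln_z,
        elbo=elbo_prev,
        elbo_history=history,
        converged=converged,
        n_iter=n_iter,
    )


def vb_fit_trace(
    record: EfretRecord,
    priors: HMMPriors,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> TracePosterior:
    """Variational Bayes fit of a single record under fixed priors."""
    if int((~record.outlier_mask).sum()) < 2:
        raise ValueError(f"record {record.record_id!r}: needs >= 2 unmasked frames")
    packed = pack_records([record])
    state = vb_iterate(packed, priors, max_iter=max_iter, tol=tol)
    return TracePosterior(
        record_id=record.record_id,
        gamma=state.gamma[0, : packed.L[0]],
        xi_sum=state.xi_sum[0],
        u_pi_hat=state.u_pi_hat[0],
        u_A_hat=state.u_A_hat[0],
        m_hat=state.m_hat[0],
        beta_hat=state.beta_hat[0],
        a_hat=state.a_hat[0],
        b_hat=state.b_hat[0],
        elbo=float(state.elbo[0]),
        elbo_history=np.array([h[0] for h in state.elbo_history]),
        converged=bool(state.converged[0]),
    )
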