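"""Prior hyperparameters for the variational HMM.

Emissions are normal-gamma per state (precision lambda_k ~ Gamma(a, b);
mean mu_k | lambda_k ~ N(m, 1/(beta * lambda))); transition rows and the
initial-state distribution carry Dirichlet pseudo-counts.  State E_FRET
means can be pinned by a large ``beta`` pseudo-count, which is how the
analysis constrains state positions to those of the independent mixture
fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class HMMPriors:
    """Shared (population-level) hyperparameters of the hierarchical HMM."""

    m: np.ndarray  # prior state means (E_FRET units)
    beta: np.ndarray  # mean-pinning pseudo-counts, > 0
    a: np.ndarray  # precision prior shape
    b: np.ndarray  # precision prior rate
    u_pi: np.ndarray  # initial-state Dirichlet counts
    u_A: np.ndarray  # transition-row Dirichlet counts (K, K)
    pin_emission: bool = True  # hold m, beta fixed during EB updates

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.u_pi = np.asarray(self.u_pi, dtype=float)
        self.u_A = np.asarray(self.u_A, dtype=float)
        K = len(self.m)
        if K < 2:
            raise ValueError("need K >= 2 states")
        for name in ("beta", "a", "b", "u_pi"):
            arr = getattr(self, name)
            if arr.shape != (K,):
                raise ValueError(f"{name} must have length K={K}")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be > 0")
        if self.u_A.shape != (K, K) or np.any(self.u_A <= 0):
            raise ValueError("u_A must be (K, K) with positive entries")

    @property
    def n_states(self) -> int:
        return len(self.m)

    def copy(self) -> "HMMPriors":
        return HMMPriors(
            m=self.m.copy(),
            beta=self.beta.copy(),
            a=self.a.copy(),
            b=self.b.copy(),
            u_pi=self.u_pi.copy(),
            u_A=self.u_A.copy(),
            pin_emission=self.pin_emission,
        )


#: documented defaults for hyperparameters the analysis does not pin
DEFAULT_PRECISION_SHAPE = 2.5
DEFAULT_PRECISION_RATE = 0.01  # E[lambda] = 250 -> emission SD ~ 0.06
DEFAULT_DIRICHLET_COUNT = 1.0


def make_priors(
    K: int = 3,
    mu: np.ndarray | None = None,
    beta: np.ndarray | float = 1.0,
    precision_shape: float = DEFAULT_PRECISION_SHAPE,
    precision_rate: float = DEFAULT_PRECISION_RATE,
    dirichlet_count: float = DEFAULT_DIRICHLET_COUNT,
    pin_emission: bool | None = None,
) -> HMMPriors:
    """Build priors with the remaining hyperparameters at defaults.

    If ``mu`` is omitted, state means spread uniformly over [0, 1] and the
    emission hyperparameters are left free for the EB updates; an explicit
    ``mu`` pins them (``pin_emission`` defaults to True in that case).
    """
    if mu is None:
        mu_arr = np.linspace(0.0, 1.0, K + 2)[1:-1]
        if pin_emission is None:
            pin_emission = False
    else:
        mu_arr = np.asarray(mu, dtype=float)
        if len(mu_arr) != K:
            raise ValueError(f"mu must have length K={K}")
        if pin_emission is None:
            pin_emission = True
    beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), (K,)).copy()
    if np.any(beta_arr <= 0):
        raise ValueError("beta must be > 0")
    return HMMPriors(
        m=mu_arr,
        beta=beta_arr,
        a=np.full(K, precision_shape),
        b=np.full(K, precision_rate),
        u_pi=np.full(K, dirichlet_count),
        u_A=np.full((K, K), dirichlet_count),
        pin_emission=pin_emission,
    )


def wt_priors() -> HMMPriors:
    """Three-state priors with means pinned at (0.06, 0.06, 0.57) and
    pseudo-counts (1000, 1000, 1000)."""
    return make_priors(K=3, mu=np.array([0.06, 0.06, 0.57]), beta=1000.0)


def mutant_priors() -> HMMPriors:
    """Three-state priors with means pinned at (0.08, 0.08, 0.47) and
    pseudo-counts (10000, 10000, 10000)."""
    return make_priors(K=3, mu=np.array([0.08, 0.08, 0.47]), beta=10000.0)
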