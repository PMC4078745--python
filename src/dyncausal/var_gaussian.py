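"""Linear Gaussian VAR(1) models and exact information-theoretic Granger measures.

The functional causal model used throughout is the order-1 vector
autoregression V_{i+1} = C·V_i + ε_i with independent Gaussian innovations.
For a stationary model every statistical quantity is determined by the lagged
autocovariance sequence Γ_k = Cov(V_t, V_{t-k}), with Γ_0 solving the
discrete Lyapunov equation Γ_0 = C Γ_0 Cᵀ + Σ and Γ_k = C Γ_{k-1} for k ≥ 1.

Observed signals are linear mixtures of the latent state (rows of a mixing
matrix W), optionally corrupted by independent additive Gaussian observation
noise and read every T-th time step.  Transfer entropy (the information
measure of Granger causality)

    T_{X→Y|Z} = I(Y_{i+1}; X^i | Y^i, Z^i)

and the instantaneous-causality measure

    T_{X·Y|Z} = I(X_{i+1}; Y_{i+1} | X^i, Y^i, Z^i)

are conditional mutual informations of jointly Gaussian vectors, hence exact
log-determinant expressions of the observed covariance sequence.  Pasts are
truncated at a finite lag depth L (default 20, with a convergence check
against depth 2L).  All measures are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .exceptions import InvalidArgumentError, NumericalError, StationarityError

#: Values below this are treated as exact zeros when deciding "T = 0".
NUMERICAL_ZERO = 1e-9

#: Default lag depth for the truncated pasts.
DEFAULT_LAG_DEPTH = 20

#: Stationarity margin on the spectral radius.
STATIONARITY_MARGIN = 1e-6

_LN2 = float(np.log(2.0))


def nats_to_bits(x: float) -> float:
    """Display conversion; all computations are carried out in nats."""
    return x / _LN2


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VARModel:
    """Order-1 linear Gaussian vector autoregression V_{i+1} = C·V_i + ε_i."""

    coefficients: np.ndarray
    innovation_cov: np.ndarray | None = None
    names: tuple[str, ...] | None = None

    def __post_init__(self):
        C = np.asarray(self.coefficients, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise InvalidArgumentError("coefficient matrix must be square")
        object.__setattr__(self, "coefficients", C)
        n = C.shape[0]
        S = self.innovation_cov
        S = np.eye(n) if S is None else np.asarray(S, dtype=float)
        if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-10):
            raise InvalidArgumentError("innovation covariance must be symmetric n×n")
        # Positive semi-definite is accepted: degenerate innovations arise in
        # companion-form state augmentations; observed joints must still be PD.
        if np.min(np.linalg.eigvalsh(S)) < -1e-10:
            raise InvalidArgumentError("innovation covariance must be positive semi-definite")
        object.__setattr__(self, "innovation_cov", S)
        names = self.names or tuple(f"V{i+1}" for i in range(n))
        if len(names) != n or len(set(names)) != n:
            raise InvalidArgumentError("names must be distinct and match the dimension")
        object.__setattr__(self, "names", tuple(names))

    @property
    def dimension(self) -> int:
        return self.coefficients.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coefficients))))

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidArgumentError(f"unknown process {name!r}") from None


@dataclass(frozen=True)
class ObservationMap:
    """Linear read-out of the latent state: mixing, additive noise, subsampling.

    Each observed signal is a row of ``weights`` applied to the latent state,
    plus independent Gaussian noise of the given variance, read every
    ``subsample``-th step.
    """

    weights: np.ndarray
    signal_names: tuple[str, ...] | None = None
    noise_variances: np.ndarray | None = None
    subsample: int = 1

    def __post_init__(self):
        W = np.atleast_2d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", W)
        m = W.shape[0]
        nv = self.noise_variances
        nv = np.zeros(m) if nv is None else np.asarray(nv, dtype=float)
        if nv.shape != (m,) or np.any(nv < 0):
            raise InvalidArgumentError("noise variances must be length-m and non-negative")
        object.__setattr__(self, "noise_variances", nv)
        if not (isinstance(self.subsample, int) and self.subsample >= 1):
            raise InvalidArgumentError("subsample factor must be a positive integer")
        names = self.signal_names or tuple(f"S{i+1}" for i in range(m))
        if len(names) != m or len(set(names)) != m:
            raise InvalidArgumentError("signal names must be distinct and match row count")
        object.__setattr__(self, "signal_names", tuple(names))

    @classmethod
    def identity(cls, names: tuple[str, ...]) -> "ObservationMap":
        return cls(weights=np.eye(len(names)), signal_names=tuple(names))

    @classmethod
    def selecting(cls, model: VARModel, names: tuple[str, ...]) -> "ObservationMap":
        """Observe a subset of the latent processes directly (others latent)."""
        W = np.zeros((len(names), model.dimension))
        for i, nm in enumerate(names):
            W[i, model.index(nm)] = 1.0
        return cls(weights=W, signal_names=tuple(names))

    def index(self, name: str) -> int:
        try:
            return self.signal_names.index(name)
        except ValueError:
            raise InvalidArgumentError(f"unknown signal {name!r}") from None


@dataclass(frozen=True)
class CovarianceSequence:
    """Lagged autocovariances Γ_0 … Γ_L with Γ_k = Cov(state_t, state_{t-k})."""

    gammas: np.ndarray  # (L+1, n, n)
    names: tuple[str, ...]

    @property
    def max_lag(self) -> int:
        return self.gammas.shape[0] - 1

    @property
    def dimension(self) -> int:
        return self.gammas.shape[1]

    def gamma(self, k: int) -> np.ndarray:
        """Γ_k for any integer k, using Γ_{−k} = Γ_kᵀ."""
        if abs(k) > self.max_lag:
            raise InvalidArgumentError(f"lag {k} exceeds available depth {self.max_lag}")
        return self.gammas[k] if k >= 0 else self.gammas[-k].T


@dataclass(frozen=True)
class GrangerResult:
    """A Granger/instantaneous-causality measure in nats at a given lag depth."""

    value: float
    lag_depth: int
    converged: bool

    def __post_init__(self):
        object.__setattr__(self, "value", max(float(self.value), 0.0))

    @property
    def bits(self) -> float:
        return nats_to_bits(self.value)

    def is_zero(self, threshold: float = NUMERICAL_ZERO) -> bool:
        return self.value <= threshold


# ---------------------------------------------------------------------------
# second-order analytics
# ---------------------------------------------------------------------------


def is_stationary(m: VARModel, margin: float = STATIONARITY_MARGIN) -> bool:
    """Stationary iff the spectral radius of C is below 1 − margin."""
    return m.spectral_radius < 1.0 - margin


def stationary_cov(m: VARModel, L: int) -> CovarianceSequence:
    """Autocovariance sequence Γ_0 … Γ_L of the stationary process.

    Γ_0 solves the discrete Lyapunov equation Γ_0 = C Γ_0 Cᵀ + Σ; higher lags
    follow from Γ_k = C Γ_{k−1}.
    """
    if not is_stationary(m):
        raise StationarityError(
            f"spectral radius {m.spectral_radius:.6f} ≥ {1 - STATIONARITY_MARGIN}"
        )
    if L < 0:
        raise InvalidArgumentError("lag depth must be non-negative")
    C = m.coefficients
    g0 = solve_discrete_lyapunov(C, m.innovation_cov)
    g0 = (g0 + g0.T) / 2.0
    gammas = np.empty((L + 1, m.dimension, m.dimension))
    gammas[0] = g0
    for k in range(1, L + 1):
        gammas[k] = C @ gammas[k - 1]
    return CovarianceSequence(gammas=gammas, names=m.names)


def observed_cov(cs: CovarianceSequence, o: ObservationMap, L: int) -> CovarianceSequence:
    """Covariance sequence of the observed signals up to observed lag L.

    Γ^obs_k = W Γ_{kT} Wᵀ, with the observation-noise variances added on the
    diagonal at lag 0 only (the noise is independent across time).
    """
    T = o.subsample
    if L * T > cs.max_lag:
        raise InvalidArgumentError(
            f"need latent lags up to {L * T}, only {cs.max_lag} available"
        )
    if o.weights.shape[1] != cs.dimension:
        raise InvalidArgumentError("mixing matrix width must match the latent dimension")
    W = o.weights
    out = np.empty((L + 1, W.shape[0], W.shape[0]))
    for k in range(L + 1):
        out[k] = W @ cs.gamma(k * T) @ W.T
    out[0] += np.diag(o.noise_variances)
    return CovarianceSequence(gammas=out, names=o.signal_names)


def joint_lag_cov(cs: CovarianceSequence, L: int | None = None) -> np.ndarray:
    """Covariance of the stacked vector (y_t, y_{t−1}, …, y_{t−L}).

    Block (i, j) is Cov(y_{t−i}, y_{t−j}) = Γ_{j−i}.  Flat index of signal s
    at lag l is l·m + s.
    """
    L = cs.max_lag if L is None else L
    m = cs.dimension
    J = np.empty(((L + 1) * m, (L + 1) * m))
    for i in range(L + 1):
        for j in range(L + 1):
            J[i * m : (i + 1) * m, j * m : (j + 1) * m] = cs.gamma(j - i)
    return J


def _logdet(S: np.ndarray, idx: list[int], max_condition: float) -> float:
    if not idx:
        return 0.0
    sub = S[np.ix_(idx, idx)]
    try:
        chol = np.linalg.cholesky(sub)
    except np.linalg.LinAlgError:
        raise NumericalError("covariance submatrix is not positive definite") from None
    d = np.diag(chol)
    if (d.max() / d.min()) ** 2 > max_condition:
        raise NumericalError("covariance submatrix is ill-conditioned")
    return 2.0 * float(np.sum(np.log(d)))


def gaussian_cmi(
    joint: np.ndarray,
    A: list[int],
    B: list[int],
    Cset: list[int] = (),
    max_condition: float = 1e14,
) -> float:
    """Conditional mutual information I(A; B | C) of a Gaussian vector, in nats.

    I = ½·ln( det Σ_{A∪C} · det Σ_{B∪C} / (det Σ_C · det Σ_{A∪B∪C}) ), with
    det Σ_∅ ≡ 1.  The result is clipped at 0 (it is non-negative up to
    round-off).
    """
    A, B, Cset = list(A), list(B), list(Cset)
    if set(A) & set(B) or (set(A) | set(B)) & set(Cset):
        raise InvalidArgumentError("index sets must be disjoint")
    val = 0.5 * (
        _logdet(joint, A + Cset, max_condition)
        + _logdet(joint, B + Cset, max_condition)
        - _logdet(joint, Cset, max_condition)
        - _logdet(joint, A + B + Cset, max_condition)
    )
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Granger measures
# ---------------------------------------------------------------------------


def _flat(o_names: tuple[str, ...], name: str, lag: int) -> int:
    return lag * len(o_names) + o_names.index(name)


def _measure(
    m: VARModel,
    o: ObservationMap,
    A_spec: list[tuple[str, int]],
    B_spec: list[tuple[str, int]],
    C_spec: list[tuple[str, int]],
    L: int,
) -> float:
    """Gaussian CMI between observed (signal, lag) sets; lag 0 is time i+1."""
    cs = stationary_cov(m, L * o.subsample)
    oc = observed_cov(cs, o, L)
    J = joint_lag_cov(oc)
    names = o.signal_names
    A = [_flat(names, s, l) for s, l in A_spec]
    B = [_flat(names, s, l) for s, l in B_spec]
    C = [_flat(names, s, l) for s, l in C_spec]
    return gaussian_cmi(J, A, B, C)


def _past(signals, L: int) -> list[tuple[str, int]]:
    return [(s, l) for s in signals for l in range(1, L + 1)]


def _resolve(m: VARModel, o: ObservationMap | None) -> ObservationMap:
    if o is None:
        return ObservationMap.identity(m.names)
    return o


def transfer_entropy(
    m: VARModel,
    o: ObservationMap | None,
    src: str,
    dst: str,
    cond: tuple[str, ...] = (),
    L: int = DEFAULT_LAG_DEPTH,
    check_convergence: bool = True,
) -> GrangerResult:
    """T_{src→dst|cond} = I(dst_{i+1}; src^i | dst^i, cond^i), in nats.

    Pasts are truncated at L lags of the observed signals.  When
    ``check_convergence`` is set, the value is recomputed at depth 2L and the
    ``converged`` flag reports |T(L) − T(2L)| < 10⁻⁸ nats.
    """
    o = _resolve(m, o)
    cond = tuple(cond)
    if src in cond or dst in cond or src == dst:
        raise InvalidArgumentError("src, dst and cond must be distinct")
    A = [(dst, 0)]

    def value_at(depth: int) -> float:
        return _measure(m, o, A, _past([src], depth), _past([dst, *cond], depth), depth)

    v = value_at(L)
    converged = abs(value_at(2 * L) - v) < 1e-8 if check_convergence else True
    return GrangerResult(value=v, lag_depth=L, converged=converged)


def instantaneous_causality(
    m: VARModel,
    o: ObservationMap | None,
    a: str,
    b: str,
    cond: tuple[str, ...] = (),
    L: int = DEFAULT_LAG_DEPTH,
    check_convergence: bool = True,
) -> GrangerResult:
    """T_{a·b|cond} = I(a_{i+1}; b_{i+1} | a^i, b^i, cond^i), in nats.

    Positive values that survive all observed conditioning sets diagnose
    latent common drivers: same-time dependence cannot be produced by the
    lagged ground-truth arrows themselves.
    """
    o = _resolve(m, o)
    cond = tuple(cond)
    if a in cond or b in cond or a == b:
        raise InvalidArgumentError("a, b and cond must be distinct")

    def value_at(depth: int) -> float:
        return _measure(m, o, [(a, 0)], [(b, 0)], _past([a, b, *cond], depth), depth)

    v = value_at(L)
    converged = abs(value_at(2 * L) - v) < 1e-8 if check_convergence else True
    return GrangerResult(value=v, lag_depth=L, converged=converged)


def simulate(
    m: VARModel,
    o: ObservationMap | None,
    steps: int,
    seed: int,
    burn_in: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the latent VAR and its observed read-out.

    Returns (latent, observed) DataFrames; ``burn_in`` initial steps are
    discarded so the retained trajectory samples the stationary distribution.
    Observed rows are taken every ``subsample``-th retained step.
    Reproducible for a fixed seed.
    """
    if not is_stationary(m):
        raise StationarityError("cannot simulate a non-stationary model")
    o = _resolve(m, o)
    rng = np.random.default_rng(seed)
    n = m.dimension
    C = m.coefficients
    # innovations drawn up front; PSD covariances handled via eigendecomposition
    evals, evecs = np.linalg.eigh(m.innovation_cov)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    total = burn_in + steps
    eps = rng.standard_normal((total, n)) @ root.T
    lat = np.empty((total, n))
    v = np.zeros(n)
    for t in range(total):
        v = C @ v + eps[t]
        lat[t] = v
    lat = lat[burn_in:]
    obs = lat[:: o.subsample] @ o.weights.T
    noisy = np.sqrt(o.noise_variances)
    if np.any(noisy > 0):
        obs = obs + rng.standard_normal(obs.shape) * noisy
    latent_df = pd.DataFrame(lat, columns=list(m.names))
    observed_df = pd.DataFrame(obs, columns=list(o.signal_names))
    return latent_df, observed_df
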