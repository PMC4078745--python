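"""Numerical studies of observation artifacts in Granger-causality analysis.

The central study concerns *spatial aggregation*: two areas, each composed of
two processes with unidirectional pairwise inter-areal coupling X_k → Y_k,
are observed only through weighted sums X* = m_x·X1 + (1−m_x)·X2 and
Y* = m_y·Y1 + (1−m_y)·Y2.  Although every underlying interaction points from
X to Y, the aggregated signals show positive transfer entropy in *both*
directions; the relative magnitude r = T_{Y→X} / T_{X→Y} of the inconsistent
reverse measure is mapped over the coupling-coefficient space.

A second family of systems has N processes per area, each area integrated by
a common driver (Z for the X's, W for the Y's), observed through per-area
averages ⟨X⟩, ⟨Y⟩.  Here the inter-areal measure T_{⟨X⟩→⟨Y⟩} depends
strongly on the *intra*-areal integration and on N, while the underlying
pairwise coupling is held fixed.

``observation_artifact_demos`` demonstrates the remaining observation artifacts that the
Gaussian machinery covers: measurement noise, time aggregation, and spatial
aggregation on a unidirectionally coupled pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedRatioError
from .graphs import ProcessGraph, unroll
from .separation import d_separated, d_separated_pruned
from .var_gaussian import (
    DEFAULT_LAG_DEPTH,
    NUMERICAL_ZERO,
    ObservationMap,
    VARModel,
    gaussian_cmi,
    is_stationary,
    joint_lag_cov,
    observed_cov,
    stationary_cov,
    transfer_entropy,
    instantaneous_causality,
)

#: Fixed entries of the two-area, two-processes-per-area coefficient matrix:
#: inter-areal couplings X1→Y1, X2→Y2 and the Y self-couplings.
FIXED_COUPLING = 0.8


# ---------------------------------------------------------------------------
# two-area system (two processes per area, weighted-sum observation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoAreaConfig:
    """Configuration of the 4-process two-area system.

    The coefficient matrix over (X1, X2, Y1, Y2) is

        [[c11, c12, 0,   0  ],
         [c21, c22, 0,   0  ],
         [0.8, 0,   0.8, 0  ],
         [0,   0.8, 0,   0.8]]

    with identity innovation covariance; the observed signals are
    X = m_x·X1 + (1−m_x)·X2 and Y = m_y·Y1 + (1−m_y)·Y2.
    """

    c11: float = 0.8
    c12: float = 0.0
    c21: float = 0.0
    c22: float = 0.2
    m_x: float = 0.3
    m_y: float = 0.7

    def __post_init__(self):
        if not (0.0 <= self.m_x <= 1.0 and 0.0 <= self.m_y <= 1.0):
            raise InvalidArgumentError("mixing weights must lie in [0, 1]")


def build_two_area(cfg: TwoAreaConfig) -> tuple[VARModel, ObservationMap]:
    """Build the two-area VAR(1) and its weighted-sum observation map."""
    f = FIXED_COUPLING
    C = np.array(
        [
            [cfg.c11, cfg.c12, 0.0, 0.0],
            [cfg.c21, cfg.c22, 0.0, 0.0],
            [f, 0.0, f, 0.0],
            [0.0, f, 0.0, f],
        ]
    )
    model = VARModel(C, names=("X1", "X2", "Y1", "Y2"))
    W = np.array(
        [
            [cfg.m_x, 1.0 - cfg.m_x, 0.0, 0.0],
            [0.0, 0.0, cfg.m_y, 1.0 - cfg.m_y],
        ]
    )
    obs = ObservationMap(W, signal_names=("X", "Y"))
    return model, obs


def two_area_process_graph(cfg: TwoAreaConfig) -> ProcessGraph:
    """Ground-truth process graph of the two-area system (zero couplings omitted)."""
    entries = {
        ("X1", "X1"): cfg.c11,
        ("X2", "X1"): cfg.c12,
        ("X1", "X2"): cfg.c21,
        ("X2", "X2"): cfg.c22,
        ("X1", "Y1"): FIXED_COUPLING,
        ("X2", "Y2"): FIXED_COUPLING,
        ("Y1", "Y1"): FIXED_COUPLING,
        ("Y2", "Y2"): FIXED_COUPLING,
    }
    edges = {(s, d, 1) for (s, d), v in entries.items() if v != 0.0}
    return ProcessGraph(
        nodes=frozenset({"X1", "X2", "Y1", "Y2"}), edges=frozenset(edges)
    )


def _te_pair(model: VARModel, obs: ObservationMap, L: int) -> tuple[float, float]:
    """(T_{X→Y}, T_{Y→X}) for a two-signal observation, sharing one joint."""
    cs = stationary_cov(model, L * obs.subsample)
    oc = observed_cov(cs, obs, L)
    J = joint_lag_cov(oc)
    names = oc.names
    ix, iy = 0, 1
    m = 2

    def flat(sig, lag):
        return lag * m + sig

    x_past = [flat(ix, l) for l in range(1, L + 1)]
    y_past = [flat(iy, l) for l in range(1, L + 1)]
    t_xy = gaussian_cmi(J, [flat(iy, 0)], x_past, y_past)
    t_yx = gaussian_cmi(J, [flat(ix, 0)], y_past, x_past)
    del names
    return t_xy, t_yx


def r_ratio(model: VARModel, obs: ObservationMap, L: int = DEFAULT_LAG_DEPTH) -> float:
    """Relative magnitude r = T_{Y→X} / T_{X→Y} of the inconsistent reverse measure.

    The true inter-areal coupling points from the X-area to the Y-area, so
    T_{X→Y} is the consistent measure and T_{Y→X} the inconsistent one.
    """
    t_xy, t_yx = _te_pair(model, obs, L)
    if t_xy <= NUMERICAL_ZERO:
        raise UndefinedRatioError(
            f"consistent-direction transfer entropy is at numerical zero ({t_xy:.3e})"
        )
    return t_yx / t_xy


@dataclass
class RGrid:
    """r values over a 2-D coefficient grid; NaN cells are non-stationary/undefined."""

    row_name: str
    col_name: str
    row_values: np.ndarray
    col_values: np.ndarray
    r: np.ndarray          # (len(row_values), len(col_values)); NaN where excluded
    excluded: np.ndarray   # bool mask, True where no r is recorded
    n_nonstationary: int = 0
    n_undefined: int = 0

    @property
    def recorded(self) -> np.ndarray:
        return self.r[~self.excluded]

    def to_frame(self):
        """DataFrame with the explicit string marker 'excluded' in masked cells."""
        import pandas as pd

        data = self.r.astype(object)
        data[self.excluded] = "excluded"
        return pd.DataFrame(
            data,
            index=pd.Index(self.row_values, name=self.row_name),
            columns=pd.Index(self.col_values, name=self.col_name),
        )


def default_grid_axis(step: float = 0.05) -> np.ndarray:
    return np.round(np.arange(-1.0, 1.0 + step / 2, step), 10)


def r_map(
    c12_values: np.ndarray | None = None,
    c21_values: np.ndarray | None = None,
    c11: float = 0.8,
    c22: float = 0.2,
    m_x: float = 0.3,
    m_y: float = 0.7,
    L: int = DEFAULT_LAG_DEPTH,
) -> RGrid:
    """Map r over the (c12, c21) coupling plane of the two-area system.

    Non-stationary cells (spectral radius ≥ 1 − margin) are excluded and
    marked, never encoded as a sentinel number.
    """
    c12_values = default_grid_axis() if c12_values is None else np.asarray(c12_values)
    c21_values = default_grid_axis() if c21_values is None else np.asarray(c21_values)
    r = np.full((len(c12_values), len(c21_values)), np.nan)
    excluded = np.ones_like(r, dtype=bool)
    n_nonstat = n_undef = 0
    for i, c12 in enumerate(c12_values):
        for j, c21 in enumerate(c21_values):
            cfg = TwoAreaConfig(c11=c11, c12=c12, c21=c21, c22=c22, m_x=m_x, m_y=m_y)
            model, obs = build_two_area(cfg)
            if not is_stationary(model):
                n_nonstat += 1
                continue
            try:
                r[i, j] = r_ratio(model, obs, L)
                excluded[i, j] = False
            except UndefinedRatioError:
                n_undef += 1
    return RGrid(
        row_name="c12",
        col_name="c21",
        row_values=c12_values,
        col_values=c21_values,
        r=r,
        excluded=excluded,
        n_nonstationary=n_nonstat,
        n_undefined=n_undef,
    )


@dataclass
class RHistogram:
    """Counts of grid cells per r bin, for each observation-weight combination."""

    bin_edges: np.ndarray
    counts: dict[tuple[float, float], np.ndarray]
    n_nonstationary: dict[tuple[float, float], int]
    n_undefined: dict[tuple[float, float], int]
    r_values: dict[tuple[float, float], np.ndarray]

    #: the weight combinations are stand-ins chosen by this package
    weights_are_standins: bool = True


#: Default weight combinations for the histogram study (the equal-weight pair
#: plus increasingly asymmetric ones); stand-ins flagged in output metadata.
DEFAULT_WEIGHT_COMBOS = ((0.5, 0.5), (0.3, 0.7), (0.7, 0.3), (0.1, 0.9))


def r_histogram(
    coeff_values: np.ndarray | None = None,
    weight_combos: tuple[tuple[float, float], ...] = DEFAULT_WEIGHT_COMBOS,
    L: int = DEFAULT_LAG_DEPTH,
    bin_edges: np.ndarray | None = None,
) -> RHistogram:
    """Histogram of r over the full (c11, c22, c12, c21) space per weight combo.

    Bins are log-spaced; values outside the edge range are clipped into the
    end bins.  Excluded (non-stationary) and undefined-ratio cells are
    counted separately.
    """
    coeff_values = (
        np.round(np.arange(-1.0, 1.0001, 0.1), 10)
        if coeff_values is None
        else np.asarray(coeff_values)
    )
    bin_edges = np.logspace(-8, 2, 51) if bin_edges is None else np.asarray(bin_edges)
    counts: dict = {}
    nonstat: dict = {}
    undef: dict = {}
    rvals: dict = {}
    for m_x, m_y in weight_combos:
        rs = []
        ns = ud = 0
        for c11 in coeff_values:
            for c22 in coeff_values:
                for c12 in coeff_values:
                    for c21 in coeff_values:
                        cfg = TwoAreaConfig(c11=c11, c12=c12, c21=c21, c22=c22, m_x=m_x, m_y=m_y)
                        model, obs = build_two_area(cfg)
                        if not is_stationary(model):
                            ns += 1
                            continue
                        try:
                            rs.append(r_ratio(model, obs, L))
                        except UndefinedRatioError:
                            ud += 1
        rs = np.asarray(rs)
        clipped = np.clip(rs, bin_edges[0], np.nextafter(bin_edges[-1], 0))
        counts[(m_x, m_y)], _ = np.histogram(clipped, bins=bin_edges)
        nonstat[(m_x, m_y)] = ns
        undef[(m_x, m_y)] = ud
        rvals[(m_x, m_y)] = rs
    return RHistogram(
        bin_edges=bin_edges,
        counts=counts,
        n_nonstationary=nonstat,
        n_undefined=undef,
        r_values=rvals,
    )


# ---------------------------------------------------------------------------
# N-processes-per-area system (common intra-areal drivers, averaged read-out)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntegratedAreasConfig:
    """Two areas of N processes each, integrated by common drivers Z and W.

    Every X_k receives Z with weight c_xz, every Y_k receives W with weight
    c_yw and its partner X_k with weight c_yx; the observed signals are the
    per-area averages ⟨X⟩ and ⟨Y⟩.  Identity innovation covariance.
    """

    N: int = 1
    c_xx: float = 0.8
    c_xz: float = 0.5
    c_zz: float = 0.8
    c_yx: float = 0.8
    c_yy: float = 0.8
    c_yw: float = 0.8
    c_ww: float = 0.8

    def __post_init__(self):
        if not (isinstance(self.N, int) and self.N >= 1):
            raise InvalidArgumentError("N must be a positive integer")


def build_integrated_areas(cfg: IntegratedAreasConfig) -> tuple[VARModel, ObservationMap]:
    """Build the (2N+2)-dimensional VAR(1) with per-area average observation."""
    N = cfg.N
    names = tuple(f"X{k+1}" for k in range(N)) + ("Z",) + tuple(
        f"Y{k+1}" for k in range(N)
    ) + ("W",)
    n = 2 * N + 2
    C = np.zeros((n, n))
    iz, iw = N, 2 * N + 1
    for k in range(N):
        C[k, k] = cfg.c_xx
        C[k, iz] = cfg.c_xz
        iy = N + 1 + k
        C[iy, k] = cfg.c_yx
        C[iy, iy] = cfg.c_yy
        C[iy, iw] = cfg.c_yw
    C[iz, iz] = cfg.c_zz
    C[iw, iw] = cfg.c_ww
    model = VARModel(C, names=names)
    W = np.zeros((2, n))
    W[0, :N] = 1.0 / N
    W[1, N + 1 : 2 * N + 1] = 1.0 / N
    obs = ObservationMap(W, signal_names=("<X>", "<Y>"))
    return model, obs


def pairwise_latent_te(cfg: IntegratedAreasConfig, L: int = DEFAULT_LAG_DEPTH) -> float:
    """Microscopic-level T_{X1→Y1 | rest}: the pairwise coupling measure.

    Conditioning on the pasts of all other underlying processes isolates the
    direct X1 → Y1 link; the result depends only on the pair's own
    coefficients and is therefore identical in every (c_yw, N) cell.
    """
    model, _ = build_integrated_areas(cfg)
    cond = tuple(n for n in model.names if n not in ("X1", "Y1"))
    return transfer_entropy(
        model, None, "X1", "Y1", cond, L=L, check_convergence=False
    ).value


@dataclass
class TeVsIntegration:
    """T_{⟨X⟩→⟨Y⟩} over the (c_yw, N) panel, with the fixed pairwise reference."""

    c_yw_values: np.ndarray
    N_values: tuple[int, ...]
    te: np.ndarray              # (len(N_values), len(c_yw_values))
    pairwise: np.ndarray        # same shape: latent-level T_{X1→Y1} per cell
    c_xz: float


def te_vs_integration(
    c_yw_values: np.ndarray | None = None,
    N_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    c_xz: float = 0.5,
    L: int = DEFAULT_LAG_DEPTH,
) -> TeVsIntegration:
    """Inter-areal transfer entropy as a function of intra-areal integration.

    T_{⟨X⟩→⟨Y⟩} increases with N when the X-area is the more integrated one
    (c_xz > c_yw) and decreases with N when the Y-area is (c_yw > c_xz),
    while the underlying pairwise coupling — and its latent-level transfer
    entropy — is identical in every cell.
    """
    c_yw_values = (
        np.round(np.linspace(0.0, 1.0, 11), 10)
        if c_yw_values is None
        else np.asarray(c_yw_values)
    )
    te = np.empty((len(N_values), len(c_yw_values)))
    pw = np.empty_like(te)
    for i, N in enumerate(N_values):
        for j, c_yw in enumerate(c_yw_values):
            cfg = IntegratedAreasConfig(N=N, c_xz=c_xz, c_yw=float(c_yw))
            model, obs = build_integrated_areas(cfg)
            te[i, j] = transfer_entropy(
                model, obs, "<X>", "<Y>", L=L, check_convergence=False
            ).value
            pw[i, j] = pairwise_latent_te(cfg, L)
    return TeVsIntegration(
        c_yw_values=c_yw_values, N_values=tuple(N_values), te=te, pairwise=pw, c_xz=c_xz
    )


@dataclass
class DeltaTPrime:
    """Relative change of the normalised inter-areal measure with N.

    T′(c_yx, N) = T(c_yx, N) / T(c_ref, N); ΔT′(c_yx, N) =
    (T′(c_yx, N) − T′(c_yx, 1)) / T′(c_yx, 1).
    """

    c_yx_values: np.ndarray
    N_values: tuple[int, ...]
    te: np.ndarray
    t_prime: np.ndarray
    delta: np.ndarray
    c_ref: float


def delta_t_prime(
    c_yx_values: np.ndarray | None = None,
    N_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    c_xz: float = 1.4,
    c_xx: float = 0.2,
    L: int = DEFAULT_LAG_DEPTH,
) -> DeltaTPrime:
    """How the dependence of T_{⟨X⟩→⟨Y⟩} on the true coupling varies with N."""
    c_yx_values = (
        np.round(np.arange(0.1, 1.4001, 0.1), 10)
        if c_yx_values is None
        else np.asarray(c_yx_values)
    )
    if 1 not in N_values:
        N_values = (1, *N_values)
    c_ref = float(c_yx_values[0])
    te = np.empty((len(N_values), len(c_yx_values)))
    for i, N in enumerate(N_values):
        for j, c_yx in enumerate(c_yx_values):
            cfg = IntegratedAreasConfig(N=N, c_xz=c_xz, c_xx=c_xx, c_yx=float(c_yx))
            model, obs = build_integrated_areas(cfg)
            te[i, j] = transfer_entropy(
                model, obs, "<X>", "<Y>", L=L, check_convergence=False
            ).value
    ref_col = te[:, [0]]
    if np.any(ref_col <= NUMERICAL_ZERO):
        raise UndefinedRatioError("reference transfer entropy is at numerical zero")
    t_prime = te / ref_col
    row1 = t_prime[[list(N_values).index(1)], :]
    delta = (t_prime - row1) / row1
    return DeltaTPrime(
        c_yx_values=c_yx_values,
        N_values=tuple(N_values),
        te=te,
        t_prime=t_prime,
        delta=delta,
        c_ref=c_ref,
    )


# ---------------------------------------------------------------------------
# observation-artifact demonstrations (measurement noise, time & spatial
# aggregation on a unidirectionally coupled pair)
# ---------------------------------------------------------------------------


def unidirectional_pair(coupling: float = 0.5, self_coupling: float = 0.8) -> VARModel:
    """Bivariate VAR(1) with Y driving X and no coupling from X to Y."""
    return VARModel(
        np.array([[self_coupling, coupling], [0.0, self_coupling]]), names=("X", "Y")
    )


def unidirectional_process_graph() -> ProcessGraph:
    return ProcessGraph(
        nodes=frozenset({"X", "Y"}),
        edges=frozenset({("X", "X", 1), ("Y", "Y", 1), ("Y", "X", 1)}),
    )


def subordinate_process_graph() -> ProcessGraph:
    """The unidirectional pair observed through subordinate signals X*, Y*.

    The subordinate signals are modelled as processes reading their source
    one step late (a pure delay does not change which Granger relations are
    zero); the interacting sources X, Y are latent.
    """
    return ProcessGraph(
        nodes=frozenset({"X", "Y", "X*", "Y*"}),
        edges=frozenset(
            {
                ("X", "X", 1),
                ("Y", "Y", 1),
                ("Y", "X", 1),
                ("X", "X*", 1),
                ("Y", "Y*", 1),
            }
        ),
        latent=frozenset({"X", "Y"}),
    )


def time_aggregate(
    model: VARModel,
    weights: np.ndarray,
    signal_names: tuple[str, ...],
    block: int,
) -> tuple[VARModel, ObservationMap]:
    """Observe block averages over ``block`` consecutive steps, every ``block`` steps.

    Implemented by companion-form state augmentation: the augmented state
    stacks (V_t, V_{t−1}, …, V_{t−block+1}) with degenerate innovations on
    the copied coordinates; the observation averages each signal across the
    stacked copies and subsamples by the block length.
    """
    if block < 1:
        raise InvalidArgumentError("block length must be >= 1")
    n = model.dimension
    W0 = np.atleast_2d(np.asarray(weights, dtype=float))
    Caug = np.zeros((n * block, n * block))
    Caug[:n, :n] = model.coefficients
    for b in range(1, block):
        Caug[b * n : (b + 1) * n, (b - 1) * n : b * n] = np.eye(n)
    Sig = np.zeros((n * block, n * block))
    Sig[:n, :n] = model.innovation_cov
    aug_names = tuple(
        f"{nm}[-{b}]" if b else nm for b in range(block) for nm in model.names
    )
    aug = VARModel(Caug, Sig, names=aug_names)
    Wagg = np.tile(W0 / block, (1, block))
    obs = ObservationMap(Wagg, signal_names=signal_names, subsample=block)
    return aug, obs


def observation_artifact_demos(L: int = DEFAULT_LAG_DEPTH) -> dict:
    """Demonstrate how subordinate observations create inconsistent positives.

    Ground truth is always the unidirectional pair with Y driving X, so the
    consistent measure is T_{Y→X} and any positive T_{X→Y} is inconsistent.
    Each scenario is verified twice: analytically (Gaussian transfer
    entropies) and graphically (d-separation on a causal structure modelling
    how the observed signals are obtained).
    """
    model = unidirectional_pair()
    window = 8
    i = window - 2  # query time: future at i+1, pasts at <= i
    micro = unroll(unidirectional_process_graph(), window)

    def past(proc, upto):
        return {(proc, t) for t in range(upto + 1)}

    report: dict = {}

    # baseline: perfect observation reproduces the ground truth relations
    fwd = transfer_entropy(model, None, "Y", "X", L=L)
    rev = transfer_entropy(model, None, "X", "Y", L=L)
    report["baseline"] = {
        "T_Y->X": fwd.value,
        "T_X->Y": rev.value,
        "graphical_forward_separated": d_separated_pruned(
            micro, {("X", i + 1)}, past("Y", i), past("X", i)
        ),
        "graphical_reverse_separated": d_separated_pruned(
            micro, {("Y", i + 1)}, past("X", i), past("Y", i)
        ),
    }

    # measurement noise on both signals
    noisy = ObservationMap(np.eye(2), signal_names=("X*", "Y*"), noise_variances=[0.5, 0.5])
    sub_micro = unroll(subordinate_process_graph(), window)
    report["measurement_noise"] = {
        "T_Y*->X*": transfer_entropy(model, noisy, "Y*", "X*", L=L).value,
        "T_X*->Y*": transfer_entropy(model, noisy, "X*", "Y*", L=L).value,
        "graphical_reverse_separated": d_separated_pruned(
            sub_micro, {("Y*", i + 1)}, past("X*", i), past("Y*", i)
        ),
    }

    # time aggregation (block averages read every 2nd step);
    # plain decimation is reported alongside: it leaves the subsampled driver
    # Markov, so the reverse measure stays at zero while instantaneous
    # causality becomes positive.
    agg_model, agg_obs = time_aggregate(
        model, np.eye(2), signal_names=("X*", "Y*"), block=2
    )
    decim = ObservationMap(np.eye(2), signal_names=("X*", "Y*"), subsample=2)

    def even_past(proc, upto):
        return {(proc, t) for t in range(0, upto + 1, 2)}

    report["time_aggregation"] = {
        "T_Y*->X*": transfer_entropy(agg_model, agg_obs, "Y*", "X*", L=L).value,
        "T_X*->Y*": transfer_entropy(agg_model, agg_obs, "X*", "Y*", L=L).value,
        "decimation_T_X*->Y*": transfer_entropy(model, decim, "X*", "Y*", L=L).value,
        "decimation_T_X*.Y*": instantaneous_causality(model, decim, "X*", "Y*", L=L).value,
        # next even observation of Y vs the even past of X given the even past of Y
        "decimation_graphical_reverse_separated": d_separated(
            micro, {("Y", 6)}, even_past("X", 4), even_past("Y", 4)
        ),
    }

    # spatial aggregation (two processes per area); the
    # underlying coupling here runs X_k → Y_k, so T_{Y→X} is the reverse
    cfg = TwoAreaConfig(c11=0.8, c12=0.4, c21=-0.4, c22=0.2)
    sp_model, sp_obs = build_two_area(cfg)
    t_xy, t_yx = _te_pair(sp_model, sp_obs, L)
    pair_obs = ObservationMap.selecting(sp_model, ("X1", "Y1"))
    report["spatial_aggregation"] = {
        "T_X->Y": t_xy,
        "T_Y->X": t_yx,
        "r": t_yx / t_xy,
        "pairwise_T_X1->Y1": transfer_entropy(sp_model, pair_obs, "X1", "Y1", L=L).value,
        "pairwise_T_Y1->X1": transfer_entropy(sp_model, pair_obs, "Y1", "X1", L=L).value,
    }
    return report
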