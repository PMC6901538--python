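"""Bayesian inference of F(z), D_perp(z), D_par(z) from transition counts.

The permeant's z-motion is modelled as Smoluchowski diffusion on a
periodic grid of z-bins: nearest-neighbor hopping rates

    R_{i±1,i} = (D_{i±1/2} / dz^2) exp(-beta (F_{i±1} - F_i) / 2)

(midpoint diffusion, detailed balance by construction, columns summing
to zero) whose propagator exp(tau R) predicts the probability of binned
transitions observed at lag tau. Free energy and log-diffusion profiles
are expanded in truncated cosine series periodic over the box height;
a Metropolis random walk over the basis coefficients with flat priors
inside wide bounds yields posterior profiles per lag, and a linear fit
of D(z; tau) against 1/tau extrapolates to infinite lag time.

Lateral (in-plane) diffusion enters through a Bessel-mode expansion of
the radial propagator with a reflecting wall at the radial cutoff R_max:
for each mode k (x_k the k-th zero of J1), the z-propagator matrix is
modified to R^(k) = R - diag(D_par(z) x_k^2 / R_max^2), and the joint
probability of ending in z-bin j with lateral displacement in radial
bin b is sum_k [exp(tau R^(k))]_{ji} w_k(b), with J0 end-weights w_k
integrated over the radial bin (the start treated as a point at dr=0).

Matrix exponentials use eigendecomposition of the generator symmetrized
by the similarity transform exp(±beta F/2), with a scaling-and-squaring
fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, expm
from scipy.special import j0, j1, jn_zeros

from .constants import beta as _beta
from .io import DiffusionProfiles, FreeEnergyProfile

__all__ = [
    "TransitionCounts",
    "BayesModel",
    "PosteriorSummary",
    "count_transitions",
    "build_rate_matrix",
    "propagator",
    "log_likelihood",
    "sample_posterior",
    "extrapolate_infinite_lag",
]

# BA settings: lag times used for the infinite-lag fit
DEFAULT_LAGS_PS: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)


@dataclass
class TransitionCounts:
    """Observed z-bin (and optionally radial) transitions at one lag.

    ``matrix[j, i]`` counts transitions from bin i to bin j over the lag;
    ``radial[b, j, i]`` additionally resolves the lateral displacement
    magnitude into ``n_radial`` uniform bins up to ``r_max`` (overflow
    accumulated in the last bin and tallied in ``n_overflow``).
    """

    lag: float
    z_edges: np.ndarray
    matrix: np.ndarray
    H: float
    temperature: float
    radial: np.ndarray | None = None
    r_max: float = 50.0
    n_overflow: int = 0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def count_transitions(trajs, n_bins: int, lags, r_max: float = 50.0,
                      n_radial: int = 100, radial: bool = True
                      ) -> list[TransitionCounts]:
    """Accumulate sliding-origin transition counts at each lag.

    Every saved frame serves as an origin; z is binned on the periodic
    grid over [-H/2, H/2) and the lateral displacement uses the
    per-axis minimum-image convention. Lags must be integer multiples of
    the save interval.
    """
    trajs = list(trajs)
    Lx, Ly, H = trajs[0].box
    T = trajs[0].temperature
    edges = np.linspace(-H / 2, H / 2, n_bins + 1)
    dr_edges = np.linspace(0, r_max, n_radial + 1)
    out = []
    for lag in lags:
        dt = trajs[0].dt
        stride_f = lag / dt
        stride = int(round(stride_f))
        if stride < 1 or abs(stride_f - stride) > 1e-6:
            raise ValueError(f"lag {lag} ps is not a multiple of the save "
                             f"interval {dt} ps")
        N = np.zeros((n_bins, n_bins))
        Nr = np.zeros((n_radial, n_bins, n_bins)) if radial else None
        n_over = 0
        for tr in trajs:
            z = tr.z
            if len(z) <= stride:
                continue
            bins = np.clip(((z + H / 2) / H * n_bins).astype(int), 0, n_bins - 1)
            i_idx = bins[:-stride]
            j_idx = bins[stride:]
            np.add.at(N, (j_idx, i_idx), 1)
            if radial:
                dxy = tr.xyz[stride:, :2] - tr.xyz[:-stride, :2]
                dxy[:, 0] -= Lx * np.round(dxy[:, 0] / Lx)
                dxy[:, 1] -= Ly * np.round(dxy[:, 1] / Ly)
                dr = np.hypot(dxy[:, 0], dxy[:, 1])
                b = (dr / (r_max / n_radial)).astype(int)
                n_over += int(np.sum(b >= n_radial))
                b = np.clip(b, 0, n_radial - 1)
                np.add.at(Nr, (b, j_idx, i_idx), 1)
        if n_over:
            warnings.warn(f"lag {lag} ps: {n_over} lateral displacements "
                          f"beyond r_max={r_max} Å accumulated in the last "
                          "radial bin", stacklevel=2)
        out.append(TransitionCounts(lag=float(lag), z_edges=edges, matrix=N,
                                    H=H, temperature=T, radial=Nr,
                                    r_max=r_max, n_overflow=n_over))
    return out


def build_rate_matrix(F, d_perp, dz: float, temperature: float) -> np.ndarray:
    """Periodic nearest-neighbor Smoluchowski rate matrix.

    Satisfies detailed balance with respect to exp(-beta F) and conserves
    probability (columns sum to zero).
    """
    F = np.asarray(F, dtype=float)
    d_perp = np.asarray(d_perp, dtype=float)
    if np.any(d_perp <= 0):
        raise ValueError("diffusion must be positive")
    n = len(F)
    b = _beta(temperature)
    d_mid = 0.5 * (d_perp + np.roll(d_perp, -1))   # D at the i+1/2 edges
    up = d_mid / dz ** 2 * np.exp(-b * (np.roll(F, -1) - F) / 2)   # i -> i+1
    dn = d_mid / dz ** 2 * np.exp(-b * (F - np.roll(F, -1)) / 2)   # i+1 -> i
    R = np.zeros((n, n))
    idx = np.arange(n)
    R[(idx + 1) % n, idx] += up
    R[idx, (idx + 1) % n] += dn
    R[idx, idx] -= R.sum(axis=0)
    return R


def propagator(R: np.ndarray, F, tau: float, temperature: float,
               extra_diag=None) -> np.ndarray:
    """exp(tau (R - diag(extra_diag))) via the symmetrized eigenproblem.

    The similarity transform S = diag(exp(-beta F / 2)) renders the
    generator symmetric (extra diagonals do not break this), so a real
    eigendecomposition applies; falls back to scaling-and-squaring if it
    fails.
    """
    b = _beta(temperature)
    s = np.exp(-b * np.asarray(F, dtype=float) / 2)
    A = R if extra_diag is None else R - np.diag(extra_diag)
    Asym = (A * s[None, :]) / s[:, None]
    Asym = 0.5 * (Asym + Asym.T)          # enforce exact symmetry
    try:
        lam, U = eigh(Asym)
        T = (U * np.exp(tau * lam)) @ U.T
        return (T / s[None, :]) * s[:, None]
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return expm(tau * A)


@dataclass
class BayesModel:
    """Basis, grid, prior-bound and sampler settings for the inference.

    Defaults follow the standard analysis settings: 100 z-bins, 10
    cosine functions for F, 6 for each ln D profile, 50 Bessel modes
    with 100 radial bins up to 50 Å.
    """

    H: float
    temperature: float
    n_bins: int = 100
    n_f: int = 10
    n_logd: int = 6
    n_modes: int = 50
    r_max: float = 50.0
    f_bound: float | None = None        # |a_k| bound, kcal/mol (10 k_BT)
    logd_halfwidth: float = 4.0         # ln D window around the init
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_bound is None:
            self.f_bound = 10.0 / _beta(self.temperature)

    @property
    def z_centers(self) -> np.ndarray:
        edges = np.linspace(-self.H / 2, self.H / 2, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def n_params(self) -> int:
        return self.n_f + 2 * self.n_logd

    def split(self, theta):
        theta = np.asarray(theta, dtype=float)
        a = theta[:self.n_f]
        c1 = theta[self.n_f:self.n_f + self.n_logd]
        c2 = theta[self.n_f + self.n_logd:]
        return a, c1, c2

    def profiles_of(self, theta):
        """(F, D_perp, D_par) on the bin grid for a coefficient vector."""
        z = self.z_centers
        a, c1, c2 = self.split(theta)
        k_f = np.arange(1, self.n_f + 1)
        k_d = np.arange(self.n_logd)
        cos_f = np.cos(2 * np.pi * np.outer(k_f, z) / self.H)
        cos_d = np.cos(2 * np.pi * np.outer(k_d, z) / self.H)
        F = a @ cos_f
        return F, np.exp(c1 @ cos_d), np.exp(c2 @ cos_d)


def _radial_weights(model: BayesModel, n_radial: int) -> np.ndarray:
    """W[k, b]: probability that a point released at dr=0 lands in radial
    bin b under Bessel mode k, reflecting wall at r_max.

    Mode 0 (x_0 = 0) is the stationary uniform mode; for k >= 1,
    int J0(x r/R) r dr = (rR/x) J1(x r/R) gives the bin integrals.
    """
    R = model.r_max
    edges = np.linspace(0, R, n_radial + 1)
    x = np.concatenate([[0.0], jn_zeros(1, model.n_modes - 1)])
    W = np.empty((model.n_modes, n_radial))
    W[0] = (edges[1:] ** 2 - edges[:-1] ** 2) / R ** 2
    for k in range(1, model.n_modes):
        a = x[k] / R
        prim = edges * j1(a * edges) / a
        W[k] = (prim[1:] - prim[:-1]) / (R ** 2 / 2 * j0(x[k]) ** 2)
    return W


def log_likelihood(theta, counts: TransitionCounts, model: BayesModel,
                   mode: str = "z", _cache: dict | None = None) -> float:
    """Log-probability of the observed transitions given coefficients.

    ``mode="z"``: sum over N[j,i] ln [exp(tau R)]_{ji}. A strictly zero
    predicted probability with a nonzero count returns -inf.
    ``mode="radial"``: joint z/radial likelihood through the Bessel-mode
    expansion (truncation ringing is floored at a tiny probability).
    """
    if counts.n_bins != model.n_bins:
        raise ValueError("counts and model grids differ")
    F, d_perp, d_par = model.profiles_of(theta)
    dz = counts.z_edges[1] - counts.z_edges[0]
    R = build_rate_matrix(F, d_perp, dz, model.temperature)
    if mode == "z":
        T = propagator(R, F, counts.lag, model.temperature)
        N = counts.matrix
        nz = N > 0
        P = T[nz]
        # the spectral exponential carries an O(1e-16) cancellation noise
        # floor, so probabilities at/below it are numerically zero
        if np.any(P <= 1e-15):
            return -np.inf
        return float(np.sum(N[nz] * np.log(P)))
    if mode != "radial":
        raise ValueError(f"unknown likelihood mode {mode!r}")
    if counts.radial is None:
        raise ValueError("counts carry no radial histogram")
    n_radial = counts.radial.shape[0]
    if _cache is not None and "W" in _cache:
        W = _cache["W"]
    else:
        W = _radial_weights(model, n_radial)
        if _cache is not None:
            _cache["W"] = W
    x = np.concatenate([[0.0], jn_zeros(1, model.n_modes - 1)])
    Ts = np.empty((model.n_modes, model.n_bins, model.n_bins))
    for k in range(model.n_modes):
        extra = d_par * (x[k] / counts.r_max) ** 2
        Ts[k] = propagator(R, F, counts.lag, model.temperature, extra_diag=extra)
    P = np.einsum("kji,kb->bji", Ts, W)
    N = counts.radial
    nz = N > 0
    Pnz = np.clip(P[nz], 1e-12, None)   # Bessel-truncation ringing floor
    return float(np.sum(N[nz] * np.log(Pnz)))


@dataclass
class PosteriorSummary:
    """Per-lag posterior profile summaries on the bin grid."""

    z: np.ndarray
    lags: tuple[float, ...]
    f_mean: dict[float, np.ndarray]
    f_sd: dict[float, np.ndarray]
    d_perp_mean: dict[float, np.ndarray]
    d_perp_sd: dict[float, np.ndarray]
    d_par_mean: dict[float, np.ndarray]
    d_par_sd: dict[float, np.ndarray]
    acceptance: dict[float, float]
    seed: int
    mode: str

    def free_energy(self, temperature: float,
                    f_ref: float = 0.0) -> FreeEnergyProfile:
        """Lag-averaged posterior free-energy profile."""
        F = np.mean([self.f_mean[l] for l in self.lags], axis=0)
        sd = np.mean([self.f_sd[l] for l in self.lags], axis=0)
        return FreeEnergyProfile(z=self.z, values=F, f_ref=f_ref,
                                 temperature=temperature, stderr=sd,
                                 method=f"bayes-{self.mode}")


def _initial_theta(counts_list, model: BayesModel):
    """Histogram-F and constant-D (MSD) initialization."""
    c0 = counts_list[0]
    occ = np.sum([c.matrix.sum(axis=0) for c in counts_list], axis=0)
    occ = np.maximum(occ, 0.5)
    F0 = -np.log(occ / occ.sum()) / _beta(model.temperature)
    z = model.z_centers
    k_f = np.arange(1, model.n_f + 1)
    a0 = 2 * np.mean(F0[None, :] * np.cos(2 * np.pi * np.outer(k_f, z)
                                          / model.H), axis=1)
    # constant-D estimate from the mean-squared minimum-image bin displacement
    dz_bins = z[:, None] - z[None, :]
    dz_bins -= model.H * np.round(dz_bins / model.H)
    msd = 0.0
    wsum = 0.0
    for c in counts_list:
        m = np.sum(c.matrix * dz_bins ** 2)
        msd += m / c.lag
        wsum += c.matrix.sum()
    d0 = max(msd / (2 * wsum), 1e-4)
    theta = np.zeros(model.n_params)
    theta[:model.n_f] = np.clip(a0, -model.f_bound, model.f_bound)
    theta[model.n_f] = np.log(d0)
    theta[model.n_f + model.n_logd] = np.log(d0)
    return theta


def sample_posterior(counts_list, model: BayesModel, mode: str = "z",
                     n_burn: int = 400, n_sweeps: int = 400, thin: int = 2,
                     initial=None) -> PosteriorSummary:
    """Adaptive component-wise Metropolis over all basis coefficients.

    One independent run per lag (flat priors inside the model bounds;
    per-coefficient Gaussian proposals adapted during burn-in toward a
    25-50% acceptance window). Reproducible for a fixed model seed.

    Raises
    ------
    RuntimeError
        If the post-adaptation acceptance collapses below 1%.
    """
    counts_list = list(counts_list)
    if not counts_list:
        raise ValueError("need at least one lag")
    theta0 = (np.asarray(initial, dtype=float) if initial is not None
              else _initial_theta(counts_list, model))
    lo = np.empty(model.n_params)
    hi = np.empty(model.n_params)
    lo[:model.n_f] = -model.f_bound
    hi[:model.n_f] = model.f_bound
    for start in (model.n_f, model.n_f + model.n_logd):
        block = slice(start, start + model.n_logd)
        lo[block] = -model.logd_halfwidth
        hi[block] = model.logd_halfwidth
        # the k=0 ln D coefficient floats in a window around its MSD init
        lo[start] = theta0[start] - model.logd_halfwidth
        hi[start] = theta0[start] + model.logd_halfwidth
    theta0 = np.clip(theta0, lo, hi)

    z = model.z_centers
    out = PosteriorSummary(z=z, lags=tuple(c.lag for c in counts_list),
                           f_mean={}, f_sd={}, d_perp_mean={}, d_perp_sd={},
                           d_par_mean={}, d_par_sd={}, acceptance={},
                           seed=model.seed, mode=mode)
    for li, counts in enumerate(counts_list):
        rng = np.random.default_rng((model.seed + 7919 * li) % 2 ** 31)
        cache: dict = {}
        theta = theta0.copy()
        ll = log_likelihood(theta, counts, model, mode=mode, _cache=cache)
        if not np.isfinite(ll):
            raise RuntimeError(f"lag {counts.lag} ps: initialization has "
                               "zero likelihood")
        step = np.full(model.n_params, 0.05)
        acc_win = np.zeros(model.n_params)
        try_win = np.zeros(model.n_params)
        n_acc_post = 0
        n_try_post = 0
        samples = []
        for sweep in range(n_burn + n_sweeps):
            for p in range(model.n_params):
                prop = theta.copy()
                prop[p] += step[p] * rng.normal()
                try_win[p] += 1
                if sweep >= n_burn:
                    n_try_post += 1
                if prop[p] < lo[p] or prop[p] > hi[p]:
                    continue
                ll_new = log_likelihood(prop, counts, model, mode=mode,
                                        _cache=cache)
                if np.log(rng.uniform()) < ll_new - ll:
                    theta, ll = prop, ll_new
                    acc_win[p] += 1
                    if sweep >= n_burn:
                        n_acc_post += 1
            if sweep < n_burn and (sweep + 1) % 25 == 0:
                frac = acc_win / np.maximum(try_win, 1)
                step *= np.where(frac < 0.25, 0.6,
                                 np.where(frac > 0.5, 1.6, 1.0))
                acc_win[:] = 0
                try_win[:] = 0
            if sweep >= n_burn and (sweep - n_burn) % thin == 0:
                samples.append(theta.copy())
        acc_frac = n_acc_post / max(n_try_post, 1)
        if acc_frac < 0.01:
            raise RuntimeError(
                f"lag {counts.lag} ps: acceptance collapsed to "
                f"{acc_frac:.3%} after adaptation (steps {step})")
        profs = np.array([np.concatenate(model.profiles_of(s))
                          for s in samples])
        n = model.n_bins
        out.f_mean[counts.lag] = profs[:, :n].mean(axis=0)
        out.f_sd[counts.lag] = profs[:, :n].std(axis=0)
        out.d_perp_mean[counts.lag] = profs[:, n:2 * n].mean(axis=0)
        out.d_perp_sd[counts.lag] = profs[:, n:2 * n].std(axis=0)
        out.d_par_mean[counts.lag] = profs[:, 2 * n:].mean(axis=0)
        out.d_par_sd[counts.lag] = profs[:, 2 * n:].std(axis=0)
        out.acceptance[counts.lag] = acc_frac
    return out


def extrapolate_infinite_lag(summary: PosteriorSummary) -> DiffusionProfiles:
    """Per-bin linear fit of D(z; tau) against 1/tau; the intercept is the
    infinite-lag diffusion profile. Requires >= 2 lags; residuals of the
    fit are retained as per-bin uncertainty diagnostics."""
    lags = np.asarray(summary.lags, dtype=float)
    if len(lags) < 2:
        raise ValueError("need at least 2 lags to extrapolate")
    x = 1.0 / lags

    def fit(stack):
        Y = np.array(stack)             # (n_lags, n_bins)
        A = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        resid = Y - A @ coef
        return coef[1], np.sqrt(np.mean(resid ** 2, axis=0))

    dp, dp_res = fit([summary.d_perp_mean[l] for l in lags])
    dl, dl_res = fit([summary.d_par_mean[l] for l in lags])
    dp = np.maximum(dp, 1e-10)
    dl = np.maximum(dl, 1e-10)
    return DiffusionProfiles(z=summary.z, d_perp=dp, d_par=dl,
                             stderr_perp=dp_res, stderr_par=dl_res,
                             lags_ps=tuple(lags),
                             method=f"bayes-{summary.mode}-infinite-lag")
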