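"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* diffusive permeant trajectories from overdamped Langevin dynamics on a
  known free-energy profile F(z) and position-dependent diffusion tensor
  (D_perp(z), D_par(z)), periodic over the box height — the ground truth
  for every profile-recovery and permeability cross-check;
* a toy leaflet of vertical lipid-chain columns on a hexagonal lattice
  with an ordered-chain microdomain bounded by sterol/disordered channel
  sites, with known nearest-neighbor class labels per permeant;
* noisy EPR power-saturation curves from the homogeneous-saturation
  amplitude formula.

Profiles are parametrized by truncated cosine series periodic over H —
the same basis family the Bayesian analysis fits — with ln D rather than
D expanded so diffusion stays positive by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import beta as _beta
from .io import ChainFrame, PermeantTrajectory, wrap_z
from .oximetry import SaturationCurve, saturation_model

__all__ = [
    "ProfileSpec",
    "SyntheticRunSpec",
    "ToyMembraneSpec",
    "ToyMembraneData",
    "evaluate_profiles",
    "simulate_permeants",
    "generate_toy_membrane",
    "synthesize_saturation_curve",
    "oxygen_like_spec",
    "water_like_spec",
]


# ---------------------------------------------------------------------------
# cosine-series profiles


def _cos_series(z, coeffs, H, k0):
    """Sum_k c_k cos(2 pi (k0+k) z / H) for k = 0..len(coeffs)-1."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    for k, c in enumerate(coeffs, start=k0):
        out += c * np.cos(2 * np.pi * k * z / H)
    return out


def _cos_series_deriv(z, coeffs, H, k0):
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    for k, c in enumerate(coeffs, start=k0):
        w = 2 * np.pi * k / H
        out += -c * w * np.sin(w * z)
    return out


@dataclass
class ProfileSpec:
    """Ground-truth F(z), D_perp(z), D_par(z) as truncated cosine series.

    ``f_coeffs[k]`` multiplies cos(2 pi (k+1) z / H) in F (kcal/mol; the
    constant term is gauge and omitted). ``log_dperp_coeffs[k]`` and
    ``log_dpar_coeffs[k]`` multiply cos(2 pi k z / H) in ln(D / Å²·ps⁻¹),
    so the k=0 entry sets the overall diffusion scale and D > 0 always.
    """

    H: float
    f_coeffs: np.ndarray
    log_dperp_coeffs: np.ndarray
    log_dpar_coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.f_coeffs = np.atleast_1d(np.asarray(self.f_coeffs, dtype=float))
        self.log_dperp_coeffs = np.atleast_1d(
            np.asarray(self.log_dperp_coeffs, dtype=float))
        self.log_dpar_coeffs = np.atleast_1d(
            np.asarray(self.log_dpar_coeffs, dtype=float))

    # pointwise evaluations -------------------------------------------------
    def f(self, z):
        return _cos_series(z, self.f_coeffs, self.H, k0=1)

    def f_prime(self, z):
        return _cos_series_deriv(z, self.f_coeffs, self.H, k0=1)

    def d_perp(self, z):
        return np.exp(_cos_series(z, self.log_dperp_coeffs, self.H, k0=0))

    def d_perp_prime(self, z):
        return self.d_perp(z) * _cos_series_deriv(
            z, self.log_dperp_coeffs, self.H, k0=0)

    def d_par(self, z):
        return np.exp(_cos_series(z, self.log_dpar_coeffs, self.H, k0=0))

    @classmethod
    def from_shapes(cls, H, f_shape, d_perp_shape, d_par_shape,
                    n_f=10, n_logd=6, n_quad=4096) -> "ProfileSpec":
        """Project arbitrary even shape functions onto the cosine basis.

        ``f_shape(z)`` in kcal/mol, ``d_*_shape(z)`` in Å²/ps (positive);
        projection by trapezoid quadrature over one period.
        """
        z = np.linspace(-H / 2, H / 2, n_quad, endpoint=False)
        fv = np.asarray(f_shape(z), dtype=float)
        ldp = np.log(np.asarray(d_perp_shape(z), dtype=float))
        ldl = np.log(np.asarray(d_par_shape(z), dtype=float))

        def proj(vals, k):
            c = np.mean(vals * np.cos(2 * np.pi * k * z / H))
            return c if k == 0 else 2 * c

        return cls(
            H=H,
            f_coeffs=np.array([proj(fv, k) for k in range(1, n_f + 1)]),
            log_dperp_coeffs=np.array([proj(ldp, k) for k in range(n_logd)]),
            log_dpar_coeffs=np.array([proj(ldl, k) for k in range(n_logd)]),
        )


def evaluate_profiles(spec: ProfileSpec, grid, water_zone=None):
    """Exact basis evaluation of (F, D_perp, D_par) on ``grid``.

    When ``water_zone`` (an |z| interval) is given, F is returned relative
    to its mean over that zone, matching the F_ref convention of the
    estimators; otherwise relative to its raw gauge.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.abs(grid) > spec.H / 2 + 1e-9):
        raise ValueError("grid must lie within [-H/2, H/2]")
    F = spec.f(grid)
    if water_zone is not None:
        lo, hi = water_zone
        mask = (np.abs(grid) >= lo) & (np.abs(grid) <= hi)
        if not np.any(mask):
            raise ValueError("water zone contains no grid points")
        F = F - F[mask].mean()
    return F, spec.d_perp(grid), spec.d_par(grid)


def oxygen_like_spec(H: float = 70.0) -> ProfileSpec:
    """Default oxygen-like fixture: midplane well ~ -1.5 kcal/mol with
    weak head-group shoulders; diffusion faster in the greasy interior.

    A qualitative test fixture, not a claim about any particular lipid.
    """
    def f_shape(z):
        return (-1.5 * np.exp(-z ** 2 / (2 * 5.0 ** 2))
                + 0.4 * np.exp(-(np.abs(z) - 16.0) ** 2 / (2 * 3.0 ** 2)))

    def dperp_shape(z):
        return 0.20 * np.exp(np.log(2.2) * np.exp(-z ** 2 / (2 * 7.0 ** 2)))

    def dpar_shape(z):
        return 0.22 * np.exp(np.log(3.0) * np.exp(-z ** 2 / (2 * 8.0 ** 2)))

    return ProfileSpec.from_shapes(H, f_shape, dperp_shape, dpar_shape)


def water_like_spec(H: float = 70.0) -> ProfileSpec:
    """Default water-like fixture: ~6 kcal/mol central barrier with a
    shallow metastable dip at the midplane; diffusion mildly enhanced
    inside."""
    def f_shape(z):
        return (6.0 * np.exp(-z ** 2 / (2 * 8.0 ** 2))
                - 0.7 * np.exp(-z ** 2 / (2 * 2.5 ** 2)))

    def dperp_shape(z):
        return 0.23 * np.exp(np.log(1.8) * np.exp(-z ** 2 / (2 * 7.0 ** 2)))

    def dpar_shape(z):
        return 0.23 * np.exp(np.log(2.2) * np.exp(-z ** 2 / (2 * 8.0 ** 2)))

    return ProfileSpec.from_shapes(H, f_shape, dperp_shape, dpar_shape)


# ---------------------------------------------------------------------------
# Brownian-dynamics run


@dataclass
class SyntheticRunSpec:
    """Parameters of one synthetic Brownian-dynamics run.

    Defaults emulate the sampling situation of an all-atom permeation
    study: tens of permeants, a few hundred ns of total sampling, frames
    saved every ps at 298 K in a ~40x40x70 Å box.
    """

    profile: ProfileSpec
    n_permeants: int = 50
    t_total: float = 20000.0       # ps per permeant
    dt_step: float = 0.02          # integration step, ps
    save_every: float = 1.0        # save interval, ps
    seed: int = 0
    Lx: float = 40.0
    Ly: float = 40.0
    temperature: float = 298.0
    permeant_type: str = "oxygen-like"
    initial: str = "boltzmann"     # or "uniform", or "water"
    water_zone: tuple[float, float] | None = None  # |z| interval for "water"

    def __post_init__(self) -> None:
        if self.n_permeants < 1:
            raise ValueError("n_permeants >= 1 required")
        if self.save_every < self.dt_step:
            raise ValueError("save interval must be >= integration step")


@njit(cache=False)
def _em_kernel(z0, x0, y0, n_steps, save_stride, dt, H, Lx, Ly,
               fp_tab, dp_tab, dpp_tab, dl_tab, beta_val, seed):
    """Euler-Maruyama in the Ito convention with the D'(z) spurious drift.

    Lookup tables are sampled on a uniform periodic grid over [-H/2, H/2)
    and linearly interpolated. Diffusion for the lateral step is evaluated
    at the pre-step z (Ito evaluation point).
    """
    np.random.seed(seed)
    M = fp_tab.size
    n = z0.size
    n_save = n_steps // save_stride + 1
    out = np.empty((n, n_save, 3))
    for i in range(n):
        z = z0[i]
        x = x0[i]
        y = y0[i]
        out[i, 0, 0] = x
        out[i, 0, 1] = y
        out[i, 0, 2] = z
        ks = 1
        for s in range(1, n_steps + 1):
            u = (z / H + 0.5) * M
            j = int(np.floor(u))
            frac = u - j
            j = j % M
            j1 = (j + 1) % M
            fp = fp_tab[j] * (1.0 - frac) + fp_tab[j1] * frac
            dp = dp_tab[j] * (1.0 - frac) + dp_tab[j1] * frac
            dpp = dpp_tab[j] * (1.0 - frac) + dpp_tab[j1] * frac
            dl = dl_tab[j] * (1.0 - frac) + dl_tab[j1] * frac
            drift = -beta_val * dp * fp + dpp
            z = z + drift * dt + np.sqrt(2.0 * dp * dt) * np.random.normal()
            z = (z + 0.5 * H) % H - 0.5 * H
            sl = np.sqrt(2.0 * dl * dt)
            x = (x + sl * np.random.normal()) % Lx
            y = (y + sl * np.random.normal()) % Ly
            if s % save_stride == 0:
                out[i, ks, 0] = x
                out[i, ks, 1] = y
                out[i, ks, 2] = z
                ks += 1
    return out


def simulate_permeants(run: SyntheticRunSpec) -> list[PermeantTrajectory]:
    """Integrate the overdamped Ito SDE

        dz = [-beta D_perp(z) F'(z) + D_perp'(z)] dt + sqrt(2 D_perp(z)) dW

    with periodic wrap over H; x and y diffuse independently with
    sqrt(2 D_par(z)) dW. Returns one trajectory per permeant, frames at
    the save interval; bitwise reproducible for a fixed seed.
    """
    spec = run.profile
    H = spec.H
    bval = _beta(run.temperature)

    M = 4096
    zg = -H / 2 + np.arange(M) * (H / M)
    fp_tab = spec.f_prime(zg)
    dp_tab = spec.d_perp(zg)
    dpp_tab = spec.d_perp_prime(zg)
    dl_tab = spec.d_par(zg)
    if not np.all(np.isfinite(fp_tab)):
        raise ValueError("non-finite force on the profile grid")

    # step-size sanity: the rms step should resolve the finest basis feature
    k_max = max(len(spec.f_coeffs) + 1, len(spec.log_dperp_coeffs))
    feature = H / (2 * np.pi * max(k_max, 1))
    rms_step = np.sqrt(2 * dp_tab.max() * run.dt_step)
    if rms_step > 0.5 * feature:
        warnings.warn(
            f"integration step too coarse: rms displacement {rms_step:.2f} Å "
            f"vs finest profile feature {feature:.2f} Å", stacklevel=2)

    rng = np.random.default_rng(run.seed)
    if run.initial == "boltzmann":
        w = np.exp(-bval * spec.f(zg))
        z0 = rng.choice(zg, size=run.n_permeants, p=w / w.sum())
        z0 = z0 + rng.uniform(0, H / M, size=run.n_permeants)
    elif run.initial == "uniform":
        z0 = rng.uniform(-H / 2, H / 2, size=run.n_permeants)
    elif run.initial == "water":
        if run.water_zone is None:
            raise ValueError("initial='water' requires water_zone")
        lo, hi = run.water_zone
        z0 = rng.uniform(lo, hi, size=run.n_permeants)
        z0 *= rng.choice([-1.0, 1.0], size=run.n_permeants)
    else:
        raise ValueError(f"unknown initial mode {run.initial!r}")
    z0 = wrap_z(z0, H)
    x0 = rng.uniform(0, run.Lx, size=run.n_permeants)
    y0 = rng.uniform(0, run.Ly, size=run.n_permeants)

    save_stride = int(round(run.save_every / run.dt_step))
    n_steps = int(round(run.t_total / run.dt_step))
    n_steps = (n_steps // save_stride) * save_stride

    out = _em_kernel(z0, x0, y0, n_steps, save_stride, run.dt_step,
                     H, run.Lx, run.Ly, fp_tab, dp_tab, dpp_tab, dl_tab,
                     bval, int(run.seed) % 2 ** 31)
    times = np.arange(out.shape[1]) * (save_stride * run.dt_step)
    trajs = []
    for i in range(run.n_permeants):
        trajs.append(PermeantTrajectory(
            permeant_id=f"p{i:04d}",
            permeant_type=run.permeant_type,
            times=times.copy(),
            xyz=out[i],
            box=(run.Lx, run.Ly, H),
            temperature=run.temperature,
        ))
    return trajs


# ---------------------------------------------------------------------------
# toy microdomain membrane


@dataclass
class ToyMembraneSpec:
    """Idealized leaflet: vertical chain columns on a hexagonal lattice.

    Sites within ``domain_radius`` of a domain center carry ordered
    saturated chains (``sat``); sites within ``channel_width`` beyond the
    domain edge form the boundary channel and alternate between sterol
    and disordered (``unsat``) chains; remaining sites are ``unsat``.
    Chains are vertical columns of ``n_carbons`` carbons spanning
    ``z_span`` (upper leaflet); the mirrored lower leaflet is laterally
    shifted by ``leaflet_offset``.
    """

    lattice_constant: float = 4.8
    nx: int = 10
    ny: int = 10
    domain_centers: tuple[tuple[float, float], ...] | None = None
    domain_radius: float = 10.0
    channel_width: float = 5.0
    channel_types: tuple[str, str] = ("sterol", "unsat")
    n_carbons: int = 8
    z_span: tuple[float, float] = (2.0, 16.0)
    leaflet_offset: float = 0.0
    seed: int = 0

    @property
    def box(self) -> tuple[float, float]:
        a = self.lattice_constant
        return (self.nx * a, self.ny * a * np.sqrt(3) / 2)


@dataclass
class ToyMembraneData:
    """Toy-membrane output with per-permeant ground-truth class labels."""

    chain_frames: list[ChainFrame]
    permeants: list[PermeantTrajectory]
    truth_classes: list[str]
    site_xy: np.ndarray          # (n_sites, 2) upper-leaflet site positions
    site_types: list[str]


def _hex_sites(spec: ToyMembraneSpec):
    a = spec.lattice_constant
    Lx, Ly = spec.box
    xs, ys = [], []
    for j in range(spec.ny):
        for i in range(spec.nx):
            xs.append((i + 0.5 * (j % 2)) * a)
            ys.append(j * a * np.sqrt(3) / 2)
    return np.column_stack([np.mod(xs, Lx), np.mod(ys, Ly)])


def _lateral_minimage(dxy, Lx, Ly):
    dxy = np.asarray(dxy, dtype=float)
    dxy[..., 0] -= Lx * np.round(dxy[..., 0] / Lx)
    dxy[..., 1] -= Ly * np.round(dxy[..., 1] / Ly)
    return dxy


def classify_types(types) -> str:
    """Three-nearest-neighbor class: '3-<type>' if unanimous, else 'Mix'."""
    types = list(types)
    if len(set(types)) == 1:
        return f"3-{types[0]}"
    return "Mix"


def generate_toy_membrane(spec: ToyMembraneSpec, n_permeants: int = 200,
                          permeant_rule: str = "uniform",
                          temperature: float = 298.0) -> ToyMembraneData:
    """Build the toy leaflet pair and place point permeants with known
    ground-truth three-nearest-neighbor classes.

    ``permeant_rule`` is ``"uniform"`` (lateral positions uniform over the
    box) or ``"channel-biased"`` (positions jittered around channel
    sites, emulating permeation paths that avoid the ordered domain).
    Truth classes are computed geometrically from site positions and the
    carbon z-levels, independently of the pathway classifier.
    """
    rng = np.random.default_rng(spec.seed)
    Lx, Ly = spec.box
    sites = _hex_sites(spec)
    centers = spec.domain_centers
    if centers is None:
        centers = ((Lx / 2, Ly / 2),)
    centers = np.asarray(centers, dtype=float)

    # type assignment per site
    d_dom = np.full(len(sites), np.inf)
    for c in centers:
        d = np.linalg.norm(_lateral_minimage(sites - c, Lx, Ly), axis=1)
        d_dom = np.minimum(d_dom, d)
    site_types: list[str] = []
    alt = 0
    for d in d_dom:
        if d <= spec.domain_radius:
            site_types.append("sat")
        elif d <= spec.domain_radius + spec.channel_width:
            site_types.append(spec.channel_types[alt % len(spec.channel_types)])
            alt += 1
        else:
            site_types.append("unsat")

    channel_mask = np.array(
        [spec.domain_radius < d <= spec.domain_radius + spec.channel_width
         for d in d_dom])
    if permeant_rule == "channel-biased" and not channel_mask.any():
        raise ValueError("channel-biased rule requires at least one channel site")

    z_lo, z_hi = spec.z_span
    z_carbons = np.linspace(z_lo, z_hi, spec.n_carbons)

    # chains: upper leaflet at sites, mirrored lower leaflet shifted
    chains: dict[str, tuple[str, np.ndarray]] = {}
    for s, (xy, ltype) in enumerate(zip(sites, site_types)):
        up = np.column_stack([np.full_like(z_carbons, xy[0]),
                              np.full_like(z_carbons, xy[1]), z_carbons])
        chains[f"u{s:03d}"] = (ltype, up)
        lo_xy = np.mod(xy + spec.leaflet_offset, (Lx, Ly))
        lo = np.column_stack([np.full_like(z_carbons, lo_xy[0]),
                              np.full_like(z_carbons, lo_xy[1]), -z_carbons])
        chains[f"l{s:03d}"] = (ltype, lo)
    H = 2 * (z_hi + 4.0)  # water margin above the chains
    frame = ChainFrame(frame=0, chains=chains, box=(Lx, Ly, H))

    # permeant placement
    if permeant_rule == "uniform":
        xy_p = rng.uniform([0, 0], [Lx, Ly], size=(n_permeants, 2))
    elif permeant_rule == "channel-biased":
        idx = rng.choice(np.where(channel_mask)[0], size=n_permeants)
        jit = rng.normal(0, spec.lattice_constant / 4, size=(n_permeants, 2))
        xy_p = np.mod(sites[idx] + jit, (Lx, Ly))
    else:
        raise ValueError(f"unknown permeant rule {permeant_rule!r}")
    z_p = rng.uniform(z_lo, z_hi, size=n_permeants)

    # independent geometric ground truth: distance to a vertical column is
    # sqrt(lateral^2 + min_k |z - z_k|^2) over the carbon z-levels
    all_xy = np.concatenate([sites, np.mod(sites + spec.leaflet_offset, (Lx, Ly))])
    all_z_sets = [z_carbons] * len(sites) + [-z_carbons] * len(sites)
    all_types = site_types + site_types
    truth = []
    permeants = []
    for i in range(n_permeants):
        dxy = _lateral_minimage(all_xy - xy_p[i], Lx, Ly)
        dlat2 = np.sum(dxy ** 2, axis=1)
        dz2 = np.array([np.min((z_p[i] - zs) ** 2) for zs in all_z_sets])
        dist = np.sqrt(dlat2 + dz2)
        order = np.argsort(dist, kind="stable")[:3]
        truth.append(classify_types([all_types[k] for k in order]))
        permeants.append(PermeantTrajectory(
            permeant_id=f"tp{i:04d}", permeant_type="probe",
            times=np.array([0.0]),
            xyz=np.array([[xy_p[i, 0], xy_p[i, 1], z_p[i]]]),
            box=(Lx, Ly, H), temperature=temperature,
        ))
    return ToyMembraneData(
        chain_frames=[frame], permeants=permeants, truth_classes=truth,
        site_xy=sites, site_types=site_types,
    )


# ---------------------------------------------------------------------------
# EPR saturation curves


def synthesize_saturation_curve(i0: float, p_half: float, powers,
                                noise_frac: float = 0.0, seed: int = 0,
                                label: str = "") -> SaturationCurve:
    """Noisy power-saturation curve from the homogeneous-saturation model.

    Amplitudes follow I = I0 sqrt(P) / (1 + (2^{2/3}-1) P/P_{1/2})^{3/2}
    multiplied by (1 + Gaussian noise of sd ``noise_frac``).
    """
    if i0 <= 0 or p_half <= 0:
        raise ValueError("I0 and P1/2 must be positive")
    powers = np.asarray(powers, dtype=float)
    if np.any(powers <= 0):
        raise ValueError("powers must be positive")
    amp = saturation_model(powers, i0, p_half)
    if noise_frac:
        rng = np.random.default_rng(seed)
        amp = amp * (1 + rng.normal(0, noise_frac, size=amp.shape))
    return SaturationCurve(power_mw=powers, amplitude=amp, label=label)
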