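"""Spin-label oximetry surrogate and power-saturation fitting.

Simulation side: the oxygen population n_O2(r) near a probe carbon —
the coordination number obtained by integrating the probe–oxygen radial
distribution function g(r) — normalized by the water-phase oxygen
concentration c_w, and the between-phase ratio

    I(r) = [n_O2(r)/c_w]_Ld / [n_O2(r)/c_w]_Lo,

the surrogate for the experimental relaxation-enhancement ratio.

Experiment side: nonlinear least-squares fit of power-saturation curves

    I = I0 sqrt(P) / (1 + (2^{2/3}-1) P/P_1/2)^{3/2},

where P is microwave power (mW) and P_1/2 is the power at which the
first-derivative amplitude falls to half its unsaturated extrapolation.
P_1/2 is proportional to R1*R2; dividing by the linewidth (prop. to R2)
isolates a parameter proportional to R1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CoordinationCurve",
    "SaturationCurve",
    "SaturationFit",
    "saturation_model",
    "coordination_curve",
    "oxygen_ratio",
    "fit_saturation",
    "relaxation_ratio_report",
]

_SAT_C = 2 ** (2.0 / 3.0) - 1.0


def saturation_model(power, i0, p_half):
    """Peak-to-peak amplitude of the first-derivative resonance under
    homogeneous saturation."""
    power = np.asarray(power, dtype=float)
    return i0 * np.sqrt(power) / (1.0 + _SAT_C * power / p_half) ** 1.5


@dataclass
class CoordinationCurve:
    """Probe–oxygen coordination as a function of contact radius.

    ``n_o2`` counts oxygen atoms within r of the probe, averaged over
    frames and probes; ``g`` is the radial distribution function on the
    shell midpoints between grid radii.
    """

    r: np.ndarray
    n_o2: np.ndarray
    g: np.ndarray
    c_w: float | None = None      # water-phase concentration, count/Å^3

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.n_o2 = np.asarray(self.n_o2, dtype=float)
        if np.any(np.diff(self.n_o2) < -1e-9):
            raise ValueError("n_O2(r) must be non-decreasing")

    def normalized(self) -> np.ndarray:
        """n_O2(r)/c_w (Å^3)."""
        if self.c_w is None or self.c_w <= 0:
            raise ValueError("c_w not set or non-positive")
        return self.n_o2 / self.c_w

    def at(self, radius: float) -> float:
        """n_O2 at a radius (linear interpolation on the grid)."""
        return float(np.interp(radius, self.r, self.n_o2))


@dataclass
class SaturationCurve:
    """(microwave power, peak-to-peak amplitude) pairs for one condition."""

    power_mw: np.ndarray
    amplitude: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.power_mw = np.asarray(self.power_mw, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(self.power_mw <= 0):
            raise ValueError("powers must be positive")
        if len(self.power_mw) != len(self.amplitude):
            raise ValueError("power/amplitude length mismatch")


@dataclass
class SaturationFit:
    """Fitted saturation parameters with covariance-based errors."""

    i0: float
    p_half: float
    i0_err: float
    p_half_err: float
    residuals: np.ndarray
    label: str = ""

    def r1_parameter(self, linewidth: float) -> float:
        """P1/2 / linewidth — proportional to R1 alone."""
        return self.p_half / linewidth


# ---------------------------------------------------------------------------
# coordination numbers


def _minimum_image(d, box):
    d = np.asarray(d, dtype=float)
    for k in range(3):
        d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    return d


def coordination_curve(probe_positions, oxygen_positions, box, radii,
                       count_molecules: bool = False,
                       atoms_per_molecule: int = 2) -> CoordinationCurve:
    """Time- and probe-averaged oxygen coordination numbers.

    Parameters
    ----------
    probe_positions : sequence of (n_probes, 3) arrays
        Probe (methyl-carbon surrogate) positions per frame, Å.
    oxygen_positions : sequence of (n_oxygens, 3) arrays
        Oxygen atom positions per frame, Å (atoms, not molecules, unless
        ``count_molecules``).
    box : (Lx, Ly, H)
        Periodic box for the 3D minimum-image convention.
    radii : increasing radii grid, Å.
    count_molecules : bool
        Divide counts by ``atoms_per_molecule`` to report molecules
        (sensitivity mode; atom counting is the default convention).

    Returns the cumulative counts n_O2(r) and g(r) normalized by shell
    volume and the mean oxygen density in the full box.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    probe_frames = list(probe_positions)
    oxy_frames = list(oxygen_positions)
    if not probe_frames or len(probe_frames) != len(oxy_frames):
        raise ValueError("need matching, non-empty probe and oxygen frames")
    box = tuple(float(v) for v in box)
    r_ins = min(box) / 2.0
    if radii[-1] > r_ins:
        warnings.warn("radii extend beyond the inscribed sphere; shell "
                      "volumes are spherical approximations there",
                      stacklevel=2)

    edges = np.concatenate([[0.0], radii])
    hist = np.zeros(len(radii))
    n_pairs_norm = 0
    n_oxy_total = 0
    for P, O in zip(probe_frames, oxy_frames):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        O = np.atleast_2d(np.asarray(O, dtype=float))
        d = _minimum_image(P[:, None, :] - O[None, :, :], box)
        dist = np.sqrt(np.sum(d ** 2, axis=-1)).ravel()
        hist += np.histogram(dist, bins=edges)[0]
        n_pairs_norm += len(P)
        n_oxy_total += len(O)
    if n_pairs_norm == 0:
        raise ValueError("no probes in any frame")

    per_probe = hist / n_pairs_norm          # mean counts per shell per probe
    if count_molecules:
        per_probe = per_probe / atoms_per_molecule
    n_o2 = np.cumsum(per_probe)

    vol = box[0] * box[1] * box[2]
    rho = (n_oxy_total / len(oxy_frames)) / vol
    if count_molecules:
        rho = rho / atoms_per_molecule
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = per_probe / (shell_vol * rho)
    return CoordinationCurve(r=radii, n_o2=n_o2, g=g)


def oxygen_ratio(curve_d: CoordinationCurve, curve_o: CoordinationCurve,
                 radius: float = 4.5) -> float:
    """I(r): ratio of c_w-normalized oxygen populations (disordered over
    ordered phase) at the contact radius (default 4.5 Å)."""
    num = curve_d.at(radius) / curve_d.c_w
    den = curve_o.at(radius) / curve_o.c_w
    if den == 0:
        raise ZeroDivisionError("ordered-phase population is zero at this radius")
    return num / den


# ---------------------------------------------------------------------------
# power-saturation fitting


def fit_saturation(curve: SaturationCurve) -> SaturationFit:
    """Nonlinear least squares of the homogeneous-saturation amplitude model.

    Initial guesses come from the unsaturated low-power region, where
    I/sqrt(P) -> I0. Requires >= 4 distinct powers.
    """
    P = curve.power_mw
    I = curve.amplitude
    if len(np.unique(P)) < 4:
        raise ValueError("need at least 4 distinct powers to fit")
    order = np.argsort(P)
    P, I = P[order], I[order]
    n_low = max(2, len(P) // 4)
    i0_guess = float(np.mean(I[:n_low] / np.sqrt(P[:n_low])))
    # amplitude peaks near P1/2 / sqrt(2); use the argmax as a rough scale
    p_half_guess = float(max(P[np.argmax(I)], P[0] * 2))
    try:
        popt, pcov = curve_fit(
            saturation_model, P, I, p0=[i0_guess, p_half_guess],
            bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"saturation fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    resid = I - saturation_model(P, *popt)
    return SaturationFit(i0=float(popt[0]), p_half=float(popt[1]),
                         i0_err=float(perr[0]), p_half_err=float(perr[1]),
                         residuals=resid, label=curve.label)


def relaxation_ratio_report(fits_d: dict, fits_o: dict,
                            linewidths_d: dict, linewidths_o: dict,
                            inert: str = "N2", oxygenated: str = "O2") -> dict:
    """Relaxation-enhancement ratios between two phases.

    Each mapping is keyed by gas condition (``inert`` and ``oxygenated``):
    ``fits_*`` hold SaturationFit per condition, ``linewidths_*`` hold
    (value, stderr) peak-to-peak linewidths in G. Enhancements are
    differences oxygenated-minus-inert; the R2-proportional ratio comes
    from linewidth enhancements, the R1-proportional ratio from
    enhancements of P1/2/linewidth, and the report carries their average
    with errors propagated in quadrature.
    """
    for d, name in ((fits_d, "fits_d"), (fits_o, "fits_o"),
                    (linewidths_d, "linewidths_d"), (linewidths_o, "linewidths_o")):
        for cond in (inert, oxygenated):
            if cond not in d:
                raise KeyError(f"{name} missing condition {cond!r}")

    def lw(table, cond):
        v = table[cond]
        return (float(v[0]), float(v[1])) if np.ndim(v) else (float(v), 0.0)

    def enhancement(a, b):
        """a - b with errors in quadrature."""
        return a[0] - b[0], float(np.hypot(a[1], b[1]))

    def ratio(num, den):
        if den[0] == 0:  # no enhancement in the reference system
            return float("nan"), float("nan")
        r = num[0] / den[0]
        err = abs(r) * float(np.hypot(num[1] / num[0] if num[0] else 0.0,
                                      den[1] / den[0]))
        return r, err

    # R2-proportional: linewidth enhancement
    d_r2 = enhancement(lw(linewidths_d, oxygenated), lw(linewidths_d, inert))
    o_r2 = enhancement(lw(linewidths_o, oxygenated), lw(linewidths_o, inert))
    r2_ratio = ratio(d_r2, o_r2)

    # R1-proportional: enhancement of P1/2 / linewidth
    def r1_param(fits, lws, cond):
        f = fits[cond]
        w, werr = lw(lws, cond)
        v = f.p_half / w
        err = abs(v) * float(np.hypot(f.p_half_err / f.p_half, werr / w))
        return v, err

    d_r1 = enhancement(r1_param(fits_d, linewidths_d, oxygenated),
                       r1_param(fits_d, linewidths_d, inert))
    o_r1 = enhancement(r1_param(fits_o, linewidths_o, oxygenated),
                       r1_param(fits_o, linewidths_o, inert))
    r1_ratio = ratio(d_r1, o_r1)

    finite = [r for r in (r1_ratio, r2_ratio) if np.isfinite(r[0])]
    if finite:
        avg = float(np.mean([r[0] for r in finite]))
        avg_err = float(np.hypot(*[r[1] for r in finite]) / len(finite)
                        if len(finite) > 1 else finite[0][1])
    else:
        avg = avg_err = float("nan")
    return {
        "R2_ratio": r2_ratio[0], "R2_ratio_err": r2_ratio[1],
        "R1_ratio": r1_ratio[0], "R1_ratio_err": r1_ratio[1],
        "average": avg, "average_err": avg_err,
    }
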