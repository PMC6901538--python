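"""Free-energy profiles from occupancy, concentrations, and partitioning.

The potential of mean force is F(z) = -k_B T ln p(z) from the pooled
z-histogram (unsymmetrized), referenced to its mean over a water zone.
The water-phase concentration is

    c_w = (N/A) e^{-beta F_ref} / Int_{-H/2}^{H/2} e^{-beta F(z)} dz,

and the membrane/water partition coefficient for an assumed thickness h

    K(h) = (1/h) Int_{-h/2}^{h/2} e^{-beta (F(z)-F_ref)} dz.

K depends on the h convention, but the ratio of K between two systems
that differ only deep inside their membranes is nearly h-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PER_A3_TO_MOLAR, beta as _beta
from .io import FreeEnergyProfile, MembraneGeometry, PermeantTrajectory

__all__ = [
    "ConcentrationResult",
    "PartitionResult",
    "estimate_pmf",
    "water_concentration",
    "partition_coefficient",
    "partition_ratio",
    "boltzmann_integral",
]


@dataclass
class ConcentrationResult:
    """Permeant concentration with both unit renderings.

    ``per_A3`` is a number density (count/Å^3); ``molar`` the same value
    in mol/L. ``method`` records how it was obtained.
    """

    per_A3: float
    method: str

    @property
    def molar(self) -> float:
        return self.per_A3 * PER_A3_TO_MOLAR


@dataclass
class PartitionResult:
    h: float
    K: float

    def ratio(self, other: "PartitionResult") -> float:
        """K ratio between two systems, each at its own stated h."""
        return self.K / other.K


def estimate_pmf(trajs, n_bins: int, geometry: MembraneGeometry,
                 replicates=None) -> FreeEnergyProfile:
    """Potential of mean force from the pooled z-histogram.

    Parameters
    ----------
    trajs : sequence of PermeantTrajectory
        Centered trajectories sharing one box.
    n_bins : int
        Uniform bins spanning [-H/2, H/2]; >= 10 required.
    geometry : MembraneGeometry
        Supplies the water-reference zone for F_ref.
    replicates : sequence of trajectory groups, optional
        Independent groups; per-bin standard errors come from the spread
        of per-replicate profiles.

    Unvisited bins get an infinite-F sentinel (with a warning) and are
    excluded from the F_ref average. Profiles are not symmetrized.
    """
    trajs = list(trajs)
    if n_bins < 10:
        raise ValueError("n_bins >= 10 required")
    if not trajs or sum(t.n_frames for t in trajs) == 0:
        raise ValueError("no frames to histogram")
    H = trajs[0].box[2]
    T = trajs[0].temperature
    edges = np.linspace(-H / 2, H / 2, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def profile_of(group):
        zs = np.concatenate([t.z for t in group])
        counts = np.histogram(zs, bins=edges)[0]
        with np.errstate(divide="ignore"):
            F = -1.0 / _beta(T) * np.log(counts / counts.sum() / np.diff(edges))
        return counts, F

    counts, F = profile_of(trajs)
    if np.any(counts == 0):
        warnings.warn(f"{int((counts == 0).sum())} unvisited z-bins set to "
                      "infinite free energy", stacklevel=2)

    lo, hi = geometry.water_zone_for_box(H)
    ref_mask = (np.abs(centers) >= lo) & (np.abs(centers) <= hi) & np.isfinite(F)
    if not np.any(ref_mask):
        raise ValueError("no finite bins inside the water-reference zone")
    f_ref = float(F[ref_mask].mean())

    stderr = None
    if replicates is not None and len(replicates) >= 2:
        reps = np.array([profile_of(g)[1] for g in replicates])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            finite = np.isfinite(reps).all(axis=0)
            stderr = np.full(n_bins, np.nan)
            stderr[finite] = reps[:, finite].std(axis=0, ddof=1) / np.sqrt(len(reps))

    return FreeEnergyProfile(z=centers, values=F, f_ref=f_ref, temperature=T,
                             stderr=stderr, method="histogram")


def boltzmann_integral(profile: FreeEnergyProfile, z_lo: float, z_hi: float,
                       relative: bool = True) -> float:
    """Trapezoidal Int e^{-beta (F - F_ref)} dz over [z_lo, z_hi].

    The integrand is interpolated linearly to the exact bounds; sentinel
    (infinite-F) bins contribute zero weight but raise if the whole range
    is sentinel.
    """
    b = _beta(profile.temperature)
    F = profile.relative() if relative else profile.values
    w = np.exp(-b * F)               # inf -> 0 weight
    w = np.where(np.isfinite(w), w, 0.0)
    if not np.any(w > 0):
        raise ValueError("profile is all-sentinel")
    zq = np.concatenate([[z_lo], profile.z[(profile.z > z_lo) & (profile.z < z_hi)],
                         [z_hi]])
    wq = np.interp(zq, profile.z, w)
    return float(np.trapezoid(wq, zq))


def water_concentration(n_permeants: int, profile: FreeEnergyProfile,
                        area: float, trajs=None,
                        geometry: MembraneGeometry | None = None) -> dict:
    """Water-phase permeant concentration.

    Primary estimate (``boltzmann-integral``): c_w = (N/A) e^{-beta F_ref}
    / Int e^{-beta F} dz over the full box. When trajectories (and a
    geometry) are supplied, a ``far-zone-count`` estimate — the
    time-averaged permeant count in the water-reference zone divided by
    its volume — is returned alongside for cross-checking.

    Returns a dict of ConcentrationResult keyed by method tag.
    """
    H = profile.z[-1] - profile.z[0] + profile.dz
    # integral of exp(-beta(F - F_ref)) over the box; the exp(-beta F_ref)
    # prefactor of Eq. 4 cancels against referencing the integrand
    integral = boltzmann_integral(profile, profile.z[0] - profile.dz / 2,
                                  profile.z[-1] + profile.dz / 2, relative=True)
    c_boltz = (n_permeants / area) / integral
    out = {"boltzmann-integral": ConcentrationResult(
        per_A3=float(c_boltz), method="boltzmann-integral")}

    if trajs is not None:
        if geometry is None:
            raise ValueError("far-zone estimate requires a geometry")
        lo, hi = geometry.water_zone_for_box(H)
        n_in, n_frames = 0, 0
        for tr in trajs:
            az = np.abs(tr.z)
            n_in += int(np.sum((az >= lo) & (az <= hi)))
        n_frames = max(t.n_frames for t in trajs)
        zone_volume = area * 2 * (hi - lo)
        out["far-zone-count"] = ConcentrationResult(
            per_A3=float(n_in / n_frames / zone_volume), method="far-zone-count")
    return out


def partition_coefficient(profile: FreeEnergyProfile, h: float) -> PartitionResult:
    """Membrane/water partition coefficient K(h) for dividing surfaces at
    |z| = h/2."""
    H = profile.z[-1] - profile.z[0] + profile.dz
    if h >= H:
        raise ValueError("h must be smaller than the box height H")
    inside = np.abs(profile.z) < h / 2
    if np.any(~np.isfinite(profile.values[inside])):
        raise ValueError("sentinel (unvisited) bins inside |z| < h/2; "
                         "cannot integrate the membrane region")
    K = boltzmann_integral(profile, -h / 2, h / 2) / h
    return PartitionResult(h=float(h), K=float(K))


def partition_ratio(profile_1: FreeEnergyProfile, h_1: float,
                    profile_2: FreeEnergyProfile, h_2: float) -> float:
    """K_1(h_1)/K_2(h_2) between two systems at their own h conventions."""
    return partition_coefficient(profile_1, h_1).ratio(
        partition_coefficient(profile_2, h_2))
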