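"""Crossing-event detection and the counting-method permeability.

A membrane-residence episode starts when a permeant passes a dividing
surface at |z| = h/2 and ends at its next surface passage. Episodes are
classified as

* ``crossing`` — entry and exit on opposite sides with a visit to the
  central midplane region |z| < z_mid in between (the transit rule);
* ``rebound`` — exit on the entry side;
* ``initial-escape`` — first exit of a permeant that was already inside
  the membrane at the start of observation; its entry history is
  unknown and, under the memoryless-exit assumption, each such exit
  contributes 0.5 crossings on average;
* ``unresolved`` — opposite-side exit without an observed midplane visit
  (including single-frame jumps clean through the membrane), ambiguous
  at the save resolution;
* ``unresolved-at-end`` — still inside when the trajectory ends.

The permeability is P = r / (2 c_w) with crossing rate
r = (effective count) / (A T_sim), the effective count being
(#crossings) + 0.5 (#initial escapes).

Event detection runs on a continuous unwrapped z built from minimum-image
frame displacements, so periodic wraps through the water slab toggle the
side bookkeeping without ever creating a membrane event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import APS_TO_CMS
from .io import MembraneGeometry, PermeantTrajectory

__all__ = [
    "Episode",
    "CrossingEventLog",
    "CountingPermeability",
    "CharacteristicTimes",
    "detect_events",
    "counting_permeability",
    "characteristic_times",
    "lateral_escape_distance",
    "poisson_interval",
]


@dataclass
class Episode:
    """One membrane-residence episode of one permeant.

    Times are frame times in ps (``None`` when not observed); sides are
    +1 (upper dividing surface) / -1 (lower); ``dr`` is the lateral
    displacement magnitude between entry and exit frames in Å.
    """

    permeant_id: str
    kind: str
    t_entry: float | None
    side_entry: int | None
    t_mid: float | None
    t_exit: float | None
    side_exit: int | None
    dr: float | None
    #: last midplane-region visit before exit (equals t_mid when the
    #: region is visited once); closes the time-reversal pair with t_mid
    t_mid_last: float | None = None


@dataclass
class CrossingEventLog:
    """Time-ordered, non-overlapping episodes for one permeant."""

    permeant_id: str
    episodes: list[Episode] = field(default_factory=list)
    t_sim: float = 0.0

    def count(self, kind: str) -> int:
        return sum(1 for e in self.episodes if e.kind == kind)


@dataclass
class CountingPermeability:
    """Counting-method permeability with a 95% CI on the crossing count."""

    effective_count: float
    rate: float                # crossings / (Å^2 ps)
    p_cms: float
    ci_cms: tuple[float, float]
    c_w: float
    ci_method: str = "poisson-exact"


@dataclass
class CharacteristicTimes:
    """Mean entrance and escape times (ps) with standard errors.

    ``tau_entr`` is the mean time from a surface entry to the first
    midplane arrival of the same episode; ``tau_esc`` from the first
    midplane arrival to the subsequent surface exit. Entries are None
    when no qualifying episode exists.
    """

    tau_entr: float | None
    tau_entr_se: float | None
    n_entr: int
    tau_esc: float | None
    tau_esc_se: float | None
    n_esc: int


def _mean_se(values):
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return None, None
    se = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else np.nan
    return float(values.mean()), float(se)


def detect_events(traj: PermeantTrajectory,
                  geometry: MembraneGeometry) -> CrossingEventLog:
    """Scan one centered trajectory for membrane-residence episodes.

    Uses the frame-time convention: an episode's entry (exit) time is the
    time of the first saved frame inside (outside) the membrane, and the
    midplane-visit time is the first frame with |z - midplane| < z_mid.
    """
    Lx, Ly, H = traj.box
    h2 = geometry.half_thickness
    if not h2 < H / 2:
        raise ValueError("need h/2 < H/2 (box edge must lie in water)")
    if not traj.centered:
        raise ValueError("trajectory must be membrane-centered")
    times = traj.times
    if len(times) >= 3:
        dt = np.diff(times)
        if np.any(dt > 1.5 * np.median(dt)):
            warnings.warn(f"frame gap larger than the save interval in "
                          f"permeant {traj.permeant_id!r}", stacklevel=2)

    # continuous coordinates from minimum-image increments
    dxyz = np.diff(traj.xyz, axis=0)
    for k, L in enumerate((Lx, Ly, H)):
        dxyz[:, k] -= L * np.round(dxyz[:, k] / L)
    cont = np.vstack([traj.xyz[0], traj.xyz[0] + np.cumsum(dxyz, axis=0)])
    Z = cont[:, 2]

    # vectorized per-frame labels on the unwrapped coordinate
    m_arr = np.round(Z / H).astype(np.int64)
    local = Z - m_arr * H
    inside = np.abs(local) < h2
    slab = np.floor((Z - h2) / H).astype(np.int64)
    midmask = inside & (np.abs(local) < geometry.z_mid)

    # segment boundaries: any change of (inside, membrane image / water slab)
    key = np.where(inside, 2 * m_arr, 2 * slab + 1)
    change = np.nonzero(np.diff(key))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(Z)]])     # exclusive

    log = CrossingEventLog(permeant_id=traj.permeant_id,
                           t_sim=float(times[-1] - times[0]))

    def mid_times(i0, i1):
        seg = midmask[i0:i1]
        if not seg.any():
            return None, None
        first = i0 + int(np.argmax(seg))
        last = i0 + len(seg) - 1 - int(np.argmax(seg[::-1]))
        return float(times[first]), float(times[last])

    n_seg = len(starts)
    for s in range(n_seg):
        i0, i1 = int(starts[s]), int(ends[s])
        if not inside[i0]:
            # through-jump: previous segment water in a different slab
            if s > 0 and not inside[i0 - 1] and slab[i0] != slab[i0 - 1]:
                side_in = +1 if slab[i0] < slab[i0 - 1] else -1
                log.episodes.append(Episode(
                    permeant_id=traj.permeant_id, kind="unresolved",
                    t_entry=float(times[i0 - 1]), side_entry=side_in,
                    t_mid=None, t_exit=float(times[i0]),
                    side_exit=-side_in, dr=None))
            continue
        m = int(m_arr[i0])
        initial = i0 == 0
        if initial:
            side_entry = None
        elif inside[i0 - 1]:
            # hopped straight from the adjacent membrane image
            from_slab = m_arr[i0 - 1] if m > m_arr[i0 - 1] else m
            side_entry = +1 if from_slab == m else -1
        else:
            side_entry = +1 if slab[i0 - 1] == m else -1
        t_mid, t_mid_last = mid_times(i0, i1)
        if i1 >= len(Z):
            dr = float(np.hypot(*(cont[-1, :2] - cont[i0, :2])))
            log.episodes.append(Episode(
                permeant_id=traj.permeant_id, kind="unresolved-at-end",
                t_entry=float(times[i0]), side_entry=side_entry,
                t_mid=t_mid, t_exit=None, side_exit=None, dr=dr,
                t_mid_last=t_mid_last))
            continue
        side_exit = +1 if Z[i1] > m * H else -1
        if initial:
            kind = "initial-escape"
        elif side_exit == side_entry:
            kind = "rebound"
        elif t_mid is not None:
            kind = "crossing"
        else:
            kind = "unresolved"
        dr = float(np.hypot(*(cont[i1, :2] - cont[i0, :2])))
        log.episodes.append(Episode(
            permeant_id=traj.permeant_id, kind=kind,
            t_entry=float(times[i0]), side_entry=side_entry,
            t_mid=t_mid, t_exit=float(times[i1]), side_exit=side_exit,
            dr=dr, t_mid_last=t_mid_last))
    return log


def poisson_interval(count: float, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval on a possibly half-integral count."""
    alpha = 1 - conf
    if count <= 0:
        return 0.0, float(stats.chi2.ppf(conf, 2) / 2)  # one-sided upper
    lo = stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (count + 1)) / 2
    return float(lo), float(hi)


def counting_permeability(logs, t_sim: float, area: float, c_w: float,
                          replicates=None) -> CountingPermeability:
    """Counting-method permeability P = r/(2 c_w) in cm/s.

    Parameters
    ----------
    logs : sequence of CrossingEventLog
    t_sim : float
        Run length in ps (shared by all permeants).
    area : float
        Leaflet cross-sectional area A in Å^2.
    c_w : float
        Water-phase concentration, count/Å^3.
    replicates : sequence of log-sequences, optional
        >= 3 independent replicate groups switch the CI to an
        across-replicate t-interval on P (each replicate spanning
        t_sim / n_replicates... the caller supplies per-group logs from
        equal-length runs).

    The effective count is (#crossings) + 0.5 (#initial escapes); the
    default CI is the exact Poisson interval on that count.
    """
    if c_w <= 0:
        raise ValueError("c_w must be positive")
    logs = list(logs)
    n_cross = sum(l.count("crossing") for l in logs)
    n_ie = sum(l.count("initial-escape") for l in logs)
    eff = n_cross + 0.5 * n_ie
    rate = eff / (area * t_sim)
    p_aps = rate / (2 * c_w)

    if replicates is not None and len(replicates) >= 3:
        t_rep = t_sim / len(replicates)
        ps = []
        for group in replicates:
            g = list(group)
            e = (sum(l.count("crossing") for l in g)
                 + 0.5 * sum(l.count("initial-escape") for l in g))
            ps.append(e / (area * t_rep) / (2 * c_w) * APS_TO_CMS)
        m, se = _mean_se(ps)
        tcrit = stats.t.ppf(0.975, len(ps) - 1)
        ci = (m - tcrit * se, m + tcrit * se)
        method = "replicate-t"
    else:
        lo, hi = poisson_interval(eff)
        scale = APS_TO_CMS / (area * t_sim * 2 * c_w)
        ci = (lo * scale, hi * scale)
        method = "poisson-exact"
    return CountingPermeability(
        effective_count=eff, rate=rate, p_cms=p_aps * APS_TO_CMS,
        ci_cms=ci, c_w=c_w, ci_method=method)


def initial_escape_expectation(n_walkers: int = 10000, h: float = 30.0,
                               d: float = 0.3, dt: float = 1.0,
                               seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo check of the 0.5-crossing initial-escape rule.

    Memoryless walkers start uniformly inside a flat membrane slab of
    thickness h with an entry side assigned uniformly at random (the
    side is unknown for permeants already inside at the start of
    observation). Each walker diffuses with constant D until it first
    exits through either dividing surface; a full crossing is scored
    when the exit side differs from the assigned entry side. Returns
    (mean score, standard error); the memoryless-exit expectation is 0.5.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(-h / 2, h / 2, size=n_walkers)
    entry = rng.choice([-1, 1], size=n_walkers)
    exit_side = np.zeros(n_walkers, dtype=int)
    active = np.ones(n_walkers, dtype=bool)
    sigma = np.sqrt(2 * d * dt)
    while active.any():
        idx = np.where(active)[0]
        z[idx] += sigma * rng.standard_normal(len(idx))
        done = np.abs(z[idx]) >= h / 2
        out = idx[done]
        exit_side[out] = np.sign(z[out]).astype(int)
        active[out] = False
    score = (exit_side != entry).astype(float)
    return float(score.mean()), float(score.std(ddof=1) / np.sqrt(n_walkers))


def characteristic_times(logs) -> CharacteristicTimes:
    """Mean entrance and escape times over midplane-visiting episodes."""
    entr, esc = [], []
    for log in logs:
        for e in log.episodes:
            if e.t_mid is None:
                continue
            if e.t_entry is not None and not e.kind.startswith("initial"):
                entr.append(e.t_mid - e.t_entry)
            if e.t_exit is not None:
                esc.append(e.t_exit - e.t_mid)
    te, tse = _mean_se(entr)
    to, tso = _mean_se(esc)
    return CharacteristicTimes(tau_entr=te, tau_entr_se=tse, n_entr=len(entr),
                               tau_esc=to, tau_esc_se=tso, n_esc=len(esc))


def lateral_escape_distance(logs) -> tuple[float, float]:
    """Root-mean-square lateral displacement between membrane entry and
    exit over all resolved residence episodes, in Å, with its standard
    error (propagated from the spread of squared displacements)."""
    dr2 = [e.dr ** 2 for log in logs for e in log.episodes
           if e.dr is not None and e.kind in
           ("crossing", "rebound", "initial-escape")]
    if not dr2:
        raise ValueError("no completed membrane-residence episodes")
    m, se = _mean_se(dr2)
    L = float(np.sqrt(m))
    L_se = float(se / (2 * L)) if se and L > 0 else np.nan
    return L, L_se
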