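"""Domain types and plain-text readers/writers.

All tabular interchange uses tab-separated text with ``#key value`` header
lines. Coordinates are membrane-centered: z = 0 at the bilayer midplane,
z periodic over the box height H, with the single water slab spanning the
periodic wrap (the box edge lies in water).

Formats
-------
Permeant trajectory TSV
    Header: ``#box Lx Ly H``, ``#temperature T``, ``#dt_ps dt``.
    Columns: frame, time_ps, permeant_id, permeant_type, x, y, z
    (one row per permeant per frame).
Chain TSV
    Header: ``#box Lx Ly H``.
    Columns: frame, chain_id, lipid_type, atom_idx, x, y, z.
Profile TSV
    Header: ``#units``, ``#temperature_K``, ``#method`` (free-form tags).
    Columns: z_A, value, stderr (free energy) or
    z_A, d_perp, d_par, stderr_perp, stderr_par (diffusion).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "PermeantTrajectory",
    "ChainFrame",
    "FreeEnergyProfile",
    "DiffusionProfiles",
    "MembraneGeometry",
    "load_permeant_trajectories",
    "write_permeant_trajectories",
    "load_chain_frames",
    "write_chain_frames",
    "load_profile_table",
    "write_profile_table",
    "recenter_and_wrap",
    "wrap_z",
]


class ParseError(ValueError):
    """Raised when a tabular input file violates the format contract."""


def wrap_z(z, H: float):
    """Wrap z into the membrane-centered interval [-H/2, H/2)."""
    return (np.asarray(z) + H / 2.0) % H - H / 2.0


@dataclass
class PermeantTrajectory:
    """Time-ordered positions of one permeant in a periodic box.

    Attributes
    ----------
    permeant_id : str
        Unique label of the permeant within its dataset.
    permeant_type : str
        Species tag, e.g. ``"oxygen-like"`` or ``"water-like"``.
    times : ndarray, shape (n,)
        Frame times in ps, strictly increasing with constant spacing.
    xyz : ndarray, shape (n, 3)
        Positions in Å; z is membrane-centered when ``centered`` is True.
    box : tuple (Lx, Ly, H)
        Periodic box edge lengths in Å.
    temperature : float
        Simulation temperature in K.
    centered : bool
        True when z = 0 is the membrane midplane.
    """

    permeant_id: str
    permeant_type: str
    times: np.ndarray
    xyz: np.ndarray
    box: tuple[float, float, float]
    temperature: float
    centered: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if len(self.times) != len(self.xyz):
            raise ValueError("times and xyz length mismatch")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError(
                    f"non-monotone times for permeant {self.permeant_id!r}"
                )
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"non-constant frame spacing for permeant {self.permeant_id!r}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Save interval in ps (0 for single-frame trajectories)."""
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]


@dataclass
class ChainFrame:
    """Lipid-chain carbon positions for one frame.

    ``chains`` maps chain_id -> (lipid_type, carbons) where carbons is an
    (n_carbons, 3) array in Å. Every chain_id carries exactly one
    lipid_type (e.g. ``sat``, ``unsat``, ``sterol``).
    """

    frame: int
    chains: dict[str, tuple[str, np.ndarray]]
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for cid, (ltype, carbons) in self.chains.items():
            carbons = np.asarray(carbons, dtype=float)
            if carbons.ndim != 2 or carbons.shape[1] != 3 or len(carbons) == 0:
                raise ValueError(f"chain {cid!r} needs >=1 carbon with (x,y,z)")
            self.chains[cid] = (ltype, carbons)

    @property
    def lipid_types(self) -> dict[str, str]:
        return {cid: ltype for cid, (ltype, _) in self.chains.items()}


@dataclass
class FreeEnergyProfile:
    """Binned free-energy profile F(z) in kcal/mol.

    Unvisited bins hold ``inf`` as a sentinel; ``f_ref`` is the constant
    water-phase reference value subtracted in Boltzmann factors.
    """

    z: np.ndarray
    values: np.ndarray
    f_ref: float
    temperature: float
    stderr: np.ndarray | None = None
    method: str = "histogram"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.z) != len(self.values):
            raise ValueError("grid/value length mismatch")
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0], rtol=1e-6):
            raise ValueError("bin centers must be uniformly spaced")
        if not np.isfinite(self.f_ref):
            raise ValueError("f_ref must be finite")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    def relative(self) -> np.ndarray:
        """F(z) - F_ref."""
        return self.values - self.f_ref


@dataclass
class DiffusionProfiles:
    """Position-dependent diffusion coefficients on the F(z) grid.

    ``d_perp`` is the component normal to the membrane surface (drives
    permeation), ``d_par`` the in-plane component; both in Å²/ps.
    """

    z: np.ndarray
    d_perp: np.ndarray
    d_par: np.ndarray
    stderr_perp: np.ndarray | None = None
    stderr_par: np.ndarray | None = None
    lags_ps: tuple[float, ...] | None = None
    method: str = "bayes"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d_perp = np.asarray(self.d_perp, dtype=float)
        self.d_par = np.asarray(self.d_par, dtype=float)
        if not (len(self.z) == len(self.d_perp) == len(self.d_par)):
            raise ValueError("grid/value length mismatch")
        if np.any(self.d_perp <= 0) or np.any(self.d_par <= 0):
            raise ValueError("diffusion coefficients must be positive")


@dataclass
class MembraneGeometry:
    """Dividing surfaces and reference zones along the membrane normal.

    ``half_thickness`` is h/2, the |z| plane separating membrane from
    water for event counting and ISD integration. ``z_mid`` is the
    half-width of the central midplane region a crossing must visit.
    ``water_zone`` is the |z| interval used to average F_ref.
    """

    half_thickness: float
    z_mid: float = 4.0
    water_zone: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.z_mid < self.half_thickness:
            raise ValueError("need 0 < z_mid < h/2")

    def water_zone_for_box(self, H: float) -> tuple[float, float]:
        """Water-reference |z| interval; default [h/2 + 5 Å, H/2]."""
        if self.water_zone is not None:
            return self.water_zone
        lo = self.half_thickness + 5.0
        hi = H / 2.0
        if lo >= hi:  # thin water slab: fall back to everything outside h/2
            lo = self.half_thickness
        return (lo, hi)


# ---------------------------------------------------------------------------
# header helpers


def _parse_headers(path) -> tuple[dict[str, list[str]], int]:
    headers: dict[str, list[str]] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            parts = line[1:].split()
            if parts:
                headers[parts[0]] = parts[1:]
    return headers, n_header


def _require_box(headers: dict, path) -> tuple[float, float, float]:
    if "box" not in headers or len(headers["box"]) != 3:
        raise ParseError(f"{path}: missing or malformed '#box Lx Ly H' header")
    lx, ly, hh = (float(v) for v in headers["box"])
    return lx, ly, hh


# ---------------------------------------------------------------------------
# permeant trajectories

_TRAJ_COLS = ["frame", "time_ps", "permeant_id", "permeant_type", "x", "y", "z"]


def load_permeant_trajectories(path) -> list[PermeantTrajectory]:
    """Read a permeant-trajectory TSV into one trajectory per permeant.

    Raises
    ------
    ParseError
        On missing header keys, malformed rows, or duplicated/non-monotone
        timestamps (the message names the offending permeant and line).
    """
    headers, n_header = _parse_headers(path)
    box = _require_box(headers, path)
    if "temperature" not in headers:
        raise ParseError(f"{path}: missing '#temperature T' header")
    temperature = float(headers["temperature"][0])

    try:
        df = pd.read_csv(
            path, sep="\t", skiprows=n_header, header=0,
            dtype={"permeant_id": str, "permeant_type": str},
        )
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(_TRAJ_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df[["x", "y", "z", "time_ps"]].isna().any().any():
        bad = int(df[["x", "y", "z", "time_ps"]].isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: malformed row at data line {bad + 2}")

    out = []
    for pid, grp in df.groupby("permeant_id", sort=True):
        grp = grp.sort_values("time_ps", kind="stable")
        t = grp["time_ps"].to_numpy(float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            line = int(grp.index[i + 1]) + n_header + 2
            raise ParseError(
                f"{path}: duplicated/non-monotone time for permeant {pid!r} "
                f"at line {line}"
            )
        out.append(PermeantTrajectory(
            permeant_id=str(pid),
            permeant_type=str(grp["permeant_type"].iloc[0]),
            times=t,
            xyz=grp[["x", "y", "z"]].to_numpy(float),
            box=box,
            temperature=temperature,
        ))
    return out


def write_permeant_trajectories(trajs, path) -> None:
    """Write trajectories to the permeant TSV dialect (one file, pooled)."""
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories to write")
    box = trajs[0].box
    dt = trajs[0].dt
    with open(path, "w") as fh:
        fh.write(f"#box {box[0]:.6g} {box[1]:.6g} {box[2]:.6g}\n")
        fh.write(f"#temperature {trajs[0].temperature:.6g}\n")
        fh.write(f"#dt_ps {dt:.6g}\n")
        fh.write("\t".join(_TRAJ_COLS) + "\n")
        frames = []
        for tr in trajs:
            for i, (t, (x, y, z)) in enumerate(zip(tr.times, tr.xyz)):
                frames.append((i, t, tr.permeant_id, tr.permeant_type, x, y, z))
        frames.sort(key=lambda r: (r[1], r[2]))
        for i, t, pid, ptype, x, y, z in frames:
            fh.write(f"{i}\t{t:.6f}\t{pid}\t{ptype}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def recenter_and_wrap(traj: PermeantTrajectory, offsets) -> PermeantTrajectory:
    """Subtract a per-frame midplane offset from z and wrap into [-H/2, H/2).

    ``offsets`` is a scalar or per-frame sequence of midplane positions
    (Å) in the original coordinates; lateral coordinates are untouched.
    """
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), traj.times.shape)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    xyz = traj.xyz.copy()
    xyz[:, 2] = wrap_z(xyz[:, 2] - offsets, traj.box[2])
    return replace(traj, xyz=xyz, centered=True)


# ---------------------------------------------------------------------------
# chain frames

_CHAIN_COLS = ["frame", "chain_id", "lipid_type", "atom_idx", "x", "y", "z"]


def load_chain_frames(path) -> list[ChainFrame]:
    """Read a chain TSV; validates that each chain has a single lipid type."""
    headers, n_header = _parse_headers(path)
    box = _require_box(headers, path)
    df = pd.read_csv(path, sep="\t", skiprows=n_header, header=0,
                     dtype={"chain_id": str, "lipid_type": str})
    missing = set(_CHAIN_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    types = df.groupby("chain_id")["lipid_type"].nunique()
    bad = types[types > 1]
    if len(bad):
        raise ParseError(
            f"{path}: chain(s) {list(bad.index)} carry conflicting lipid_type labels"
        )
    out = []
    for fidx, grp in df.groupby("frame", sort=True):
        chains = {}
        for cid, cgrp in grp.groupby("chain_id", sort=True):
            cgrp = cgrp.sort_values("atom_idx")
            chains[str(cid)] = (
                str(cgrp["lipid_type"].iloc[0]),
                cgrp[["x", "y", "z"]].to_numpy(float),
            )
        out.append(ChainFrame(frame=int(fidx), chains=chains, box=box))
    return out


def write_chain_frames(frames, path) -> None:
    frames = list(frames)
    if not frames:
        raise ValueError("no chain frames to write")
    box = frames[0].box or (0.0, 0.0, 0.0)
    with open(path, "w") as fh:
        fh.write(f"#box {box[0]:.6g} {box[1]:.6g} {box[2]:.6g}\n")
        fh.write("\t".join(_CHAIN_COLS) + "\n")
        for fr in frames:
            for cid in sorted(fr.chains):
                ltype, carbons = fr.chains[cid]
                for ai, (x, y, z) in enumerate(carbons):
                    fh.write(
                        f"{fr.frame}\t{cid}\t{ltype}\t{ai}\t"
                        f"{x:.6f}\t{y:.6f}\t{z:.6f}\n"
                    )


# ---------------------------------------------------------------------------
# profile tables


def write_profile_table(profile, path) -> None:
    """Write a FreeEnergyProfile or DiffusionProfiles as TSV.

    Infinite free-energy sentinels (never-visited bins) are written as the
    token ``inf`` and survive a round trip.
    """
    with open(path, "w") as fh:
        if isinstance(profile, FreeEnergyProfile):
            fh.write("#units z_A kcal/mol\n")
            fh.write(f"#temperature_K {profile.temperature:.6g}\n")
            fh.write(f"#f_ref {profile.f_ref:.8g}\n")
            fh.write(f"#method {profile.method}\n")
            fh.write("z_A\tvalue\tstderr\n")
            se = profile.stderr
            for i, (z, v) in enumerate(zip(profile.z, profile.values)):
                s = f"{se[i]:.8g}" if se is not None else "nan"
                fh.write(f"{z:.6f}\t{v:.8g}\t{s}\n")
        elif isinstance(profile, DiffusionProfiles):
            fh.write("#units z_A A2/ps\n")
            lags = " ".join(f"{l:g}" for l in profile.lags_ps or ())
            fh.write(f"#lags_ps {lags}\n")
            fh.write(f"#method {profile.method}\n")
            fh.write("z_A\td_perp\td_par\tstderr_perp\tstderr_par\n")
            sp = profile.stderr_perp
            sl = profile.stderr_par
            for i, z in enumerate(profile.z):
                s1 = f"{sp[i]:.8g}" if sp is not None else "nan"
                s2 = f"{sl[i]:.8g}" if sl is not None else "nan"
                fh.write(
                    f"{z:.6f}\t{profile.d_perp[i]:.8g}\t{profile.d_par[i]:.8g}"
                    f"\t{s1}\t{s2}\n"
                )
        else:
            raise TypeError(f"cannot write profile of type {type(profile)!r}")


def load_profile_table(path):
    """Read a profile TSV back into the matching profile object."""
    headers, n_header = _parse_headers(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_header, header=0)
    if "value" in df.columns:
        se = df["stderr"].to_numpy(float)
        return FreeEnergyProfile(
            z=df["z_A"].to_numpy(float),
            values=df["value"].to_numpy(float),
            f_ref=float(headers.get("f_ref", ["0"])[0]),
            temperature=float(headers.get("temperature_K", ["298"])[0]),
            stderr=None if np.all(np.isnan(se)) else se,
            method=" ".join(headers.get("method", ["histogram"])),
        )
    lags = tuple(float(v) for v in headers.get("lags_ps", []))
    sp = df["stderr_perp"].to_numpy(float)
    sl = df["stderr_par"].to_numpy(float)
    return DiffusionProfiles(
        z=df["z_A"].to_numpy(float),
        d_perp=df["d_perp"].to_numpy(float),
        d_par=df["d_par"].to_numpy(float),
        stderr_perp=None if np.all(np.isnan(sp)) else sp,
        stderr_par=None if np.all(np.isnan(sl)) else sl,
        lags_ps=lags or None,
        method=" ".join(headers.get("method", ["bayes"])),
    )
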