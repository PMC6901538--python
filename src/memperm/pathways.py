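"""Three-nearest-neighbor classification of permeant surroundings.

For each permeant sample the three closest lipid chains are found, the
chain–permeant distance being the minimum over all (permeant heavy atom,
chain carbon) pairs under the lateral periodic minimum-image convention.
The neighbor triple is sorted into classes: ``3-<type>`` when all three
chains share a lipid type, otherwise ``Mix``. Class frequencies are
accumulated per 1 Å z-slab and normalized, resolving which lipid
environments carry the permeation pathways as a function of depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ChainFrame

__all__ = ["NeighborProfile", "assign_three_nearest", "neighbor_profile"]


@dataclass
class NeighborProfile:
    """Per-slab class probabilities of the three-nearest-neighbor analysis.

    ``probabilities[class][s]`` is the frequency of the class in slab s;
    occupied slabs sum to 1 across classes, empty slabs hold NaN.
    """

    slab_centers: np.ndarray
    classes: tuple[str, ...]
    probabilities: dict[str, np.ndarray]
    counts: np.ndarray

    def to_table(self):
        import pandas as pd
        cols = {"z": self.slab_centers}
        cols.update({f"p_{c}": self.probabilities[c] for c in self.classes})
        cols["n"] = self.counts
        return pd.DataFrame(cols)


def _classify(types) -> str:
    return f"3-{types[0]}" if len(set(types)) == 1 else "Mix"


def assign_three_nearest(permeant_atoms, frame: ChainFrame,
                         lateral_box) -> tuple[tuple[str, str, str], str]:
    """Three nearest chains and the resulting class for one permeant.

    Parameters
    ----------
    permeant_atoms : (n_heavy, 3) array
        Heavy-atom coordinates of the permeant, Å (a point permeant is a
        single row).
    frame : ChainFrame
    lateral_box : (Lx, Ly)
        Lateral periodic lengths for the minimum-image convention
        (z is not imaged: chains live inside the membrane).

    Ties at the third neighbor are broken by (distance, chain_id) so
    repeated runs agree bitwise.
    """
    atoms = np.atleast_2d(np.asarray(permeant_atoms, dtype=float))
    if len(frame.chains) < 3:
        raise ValueError("need at least 3 chains to classify")
    Lx, Ly = lateral_box
    entries = []
    for cid in sorted(frame.chains):
        ltype, carbons = frame.chains[cid]
        d = atoms[:, None, :] - carbons[None, :, :]
        d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
        d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
        dist = float(np.sqrt(np.sum(d ** 2, axis=-1)).min())
        entries.append((dist, cid, ltype))
    entries.sort(key=lambda e: (e[0], e[1]))
    top = entries[:3]
    return tuple(cid for _, cid, _ in top), _classify([t for _, _, t in top])


def neighbor_profile(trajs, chain_frames, slab_width: float = 1.0,
                     lipid_types=None) -> NeighborProfile:
    """Depth-resolved class probabilities pooled over permeants and frames.

    Trajectory frames are matched to chain frames by frame index (a
    single chain frame is broadcast to all trajectory frames — the
    static-lattice case). The z of the permeant's first heavy atom
    assigns the sample to a slab of width ``slab_width``.
    """
    chain_frames = list(chain_frames)
    trajs = list(trajs)
    if not chain_frames or not trajs:
        raise ValueError("need at least one chain frame and one trajectory")
    by_index = {cf.frame: cf for cf in chain_frames}
    H = trajs[0].box[2]
    Lx, Ly = trajs[0].box[0], trajs[0].box[1]

    if lipid_types is None:
        lipid_types = sorted({t for cf in chain_frames
                              for t, _ in cf.chains.values()})
    classes = tuple(f"3-{t}" for t in lipid_types) + ("Mix",)

    edges = np.arange(-H / 2, H / 2 + slab_width / 2, slab_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    tally = {c: np.zeros(len(centers)) for c in classes}
    n_shared = 0
    for tr in trajs:
        for fi in range(tr.n_frames):
            cf = by_index.get(fi, chain_frames[0] if len(chain_frames) == 1
                              else None)
            if cf is None:
                continue
            n_shared += 1
            _, cls = assign_three_nearest(tr.xyz[fi], cf, (Lx, Ly))
            s = int(np.clip(np.searchsorted(edges, tr.xyz[fi, 2],
                                            side="right") - 1,
                            0, len(centers) - 1))
            tally[cls][s] += 1
    if n_shared == 0:
        raise ValueError("no frames shared between trajectories and chains")
    counts = np.sum([tally[c] for c in classes], axis=0)
    probs = {}
    with np.errstate(invalid="ignore"):
        for c in classes:
            probs[c] = np.where(counts > 0, tally[c] / np.maximum(counts, 1),
                                np.nan)
    return NeighborProfile(slab_centers=centers, classes=classes,
                           probabilities=probs, counts=counts)
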