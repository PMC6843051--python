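"""Transition-progress analysis between two reference states.

The scalar progress coordinate is

    σ(r) = ½ (RMSD_A(r) − RMSD_B(r)) / RMSD_{A,B} + ½,

where each RMSD is taken after an independent optimal (Kabsch) superposition
onto the corresponding reference, making σ a pure shape coordinate: 0 at
state A, 1 at state B, not clipped (conformations farther from one state
than the other reference is can fall slightly outside [0, 1]).  Because σ
projects the two-dimensional (RMSD_A, RMSD_B) location onto the A–B line,
the scatter of RMSD_B vs RMSD_A is kept alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import CaTrace, kabsch_superpose

__all__ = [
    "TransitionRecord",
    "EnergyProfile",
    "sigma_of",
    "scatter_table",
    "bin_by_sigma",
    "align_energy_scales",
]


def _coords(obj) -> np.ndarray:
    return obj.coords if isinstance(obj, CaTrace) else np.asarray(obj, float)


@dataclass
class TransitionRecord:
    """Per-frame RMSDs to both references and the σ progress coordinate."""

    rmsd_A: np.ndarray
    rmsd_B: np.ndarray
    sigma: np.ndarray
    rmsd_AB: float
    times: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sigma)

    def to_frame(self, potential=None) -> pd.DataFrame:
        d = {}
        if self.times is not None:
            d["time_ps"] = self.times
        d.update(rmsd_A=self.rmsd_A, rmsd_B=self.rmsd_B, sigma=self.sigma)
        if potential is not None:
            d["E_pot"] = np.asarray(potential, float)
        return pd.DataFrame(d)


@dataclass
class EnergyProfile:
    """σ-binned potential-energy profile (regular bins, right-closed last)."""

    bin_edges: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    count: np.ndarray
    ff_label: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def shifted(self, shift: float) -> "EnergyProfile":
        return EnergyProfile(self.bin_edges.copy(), self.mean + shift,
                             self.std.copy(), self.count.copy(),
                             self.ff_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
            "mean": self.mean, "std": self.std, "n": self.count,
        })


def sigma_of(coords, ref_A: CaTrace, ref_B: CaTrace):
    """(RMSD_A, RMSD_B, σ) of one conformation.

    Each RMSD uses its own optimal superposition; RMSD_{A,B} uses the same
    convention (A superposed onto B).  Raises for an identical reference
    pair (σ undefined, division by zero).
    """
    a, b = _coords(ref_A), _coords(ref_B)
    x = _coords(coords)
    rmsd_ab = kabsch_superpose(a, b)[3]
    if rmsd_ab <= 1e-12:
        raise ValueError("reference structures A and B are identical "
                         "(RMSD_AB = 0): σ is undefined")
    ra = kabsch_superpose(x, a)[3]
    rb = kabsch_superpose(x, b)[3]
    return ra, rb, 0.5 * (ra - rb) / rmsd_ab + 0.5


def scatter_table(traj, ref_A: CaTrace, ref_B: CaTrace) -> TransitionRecord:
    """Per-frame transition record of a trajectory.

    ``traj`` may be a :class:`~mcgpath.dynamics.Trajectory`, an (F, N, 3)
    array or a list of frames.  The metric triangle inequality
    |RMSD_A − RMSD_B| ≤ RMSD_{A,B} holds per frame up to alignment round-off.
    """
    times = None
    if hasattr(traj, "coords") and hasattr(traj, "times"):
        frames, times = traj.coords, traj.times
    else:
        frames = np.asarray([_coords(f) for f in traj], dtype=float)
    a, b = _coords(ref_A), _coords(ref_B)
    rmsd_ab = kabsch_superpose(a, b)[3]
    if rmsd_ab <= 1e-12:
        raise ValueError("reference structures A and B are identical "
                         "(RMSD_AB = 0): σ is undefined")
    ra = np.array([kabsch_superpose(f, a)[3] for f in frames])
    rb = np.array([kabsch_superpose(f, b)[3] for f in frames])
    sigma = 0.5 * (ra - rb) / rmsd_ab + 0.5
    return TransitionRecord(ra, rb, sigma, rmsd_ab, times=times)


def bin_by_sigma(records, energies, n_bins: int = 20,
                 ff_label: str = "") -> EnergyProfile:
    """Group frames into regular σ intervals and average their energies.

    ``records`` may be a :class:`TransitionRecord` or a plain σ array.
    Bins span [min σ, max σ]; interior bins are right-open and the last bin
    right-closed, so the frame at max σ is counted.  Per-bin sample standard
    deviation (ddof = 1; 0 for singleton bins); empty bins carry NaN
    mean/std and count 0.
    """
    sigma = records.sigma if isinstance(records, TransitionRecord) \
        else np.asarray(records, float)
    energies = np.asarray(energies, float)
    if sigma.size == 0:
        raise ValueError("empty input: no frames to bin")
    if sigma.shape != energies.shape:
        raise ValueError("records and energies must have the same length")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")

    lo, hi = float(sigma.min()), float(sigma.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    if hi == lo:
        idx = np.zeros(sigma.shape, dtype=int)
    else:
        idx = np.minimum(((sigma - lo) / (hi - lo) * n_bins).astype(int),
                         n_bins - 1)
    mean = np.full(n_bins, np.nan)
    std = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        e = energies[idx == b]
        count[b] = e.size
        if e.size:
            mean[b] = e.mean()
            std[b] = e.std(ddof=1) if e.size > 1 else 0.0
    return EnergyProfile(edges, mean, std, count, ff_label=ff_label)


def align_energy_scales(profile_A: EnergyProfile, profile_B: EnergyProfile,
                        sigma_star: float = 0.4) -> float:
    """Additive shift that aligns profile B to profile A at σ*.

    The two biased force fields have incomparable absolute energy scales;
    where their trajectories approach each other in conformation space
    (σ* ≈ 0.4 in practice) similar structures should have similar energy,
    which fixes the relative offset.  Returns the constant to add to
    profile B so that the two bin means containing σ* agree.
    """
    shifts = []
    for name, prof in (("A", profile_A), ("B", profile_B)):
        edges = prof.bin_edges
        if sigma_star < edges[0] or sigma_star > edges[-1]:
            raise ValueError(
                f"σ* = {sigma_star} outside profile {name} range "
                f"[{edges[0]:.3f}, {edges[-1]:.3f}]; choose a different σ*")
        b = min(int(np.searchsorted(edges, sigma_star, side="right")) - 1,
                len(prof.mean) - 1)
        b = max(b, 0)
        if prof.count[b] == 0:
            raise ValueError(
                f"profile {name} has no frames in the bin containing "
                f"σ* = {sigma_star}; choose a different σ*")
        shifts.append(prof.mean[b])
    return float(shifts[0] - shifts[1])
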