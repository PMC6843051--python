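"""Synthetic Cα geometries: ideal helices, strands, two-state hinge toys.

These generators provide download-free stand-ins for real reference
structures at desk scale.  The helix targets the stiff secondary-structure
regime of the force field (θ ≈ 90°, φ ≈ +50°) and the strand the soft one
(θ ≈ 130°, φ = 180°); the hinge pair is a two-helix protein whose A and B
states differ by a single loop dihedral — i.e. by a rigid rotation of one
arm about the hinge bond — giving a clean two-state transition toy.  All
generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import CaTrace

__all__ = [
    "make_helix",
    "make_strand",
    "make_hinge_pair",
    "make_arc_cloud",
    "ArcCloud",
    "HELIX_RISE",
    "HELIX_RADIUS",
    "HELIX_TWIST_DEG",
]

HELIX_RISE = 1.5       # Å per residue
HELIX_RADIUS = 2.3     # Å
HELIX_TWIST_DEG = 100.0  # degrees per residue (right-handed)

STRAND_RISE = 3.5      # Å per residue along the chain axis
STRAND_ZIGZAG_DEG = 25.0  # alternating bond tilt from the axis

LOOP_THETA_DEG = 100.0   # hinge-loop pseudo-angle
LOOP_PHI_DEG = -150.0    # hinge-loop pseudo-dihedral (strand-soft amplitude)


def _trace(coords, label: str) -> CaTrace:
    n = coords.shape[0]
    return CaTrace(list(range(1, n + 1)), ["ALA"] * n, coords, label=label)


def make_helix(n: int, seed: int = 0, noise_sd: float = 0.0,
               label: str = "helix") -> CaTrace:
    """Ideal right-handed Cα helix (rise 1.5 Å, radius 2.3 Å, 100°/residue).

    Noiseless geometry has θ ≈ 90.4° and φ ≈ +50.0° at every residue, Cα–Cα
    spacing ≈ 3.83 Å, and all (i, i+4) distances ≈ 6.2 Å (below the 8.5 Å
    contact cutoff).  ``noise_sd`` adds isotropic Gaussian jitter in Å.
    """
    if n < 4:
        raise ValueError("a helix needs at least 4 residues")
    i = np.arange(n)
    w = np.radians(HELIX_TWIST_DEG)
    x = np.stack([HELIX_RADIUS * np.cos(i * w),
                  HELIX_RADIUS * np.sin(i * w),
                  HELIX_RISE * i], axis=1)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, x.shape)
    return _trace(x, label)


def make_strand(n: int, seed: int = 0, noise_sd: float = 0.0,
                label: str = "strand") -> CaTrace:
    """Extended planar zig-zag strand (rise 3.5 Å, bonds tilted ±25°).

    Noiseless geometry has θ = 130° and φ = 180° throughout, so every
    dihedral falls in the soft (strand) amplitude regime and no |i−j| > 3
    pair comes anywhere near the 8.5 Å contact cutoff.
    """
    if n < 4:
        raise ValueError("a strand needs at least 4 residues")
    i = np.arange(n)
    half_amp = 0.5 * STRAND_RISE * np.tan(np.radians(STRAND_ZIGZAG_DEG))
    x = np.stack([STRAND_RISE * i,
                  half_amp * np.where(i % 2 == 0, 1.0, -1.0),
                  np.zeros(n)], axis=1)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, x.shape)
    return _trace(x, label)


def _nerf_chain(d, theta, phi) -> np.ndarray:
    """Build Cartesian coordinates from internal coordinates (NeRF).

    ``d`` has N−1 bond lengths, ``theta`` N−2 angles and ``phi`` N−3
    dihedrals, all in Å / radians.  The first three beads are placed in the
    xy-plane; each later bead i+3 is placed from (i, i+1, i+2) at distance
    d, angle θ and signed dihedral φ in the same right-handed convention as
    :func:`mcgpath.structures.compute_internal_coords`.
    """
    n = len(d) + 1
    x = np.zeros((n, 3))
    x[1] = [d[0], 0.0, 0.0]
    x[2] = x[1] + d[1] * np.array([-np.cos(theta[0]), np.sin(theta[0]), 0.0])
    for i in range(3, n):
        a, b, c = x[i - 3], x[i - 2], x[i - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        nrm = np.cross(b - a, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        dd, th, ph = d[i - 1], theta[i - 2], phi[i - 3]
        d2 = np.array([-dd * np.cos(th),
                       dd * np.sin(th) * np.cos(ph),
                       dd * np.sin(th) * np.sin(ph)])
        x[i] = c + d2[0] * bc + d2[1] * m + d2[2] * nrm
    return x


@dataclass
class HingeGeometry:
    """Index bookkeeping of the hinge toy (arm/loop bead ranges)."""

    n: int
    arm1: slice
    loop: slice
    arm2: slice
    hinge_dihedral_index: int


def hinge_geometry(n: int) -> HingeGeometry:
    n_arm = (n - 4) // 2
    la = n_arm + (n - 4) % 2  # first arm absorbs the odd residue
    return HingeGeometry(n=n, arm1=slice(0, la), loop=slice(la, la + 4),
                         arm2=slice(la + 4, n), hinge_dihedral_index=la)


def _hinge_state(n: int, chi_deg: float) -> np.ndarray:
    geom = hinge_geometry(n)
    # helix internal coordinates of the ideal generator, computed in closed
    # form from the parametric helix
    w = np.radians(HELIX_TWIST_DEG)
    pts = np.stack([HELIX_RADIUS * np.cos(np.arange(4) * w),
                    HELIX_RADIUS * np.sin(np.arange(4) * w),
                    HELIX_RISE * np.arange(4)], axis=1)
    b = np.diff(pts, axis=0)
    d_h = float(np.linalg.norm(b[0]))
    u = b / np.linalg.norm(b, axis=1)[:, None]
    th_h = float(np.arccos(np.clip(-np.dot(u[0], u[1]), -1, 1)))
    n1, n2 = np.cross(b[0], b[1]), np.cross(b[1], b[2])
    m = np.cross(n1, b[1] / np.linalg.norm(b[1]))
    ph_h = float(np.arctan2(-np.dot(m, n2), np.dot(n1, n2)))

    d = np.full(n - 1, d_h)
    theta = np.full(n - 2, th_h)
    phi = np.full(n - 3, ph_h)
    # loop beads: soft strand-like geometry; θ index i sits at bead i+1
    for i in range(n - 2):
        if geom.loop.start <= i + 1 < geom.loop.stop:
            theta[i] = np.radians(LOOP_THETA_DEG)
    # dihedral i spans beads i..i+3; mark every window touching the loop
    for i in range(n - 3):
        if i + 3 >= geom.loop.start and i < geom.loop.stop:
            phi[i] = np.radians(LOOP_PHI_DEG)
    phi[geom.hinge_dihedral_index] = np.radians(chi_deg)
    return _nerf_chain(d, theta, phi)


def make_hinge_pair(n: int, chi_A: float = 30.0, chi_B: float = 120.0,
                    seed: int = 0):
    """Two-state hinge toy: a helix–loop–helix with a switchable hinge dihedral.

    The two returned CaTraces (labelled "A" and "B") share all internal
    coordinates except the central loop dihedral, set to χ_A and χ_B
    degrees; state B is therefore state A with its second arm rigidly
    rotated about the hinge bond by χ_B − χ_A.  The loop geometry is tuned
    so that the default χ_A = 30° folds the two arms into mutual contact
    (a closed, contact-stabilized state, dozens of inter-arm pairs inside
    the 8.5 Å cutoff) while χ_B = 120° swings them fully apart (open, no
    inter-arm contacts) — a desk-scale analogue of a closed/open two-domain
    protein.  ``seed`` is accepted for API symmetry with the other
    generators (construction is deterministic).
    """
    if n < 16:
        raise ValueError("hinge toy needs at least 16 residues")
    for name, chi in (("chi_A", chi_A), ("chi_B", chi_B)):
        if not -180.0 < chi <= 180.0:
            raise ValueError(f"{name} must lie in (−180, 180] degrees")
    if chi_A == chi_B:
        raise ValueError("chi_A and chi_B must differ")
    a = _trace(_hinge_state(n, chi_A), "A")
    b = _trace(_hinge_state(n, chi_B), "B")
    return a, b


@dataclass
class ArcCloud:
    """Noisy 2-D samples of a quarter-circle arc plus the generating curve."""

    points: np.ndarray      # (n, 2) noisy samples
    endpoints: np.ndarray   # (2, 2) exact arc ends, for pinning
    curve: np.ndarray       # (200, 2) dense noiseless samples of the arc
    radius: float
    noise_sd: float


def make_arc_cloud(n_points: int, noise_sd: float, seed: int = 0,
                   radius: float = 1.0) -> ArcCloud:
    """Uniform samples along a quarter circle with isotropic Gaussian noise."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, np.pi / 2.0, n_points)
    t.sort()
    pts = radius * np.stack([np.cos(t), np.sin(t)], axis=1)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    tc = np.linspace(0.0, np.pi / 2.0, 200)
    curve = radius * np.stack([np.cos(tc), np.sin(tc)], axis=1)
    endpoints = np.array([[radius, 0.0], [0.0, radius]])
    return ArcCloud(points=pts, endpoints=endpoints, curve=curve,
                    radius=radius, noise_sd=noise_sd)
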