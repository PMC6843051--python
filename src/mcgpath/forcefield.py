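"""The structure-biased minimalist Cα force field.

The potential is split into bonded terms (virtual bonds, pseudo-bond angles,
pseudo-dihedrals) and non-bonded Morse pair terms.  Rest values d0, θ0, φ0
and r0 are read from a chosen reference structure, which thereby becomes a
built-in minimum of the field (a Go-like structural bias).  Non-bonded pairs
are split by their *reference* distance against r_cut = 8.5 Å: closer pairs
("local") get structure-specific Morse parameters that strengthen and
shorten with decreasing r0, mimicking hydrogen bonds and specific contacts;
the rest ("non-local") share one shallow generic hydrophobic well.

Secondary structure enters only through the reference geometry: bond-angle
stiffness follows a damped-sinc law of θ0 (stiff for helices near 90°, soft
for strands above 110°), and the dihedral amplitude is 25 kcal/mol in the
helical regime (|φ0| ≤ 80°) versus 5 kcal/mol for strands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .structures import CaTrace, compute_internal_coords

__all__ = [
    "ForceFieldParams",
    "BiasedTopology",
    "angle_stiffness",
    "dihedral_amplitude",
    "local_morse_params",
    "build_topology",
    "energy",
    "forces",
    "morse",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants (kcal/mol, Å, radians where applicable)."""

    B: float = 3000.0                 # angle-stiffness scale
    k0: float = 10.0                  # angle-stiffness floor
    beta: float = 1.667               # damped-sinc frequency, rad⁻¹
    A_helix: float = 25.0             # dihedral amplitude, |φ0| ≤ threshold
    A_strand: float = 5.0             # dihedral amplitude otherwise
    dihedral_threshold_deg: float = 80.0
    r_cut: float = 8.5                # local/non-local split on reference r0
    local_eps_scale: float = 3.8
    local_alpha_scale: float = 2.2
    local_decay_r: float = 6.1
    local_decay_exp: int = 8
    local_eps_floor: float = 0.05
    local_alpha_floor: float = 0.70
    nl_r0: float = 9.5                # generic hydrophobic well position
    nl_eps: float = 0.05
    nl_alpha: float = 0.70
    theta_clamp_deg: tuple = (5.0, 175.0)

    def __post_init__(self):
        for name in ("B", "k0", "beta", "A_helix", "A_strand", "r_cut",
                     "local_eps_scale", "local_alpha_scale", "local_decay_r",
                     "local_eps_floor", "local_alpha_floor", "nl_r0",
                     "nl_eps", "nl_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_PARAMS = ForceFieldParams()


def angle_stiffness(theta0: float, params: ForceFieldParams = DEFAULT_PARAMS) -> float:
    """Bond-angle stiffness kθ(θ0) = [B·(sin(βθ0)/(βθ0))² + k0] / sin²θ0.

    The damped-sinc prefactor comes from inverse angle fluctuations of
    atomistic reference simulations (equipartition, k' = k_B T / ⟨δθ²⟩); the
    1/sin²θ0 factor converts to the harmonic-cosine functional form used
    here.  θ0 in radians; result in kcal/mol.  θ0 outside the clamp window
    is clamped with a warning to keep the stiffness bounded near collinear
    reference geometry.
    """
    lo, hi = np.radians(params.theta_clamp_deg[0]), np.radians(params.theta_clamp_deg[1])
    t = float(theta0)
    if t < lo or t > hi:
        warnings.warn(
            f"θ0 = {np.degrees(t):.1f}° outside [{params.theta_clamp_deg[0]}, "
            f"{params.theta_clamp_deg[1]}]°; clamped", stacklevel=2)
        t = min(max(t, lo), hi)
    ki = stiffness_prefactor(t, params)
    return ki / np.sin(t) ** 2


def stiffness_prefactor(theta0: float, params: ForceFieldParams = DEFAULT_PARAMS) -> float:
    """The damped-sinc factor k_i(θ0) = B·(sin(βθ0)/(βθ0))² + k0 alone."""
    bt = params.beta * float(theta0)
    return params.B * (np.sin(bt) / bt) ** 2 + params.k0


def dihedral_amplitude(phi0: float, params: ForceFieldParams = DEFAULT_PARAMS) -> float:
    """Dihedral amplitude: A_helix for |φ0| ≤ 80°, A_strand beyond.

    φ0 in radians; the threshold compares the absolute value (helices sit
    near +50°, and the rule is taken symmetric in sign).
    """
    thr = np.radians(params.dihedral_threshold_deg)
    return params.A_helix if abs(float(phi0)) <= thr else params.A_strand


def local_morse_params(r0: float, params: ForceFieldParams = DEFAULT_PARAMS):
    """Distance-dependent (ε, α) of a local Morse pair.

    ε(r0) = 3.8·exp(−(r0/6.1)⁸) + 0.05 kcal/mol and
    α(r0) = 2.2·exp(−(r0/6.1)⁸) + 0.70 Å⁻¹: strong short-ranged wells in the
    hydrogen-bond range, decaying to the generic hydrophobic floor before
    r_cut.
    """
    r0 = float(r0)
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if r0 >= params.r_cut:
        raise ValueError(
            f"r0 = {r0:.2f} Å ≥ r_cut = {params.r_cut} Å: pair is non-local")
    decay = np.exp(-((r0 / params.local_decay_r) ** params.local_decay_exp))
    eps = params.local_eps_scale * decay + params.local_eps_floor
    alpha = params.local_alpha_scale * decay + params.local_alpha_floor
    return eps, alpha


def morse(r, eps: float, alpha: float, r0: float):
    """Morse pair potential ε[(e^{−α(r−r0)} − 1)² − 1]; minimum −ε at r0."""
    e = np.exp(-alpha * (np.asarray(r, float) - r0))
    return eps * ((e - 1.0) ** 2 - 1.0)


@dataclass
class BiasedTopology:
    """Compiled force-field terms for one reference structure.

    Term arrays (index arrays are int64):

    - ``bond_idx`` (nb, 2), ``bond_d0`` (nb,): virtual bonds i—i+1.
    - ``ang_idx`` (na, 3), ``ang_theta0`` (na,), ``ang_k`` (na,).
    - ``dih_idx`` (nd, 4), ``dih_phi0`` (nd,), ``dih_amp`` (nd,).
    - ``loc_idx`` (nl, 2), ``loc_r0``, ``loc_eps``, ``loc_alpha``.
    - ``nl_idx`` (nn, 2): non-local pairs sharing the generic constants.

    Pairs with |i−j| ≤ 3 are already covered by bonded terms and appear in
    neither pair list; local ∪ non-local is exactly the set of |i−j| > 3
    pairs.
    """

    bond_idx: np.ndarray
    bond_d0: np.ndarray
    ang_idx: np.ndarray
    ang_theta0: np.ndarray
    ang_k: np.ndarray
    dih_idx: np.ndarray
    dih_phi0: np.ndarray
    dih_amp: np.ndarray
    loc_idx: np.ndarray
    loc_r0: np.ndarray
    loc_eps: np.ndarray
    loc_alpha: np.ndarray
    nl_idx: np.ndarray
    n_beads: int
    reference_label: str = ""
    params: ForceFieldParams = field(default_factory=ForceFieldParams)

    @property
    def ang_cos0(self) -> np.ndarray:
        return np.cos(self.ang_theta0)

    def only(self, *terms: str) -> "BiasedTopology":
        """Copy with every term family not named in ``terms`` emptied.

        Term names: ``bonds``, ``angles``, ``dihedrals``, ``local``,
        ``nonlocal``.  Useful for inspecting per-term forces.
        """
        t = BiasedTopology(**{k: v for k, v in self.__dict__.items()})
        if "bonds" not in terms:
            t.bond_idx = np.zeros((0, 2), dtype=np.int64)
            t.bond_d0 = np.zeros(0)
        if "angles" not in terms:
            t.ang_idx = np.zeros((0, 3), dtype=np.int64)
            t.ang_theta0 = np.zeros(0)
            t.ang_k = np.zeros(0)
        if "dihedrals" not in terms:
            t.dih_idx = np.zeros((0, 4), dtype=np.int64)
            t.dih_phi0 = np.zeros(0)
            t.dih_amp = np.zeros(0)
        if "local" not in terms:
            t.loc_idx = np.zeros((0, 2), dtype=np.int64)
            t.loc_r0 = np.zeros(0)
            t.loc_eps = np.zeros(0)
            t.loc_alpha = np.zeros(0)
        if "nonlocal" not in terms:
            t.nl_idx = np.zeros((0, 2), dtype=np.int64)
        return t

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "reference_label": self.reference_label,
            "n_beads": self.n_beads,
            "params": asdict(self.params),
            "bonds": [[int(i), int(j), float(d)] for (i, j), d in
                      zip(self.bond_idx, self.bond_d0)],
            "angles": [[int(i), int(j), int(k), float(t), float(kk)]
                       for (i, j, k), t, kk in
                       zip(self.ang_idx, self.ang_theta0, self.ang_k)],
            "dihedrals": [[int(i), int(j), int(k), int(l), float(p), float(a)]
                          for (i, j, k, l), p, a in
                          zip(self.dih_idx, self.dih_phi0, self.dih_amp)],
            "local_pairs": [[int(i), int(j), float(r), float(e), float(a)]
                            for (i, j), r, e, a in
                            zip(self.loc_idx, self.loc_r0, self.loc_eps,
                                self.loc_alpha)],
            "nonlocal_pairs": [[int(i), int(j)] for i, j in self.nl_idx],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BiasedTopology":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        p = doc["params"]
        p["theta_clamp_deg"] = tuple(p["theta_clamp_deg"])
        bonds = np.array(doc["bonds"], dtype=float).reshape(-1, 3)
        angs = np.array(doc["angles"], dtype=float).reshape(-1, 5)
        dihs = np.array(doc["dihedrals"], dtype=float).reshape(-1, 6)
        locs = np.array(doc["local_pairs"], dtype=float).reshape(-1, 5)
        nls = np.array(doc["nonlocal_pairs"], dtype=float).reshape(-1, 2)
        return cls(
            bond_idx=bonds[:, :2].astype(np.int64), bond_d0=bonds[:, 2],
            ang_idx=angs[:, :3].astype(np.int64), ang_theta0=angs[:, 3],
            ang_k=angs[:, 4],
            dih_idx=dihs[:, :4].astype(np.int64), dih_phi0=dihs[:, 4],
            dih_amp=dihs[:, 5],
            loc_idx=locs[:, :2].astype(np.int64), loc_r0=locs[:, 2],
            loc_eps=locs[:, 3], loc_alpha=locs[:, 4],
            nl_idx=nls.astype(np.int64),
            n_beads=int(doc["n_beads"]),
            reference_label=doc.get("reference_label", ""),
            params=ForceFieldParams(**p),
        )


def build_topology(reference: CaTrace,
                   params: ForceFieldParams = DEFAULT_PARAMS) -> BiasedTopology:
    """Compile the biased force field from a reference Cα trace.

    Bond, angle and dihedral rest values come from the reference internal
    coordinates; every |i−j| > 3 pair is classified local (reference
    distance strictly below r_cut, with structure-specific Morse parameters)
    or non-local (generic constants).
    """
    x = reference.coords
    n = x.shape[0]
    ic = compute_internal_coords(reference)

    bond_idx = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1).astype(np.int64)
    ang_idx = np.stack([np.arange(n - 2), np.arange(1, n - 1),
                        np.arange(2, n)], axis=1).astype(np.int64)
    dih_idx = np.stack([np.arange(n - 3), np.arange(1, n - 2),
                        np.arange(2, n - 1), np.arange(3, n)],
                       axis=1).astype(np.int64)
    ang_k = np.array([angle_stiffness(t, params) for t in ic.bond_angles])
    dih_amp = np.array([dihedral_amplitude(p, params) for p in ic.dihedrals])

    ii, jj = np.triu_indices(n, k=4)  # all |i−j| > 3 pairs
    rij = np.linalg.norm(x[jj] - x[ii], axis=1)
    is_local = rij < params.r_cut
    loc_idx = np.stack([ii[is_local], jj[is_local]], axis=1).astype(np.int64)
    loc_r0 = rij[is_local]
    le, la = np.empty_like(loc_r0), np.empty_like(loc_r0)
    for p, r0 in enumerate(loc_r0):
        le[p], la[p] = local_morse_params(r0, params)
    nl_idx = np.stack([ii[~is_local], jj[~is_local]], axis=1).astype(np.int64)

    return BiasedTopology(
        bond_idx=bond_idx, bond_d0=ic.bond_lengths,
        ang_idx=ang_idx, ang_theta0=ic.bond_angles, ang_k=ang_k,
        dih_idx=dih_idx, dih_phi0=ic.dihedrals, dih_amp=dih_amp,
        loc_idx=loc_idx, loc_r0=loc_r0, loc_eps=le, loc_alpha=la,
        nl_idx=nl_idx, n_beads=n,
        reference_label=reference.label, params=params)


def _check_overlaps(x: np.ndarray, topology: BiasedTopology) -> None:
    for idx in (topology.loc_idx, topology.nl_idx):
        if len(idx) == 0:
            continue
        r = np.linalg.norm(x[idx[:, 1]] - x[idx[:, 0]], axis=1)
        bad = r < 0.1
        if np.any(bad):
            b = int(np.argmax(bad))
            raise ValueError(
                f"beads {idx[b, 0]} and {idx[b, 1]} overlap "
                f"(r = {r[b]:.3f} Å < 0.1 Å)")


def _eval(x, topology: BiasedTopology, bond_k: float):
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape != (topology.n_beads, 3):
        raise ValueError(
            f"coords shape {x.shape} does not match topology "
            f"({topology.n_beads} beads)")
    _check_overlaps(x, topology)
    f = np.zeros_like(x)
    eb, ea, ed, el, en = _kernels.energy_forces(
        x, topology.bond_idx, topology.bond_d0, float(bond_k),
        topology.ang_idx, np.cos(topology.ang_theta0), topology.ang_k,
        topology.dih_idx, topology.dih_phi0, topology.dih_amp,
        topology.loc_idx, topology.loc_r0, topology.loc_eps,
        topology.loc_alpha,
        topology.nl_idx, topology.params.nl_r0, topology.params.nl_eps,
        topology.params.nl_alpha, f)
    energies = {
        "bond_penalty": eb, "angle": ea, "dihedral": ed,
        "local": el, "nonlocal": en,
        "total": eb + ea + ed + el + en,
    }
    return energies, f


def energy(coords, topology: BiasedTopology, bond_k: float = 0.0) -> dict:
    """Per-term potential energies (kcal/mol) at the given coordinates.

    ``bond_k`` > 0 adds the stiff-harmonic bond restraint used by the
    harmonic dynamics mode to ``bond_penalty``; with the default 0 the bonds
    are treated as holonomic and contribute no energy.
    """
    return _eval(coords, topology, bond_k)[0]


def forces(coords, topology: BiasedTopology, bond_k: float = 0.0) -> np.ndarray:
    """Analytic forces −∇U, kcal/(mol·Å), shape (N, 3)."""
    return _eval(coords, topology, bond_k)[1]
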