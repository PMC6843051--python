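"""Cα-trace structures, internal coordinates, superposition and trajectory I/O.

The whole package works on a single-chain Cα trace: one bead per residue,
placed at the alpha-carbon.  Local geometry is described by the pseudo-bond
lengths d_i, pseudo-bond angles θ_i and pseudo-dihedrals φ_i defined over
consecutive beads; together they uniquely encode the secondary structure of
a Cα-only chain.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CaTrace",
    "InternalCoordinates",
    "ChainBreakError",
    "read_ca_trace",
    "compute_internal_coords",
    "kabsch_superpose",
    "rmsd",
    "write_trajectory",
    "read_trajectory",
]

#: Cα–Cα virtual bond length limits (Å): warn outside the soft band,
#: treat anything above the hard limit as a chain break.
BOND_SOFT_RANGE = (2.5, 4.5)
BOND_HARD_MAX = 6.0


class ChainBreakError(ValueError):
    """Raised when consecutive Cα beads are too far apart to be bonded."""


@dataclass
class CaTrace:
    """Ordered Cα coordinates of one protein chain.

    Parameters
    ----------
    residue_ids : sequence of int
        Residue numbers in chain order.
    residue_names : sequence of str
        Three-letter residue codes (``"GLY"`` etc.; toy builders use ``"ALA"``).
    coords : (N, 3) float array
        Cα positions in Å.
    label : str
        Free-text tag, conventionally ``"A"``/``"B"`` for reference states.
    """

    residue_ids: list[int]
    residue_names: list[str]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 4:
            raise ValueError(f"a CaTrace needs at least 4 residues, got {n}")
        if len(self.residue_ids) != n or len(self.residue_names) != n:
            raise ValueError("residue_ids/residue_names length must match coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any(d > BOND_HARD_MAX):
            i = int(np.argmax(d > BOND_HARD_MAX))
            raise ChainBreakError(
                f"Cα–Cα distance {d[i]:.2f} Å between residues "
                f"{self.residue_ids[i]} and {self.residue_ids[i + 1]} exceeds "
                f"{BOND_HARD_MAX} Å: chain break"
            )
        lo, hi = BOND_SOFT_RANGE
        if np.any((d < lo) | (d > hi)):
            warnings.warn(
                "consecutive Cα–Cα distances outside the "
                f"[{lo}, {hi}] Å band (min {d.min():.2f}, max {d.max():.2f} Å)",
                stacklevel=2,
            )

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_residues

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "CaTrace":
        """Copy of this trace with new coordinates (same residues)."""
        return CaTrace(
            list(self.residue_ids),
            list(self.residue_names),
            np.array(coords, dtype=float),
            self.label if label is None else label,
        )


@dataclass
class InternalCoordinates:
    """Pseudo-bond internal coordinates of a Cα trace.

    ``bond_lengths`` has N−1 entries (Å), ``bond_angles`` N−2 entries
    (radians, in (0, π)), ``dihedrals`` N−3 entries (radians, signed,
    right-handed IUPAC convention, range (−π, π]).
    """

    bond_lengths: np.ndarray
    bond_angles: np.ndarray
    dihedrals: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bond_lengths) + 1
        if len(self.bond_angles) != n - 2 or len(self.dihedrals) != n - 3:
            raise ValueError("inconsistent internal-coordinate counts")
        if np.any(self.bond_angles <= 0) or np.any(self.bond_angles >= np.pi):
            raise ValueError("bond angles must lie strictly inside (0, π)")


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _as_handle(pdb_source):
    """Return a text handle for a path, file-like object or raw PDB text."""
    if hasattr(pdb_source, "read"):
        return pdb_source
    if isinstance(pdb_source, (str, os.PathLike)):
        s = os.fspath(pdb_source)
        if "\n" in s:  # raw PDB text, not a path
            return io.StringIO(s)
        return open(s)
    raise TypeError(f"cannot read PDB from {type(pdb_source)!r}")


def read_ca_trace(pdb_source, chain_selector: str | None = None,
                  model_index: int = 0, label: str = "") -> CaTrace:
    """Extract the Cα trace of one chain from a PDB file.

    Parameters
    ----------
    pdb_source : path, file-like or str
        PDB file path, open text handle, or the PDB text itself.
    chain_selector : str, optional
        Chain identifier.  If omitted and the model has exactly one chain,
        that chain is used.
    model_index : int
        Which MODEL to read (0-based); default first.
    label : str
        Label stored on the returned trace.

    Notes
    -----
    Only ATOM records with atom name CA are used; HETATM residues (waters,
    ions, ligands) are skipped.  Alternate locations resolve to the highest
    occupancy.  A gap in residue numbering combined with a Cα–Cα distance
    above 6 Å is reported as a chain break.
    """
    from Bio.PDB import PDBParser

    handle = _as_handle(pdb_source)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", handle)
    models = list(structure)
    if not models:
        raise ValueError("PDB source contains no models")
    if model_index >= len(models):
        raise ValueError(
            f"model index {model_index} out of range ({len(models)} models)")
    model = models[model_index]

    chains = {c.id: c for c in model}
    if chain_selector is None:
        if len(chains) != 1:
            raise ValueError(
                "chain_selector required: file has chains "
                + ", ".join(sorted(chains)))
        chain = next(iter(chains.values()))
    else:
        if chain_selector not in chains:
            raise ValueError(
                f"chain {chain_selector!r} not found; available chains: "
                + ", ".join(sorted(chains)))
        chain = chains[chain_selector]

    ids, names, xyz = [], [], []
    for res in chain:
        hetflag, resseq, _icode = res.id
        if hetflag.strip():
            continue  # HETATM residue
        if "CA" not in res:
            raise ValueError(
                f"residue {res.get_resname()} {resseq} in chain {chain.id} "
                "has no Cα atom")
        # Biopython's DisorderedAtom already selects the highest-occupancy
        # altloc, so get_coord() is the record we want.
        ids.append(int(resseq))
        names.append(res.get_resname())
        xyz.append(res["CA"].get_coord())

    if len(xyz) < 4:
        raise ValueError(f"chain {chain.id} has only {len(xyz)} Cα atoms; need ≥ 4")
    coords = np.asarray(xyz, dtype=float)

    # chain-break scan: numbering gap together with a broken virtual bond
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    for i in range(len(d)):
        if ids[i + 1] - ids[i] > 1 and d[i] > BOND_HARD_MAX:
            raise ChainBreakError(
                f"chain break between residues {ids[i]} and {ids[i + 1]} "
                f"(gap in numbering, Cα–Cα = {d[i]:.2f} Å)")
    return CaTrace(ids, names, coords, label=label)


# ---------------------------------------------------------------------------
# Internal coordinates
# ---------------------------------------------------------------------------

def compute_internal_coords(trace: CaTrace | np.ndarray) -> InternalCoordinates:
    """Pseudo-bond lengths, angles and signed dihedrals of a Cα trace.

    θ_i is the angle at bead i+1 over beads (i, i+1, i+2); φ_i the signed
    dihedral over beads (i..i+3) with the right-handed convention (trans
    = 180°).  Three collinear consecutive beads make the dihedral through
    them undefined and raise a ``ValueError`` naming the bead index.
    """
    x = trace.coords if isinstance(trace, CaTrace) else np.asarray(trace, float)
    b = np.diff(x, axis=0)                       # bond vectors, (N-1, 3)
    d = np.linalg.norm(b, axis=1)
    if np.any(d == 0):
        raise ValueError("coincident consecutive beads")

    u = b / d[:, None]
    cos_t = -np.einsum("ij,ij->i", u[:-1], u[1:])
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))

    # dihedrals via the atan2 formulation (numerically stable, signed)
    b1, b2, b3 = b[:-2], b[1:-1], b[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=1)
    n2n = np.linalg.norm(n2, axis=1)
    degenerate = (n1n < 1e-10 * d[:-2] * d[1:-1]) | (n2n < 1e-10 * d[1:-1] * d[2:])
    if np.any(degenerate):
        i = int(np.argmax(degenerate))
        raise ValueError(
            f"dihedral undefined: three collinear consecutive beads starting "
            f"at index {i if n1n[i] < n2n[i] else i + 1}")
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    # minus sign selects the right-handed (IUPAC) convention: a right-handed
    # helix has positive φ
    phi = np.arctan2(-np.einsum("ij,ij->i", m, n2),
                     np.einsum("ij,ij->i", n1, n2))
    # range (−π, π]: map −π to +π
    phi = np.where(np.isclose(phi, -np.pi), np.pi, phi)
    return InternalCoordinates(d, theta, phi)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-RMSD rigid superposition of ``mobile`` onto ``reference``.

    Uses the SVD formulation with the determinant sign correction, so only
    proper rotations (det = +1) are returned; mirror images are never
    matched by a reflection.

    Returns
    -------
    aligned : (N, 3) array
        ``mobile @ R.T + t``.
    rotation : (3, 3) array
    translation : (3,) array
    rmsd : float
        √((1/N) Σ |r_i − r_i^ref|²) after superposition.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    aligned = P @ R.T + t
    val = float(np.sqrt(np.mean(np.sum((aligned - Q) ** 2, axis=1))))
    return aligned, R, t, val


def rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (convenience wrapper)."""
    return kabsch_superpose(mobile, reference)[3]


# ---------------------------------------------------------------------------
# Trajectory I/O (multi-model PDB and XYZ)
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f in ("pdb", "xyz"):
            return f
        raise ValueError(f"unknown trajectory format {fmt!r}; use 'pdb' or 'xyz'")
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer trajectory format from {path!r}")


def write_trajectory(frames, path, fmt: str | None = None,
                     residue_names=None, residue_ids=None) -> None:
    """Write coordinate frames as multi-model PDB or XYZ.

    ``frames`` is a sequence of (N, 3) arrays (or CaTraces).  XYZ files carry
    6 decimals and the element column "CA"; PDB carries the format's native 3
    decimals with one MODEL/ENDMDL block per frame.
    """
    frames = [f.coords if isinstance(f, CaTrace) else np.asarray(f, float)
              for f in frames]
    if not frames:
        raise ValueError("empty frame list")
    n = frames[0].shape[0]
    if any(f.shape != (n, 3) for f in frames):
        raise ValueError("all frames must share the same (N, 3) shape")
    fmt = _infer_format(path, fmt)
    if residue_names is None:
        residue_names = ["ALA"] * n
    if residue_ids is None:
        residue_ids = list(range(1, n + 1))

    with open(path, "w") as fh:
        if fmt == "xyz":
            for x in frames:
                fh.write(f"{n}\nmcgpath Cα trace frame\n")
                for row in x:
                    fh.write(f"CA {row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")
        else:
            for imodel, x in enumerate(frames, start=1):
                fh.write(f"MODEL {imodel:8d}\n")
                for i, row in enumerate(x):
                    fh.write(
                        "ATOM  {serial:5d}  CA  {res:<3s} A{resid:4d}    "
                        "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                        .format(serial=i + 1, res=residue_names[i][:3],
                                resid=residue_ids[i], x=row[0], y=row[1],
                                z=row[2]))
                fh.write("ENDMDL\n")
            fh.write("END\n")


def read_trajectory(path, fmt: str | None = None) -> list[np.ndarray]:
    """Read a trajectory written by :func:`write_trajectory`.

    Returns a list of (N, 3) coordinate arrays.
    """
    fmt = _infer_format(path, fmt)
    frames: list[np.ndarray] = []
    if fmt == "xyz":
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i].split()[0])
            block = lines[i + 2:i + 2 + n]
            frames.append(np.array(
                [[float(v) for v in ln.split()[1:4]] for ln in block]))
            i += 2 + n
    else:
        current: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                rec = line[:6]
                if rec == "MODEL ":
                    current = []
                elif rec in ("ATOM  ", "HETATM") and line[12:16].strip() == "CA":
                    current.append([float(line[30:38]), float(line[38:46]),
                                    float(line[46:54])])
                elif rec.startswith("ENDMDL"):
                    frames.append(np.array(current))
                    current = []
        if not frames and current:  # single-model file without MODEL records
            frames.append(np.array(current))
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def write_pdb(trace: CaTrace, path) -> None:
    """Write one CaTrace as a single-model PDB file."""
    write_trajectory([trace.coords], path, fmt="pdb",
                     residue_names=trace.residue_names,
                     residue_ids=trace.residue_ids)
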