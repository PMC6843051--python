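"""Numba kernels: force-field evaluation and the Langevin integrator.

All numerical heavy lifting lives here as ``@njit`` functions operating on
plain arrays; :mod:`mcgpath.forcefield` and :mod:`mcgpath.dynamics` provide
the typed, validated API on top.

Unit system: Å / ps / amu, energies in kcal/mol.  One amu·Å²/ps² equals
exactly 10 J/mol, hence the conversion constant below.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: kcal/mol per internal energy unit (amu Å² ps⁻²)
KCAL_PER_INTERNAL = 10.0 / 4184.0
#: Boltzmann constant, kcal/(mol K)
KB = 1.9872041e-3
#: evaluation cutoff for the generic non-local Morse term (Å); the potential
#: is truncated and shifted to zero here (the shift is ~2e-6 kcal/mol)
NONLOCAL_EVAL_CUTOFF = 25.0


@njit(cache=True)
def _morse(r, eps, alpha, r0):
    e = np.exp(-alpha * (r - r0))
    return eps * ((e - 1.0) ** 2 - 1.0)


@njit(cache=True)
def _morse_dudr(r, eps, alpha, r0):
    e = np.exp(-alpha * (r - r0))
    return 2.0 * eps * (e - 1.0) * (-alpha * e)


@njit(cache=True)
def energy_forces(x,
                  bond_idx, bond_d0, bond_k,
                  ang_idx, ang_cos0, ang_k,
                  dih_idx, dih_phi0, dih_amp,
                  loc_idx, loc_r0, loc_eps, loc_alpha,
                  nl_idx, nl_r0, nl_eps, nl_alpha,
                  forces):
    """Evaluate all force-field terms; fill ``forces`` with −∇U.

    Returns the tuple ``(e_bond, e_angle, e_dihedral, e_local, e_nonlocal)``
    in kcal/mol.  ``bond_k`` = 0 disables the harmonic bond restraint (the
    constraint-dynamics mode, where bonds are holonomic).
    """
    n = x.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    e_bond = 0.0
    if bond_k > 0.0:
        for b in range(bond_idx.shape[0]):
            i = bond_idx[b, 0]
            j = bond_idx[b, 1]
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dev = r - bond_d0[b]
            e_bond += 0.5 * bond_k * dev * dev
            f = -bond_k * dev / r
            forces[j, 0] += f * dx
            forces[j, 1] += f * dy
            forces[j, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz

    # harmonic-cosine bond angles: u = ½ kθ (cosθ − cosθ0)²
    e_ang = 0.0
    for a in range(ang_idx.shape[0]):
        i = ang_idx[a, 0]
        j = ang_idx[a, 1]
        k = ang_idx[a, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        dot = ux * vx + uy * vy + uz * vz
        ct = dot / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        diff = ct - ang_cos0[a]
        e_ang += 0.5 * ang_k[a] * diff * diff
        g = ang_k[a] * diff  # dU/d cosθ
        # ∇_i cosθ and ∇_k cosθ
        gix = (vx / (nu * nv)) - ct * ux / (nu * nu)
        giy = (vy / (nu * nv)) - ct * uy / (nu * nu)
        giz = (vz / (nu * nv)) - ct * uz / (nu * nu)
        gkx = (ux / (nu * nv)) - ct * vx / (nv * nv)
        gky = (uy / (nu * nv)) - ct * vy / (nv * nv)
        gkz = (uz / (nu * nv)) - ct * vz / (nv * nv)
        forces[i, 0] -= g * gix
        forces[i, 1] -= g * giy
        forces[i, 2] -= g * giz
        forces[k, 0] -= g * gkx
        forces[k, 1] -= g * gky
        forces[k, 2] -= g * gkz
        forces[j, 0] += g * (gix + gkx)
        forces[j, 1] += g * (giy + gky)
        forces[j, 2] += g * (giz + gkz)

    # dihedrals: u = A [1 − cos(φ − φ0)]
    e_dih = 0.0
    for d in range(dih_idx.shape[0]):
        i = dih_idx[d, 0]
        j = dih_idx[d, 1]
        k = dih_idx[d, 2]
        l = dih_idx[d, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]
        b2y = x[k, 1] - x[j, 1]
        b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]
        b3y = x[l, 1] - x[k, 1]
        b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        # φ = atan2(−(n1 × b2)·n2 / |b2|, n1·n2): right-handed (IUPAC) signed
        # dihedral, matching structures.compute_internal_coords
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        yy = -(mx * n2x + my * n2y + mz * n2z) / nb2
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yy, xx)
        dphi = phi - dih_phi0[d]
        e_dih += dih_amp[d] * (1.0 - np.cos(dphi))
        dudphi = dih_amp[d] * np.sin(dphi)
        # gradients of φ (standard four-site formulas)
        c1 = -nb2 / n1sq
        gi_x = c1 * n1x
        gi_y = c1 * n1y
        gi_z = c1 * n1z
        c4 = nb2 / n2sq
        gl_x = c4 * n2x
        gl_y = c4 * n2y
        gl_z = c4 * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gj_x = -(1.0 + s12) * gi_x + s32 * gl_x
        gj_y = -(1.0 + s12) * gi_y + s32 * gl_y
        gj_z = -(1.0 + s12) * gi_z + s32 * gl_z
        gk_x = s12 * gi_x - (1.0 + s32) * gl_x
        gk_y = s12 * gi_y - (1.0 + s32) * gl_y
        gk_z = s12 * gi_z - (1.0 + s32) * gl_z
        forces[i, 0] -= dudphi * gi_x
        forces[i, 1] -= dudphi * gi_y
        forces[i, 2] -= dudphi * gi_z
        forces[j, 0] -= dudphi * gj_x
        forces[j, 1] -= dudphi * gj_y
        forces[j, 2] -= dudphi * gj_z
        forces[k, 0] -= dudphi * gk_x
        forces[k, 1] -= dudphi * gk_y
        forces[k, 2] -= dudphi * gk_z
        forces[l, 0] -= dudphi * gl_x
        forces[l, 1] -= dudphi * gl_y
        forces[l, 2] -= dudphi * gl_z

    # structure-biased local Morse pairs
    e_loc = 0.0
    for p in range(loc_idx.shape[0]):
        i = loc_idx[p, 0]
        j = loc_idx[p, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e_loc += _morse(r, loc_eps[p], loc_alpha[p], loc_r0[p])
        f = -_morse_dudr(r, loc_eps[p], loc_alpha[p], loc_r0[p]) / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    # generic non-local Morse pairs (truncated & shifted at the eval cutoff)
    e_nl = 0.0
    rc = NONLOCAL_EVAL_CUTOFF
    u_shift = _morse(rc, nl_eps, nl_alpha, nl_r0)
    for p in range(nl_idx.shape[0]):
        i = nl_idx[p, 0]
        j = nl_idx[p, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rc:
            continue
        e_nl += _morse(r, nl_eps, nl_alpha, nl_r0) - u_shift
        f = -_morse_dudr(r, nl_eps, nl_alpha, nl_r0) / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    return e_bond, e_ang, e_dih, e_loc, e_nl


@njit(cache=True)
def shake(x, bond_idx, bond_d0, invm, tol, max_iter):
    """Iteratively restore all bond lengths to d0 (Gauss–Seidel sweeps).

    Corrections are mass-weighted and applied along the current bond
    direction.  Returns the number of sweeps used (== max_iter + 1 when the
    tolerance was not reached).
    """
    nb = bond_idx.shape[0]
    for it in range(max_iter):
        max_dev = 0.0
        for b in range(nb):
            i = bond_idx[b, 0]
            j = bond_idx[b, 1]
            rx = x[j, 0] - x[i, 0]
            ry = x[j, 1] - x[i, 1]
            rz = x[j, 2] - x[i, 2]
            r2 = rx * rx + ry * ry + rz * rz
            d0 = bond_d0[b]
            diff = r2 - d0 * d0
            dev = abs(np.sqrt(r2) - d0)
            if dev > max_dev:
                max_dev = dev
            g = diff / (2.0 * r2 * (invm[i] + invm[j]))
            x[i, 0] += g * invm[i] * rx
            x[i, 1] += g * invm[i] * ry
            x[i, 2] += g * invm[i] * rz
            x[j, 0] -= g * invm[j] * rx
            x[j, 1] -= g * invm[j] * ry
            x[j, 2] -= g * invm[j] * rz
        if max_dev < tol:
            return it + 1
    return max_iter + 1


@njit(cache=True)
def rattle_velocities(x, v, bond_idx, invm, tol, max_iter):
    """Project velocities onto the constraint manifold (r_ij · v_ij = 0)."""
    nb = bond_idx.shape[0]
    for it in range(max_iter):
        max_dev = 0.0
        for b in range(nb):
            i = bond_idx[b, 0]
            j = bond_idx[b, 1]
            rx = x[j, 0] - x[i, 0]
            ry = x[j, 1] - x[i, 1]
            rz = x[j, 2] - x[i, 2]
            r2 = rx * rx + ry * ry + rz * rz
            vx = v[j, 0] - v[i, 0]
            vy = v[j, 1] - v[i, 1]
            vz = v[j, 2] - v[i, 2]
            rv = rx * vx + ry * vy + rz * vz
            dev = abs(rv) / np.sqrt(r2)
            if dev > max_dev:
                max_dev = dev
            g = rv / (r2 * (invm[i] + invm[j]))
            v[i, 0] += g * invm[i] * rx
            v[i, 1] += g * invm[i] * ry
            v[i, 2] += g * invm[i] * rz
            v[j, 0] -= g * invm[j] * rx
            v[j, 1] -= g * invm[j] * ry
            v[j, 2] -= g * invm[j] * rz
        if max_dev < tol:
            return it + 1
    return max_iter + 1


@njit(cache=True)
def run_baoab(x, v, masses, dt, gamma, temperature, n_steps, dump_interval,
              seed, ndof,
              bond_idx, bond_d0, bond_k,
              ang_idx, ang_cos0, ang_k,
              dih_idx, dih_phi0, dih_amp,
              loc_idx, loc_r0, loc_eps, loc_alpha,
              nl_idx, nl_r0, nl_eps, nl_alpha,
              use_constraints, constraint_tol, max_shake_iter,
              out_coords, out_vels, out_energies, out_kin_t):
    """BAOAB Langevin integration with optional holonomic bond constraints.

    Splitting per step: B(dt/2) A(dt/2) O(dt) A(dt/2) B(dt/2), with SHAKE
    after each drift and a velocity projection after each kick / OU update
    (the constrained-BAOAB scheme).  ``x`` and ``v`` are modified in place;
    dumped frames (including the initial one) go into the ``out_*`` arrays.

    Returns −1 on success, or the 1-based step number at which coordinates
    became non-finite.
    """
    np.random.seed(seed)
    n = x.shape[0]
    invm = 1.0 / masses
    half = 0.5 * dt

    kT_int = KB * temperature / KCAL_PER_INTERNAL  # amu Å²/ps²
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    vtol = 1e-10

    forces = np.zeros((n, 3))
    eb, ea, ed, el, en = energy_forces(
        x, bond_idx, bond_d0, bond_k, ang_idx, ang_cos0, ang_k,
        dih_idx, dih_phi0, dih_amp, loc_idx, loc_r0, loc_eps, loc_alpha,
        nl_idx, nl_r0, nl_eps, nl_alpha, forces)

    # initial frame
    idump = 0
    for i in range(n):
        for c in range(3):
            out_coords[idump, i, c] = x[i, c]
            out_vels[idump, i, c] = v[i, c]
    out_energies[idump, 0] = eb
    out_energies[idump, 1] = ea
    out_energies[idump, 2] = ed
    out_energies[idump, 3] = el
    out_energies[idump, 4] = en
    ke = 0.0
    for i in range(n):
        ke += 0.5 * masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
    out_kin_t[idump] = 2.0 * ke * KCAL_PER_INTERNAL / (ndof * KB)
    idump += 1

    for step in range(1, n_steps + 1):
        # B: half kick
        fscale = half / KCAL_PER_INTERNAL
        for i in range(n):
            for c in range(3):
                v[i, c] += fscale * invm[i] * forces[i, c]
        if use_constraints:
            rattle_velocities(x, v, bond_idx, invm, vtol, max_shake_iter)
        # A: half drift
        if use_constraints:
            for i in range(n):
                for c in range(3):
                    x[i, c] += half * v[i, c]
            xs = x.copy()
            shake(x, bond_idx, bond_d0, invm, constraint_tol, max_shake_iter)
            for i in range(n):
                for c in range(3):
                    v[i, c] += (x[i, c] - xs[i, c]) / half
        else:
            for i in range(n):
                for c in range(3):
                    x[i, c] += half * v[i, c]
        # O: Ornstein–Uhlenbeck velocity update
        if gamma > 0.0:
            for i in range(n):
                sd = np.sqrt(kT_int * invm[i])
                for c in range(3):
                    v[i, c] = c1 * v[i, c] + c2 * sd * np.random.standard_normal()
            if use_constraints:
                rattle_velocities(x, v, bond_idx, invm, vtol, max_shake_iter)
        # A: half drift
        if use_constraints:
            for i in range(n):
                for c in range(3):
                    x[i, c] += half * v[i, c]
            xs = x.copy()
            shake(x, bond_idx, bond_d0, invm, constraint_tol, max_shake_iter)
            for i in range(n):
                for c in range(3):
                    v[i, c] += (x[i, c] - xs[i, c]) / half
        else:
            for i in range(n):
                for c in range(3):
                    x[i, c] += half * v[i, c]
        # force refresh + B: half kick
        eb, ea, ed, el, en = energy_forces(
            x, bond_idx, bond_d0, bond_k, ang_idx, ang_cos0, ang_k,
            dih_idx, dih_phi0, dih_amp, loc_idx, loc_r0, loc_eps, loc_alpha,
            nl_idx, nl_r0, nl_eps, nl_alpha, forces)
        for i in range(n):
            for c in range(3):
                v[i, c] += fscale * invm[i] * forces[i, c]
        if use_constraints:
            rattle_velocities(x, v, bond_idx, invm, vtol, max_shake_iter)

        blown = False
        for i in range(n):
            for c in range(3):
                if not np.isfinite(x[i, c]):
                    blown = True
        if blown:
            return step

        if step % dump_interval == 0:
            for i in range(n):
                for c in range(3):
                    out_coords[idump, i, c] = x[i, c]
                    out_vels[idump, i, c] = v[i, c]
            out_energies[idump, 0] = eb
            out_energies[idump, 1] = ea
            out_energies[idump, 2] = ed
            out_energies[idump, 3] = el
            out_energies[idump, 4] = en
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (
                    v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
            out_kin_t[idump] = 2.0 * ke * KCAL_PER_INTERNAL / (ndof * KB)
            idump += 1

    return -1
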