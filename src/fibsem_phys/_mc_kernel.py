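"""Numba kernel for the single-scattering electron Monte Carlo.

Units inside the kernel: positions nm, energies keV, cross sections cm^2,
number densities cm^-3.  The sample surface is the plane z = 0; the sample
occupies z > 0 and the beam starts at the surface heading in +z.

The physics is the classic low-voltage SEM single-scattering scheme:
exponential free paths from the total elastic mean free path (by default the
Browning empirical fit to Mott data, which stays accurate for high-Z targets
below ~2 keV; optionally pure screened Rutherford), screened-Rutherford
elastic deflections, and continuous Joy-Luo (modified Bethe) energy loss
between scattering events.
"""

import math

import numpy as np
from numba import njit

E_MIN_KEV = 0.05  # electrons below this are counted as absorbed
MAX_STEPS = 10_000
_BOUND_EPS = 1e-6  # nm nudge across region boundaries


@njit(cache=True, inline="always")
def _sigma_rutherford(Z2: float, Z067: float, E: float) -> float:
    """Screened-Rutherford total elastic cross section, cm^2 (E in keV)."""
    alpha = 3.4e-3 * Z067 / E
    rel = (E + 511.0) / (E + 1024.0)
    return 5.21e-21 * Z2 / (E * E) * 4.0 * math.pi / (alpha * (1.0 + alpha)) * rel * rel


@njit(cache=True, inline="always")
def _sigma_browning(Z17: float, Z2: float, E: float) -> float:
    """Browning empirical total elastic cross section (Mott-data fit), cm^2."""
    return 3.0e-18 * Z17 / (
        E + 0.005 * Z17 * math.sqrt(E) + 0.0007 * Z2 / math.sqrt(E))


@njit(cache=True, inline="always")
def _stopping_nm(rho: float, f: np.ndarray, J: np.ndarray, k0: int, k1: int,
                 E: float) -> float:
    """Joy-Luo stopping power in keV/nm for one material (elements k0..k1)."""
    s = 0.0
    for k in range(k0, k1):
        s += f[k] * math.log(1.166 * (E + 0.85 * J[k]) / J[k])
    return 78500.0 * rho / E * s * 1e-7


@njit(cache=True)
def run_trajectories(
    seed,
    n,
    E0,
    x0,
    y0,
    beam_sigma,
    regions,      # (R, 5): xlo, xhi, zlo, zhi, material index
    mat_offsets,  # (M+1,) element-slab offsets per material
    elem_Z2,      # (K,) Z^2
    elem_Z067,    # (K,) Z^0.67
    elem_Z17,     # (K,) Z^1.7
    elem_J,       # (K,) mean ionization potential, keV
    elem_nd,      # (K,) number density, atoms/cm^3
    elem_f,       # (K,) weight_fraction * Z / A (stopping-power factor)
    mat_rho,      # (M,) g/cm^3
    use_browning, # 1: Browning total cross section for free paths, 0: Rutherford
):
    """Trace ``n`` primaries; return backscatter records and status counters."""
    np.random.seed(seed)

    exit_E = np.empty(n, dtype=np.float64)
    exit_theta = np.empty(n, dtype=np.float64)
    exit_x = np.empty(n, dtype=np.float64)
    exit_y = np.empty(n, dtype=np.float64)
    max_depth = np.empty(n, dtype=np.float64)
    n_back = 0
    n_capped = 0
    geom_error = 0

    nreg = regions.shape[0]
    inv_mfp = np.empty(elem_Z2.shape[0], dtype=np.float64)

    for _ in range(n):
        if beam_sigma > 0.0:
            x = x0 + beam_sigma * np.random.standard_normal()
            y = y0 + beam_sigma * np.random.standard_normal()
        else:
            x = x0
            y = y0
        z = 1e-9  # just inside the sample
        ux = 0.0
        uy = 0.0
        uz = 1.0
        E = E0
        zmax = 0.0
        steps = 0

        while True:
            steps += 1
            if steps > MAX_STEPS:
                n_capped += 1
                break

            # region lookup
            reg = -1
            for r in range(nreg):
                if (regions[r, 0] <= x < regions[r, 1]
                        and regions[r, 2] <= z < regions[r, 3]):
                    reg = r
                    break
            if reg < 0:
                geom_error += 1
                break
            m = int(regions[reg, 4])
            k0 = mat_offsets[m]
            k1 = mat_offsets[m + 1]

            # total inverse elastic mean free path (cm^-1) in this material
            tot = 0.0
            for k in range(k0, k1):
                if use_browning:
                    sig = _sigma_browning(elem_Z17[k], elem_Z2[k], E)
                else:
                    sig = _sigma_rutherford(elem_Z2[k], elem_Z067[k], E)
                v = elem_nd[k] * sig
                inv_mfp[k] = v
                tot += v
            lam_nm = 1e7 / tot

            s = -lam_nm * math.log(1.0 - np.random.random())

            # distance to the current region boundary along the direction
            t_bound = 1e30
            if ux > 0.0:
                t = (regions[reg, 1] - x) / ux
                if t < t_bound:
                    t_bound = t
            elif ux < 0.0:
                t = (regions[reg, 0] - x) / ux
                if t < t_bound:
                    t_bound = t
            if uz > 0.0:
                t = (regions[reg, 3] - z) / uz
                if t < t_bound:
                    t_bound = t
            elif uz < 0.0:
                t = (regions[reg, 2] - z) / uz
                if t < t_bound:
                    t_bound = t

            hit_boundary = t_bound < s
            d = t_bound if hit_boundary else s

            # continuous energy loss over the segment
            dE = _stopping_nm(mat_rho[m], elem_f, elem_J, k0, k1, E) * d
            if E - dE <= E_MIN_KEV:
                break  # absorbed
            E -= dE

            x += ux * d
            y += uy * d
            z += uz * d
            if z > zmax:
                zmax = z

            if z <= 1e-12 and uz < 0.0:
                # crossed the entrance surface heading out: backscattered
                exit_E[n_back] = E
                exit_theta[n_back] = math.degrees(math.acos(-uz))
                exit_x[n_back] = x
                exit_y[n_back] = y
                max_depth[n_back] = zmax
                n_back += 1
                break

            if hit_boundary:
                # step truncated at an internal boundary: nudge across and
                # resample the free path in the new material (no deflection)
                x += ux * _BOUND_EPS
                y += uy * _BOUND_EPS
                z += uz * _BOUND_EPS
                continue

            # elastic scattering event: pick the scatterer ~ n_i * sigma_i
            pick = np.random.random() * tot
            acc = 0.0
            ksel = k1 - 1
            for k in range(k0, k1):
                acc += inv_mfp[k]
                if pick <= acc:
                    ksel = k
                    break

            alpha = 3.4e-3 * elem_Z067[ksel] / E
            R = np.random.random()
            ct = 1.0 - 2.0 * alpha * R / (1.0 + alpha - R)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)

            if abs(uz) > 0.999999:
                sgn = 1.0 if uz > 0.0 else -1.0
                ux = st * cp
                uy = st * sp
                uz = sgn * ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                nx = ux * ct + st * (ux * uz * cp - uy * sp) / den
                ny = uy * ct + st * (uy * uz * cp + ux * sp) / den
                nz = uz * ct - den * st * cp
                norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                ux = nx / norm
                uy = ny / norm
                uz = nz / norm

    return (exit_E[:n_back], exit_theta[:n_back], exit_x[:n_back],
            exit_y[:n_back], max_depth[:n_back], n_capped, geom_error)
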