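"""Detector model for backscattered electrons.

A positively biased sample turns the in-column detector into an effective
backscatter detector: the bias forms an axial potential barrier that rejects
slow secondary electrons, while the objective-lens geometry only accepts
exits within a maximum polar angle.  Full ray tracing of the acceptance
region is approximated here by the separable rule

    detected  <=>  exit angle <= max_polar_angle  AND  exit energy > E_cut(bias)

with E_cut = max(0, bias - offset); the 45-degree angular threshold is itself
a good approximation of the traced cut-off.  A user-supplied energy x angle
lookup table can replace the separable rule.

The module also inverts detected contrast to osmium stain concentration
against a heavy-metal reference compound via a Monte Carlo calibration sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from fibsem_phys import scatter_mc
from fibsem_phys.materials import (
    get_material,
    make_stained_lipid,
    weight_fraction,
)


class EmptySetError(ValueError):
    """Efficiency is undefined on an empty backscatter set."""


@dataclass(frozen=True)
class AcceptanceMask:
    """Separable detector acceptance: angular cut plus bias energy cutoff.

    ``energy_cutoff_offset`` is the calibratable offset (in volts) between the
    applied sample bias and the effective low-energy cutoff; the default 550 V
    makes a +600 V bias block <= 50 eV electrons (secondaries) while biases up
    to +400 V block nothing.
    """

    max_polar_angle: float = 45.0   # degrees
    bias_voltage: float = 600.0     # V
    energy_cutoff_offset: float = 550.0  # V

    def __post_init__(self) -> None:
        if not (0.0 < self.max_polar_angle <= 90.0):
            raise ValueError("max_polar_angle must be in (0, 90] degrees")
        if not (-1000.0 <= self.bias_voltage <= 1000.0):
            raise ValueError("bias_voltage must be within +-1000 V")

    def detected(self, exit_energy_kev, exit_angle_deg) -> np.ndarray:
        """Boolean mask of detected electrons (energies keV, angles degrees)."""
        e_cut_kev = bias_energy_cutoff(self) * 1e-3
        return (np.asarray(exit_angle_deg) <= self.max_polar_angle) & (
            np.asarray(exit_energy_kev) > e_cut_kev)


def bias_energy_cutoff(mask: AcceptanceMask) -> float:
    """Minimum detectable exit energy in eV: max(0, bias - offset)."""
    return max(0.0, mask.bias_voltage - mask.energy_cutoff_offset)


@dataclass(frozen=True)
class TabulatedAcceptance:
    """Acceptance from an (energy_eV, angle_deg, detected) lookup grid.

    Rows come from e.g. an electron-optics ray-tracing run exported as CSV
    with columns ``energy_eV, angle_deg, detected``; lookups snap to the
    nearest grid node.
    """

    energy_ev: np.ndarray
    angle_deg: np.ndarray
    table: np.ndarray  # (n_energy, n_angle) of 0/1

    @classmethod
    def from_csv(cls, path: str | Path) -> "TabulatedAcceptance":
        raw = np.genfromtxt(path, delimiter=",", names=True)
        raw = np.atleast_1d(raw)
        e = np.unique(raw["energy_eV"])
        a = np.unique(raw["angle_deg"])
        tab = np.zeros((e.size, a.size))
        ei = np.searchsorted(e, raw["energy_eV"])
        ai = np.searchsorted(a, raw["angle_deg"])
        tab[ei, ai] = raw["detected"]
        return cls(e, a, tab)

    def detected(self, exit_energy_kev, exit_angle_deg) -> np.ndarray:
        e = np.atleast_1d(np.asarray(exit_energy_kev, dtype=float)) * 1e3
        a = np.atleast_1d(np.asarray(exit_angle_deg, dtype=float))
        ei = np.clip(np.searchsorted(self.energy_ev, e), 0, self.energy_ev.size - 1)
        ai = np.clip(np.searchsorted(self.angle_deg, a), 0, self.angle_deg.size - 1)
        return self.table[ei, ai] > 0.5


def detection_efficiency(bset: scatter_mc.BackscatterSet,
                         mask: AcceptanceMask) -> float:
    """Fraction of backscattered electrons accepted by the detector mask."""
    if bset.n_backscattered == 0:
        raise EmptySetError("no backscattered electrons in the set")
    keep = mask.detected(bset.exit_energy, bset.exit_angle)
    return float(np.count_nonzero(keep)) / bset.n_backscattered


def detected_signal(n_primary: float, backscatter_yield: float,
                    efficiency: float) -> float:
    """Expected detected electrons = primaries x yield x efficiency."""
    if n_primary < 0 or backscatter_yield < 0 or efficiency < 0:
        raise ValueError("inputs must be non-negative")
    return n_primary * backscatter_yield * efficiency


#: Parametric secondary-electron yield at zero bias (no cascade physics);
#: secondaries vanish once the bias cutoff exceeds their ~50 eV energies.
SECONDARY_YIELD_AT_ZERO_BIAS = 1.0


def secondary_yield(mask: AcceptanceMask,
                    delta_se: float = SECONDARY_YIELD_AT_ZERO_BIAS) -> float:
    """Parametric secondary-electron contribution under a given bias."""
    return 0.0 if bias_energy_cutoff(mask) >= 50.0 else delta_se


def combine_detectors(signal_a, signal_b, var_a: float, var_b: float):
    """Inverse-variance weighted average of two detector channels.

    The combined per-pixel variance 1/(1/var_a + 1/var_b) is never larger
    than the better channel's.  Accepts bare arrays or ImageGrid-likes with a
    ``values`` attribute (returned type follows input a).
    """
    a = getattr(signal_a, "values", signal_a)
    b = getattr(signal_b, "values", signal_b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if var_a <= 0 or var_b <= 0:
        raise ValueError("variances must be positive")
    wa = 1.0 / var_a
    wb = 1.0 / var_b
    out = (wa * a + wb * b) / (wa + wb)
    if hasattr(signal_a, "values"):
        from dataclasses import replace
        return replace(signal_a, values=out)
    return out


def combined_variance(var_a: float, var_b: float) -> float:
    return 1.0 / (1.0 / var_a + 1.0 / var_b)


# ---------------------------------------------------------------------------
# Stain-concentration calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StainCalibration:
    """Monte Carlo calibration curve: x_os -> detected contrast vs epoxy."""

    x_os: np.ndarray
    contrast: np.ndarray          # detected contrast vs epoxy, monotone in x_os
    os_weight_fraction: np.ndarray
    landing_energy: float
    mask: AcceptanceMask


def build_stain_calibration(E: float, mask: AcceptanceMask,
                            x_grid=(0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
                            n: int = 50_000, seed: int = 0) -> StainCalibration:
    """Sweep stained-lipid osmium loading and record detected contrast vs epoxy.

    The forward curve underpinning :func:`infer_stain_fraction`; built at the
    same landing energy and detector mask as the measurement to invert.
    """
    epoxy = get_material("epoxy")
    xs = np.asarray(sorted(x_grid), dtype=float)
    contrasts = np.empty(xs.size)
    wfs = np.empty(xs.size)
    for i, x in enumerate(xs):
        lipid = make_stained_lipid(float(x))
        _, _, c = scatter_mc.contrast_pair(lipid, epoxy, E, mask=mask, n=n,
                                           seed=seed + 101 * i)
        contrasts[i] = c
        wfs[i] = weight_fraction(lipid, "Os")
    return StainCalibration(xs, contrasts, wfs, E, mask)


def infer_stain_fraction(measured_contrast_vs_epoxy: float,
                         calibration: StainCalibration):
    """Invert a measured membrane-vs-epoxy contrast to osmium concentration.

    Returns ``(os_weight_fraction, x_os)`` by monotone interpolation of the
    calibration curve; raises if the contrast falls outside the curve.
    """
    c = calibration.contrast
    if not (c.min() - 1e-12 <= measured_contrast_vs_epoxy <= c.max() + 1e-12):
        raise ValueError(
            f"contrast {measured_contrast_vs_epoxy:.4f} outside calibration "
            f"range [{c.min():.4f}, {c.max():.4f}]")
    # enforce strict monotonicity against Monte Carlo jitter
    c_mono = np.maximum.accumulate(c)
    x = float(np.interp(measured_contrast_vs_epoxy, c_mono, calibration.x_os))
    wf = float(np.interp(x, calibration.x_os, calibration.os_weight_fraction))
    return wf, x
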