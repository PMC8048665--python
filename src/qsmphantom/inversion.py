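"""Closed-form baseline dipole inversions: TKD and Tikhonov-gradient L2.

Both invert the k-space relation F(k) = D(k) X(k).  TKD divides by D where
|D| exceeds a threshold t and clamps the inverse filter to 1/(t sign(D))
elsewhere (sign-preserving amplitude clamp).  The closed-form L2 solution
minimises ||D X - F||^2 + lambda ||G X||^2 with G the first-difference
gradient operator, giving X = D F / (D^2 + lambda |G|^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import FieldMap, dipole_kernel
from .phantom import SusceptibilityVolume

__all__ = ["InversionConfig", "invert_tkd", "invert_l2", "gradient_spectrum", "sweep_inversion"]


@dataclass
class InversionConfig:
    method: str = "tkd"  # "tkd" | "l2"
    threshold: float = 0.2
    lam: float = 1e-2

    def __post_init__(self):
        if self.method not in ("tkd", "l2"):
            raise ValueError(f"unknown inversion method {self.method!r}")
        if not 0.0 < self.threshold <= 2.0 / 3.0:
            raise ValueError("TKD threshold must lie in (0, 2/3]")
        if self.lam <= 0:
            raise ValueError("L2 lambda must be positive")


def _field_ppm(local_field: FieldMap | np.ndarray, spacing):
    if isinstance(local_field, FieldMap):
        return local_field.in_unit("ppm"), local_field.spacing
    return np.asarray(local_field, dtype=np.float64), spacing


def gradient_spectrum(shape) -> np.ndarray:
    """|G(k)|^2 of the 3-D first-difference gradient operator."""
    out = np.zeros(shape)
    for axis, n in enumerate(shape):
        f = np.fft.fftfreq(n)
        shp = [1] * len(shape)
        shp[axis] = n
        out = out + ((2.0 * np.sin(np.pi * f)) ** 2).reshape(shp)
    return out


def invert_tkd(
    local_field: FieldMap | np.ndarray,
    config: InversionConfig | None = None,
    mask: np.ndarray | None = None,
    spacing=(1.0, 1.0, 1.0),
    b0_axis: int = 2,
) -> SusceptibilityVolume:
    """Truncated k-space division with sign-preserving amplitude clamping."""
    config = config or InversionConfig(method="tkd")
    f, spacing = _field_ppm(local_field, spacing)
    if mask is None:
        mask = np.ones(f.shape, dtype=bool)
    t = config.threshold
    d = dipole_kernel(f.shape, spacing, b0_axis=b0_axis)
    sign = np.where(d >= 0, 1.0, -1.0)
    dinv = np.where(np.abs(d) > t, 1.0 / np.where(d == 0, 1.0, d), 1.0 / (t * sign))
    chi = np.fft.ifftn(np.fft.fftn(f * mask) * dinv).real
    chi = np.where(mask, chi, 0.0)
    return SusceptibilityVolume(chi, "local", mask.astype(bool), spacing)


def invert_l2(
    local_field: FieldMap | np.ndarray,
    config: InversionConfig | None = None,
    mask: np.ndarray | None = None,
    spacing=(1.0, 1.0, 1.0),
    b0_axis: int = 2,
) -> SusceptibilityVolume:
    """Closed-form L2 (Tikhonov with gradient penalty) dipole inversion."""
    config = config or InversionConfig(method="l2")
    if config.lam <= 0:
        raise ValueError("L2 lambda must be positive")
    f, spacing = _field_ppm(local_field, spacing)
    if mask is None:
        mask = np.ones(f.shape, dtype=bool)
    d = dipole_kernel(f.shape, spacing, b0_axis=b0_axis)
    e = gradient_spectrum(f.shape)
    denom = d * d + config.lam * e
    denom[denom == 0] = 1.0  # k = 0: filter forced to 0 below
    filt = d / denom
    filt[(d == 0) & (e == 0)] = 0.0
    chi = np.fft.ifftn(np.fft.fftn(f * mask) * filt).real
    chi = np.where(mask, chi, 0.0)
    return SusceptibilityVolume(chi, "local", mask.astype(bool), spacing)


def sweep_inversion(
    local_field: FieldMap | np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray,
    method: str,
    grid,
    spacing=(1.0, 1.0, 1.0),
) -> tuple[list[float], list[SusceptibilityVolume]]:
    """nRMSE of the reconstruction for each regularisation value in ``grid``."""
    from .metrics import nrmse

    scores, recons = [], []
    for v in grid:
        if method == "tkd":
            cfg = InversionConfig(method="tkd", threshold=float(v))
            rec = invert_tkd(local_field, cfg, mask, spacing)
        else:
            cfg = InversionConfig(method="l2", lam=float(v))
            rec = invert_l2(local_field, cfg, mask, spacing)
        scores.append(nrmse(rec.chi, truth, mask))
        recons.append(rec)
    return scores, recons
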