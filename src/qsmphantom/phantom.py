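"""Ground-truth susceptibility composition from tissue labels and relaxometry.

The head phantom assigns each of 16 tissue classes a mean volume magnetic
susceptibility (ppm) and modulates it voxel-wise with the deviation of the
apparent relaxation rates from their tissue means::

    chi_tissue(r) = chi_mean + a * (R2*(r) - R2*_ref) + b * (R1(r) - R1_ref)

with ``a`` and ``b`` in ppm*s against rates in 1/s.  Partial voluming between
brain tissues is modelled by Gaussian-smoothing the binary tissue masks
(FWHM 1.2 voxels) and renormalising them into probability maps; the composed
map is the probability-weighted sum over tissues.  Near air-tissue interfaces
R2* is unreliable (static-field gradients inflate it), so a gradient-gated
blend falls back to the a=0 composition there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FWHM_TO_SIGMA",
    "TissueParamTable",
    "TissueModel",
    "ParameterMaps",
    "SusceptibilityVolume",
    "tissue_chi_map",
    "partial_volume_maps",
    "gradient_reliability_blend",
    "compose_chi",
    "localize_chi",
    "lowpass_gradient_magnitude",
    "build_tissue_model",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_TABLE_COLUMNS = (
    "name",
    "chi_mean",
    "a_tissue",
    "b_tissue",
    "is_brain_tissue",
    "is_piecewise_constant",
)


class TissueParamTable:
    """Per-label susceptibility parameters (chi_mean [ppm], a, b [ppm*s]).

    ``is_brain_tissue`` marks labels that participate in partial-volume
    smoothing; ``is_piecewise_constant`` forces a = b = 0 (bone, air, muscle,
    fat).  Two literature-derived models ship as package data.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "label" in df.columns:
            df = df.set_index("label")
        missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"tissue table is missing columns {missing}")
        if df.index.duplicated().any():
            raise ValueError("duplicate tissue labels in table")
        if not np.all(np.isfinite(df["chi_mean"].to_numpy(float))):
            raise ValueError("non-finite chi_mean in tissue table")
        df["is_brain_tissue"] = df["is_brain_tissue"].astype(bool)
        df["is_piecewise_constant"] = df["is_piecewise_constant"].astype(bool)
        pw = df["is_piecewise_constant"]
        df.loc[pw, ["a_tissue", "b_tissue"]] = 0.0
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "TissueParamTable":
        return cls(pd.read_csv(path))

    @classmethod
    def _from_package(cls, fname: str) -> "TissueParamTable":
        with resources.files("qsmphantom.data").joinpath(fname).open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def model1(cls) -> "TissueParamTable":
        return cls._from_package("chi_model1.csv")

    @classmethod
    def model2(cls) -> "TissueParamTable":
        return cls._from_package("chi_model2.csv")

    @property
    def labels(self) -> np.ndarray:
        return self.df.index.to_numpy()

    def row(self, label: int) -> pd.Series:
        try:
            return self.df.loc[label]
        except KeyError:
            raise KeyError(f"no tissue row for label {label}") from None

    def label_of(self, name: str) -> int:
        hit = self.df.index[self.df["name"] == name]
        if len(hit) != 1:
            raise KeyError(f"no unique tissue named {name!r}")
        return int(hit[0])

    def check_covers(self, labels: np.ndarray) -> None:
        present = np.unique(labels)
        present = present[present != 0]
        missing = sorted(set(present.tolist()) - set(self.labels.tolist()))
        if missing:
            raise KeyError(f"label volume contains labels without table rows: {missing}")


@dataclass
class ParameterMaps:
    """Co-registered quantitative maps on a common voxel grid.

    M0 in arbitrary signal units, R1 and R2* in 1/s, spacing in mm.  FA and
    the fiber-to-B0 angle (radians) are optional and only used by the
    white-matter microstructure term.
    """

    m0: np.ndarray
    r1: np.ndarray
    r2star: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fa: np.ndarray | None = None
    fiber_theta: np.ndarray | None = None

    def __post_init__(self):
        shape = self.m0.shape
        for attr in ("r1", "r2star", "fa", "fiber_theta"):
            vol = getattr(self, attr)
            if vol is not None and vol.shape != shape:
                raise ValueError(f"{attr} shape {vol.shape} != m0 shape {shape}")
        if np.any(self.r1 < 0) or np.any(self.r2star < 0):
            raise ValueError("relaxation rates must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.m0.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class TissueModel:
    """Label volume plus partial-volume probability maps and reference means."""

    labels: np.ndarray
    probability_maps: dict[int, np.ndarray]
    ref_r2star: dict[int, float]
    ref_r1: dict[int, float]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def ref_means(self, label: int) -> tuple[float, float]:
        """(R2*_ref, R1_ref) over the binary label mask."""
        return self.ref_r2star[label], self.ref_r1[label]


@dataclass
class SusceptibilityVolume:
    """A chi map in ppm, either whole-head or brain-only ('local', demeaned)."""

    chi: np.ndarray
    mode: str  # "whole_head" | "local"
    brain_mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.mode not in ("whole_head", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.chi.shape != self.brain_mask.shape:
            raise ValueError("chi and brain_mask shapes differ")
        self.spacing = tuple(float(s) for s in self.spacing)


def tissue_chi_map(
    params: ParameterMaps,
    table: TissueParamTable,
    tissue_id: int,
    ref_means: tuple[float, float],
    include_r2star: bool = True,
    dev_clip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Evaluate the modulated tissue susceptibility at every voxel (ppm).

    ``ref_means`` is (R2*_ref, R1_ref), the label-wise means of the same
    parameter maps.  ``include_r2star=False`` drops the a-term (used near
    strong field gradients where R2* cannot be trusted).  ``dev_clip``
    optionally bounds the (R2*, R1) deviations at absolute values, keeping
    the per-tissue law from extrapolating onto foreign compartments' rates
    (the counterpart of relaxometry-threshold boundary corrections on
    acquired segmentations).
    """
    row = table.row(tissue_id)
    r2s_ref, r1_ref = ref_means
    a = float(row["a_tissue"]) if include_r2star else 0.0
    b = float(row["b_tissue"])
    chi = np.full(params.shape, float(row["chi_mean"]))
    dev2 = params.r2star - r2s_ref
    dev1 = params.r1 - r1_ref
    if dev_clip is not None:
        dev2 = np.clip(dev2, -dev_clip[0], dev_clip[0])
        dev1 = np.clip(dev1, -dev_clip[1], dev_clip[1])
    if a != 0.0:
        chi += a * dev2
    if b != 0.0:
        chi += b * dev1
    return chi


def partial_volume_maps(
    labels: np.ndarray,
    brain_flags: Mapping[int, bool],
    fwhm_voxels: float = 1.2,
) -> dict[int, np.ndarray]:
    """Probability maps P_tissue from binary label masks.

    Brain-tissue masks are smoothed with a 3-D Gaussian of FWHM
    ``fwhm_voxels``; vein and non-brain masks pass through binary.  The
    output is renormalised so the per-voxel sum over tissues is 1.
    """
    sigma = fwhm_voxels * FWHM_TO_SIGMA
    smoothed: dict[int, np.ndarray] = {}
    if not any(brain_flags.get(int(lab), False) for lab in brain_flags):
        raise ValueError("at least one brain tissue is required")
    for lab in sorted(brain_flags):
        mask = (labels == lab).astype(np.float64)
        if not mask.any():
            warnings.warn(f"tissue label {lab} has an all-zero mask", stacklevel=2)
            smoothed[lab] = mask
            continue
        if brain_flags[lab]:
            # zero-padded edges: masks are compactly supported inside the grid
            mask = ndimage.gaussian_filter(mask, sigma=sigma, mode="constant", truncate=4.0)
        smoothed[lab] = mask
    total = np.zeros(labels.shape, dtype=np.float64)
    for s in smoothed.values():
        total += s
    nz = total > 0
    probs: dict[int, np.ndarray] = {}
    for lab, s in smoothed.items():
        p = np.zeros_like(s)
        p[nz] = s[nz] / total[nz]
        probs[lab] = p
    return probs


def gradient_reliability_blend(
    chi_full: np.ndarray,
    chi_no_r2star: np.ndarray,
    field_gradient_mag: np.ndarray,
    g_lo: float = 0.08,
    g_hi: float = 0.3,
) -> np.ndarray:
    """Blend the full and a=0 compositions by field-gradient reliability.

    Returns ``chi_full`` where the (low-pass-filtered) field gradient is below
    ``g_lo`` [ppm/mm], ``chi_no_r2star`` above ``g_hi``, and a linear mix in
    between, so the result is continuous in the gradient value.
    """
    if g_lo >= g_hi:
        raise ValueError(f"g_lo ({g_lo}) must be < g_hi ({g_hi})")
    w = np.clip((field_gradient_mag - g_lo) / (g_hi - g_lo), 0.0, 1.0)
    return (1.0 - w) * chi_full + w * chi_no_r2star


def lowpass_gradient_magnitude(
    field_ppm: np.ndarray,
    spacing: tuple[float, float, float],
    fwhm_mm: float = 5.0,
) -> np.ndarray:
    """|grad| of a Gaussian low-pass-filtered field map, in ppm/mm."""
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]
    smooth = ndimage.gaussian_filter(field_ppm, sigma=sigma_vox, mode="nearest")
    grads = np.gradient(smooth, *spacing)
    return np.sqrt(sum(g * g for g in grads))


def compose_chi(
    per_tissue_chi: Mapping[int, np.ndarray | float],
    probability_maps: Mapping[int, np.ndarray],
    brain_mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    chi_background: float = 9.2,
) -> SusceptibilityVolume:
    """Probability-weighted sum chi(r) = sum_t P_t(r) chi_t(r) (whole head).

    Voxels not covered by any tissue receive the background (air)
    susceptibility.
    """
    shape = brain_mask.shape
    chi = np.zeros(shape, dtype=np.float64)
    covered = np.zeros(shape, dtype=np.float64)
    for lab, p in probability_maps.items():
        if p.shape != shape:
            raise ValueError(f"probability map for label {lab} has shape {p.shape}, expected {shape}")
        if lab not in per_tissue_chi:
            raise KeyError(f"no chi map supplied for label {lab}")
        c = per_tissue_chi[lab]
        if np.isscalar(c):
            chi += p * float(c)
        else:
            if c.shape != shape:
                raise ValueError(f"chi map for label {lab} has shape {c.shape}, expected {shape}")
            chi += p * c
        covered += p
    chi[covered <= 0] = chi_background
    return SusceptibilityVolume(chi, "whole_head", brain_mask.astype(bool), spacing)


def localize_chi(chi_whole: SusceptibilityVolume, brain_mask: np.ndarray) -> SusceptibilityVolume:
    """Brain-only chi: demeaned inside the mask, zero outside.

    Mimics 'perfect' background-field correction; the operation is
    idempotent.
    """
    mask = brain_mask.astype(bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    chi = np.where(mask, chi_whole.chi, 0.0)
    chi[mask] -= chi[mask].mean()
    return SusceptibilityVolume(chi, "local", mask, chi_whole.spacing)


def build_tissue_model(
    labels: np.ndarray,
    params: ParameterMaps,
    table: TissueParamTable,
    fwhm_voxels: float = 1.2,
) -> TissueModel:
    """Assemble a TissueModel: probability maps plus per-label reference means.

    Reference means are computed over the binary (pre-smoothing) label masks,
    because the modulation law is defined per tissue segment class.
    """
    table.check_covers(labels)
    present = [int(l) for l in np.unique(labels) if l != 0]
    flags = {lab: bool(table.row(lab)["is_brain_tissue"]) for lab in present}
    probs = partial_volume_maps(labels, flags, fwhm_voxels=fwhm_voxels)
    ref_r2s: dict[int, float] = {}
    ref_r1: dict[int, float] = {}
    for lab in present:
        m = labels == lab
        ref_r2s[lab] = float(params.r2star[m].mean())
        ref_r1[lab] = float(params.r1[m].mean())
    return TissueModel(labels=labels, probability_maps=probs, ref_r2star=ref_r2s, ref_r1=ref_r1)
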