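"""Download-free synthetic head phantom with brain-like geometry and texture.

The generator builds a nested-ellipsoid head (scalp fat, muscle, skull bone,
subarachnoid CSF, cortical gray matter, white matter) containing ventricles,
six deep-gray-matter nuclei, a thalamus, vein cylinders, one calcification
sphere, and air cavities (sinus and ear canals), for all 16 tissue classes of
the susceptibility model.  R1 and R2* receive spatially correlated texture
around tissue-typical 7 T means; the two rates share a latent "perturber
concentration" field (iron/myelin drive both rates in vivo), with per-tissue
amplitudes chosen so that the modulated susceptibility keeps a realistic
~0.01 ppm within-tissue spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import ParameterMaps, TissueModel, TissueParamTable

__all__ = ["SyntheticHeadSpec", "GeometryError", "generate_head", "LABELS"]

# fixed label taxonomy shared with the shipped tissue tables
LABELS = {
    "caudate": 1,
    "globus_pallidus": 2,
    "putamen": 3,
    "red_nucleus": 4,
    "dentate_nucleus": 5,
    "substantia_nigra": 6,
    "thalamus": 7,
    "white_matter": 8,
    "gray_matter": 9,
    "csf": 10,
    "blood": 11,
    "fat": 12,
    "bone": 13,
    "air": 14,
    "muscle": 15,
    "calcification": 16,
}

# tissue-typical 7 T relaxation means: R1 [1/s] (from T1), R2* [1/s] (from T2*)
_R1_MEAN = {
    "caudate": 1000.0 / 1500.0,
    "globus_pallidus": 1000.0 / 1100.0,
    "putamen": 1000.0 / 1400.0,
    "red_nucleus": 1000.0 / 1300.0,
    "dentate_nucleus": 1000.0 / 1300.0,
    "substantia_nigra": 1000.0 / 1200.0,
    "thalamus": 1000.0 / 1400.0,
    "white_matter": 1000.0 / 1100.0,
    "gray_matter": 1000.0 / 1900.0,
    "csf": 0.25,
    "blood": 1000.0 / 2100.0,
    "fat": 1000.0 / 600.0,
    "bone": 1000.0 / 300.0,
    "air": 0.0,
    "muscle": 1000.0 / 1800.0,
    "calcification": 1.0,
}
_R2S_MEAN = {
    "caudate": 1000.0 / 28.0,
    "globus_pallidus": 1000.0 / 14.0,
    "putamen": 1000.0 / 22.0,
    "red_nucleus": 1000.0 / 16.0,
    "dentate_nucleus": 1000.0 / 16.0,
    "substantia_nigra": 1000.0 / 15.0,
    "thalamus": 1000.0 / 28.0,
    "white_matter": 1000.0 / 26.0,
    "gray_matter": 1000.0 / 33.0,
    "csf": 10.0,
    "blood": 1000.0 / 8.0,
    "fat": 1000.0 / 20.0,
    "bone": 1000.0,
    "air": 0.0,
    "muscle": 1000.0 / 25.0,
    "calcification": 1000.0,  # no-signal, ultra-fast decay
}
_M0_BASE = {
    "caudate": 0.85,
    "globus_pallidus": 0.80,
    "putamen": 0.85,
    "red_nucleus": 0.80,
    "dentate_nucleus": 0.80,
    "substantia_nigra": 0.80,
    "thalamus": 0.85,
    "white_matter": 0.75,
    "gray_matter": 0.85,
    "csf": 1.00,
    "blood": 0.70,
    "fat": 0.90,
    "bone": 0.05,
    "air": 0.0,
    "muscle": 0.80,
    "calcification": 0.0,  # no MR signal inside the calcification
}


# fractional R2* texture overrides: blood and calcification rates are
# flow/no-signal-corrupted in acquired data, so their modulation is kept
# near piecewise-constant (their b coefficients are too small for the
# R1-term to balance an R2*-driven chi texture)
_R2S_FRAC_SD_OVERRIDE = {"blood": 0.002, "calcification": 0.002}


class GeometryError(ValueError):
    """A requested structure does not fit the grid / enclosing ellipsoid."""


@dataclass
class SyntheticHeadSpec:
    """Geometry and texture parameters for the synthetic head.

    Geometry is expressed in fractions of the grid so the same spec scales to
    smaller test grids; vein radii and the calcification radius are in voxels
    as they represent structures near the voxel scale.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 1

    # nested shells: semi-axes of the scalp ellipsoid (fractions of shape),
    # then shell thicknesses in voxels at 128; scaled by shape/128 otherwise
    head_axes_frac: tuple[float, float, float] = (0.41, 0.48, 0.44)
    fat_thickness: float = 3.0
    muscle_thickness: float = 3.0
    bone_thickness: float = 5.0
    csf_thickness: float = 2.0
    cortex_thickness: float = 5.0

    vein_radius: float = 2.0  # voxels (absolute: veins live near the voxel scale)
    calc_radius: float = 2.0  # voxels (absolute)

    # texture: correlation length of the latent field (voxels), fractional
    # R2* SD, target chi texture SD (ppm) that sets the per-tissue R1 SD
    texture_corr_vox: float = 3.0
    r2s_frac_sd: float = 0.02
    chi_texture_sd: float = 0.008
    m0_modulation: float = 0.05

    include_microstructure: bool = True

    def scale(self) -> float:
        return min(self.shape) / 128.0


def _ellipsoid(grid, center, semi_axes) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    ax, ay, az = semi_axes
    if min(ax, ay, az) <= 0:
        raise GeometryError(f"non-positive ellipsoid semi-axes {semi_axes}")
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(grid, center, radius) -> np.ndarray:
    return _ellipsoid(grid, center, (radius, radius, radius))


def _cylinder(grid, point, axis, radius) -> np.ndarray:
    """Infinite cylinder |(r - p) x u| < radius (axis u normalised)."""
    x, y, z = grid
    u = np.asarray(axis, dtype=float)
    u /= np.linalg.norm(u)
    dx, dy, dz = x - point[0], y - point[1], z - point[2]
    cx = dy * u[2] - dz * u[1]
    cy = dz * u[0] - dx * u[2]
    cz = dx * u[1] - dy * u[0]
    return cx * cx + cy * cy + cz * cz <= radius * radius


def _correlated_field(rng: np.random.Generator, shape, corr_vox: float) -> np.ndarray:
    """Unit-SD Gaussian random field with ~corr_vox correlation length."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_vox, mode="wrap")
    sd = g.std()
    if sd == 0:
        return g
    return g / sd


def _build_labels(spec: SyntheticHeadSpec) -> tuple[np.ndarray, dict]:
    shape = np.asarray(spec.shape, dtype=float)
    s = spec.scale()
    center = (shape - 1) / 2.0
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in spec.shape], indexing="ij")

    head_ax = np.asarray(spec.head_axes_frac) * shape
    if np.any(center - head_ax < 0.0) or np.any(center + head_ax > shape - 1.0):
        raise GeometryError(
            f"head ellipsoid semi-axes {head_ax} do not fit grid {spec.shape} "
            "with a 1-voxel margin"
        )

    t_fat = spec.fat_thickness * s
    t_mus = spec.muscle_thickness * s
    t_bone = spec.bone_thickness * s
    t_csf = spec.csf_thickness * s
    t_ctx = spec.cortex_thickness * s

    muscle_ax = head_ax - t_fat
    bone_ax = muscle_ax - t_mus
    csf_ax = bone_ax - t_bone
    brain_ax = csf_ax - t_csf
    wm_ax = brain_ax - t_ctx
    if np.any(wm_ax <= 4):
        raise GeometryError(f"shells leave no room for white matter (wm semi-axes {wm_ax})")

    L = LABELS
    labels = np.full(spec.shape, L["air"], dtype=np.int16)
    for ax, lab in (
        (head_ax, "fat"),
        (muscle_ax, "muscle"),
        (bone_ax, "bone"),
        (csf_ax, "csf"),
        (brain_ax, "gray_matter"),
        (wm_ax, "white_matter"),
    ):
        labels[_ellipsoid(grid, center, ax)] = L[lab]

    brain_ell = _ellipsoid(grid, center, brain_ax)
    inner_ell = _ellipsoid(grid, center, csf_ax)
    N = shape  # fractions below are of the full grid extent

    def at(fx, fy, fz):
        return center + np.array([fx, fy, fz]) * N

    structures: list[tuple[str, np.ndarray]] = []
    # lateral ventricles (CSF), thalamus first (neighbours may overwrite its
    # rim, as the smaller nuclei sit against it anatomically), then the six
    # deep-gray nuclei
    for sgn in (+1, -1):
        structures.append(("thalamus", _sphere(grid, at(sgn * 0.08, -0.10, 0.0), 0.070 * N[0])))
    for sgn in (+1, -1):
        structures.append(("csf", _ellipsoid(grid, at(sgn * 0.08, 0.0, 0.02), np.array([0.035, 0.09, 0.045]) * N)))
        structures.append(("caudate", _sphere(grid, at(sgn * 0.09, 0.075, 0.035), 0.047 * N[0])))
        structures.append(("globus_pallidus", _sphere(grid, at(sgn * 0.10, -0.01, -0.035), 0.043 * N[0])))
        structures.append(("putamen", _sphere(grid, at(sgn * 0.185, 0.025, -0.005), 0.055 * N[0])))
        structures.append(("red_nucleus", _sphere(grid, at(sgn * 0.04, -0.08, -0.06), 0.031 * N[0])))
        structures.append(("substantia_nigra", _sphere(grid, at(sgn * 0.065, -0.095, -0.12), 0.035 * N[0])))
        structures.append(("dentate_nucleus", _sphere(grid, at(sgn * 0.07, -0.18, -0.16), 0.047 * N[0])))
    structures.append(("calcification", _sphere(grid, at(0.0, 0.10, -0.03), spec.calc_radius)))

    report = []
    for name, m in structures:
        m &= brain_ell
        if not m.any():
            report.append(name)
        labels[m] = L[name]
    if report:
        raise GeometryError(f"structures fell outside the brain ellipsoid: {report}")

    # veins: superior sagittal sinus along y near the brain apex + deep veins
    veins = np.zeros(spec.shape, dtype=bool)
    veins |= _cylinder(grid, at(0.0, 0.0, 0.30), (0, 1, 0), spec.vein_radius)
    veins |= _cylinder(grid, at(0.12, 0.0, 0.08), (0, 1, 0), 0.75 * spec.vein_radius)
    veins |= _cylinder(grid, at(-0.12, 0.0, 0.08), (0, 1, 0), 0.75 * spec.vein_radius)
    veins |= _cylinder(grid, at(0.0, 0.05, 0.12), (1, 0, 0), 0.5 * spec.vein_radius)
    veins &= brain_ell
    veins &= labels != L["calcification"]
    if not veins.any():
        raise GeometryError("vein cylinders fell outside the brain ellipsoid")
    labels[veins] = L["blood"]

    # air cavities carved into the skull base / face region (outside brain)
    sinus = _ellipsoid(grid, at(0.0, 0.34, -0.17), np.array([0.07, 0.055, 0.055]) * N)
    ears = _sphere(grid, at(0.37, 0.0, -0.11), 0.023 * N[0]) | _sphere(
        grid, at(-0.37, 0.0, -0.11), 0.023 * N[0]
    )
    cavities = (sinus | ears) & ~inner_ell
    labels[cavities] = L["air"]

    masks = {
        "brain": inner_ell,  # everything inside the skull: brain + CSF envelope
        "brain_tissue_ell": brain_ell,
    }
    return labels, masks


def _r1_frac_sd(table: TissueParamTable, name: str, spec: SyntheticHeadSpec) -> float:
    """Per-tissue R1 texture amplitude giving ~chi_texture_sd after modulation.

    The shared latent field enters both rates; the a- and b-terms then
    partially cancel as they do for real iron/myelin-driven contrast.
    """
    lab = LABELS[name]
    if lab not in table.labels:
        return 0.03
    row = table.row(lab)
    a, b = float(row["a_tissue"]), float(row["b_tissue"])
    m1, m2 = _R1_MEAN[name], _R2S_MEAN[name]
    if b * m1 == 0:
        return 0.03
    s2 = _R2S_FRAC_SD_OVERRIDE.get(name, spec.r2s_frac_sd)
    target = spec.chi_texture_sd
    val = (target - a * m2 * s2) / (b * m1)
    return float(np.clip(val, 0.01, 0.08))


def generate_head(
    spec: SyntheticHeadSpec | None = None,
    table: TissueParamTable | None = None,
) -> tuple[TissueModel, ParameterMaps, dict[str, np.ndarray]]:
    """Generate (TissueModel, ParameterMaps, roi_masks); deterministic per seed.

    ROI masks: ``brain`` (inside-skull mask), ``tissue`` (GM+WM), ``blood``
    (veins), ``dgm`` (six nuclei), ``calc``, and a ``dgm_regions`` mapping of
    the six deep-gray nuclei used by the linearity metric.
    """
    spec = spec or SyntheticHeadSpec()
    table = table or TissueParamTable.model1()
    rng = np.random.default_rng(spec.seed)
    labels, masks = _build_labels(spec)
    L = LABELS
    name_of = {v: k for k, v in L.items()}

    # latent perturber field shared by R1/R2*, plus small independent parts
    g = _correlated_field(rng, spec.shape, spec.texture_corr_vox)
    h1 = _correlated_field(rng, spec.shape, spec.texture_corr_vox)
    h2 = _correlated_field(rng, spec.shape, spec.texture_corr_vox)
    g = np.clip(g, -3.0, 3.0)
    h1 = np.clip(h1, -3.0, 3.0)
    h2 = np.clip(h2, -3.0, 3.0)
    indep = 0.005  # independent fractional SD on each rate

    # acquired relaxometry has the same point-spread function as the tissue
    # probabilities: brain-tissue boundaries are partial-volume mixtures of
    # the per-tissue textured rates, while sharp compartments keep their own
    # rates.  The mixing weights are the probabilities scaled by each
    # tissue's modulation coefficient (|a| for R2*, b for R1, plus a small
    # floor): with those weights the composed susceptibility at a two-tissue
    # interface reduces exactly to the partial-volume mix of the tissue
    # means -- the deviation terms of the two laws cancel pairwise, as they
    # do in acquired data where the coefficients were fit to the same maps.
    present = [int(l) for l in np.unique(labels)]
    flags = {lab: bool(table.row(lab)["is_brain_tissue"]) for lab in present}
    from .phantom import partial_volume_maps

    probs = partial_volume_maps(labels, flags, fwhm_voxels=1.2)
    mixed = [lab for lab in present if not bool(table.row(lab)["is_piecewise_constant"])]

    def _coef(lab, col):
        return abs(float(table.row(lab)[col]))

    w1sum = np.zeros(spec.shape)
    w2sum = np.zeros(spec.shape)
    psum = np.zeros(spec.shape)
    for lab in mixed:
        w1sum += probs[lab] * _coef(lab, "b_tissue")
        w2sum += probs[lab] * _coef(lab, "a_tissue")
        psum += probs[lab]
    mixed_owned = np.isin(labels, mixed) & (w1sum > 0) & (w2sum > 0)
    for w in (w1sum, w2sum, psum):
        w[w == 0] = 1.0

    r1 = np.zeros(spec.shape)
    r2s = np.zeros(spec.shape)
    m0 = np.zeros(spec.shape)
    ref_r1: dict[int, float] = {}
    ref_r2s: dict[int, float] = {}
    for lab in present:
        name = name_of[lab]
        s1 = _r1_frac_sd(table, name, spec)
        s2 = _R2S_FRAC_SD_OVERRIDE.get(name, spec.r2s_frac_sd)
        own = labels == lab
        # per-label demeaning of the latent fields pins every label mean to
        # its design value (stationarity by construction; a regional
        # fluctuation of the random field cannot drift a tissue's mean)
        g_t = g - g[own].mean()
        h1_t = h1 - h1[own].mean()
        h2_t = h2 - h2[own].mean()
        tex1 = _R1_MEAN[name] * (1.0 + s1 * g_t + indep * h1_t)
        tex2 = _R2S_MEAN[name] * (1.0 + s2 * g_t + min(indep, s2) * h2_t)
        # reference rates are the tissue's uncontaminated (pre-mixing) label
        # means: the characteristic rates of the pure tissue, which is what
        # the modulation law is defined against
        ref_r1[lab] = float(tex1[own].mean())
        ref_r2s[lab] = float(tex2[own].mean())
        if lab in mixed:
            w1 = np.where(mixed_owned, probs[lab] * _coef(lab, "b_tissue") / w1sum, 0.0)
            w2 = np.where(mixed_owned, probs[lab] * _coef(lab, "a_tissue") / w2sum, 0.0)
            wp = np.where(mixed_owned, probs[lab] / psum, 0.0)
            # own voxels that fall outside the mixed support keep pure rates
            pure = own & ~mixed_owned
            w1[pure] = w2[pure] = wp[pure] = 1.0
        else:
            w1 = w2 = wp = own.astype(float)
        nz = (w1 > 0) | (w2 > 0) | (wp > 0)
        r1[nz] += w1[nz] * tex1[nz]
        r2s[nz] += w2[nz] * tex2[nz]
        m0[nz] += wp[nz] * _M0_BASE[name]
    r1 = np.clip(r1, 0.0, None)
    r2s = np.clip(r2s, 0.0, None)

    # mild, very smooth receive/density modulation of M0
    mod = _correlated_field(rng, spec.shape, 5.0 * spec.texture_corr_vox)
    m0 = np.clip(m0 * (1.0 + spec.m0_modulation * mod), 0.0, None)

    # white-matter microstructure inputs: high FA and a smooth fiber field
    fa = np.full(spec.shape, 0.05)
    wm = labels == L["white_matter"]
    fa_tex = np.clip(0.6 + 0.1 * _correlated_field(rng, spec.shape, spec.texture_corr_vox), 0.2, 0.95)
    fa[wm] = fa_tex[wm]
    vx = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 5.0, mode="wrap")
    vy = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 5.0, mode="wrap")
    vz = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 5.0, mode="wrap")
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    norm[norm == 0] = 1.0
    theta = np.arccos(np.abs(vz) / norm)

    params = ParameterMaps(
        m0=m0, r1=r1, r2star=r2s, spacing=spec.spacing, fa=fa, fiber_theta=theta
    )
    model = TissueModel(
        labels=labels, probability_maps=probs, ref_r2star=ref_r2s, ref_r1=ref_r1
    )

    dgm_names = (
        "caudate",
        "globus_pallidus",
        "putamen",
        "red_nucleus",
        "dentate_nucleus",
        "substantia_nigra",
    )
    dgm_regions = {n: labels == L[n] for n in dgm_names}
    dgm = np.zeros(spec.shape, dtype=bool)
    for m in dgm_regions.values():
        dgm |= m
    roi_masks = {
        "brain": masks["brain"],
        "tissue": (labels == L["gray_matter"]) | wm,
        "blood": labels == L["blood"],
        "dgm": dgm,
        "calc": labels == L["calcification"],
        "dgm_regions": dgm_regions,
    }
    return model, params, roi_masks
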