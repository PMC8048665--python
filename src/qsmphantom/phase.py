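"""Reference phase processing: unwrap, echo combination, background removal.

The chain mirrors a standard QSM preprocessing pipeline: spatial unwrapping
of inter-echo phase differences (quality-guided), integration across echoes,
a weighted per-voxel line fit phase(TE) = phi0 + 2*pi*f*TE, and removal of
the background field by the Laplacian boundary value (LBV) method -- the
background field is harmonic inside the brain, so solving Laplace's equation
with the measured field as boundary values isolates it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg
from skimage.restoration import unwrap_phase as _unwrap_phase

from .field import FieldMap
from .gre import EchoSeries

__all__ = [
    "unwrap_spatial",
    "fit_frequency",
    "echoes_to_field",
    "repair_field_outliers",
    "remove_background_lbv",
]

TWO_PI = 2.0 * np.pi


def unwrap_spatial(
    wrapped: np.ndarray,
    magnitude: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Spatially unwrap a phase volume inside a reliability mask.

    The result differs from the input by integer multiples of 2*pi
    voxel-wise.  The global 2*pi ambiguity is fixed so the unwrapped phase
    equals the wrapped phase at the highest-magnitude voxel (a reliable,
    high-signal seed); voxels outside the mask keep their wrapped values.
    """
    if mask is not None:
        mask = mask.astype(bool)
        if not mask.any():
            raise ValueError("empty reliability mask")
        marr = np.ma.array(wrapped, mask=~mask)
        unwrapped = np.asarray(_unwrap_phase(marr))
        out = np.where(mask, unwrapped, wrapped)
    else:
        mask = np.ones(wrapped.shape, dtype=bool)
        out = np.asarray(_unwrap_phase(wrapped))
    if magnitude is not None:
        seed = np.unravel_index(np.argmax(np.where(mask, magnitude, -np.inf)), wrapped.shape)
    else:
        seed = tuple(np.array(np.nonzero(mask))[:, 0])
    k = np.round((out[seed] - wrapped[seed]) / TWO_PI)
    return out - TWO_PI * k


def fit_frequency(
    unwrapped: np.ndarray,
    magnitude: np.ndarray,
    te_list,
    spacing=(1.0, 1.0, 1.0),
    b0: float = 7.0,
    weighting: str = "te2mag2",
) -> tuple[FieldMap, np.ndarray, np.ndarray]:
    """Weighted per-voxel line fit phase(TE) = phi0 + 2*pi*f*TE.

    Weights: 'te2mag2' (TE_j^2 |S_j|^2, inverse-variance weighting for the
    phase noise of a magnitude-|S| signal combined at echo level), 'mag2', or
    'uniform'.  Returns (frequency map [Hz], weighted mean-squared residual
    map [rad^2], valid mask); voxels with zero total weight get f = 0 and are
    flagged invalid.
    """
    te = np.asarray(te_list, dtype=float).reshape((-1,) + (1,) * (unwrapped.ndim - 1))
    if unwrapped.shape[0] != te.size or unwrapped.shape != magnitude.shape:
        raise ValueError("unwrapped/magnitude/TE shapes are inconsistent")
    if te.size < 2:
        raise ValueError("need at least two echoes to fit a frequency")
    if weighting == "te2mag2":
        w = te**2 * magnitude**2
    elif weighting == "mag2":
        w = magnitude**2
    elif weighting == "uniform":
        w = np.ones_like(magnitude)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sw = w.sum(axis=0)
    valid = sw > 0
    sw_safe = np.where(valid, sw, 1.0)
    swx = (w * te).sum(axis=0)
    swxx = (w * te**2).sum(axis=0)
    swy = (w * unwrapped).sum(axis=0)
    swxy = (w * te * unwrapped).sum(axis=0)
    denom = sw * swxx - swx**2
    # zero denom: all weight on one echo -> slope undefined
    ok = valid & (denom > 0)
    denom_safe = np.where(ok, denom, 1.0)
    slope = np.where(ok, (sw * swxy - swx * swy) / denom_safe, 0.0)
    intercept = np.where(ok, (swy - slope * swx) / sw_safe, 0.0)
    fit = intercept + slope * te
    resid = np.where(ok, (w * (unwrapped - fit) ** 2).sum(axis=0) / sw_safe, 0.0)
    freq = slope / TWO_PI
    fm = FieldMap(freq, "Hz", spacing, b0=b0)
    return fm, resid, ok


def echoes_to_field(
    series: EchoSeries,
    brain_mask: np.ndarray,
    weighting: str = "te2mag2",
) -> tuple[FieldMap, np.ndarray, np.ndarray]:
    """Complex echoes -> fitted frequency map (Hz) inside the brain mask.

    Inter-echo phase differences are unwrapped spatially (they vary far less
    than the absolute phase), integrated across echoes on top of the
    unwrapped first-echo phase, and combined by the weighted line fit.
    """
    mags = series.magnitude
    unwrapped = np.empty_like(mags)
    unwrapped[0] = unwrap_spatial(np.angle(series.data[0]), mags[0], brain_mask)
    acc = unwrapped[0]
    for j in range(1, series.data.shape[0]):
        d = np.angle(series.data[j] * np.conj(series.data[j - 1]))
        d_unw = unwrap_spatial(d, np.minimum(mags[j], mags[j - 1]), brain_mask)
        acc = acc + d_unw
        unwrapped[j] = acc
    b0 = series.meta.get("b0", 7.0)
    return fit_frequency(
        unwrapped, mags, series.protocol.te, series.spacing, b0=b0, weighting=weighting
    )


def repair_field_outliers(
    field: FieldMap,
    valid: np.ndarray,
    brain_mask: np.ndarray,
    delta_te_min: float,
    frac: float = 0.3,
) -> tuple[FieldMap, np.ndarray]:
    """Replace unreliable frequency estimates with a local median.

    Spatial unwrapping fails around no-signal regions (calcifications) where
    inter-voxel phase steps exceed pi; the resulting frequency errors are
    near-multiples of 1/delta-TE and stand out from their neighbourhood by a
    large fraction of that aliasing scale.  Voxels flagged invalid by the
    fit, or deviating from the 3x3x3 median by more than ``frac/delta_te``
    Hz, take the median value.  Returns (repaired field, repaired mask).
    """
    hz = field.in_unit("Hz").copy()
    mask = brain_mask.astype(bool)
    med = ndimage.median_filter(hz, size=3)
    bad = ((np.abs(hz - med) > frac / delta_te_min) | ~valid) & mask
    hz[bad] = med[bad]
    out = FieldMap(hz, "Hz", field.spacing, field.b0, field.gamma_bar).as_unit(field.unit)
    return out, bad


def remove_background_lbv(
    field: FieldMap,
    brain_mask: np.ndarray,
    erode_voxels: int = 1,
    tol: float = 1e-6,
    maxiter: int = 10_000,
) -> FieldMap:
    """Laplacian-boundary-value background removal.

    Solves Laplace's equation on the interior of the (eroded) mask with
    Dirichlet values taken from the measured field on the mask boundary; the
    harmonic solution is the background estimate and is subtracted.  The
    returned local field is zero outside the eroded mask and zero-mean over
    it.  Raises if conjugate gradients do not reach the relative tolerance.
    """
    data = np.asarray(field.data, dtype=np.float64)
    mask = brain_mask.astype(bool).copy()
    # clear the outermost voxel layer so np.roll neighbour lookups never wrap
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = edge
            mask[tuple(sl)] = False
    if erode_voxels > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_voxels)
    interior = ndimage.binary_erosion(mask)
    n = int(interior.sum())
    if n == 0:
        raise ValueError("mask too small: no interior voxels after erosion")

    index = np.full(data.shape, -1, dtype=np.int64)
    index[interior] = np.arange(n)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    own = index[interior]
    for axis in range(3):
        for shift in (+1, -1):
            nb_index = np.roll(index, -shift, axis=axis)[interior]
            nb_data = np.roll(data, -shift, axis=axis)[interior]
            inside = nb_index >= 0
            rows.append(own[inside])
            cols.append(nb_index[inside])
            vals.append(np.full(int(inside.sum()), -1.0))
            # neighbour on the boundary layer: Dirichlet value from the field
            rhs[own[~inside]] += nb_data[~inside]
    rows.append(own)
    cols.append(own)
    vals.append(np.full(n, 6.0))
    lap = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    x0 = data[interior]
    sol, info = cg(lap, rhs, x0=x0, rtol=tol, maxiter=maxiter)
    if info != 0:
        resid = np.linalg.norm(lap @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise RuntimeError(
            f"LBV solver did not converge (info={info}, relative residual {resid:.3e})"
        )
    harmonic = data.copy()
    harmonic[interior] = sol
    local = np.where(mask, data - harmonic, 0.0)
    local[mask] -= local[mask].mean()
    return FieldMap(local, field.unit, field.spacing, field.b0, field.gamma_bar)
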