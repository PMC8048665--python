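"""Shared fixtures: the synthetic head and its simulated data products.

The expensive 128-cube phantom and its noiseless simulations are built once
per session and shared between the module tests and the acceptance suite.
"""

import numpy as np
import pytest
from scipy import ndimage

from qsmphantom import (
    PROTOCOLS,
    TissueParamTable,
    localize_chi,
)
from qsmphantom.field import field_from_chi
from qsmphantom.gre import EchoSeries, downsample_mask, fourier_downsample
from qsmphantom.pipeline import ground_truth_chi, process_echoes, simulate_echoes
from qsmphantom.synth import SyntheticHeadSpec, generate_head


@pytest.fixture(scope="session")
def table1():
    return TissueParamTable.model1()


@pytest.fixture(scope="session")
def head128(table1):
    """Default 128-cube synthetic head (seed 1)."""
    return generate_head(SyntheticHeadSpec(), table1)


@pytest.fixture(scope="session")
def head_small(table1):
    """Small 48-cube head for cheap module tests."""
    return generate_head(SyntheticHeadSpec(shape=(48, 48, 48), seed=2), table1)


@pytest.fixture(scope="session")
def gt128(head128, table1):
    """(chi_whole, chi_local, ground-truth local field) at 128-cube."""
    model, params, rois = head128
    chi_w = ground_truth_chi(model, params, table1, rois["brain"])
    chi_l = localize_chi(chi_w, rois["brain"])
    return chi_w, chi_l, field_from_chi(chi_l)


@pytest.fixture(scope="session")
def local_sim128(head128, gt128):
    """Noiseless local-field simulation (challenge protocol) + processing."""
    model, params, rois = head128
    _, chi_l, _ = gt128
    series, fm = simulate_echoes(
        chi_l, params, PROTOCOLS["challenge"], rois["brain"], phi0_seed=3
    )
    processed = process_echoes(series, rois["brain"], background_removal=False)
    return {"series": series, "field_true": fm, "processed": processed}


@pytest.fixture(scope="session")
def wholehead128(head128, gt128):
    """Whole-head (background fields + shim) simulation, native + 2 mm runs."""
    model, params, rois = head128
    chi_w, _, gt_field_local = gt128
    proto = PROTOCOLS["p1"]
    series, fm = simulate_echoes(
        chi_w, params, proto, rois["brain"], phi0_seed=3, shim=True
    )
    native = process_echoes(series, rois["brain"], background_removal=True, mask_erosion=6)
    low = np.stack(
        [fourier_downsample(series.data[j], (1, 1, 1), (2, 2, 2))[0] for j in range(proto.n_echoes)]
    )
    series_low = EchoSeries(low, proto, (2.0, 2.0, 2.0), dict(series.meta))
    brain_low = downsample_mask(rois["brain"], (1, 1, 1), (2, 2, 2))
    lowres = process_echoes(series_low, brain_low, background_removal=True, mask_erosion=3)
    gt_low, _ = fourier_downsample(gt_field_local.data, (1, 1, 1), (2, 2, 2))
    return {
        "native": native,
        "lowres": lowres,
        "gt_local_native": gt_field_local.data,
        "gt_local_low": gt_low,
        "rois": rois,
    }


def demeaned_error(recovered, truth, mask):
    """Offset-free error map (the absolute field offset is unobservable)."""
    d = recovered - truth
    return np.where(mask, d - d[mask].mean(), 0.0)


@pytest.fixture(scope="session")
def signal_free_exclusion(head128, local_sim128):
    """No-signal voxels and their immediate surrounding (unwrap failure zone)."""
    _, _, rois = head128
    mag = np.abs(local_sim128["series"].data[0])
    nosig = mag < 1e-3 * mag.max()
    return ndimage.binary_dilation(nosig & rois["brain"], iterations=6) | nosig
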