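"""End-to-end orchestration: phantom -> field -> signal -> processing -> QSM.

`run_pipeline` materialises a full simulated study into an output directory
(NIfTI volumes, JSON manifest and metric report); the intermediate helpers
are plain functions over in-memory arrays so the stages can be recombined
programmatically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as qio
from .field import FieldMap, field_from_chi, microstructure_shift, simulate_shim
from .gre import (
    PROTOCOLS,
    EchoSeries,
    Protocol,
    add_noise,
    downsample_mask,
    fourier_downsample,
    gibbs_suppress,
    gre_signal,
    transceiver_phase,
)
from .inversion import InversionConfig, invert_l2, invert_tkd
from .metrics import evaluate_all
from .phantom import (
    ParameterMaps,
    SusceptibilityVolume,
    TissueModel,
    TissueParamTable,
    compose_chi,
    gradient_reliability_blend,
    localize_chi,
    lowpass_gradient_magnitude,
    tissue_chi_map,
)
from .phase import echoes_to_field, remove_background_lbv
from .synth import LABELS, SyntheticHeadSpec, generate_head

log = logging.getLogger("qsmphantom")

__all__ = ["RunConfig", "ground_truth_chi", "simulate_echoes", "process_echoes", "run_pipeline"]


def ground_truth_chi(
    model: TissueModel,
    params: ParameterMaps,
    table: TissueParamTable,
    brain_mask: np.ndarray,
    blend: bool = True,
    g_lo: float = 0.08,
    g_hi: float = 0.3,
    lp_fwhm_mm: float = 5.0,
    clip_sd: float | None = None,
    b0: float = 7.0,
) -> SusceptibilityVolume:
    """Compose the whole-head ground-truth chi map (ppm).

    Evaluates the modulated per-tissue chi maps, mixes them with the
    partial-volume probabilities, and (optionally) blends towards the
    R2*-free composition where the low-pass-filtered field gradient marks
    R2* as unreliable.  ``clip_sd`` bounds each tissue's rate deviation at
    that many within-label standard deviations so the per-tissue law is not
    extrapolated onto foreign compartments (veins, calcification, CSF)
    smoothed into its support.
    """
    chi_air = float(table.row(LABELS["air"])["chi_mean"]) if LABELS["air"] in table.labels else 9.2

    clips: dict[int, tuple[float, float] | None] = {}
    for lab in model.probability_maps:
        if clip_sd is None:
            clips[lab] = None
        else:
            m = model.labels == lab
            if not m.any():
                clips[lab] = None
            else:
                clips[lab] = (
                    clip_sd * float(params.r2star[m].std()),
                    clip_sd * float(params.r1[m].std()),
                )

    def _compose(include_r2star: bool) -> SusceptibilityVolume:
        per_tissue = {}
        for lab in model.probability_maps:
            row = table.row(lab)
            if row["is_piecewise_constant"]:
                per_tissue[lab] = float(row["chi_mean"])
            else:
                per_tissue[lab] = tissue_chi_map(
                    params,
                    table,
                    lab,
                    model.ref_means(lab),
                    include_r2star=include_r2star,
                    dev_clip=clips[lab],
                )
        return compose_chi(
            per_tissue, model.probability_maps, brain_mask, params.spacing, chi_background=chi_air
        )

    chi_full = _compose(True)
    if not blend:
        return chi_full
    chi_no_a = _compose(False)
    fm = field_from_chi(chi_full, b0=b0)
    grad = lowpass_gradient_magnitude(fm.data, params.spacing, fwhm_mm=lp_fwhm_mm)
    chi = gradient_reliability_blend(chi_full.chi, chi_no_a.chi, grad, g_lo=g_lo, g_hi=g_hi)
    return SusceptibilityVolume(chi, "whole_head", brain_mask.astype(bool), params.spacing)


def simulate_echoes(
    chi: SusceptibilityVolume,
    params: ParameterMaps,
    protocol: Protocol,
    brain_mask: np.ndarray,
    phi0_seed: int = 0,
    shim: bool | None = None,
    microstructure: bool = False,
    wm_mask: np.ndarray | None = None,
    peak_snr: float | None = None,
    noise_seed: int = 0,
    b0: float = 7.0,
) -> tuple[EchoSeries, FieldMap]:
    """chi -> frequency map -> complex echoes; returns (echoes, field used).

    Shimming defaults to on for whole-head chi (background fields present)
    and off for local chi.
    """
    fm = field_from_chi(chi, b0=b0)
    if shim is None:
        shim = chi.mode == "whole_head"
    if shim:
        fm = simulate_shim(fm, brain_mask)
    if microstructure:
        if wm_mask is None or params.fa is None or params.fiber_theta is None:
            raise ValueError("microstructure shift needs a WM mask plus FA and fiber angle maps")
        fm = microstructure_shift(fm, params.fa, params.fiber_theta, wm_mask)
    phi0 = transceiver_phase(chi.chi.shape, brain_mask, seed=phi0_seed)
    series = gre_signal(params, fm, phi0, protocol)
    series.meta.update(mode=chi.mode, phi0_seed=phi0_seed, microstructure=microstructure)
    if peak_snr is not None:
        series = add_noise(series, peak_snr=peak_snr, seed=noise_seed)
    return series, fm


def process_echoes(
    series: EchoSeries,
    brain_mask: np.ndarray,
    background_removal: bool = True,
    despike: bool = True,
    mask_erosion: int = 0,
) -> dict:
    """Echoes -> fitted field (Hz) [-> outlier repair -> LBV local field].

    ``despike`` repairs invalid/unwrap-corrupted frequency estimates with a
    local median before background removal (the raw fit is kept under
    ``"field_raw"``).  ``mask_erosion`` shrinks the processing mask first --
    with strong background fields, phase unwrapping is unreliable in the
    outermost mask layers near air cavities, and erosion is the standard
    remedy; the eroded mask is returned under ``"mask"``.
    """
    from scipy import ndimage as _ndi

    from .phase import repair_field_outliers

    if mask_erosion > 0:
        brain_mask = _ndi.binary_erosion(brain_mask.astype(bool), iterations=mask_erosion)
    fitted, resid, valid = echoes_to_field(series, brain_mask)
    out = {"field_raw": fitted, "residual": resid, "valid": valid}
    if despike:
        dte = float(np.diff(series.protocol.te).min())
        fitted, repaired = repair_field_outliers(fitted, valid, brain_mask, dte)
        out["repaired"] = repaired
    out["field"] = fitted
    out["mask"] = brain_mask.astype(bool)
    if background_removal:
        out["local_field"] = remove_background_lbv(fitted, brain_mask)
    return out


@dataclass
class RunConfig:
    """Configuration of a full simulated study (YAML-serialisable)."""

    out_dir: str = "qsm_run"
    phantom_dir: str | None = None  # None -> generate the synthetic head
    model: str = "model1"  # model1 | model2 | path to a CSV
    protocol: str = "challenge"  # preset name or inline dict via from_yaml
    mode: str = "whole_head"  # whole_head | local
    grid: int = 128
    phantom_seed: int = 1
    phi0_seed: int = 10
    noise_seed: int = 20
    peak_snr: float | None = None
    shim: bool = True
    microstructure: bool = False
    blend: bool = True
    downsample_to: float | None = None  # target spacing in mm
    invert: bool = True
    tkd_threshold: float = 0.2
    l2_lambda: float = 1e-2
    mask_erosion: int = 3  # processing-mask erosion for whole-head runs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def table(self) -> TissueParamTable:
        if self.model == "model1":
            return TissueParamTable.model1()
        if self.model == "model2":
            return TissueParamTable.model2()
        return TissueParamTable.from_csv(self.model)

    def protocol_obj(self) -> Protocol:
        if isinstance(self.protocol, str):
            return PROTOCOLS[self.protocol]
        return Protocol(**self.protocol)


def _save(vol, spacing, path, desc=None):
    qio.save_volume(vol, spacing, path, description=desc)


def run_pipeline(config: RunConfig) -> Path:
    """Execute generate -> compose -> field -> signal -> process -> invert -> score.

    Writes NIfTI volumes, a JSON manifest with every seed and parameter, and
    (when inversion runs) the metric report.  Deterministic stages are
    bit-reproducible for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    table = config.table()
    protocol = config.protocol_obj()
    stage = "generate"
    try:
        spec = SyntheticHeadSpec(
            shape=(config.grid,) * 3, seed=config.phantom_seed
        )
        model, params, rois = generate_head(spec, table)
        spacing = params.spacing
        log.info("generated synthetic head %s", spec.shape)

        stage = "compose"
        chi_whole = ground_truth_chi(model, params, table, rois["brain"], blend=config.blend)
        chi_local = localize_chi(chi_whole, rois["brain"])
        chi_gt = chi_whole if config.mode == "whole_head" else chi_local
        _save(chi_whole.chi, spacing, out / "chi_whole_head.nii.gz", "ppm")
        _save(chi_local.chi, spacing, out / "chi_local.nii.gz", "ppm")
        _save(model.labels.astype(np.int16), spacing, out / "labels.nii.gz")
        _save(rois["brain"].astype(np.uint8), spacing, out / "brain_mask.nii.gz")

        stage = "simulate"
        series, field_used = simulate_echoes(
            chi_gt,
            params,
            protocol,
            rois["brain"],
            phi0_seed=config.phi0_seed,
            shim=config.shim if config.mode == "whole_head" else False,
            microstructure=config.microstructure,
            wm_mask=model.labels == LABELS["white_matter"],
            peak_snr=config.peak_snr,
            noise_seed=config.noise_seed,
        )
        _save(field_used.in_unit("ppm"), spacing, out / "field_simulated_ppm.nii.gz", "ppm")

        stage = "downsample"
        truth_chi = chi_local.chi
        masks = {k: v for k, v in rois.items() if k != "dgm_regions"}
        dgm_regions = rois["dgm_regions"]
        if config.downsample_to is not None:
            target = (config.downsample_to,) * 3
            low = [fourier_downsample(series.data[j], spacing, target)[0] for j in range(series.data.shape[0])]
            eff = fourier_downsample(series.data[0], spacing, target)[1]
            series = EchoSeries(np.stack(low), protocol, eff, dict(series.meta))
            truth_chi, _ = fourier_downsample(truth_chi, spacing, target)
            truth_chi = gibbs_suppress(truth_chi)
            masks = {k: downsample_mask(v, spacing, target) for k, v in masks.items()}
            dgm_regions = {k: downsample_mask(v, spacing, target) for k, v in dgm_regions.items()}
            spacing = eff
        for j, te in enumerate(protocol.te):
            _save(np.abs(series.data[j]), spacing, out / f"echo{j + 1}_mag.nii.gz")
            _save(np.angle(series.data[j]), spacing, out / f"echo{j + 1}_phase.nii.gz", "rad")

        stage = "process"
        whole = config.mode == "whole_head"
        processed = process_echoes(
            series,
            masks["brain"],
            background_removal=whole,
            mask_erosion=config.mask_erosion if whole else 0,
        )
        masks["brain"] = processed["mask"]
        fitted = processed["field"]
        _save(fitted.in_unit("Hz"), spacing, out / "field_fitted_hz.nii.gz", "Hz")
        _save(processed["residual"], spacing, out / "fit_residual_rad2.nii.gz", "rad^2")
        local = processed.get("local_field", fitted)
        _save(local.in_unit("Hz"), spacing, out / "field_local_hz.nii.gz", "Hz")

        report = None
        if config.invert:
            stage = "invert"
            local_ppm = FieldMap(
                np.where(masks["brain"], local.in_unit("ppm"), 0.0), "ppm", spacing
            )
            recon_tkd = invert_tkd(
                local_ppm, InversionConfig("tkd", threshold=config.tkd_threshold), masks["brain"], spacing
            )
            recon_l2 = invert_l2(
                local_ppm, InversionConfig("l2", lam=config.l2_lambda), masks["brain"], spacing
            )
            _save(recon_tkd.chi, spacing, out / "chi_tkd.nii.gz", "ppm")
            _save(recon_l2.chi, spacing, out / "chi_l2.nii.gz", "ppm")

            stage = "score"
            prescribed = {
                name: float(table.row(LABELS[name])["chi_mean"]) for name in dgm_regions
            }
            voxvol = float(np.prod(spacing))
            report = {
                "tkd": evaluate_all(
                    recon_tkd.chi, truth_chi, dict(masks, dgm_regions=dgm_regions), prescribed, voxvol
                ).as_dict(),
                "l2": evaluate_all(
                    recon_l2.chi, truth_chi, dict(masks, dgm_regions=dgm_regions), prescribed, voxvol
                ).as_dict(),
            }
            (out / "metrics.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "protocol": {"tr": protocol.tr, "te": list(protocol.te), "flip_deg": protocol.flip_deg},
        "stages": ["generate", "compose", "simulate", "downsample", "process"]
        + (["invert", "score"] if config.invert else []),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
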