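"""Digital glioblastoma phantom with full ground truth.

Generates per-case co-registered volumes on a shared grid: a two-hemisphere
ellipsoidal "brain" containing a tumor built from three nested spherical
compartments — necrotic core, enhancing rim, infiltrative margin — plus

* FLT and FMISO SUV maps (compartment mean + Gaussian noise, optional
  Gaussian PSF emulating PET resolution),
* a DSC-MRI series produced by the forward signal model
  S(t) = S0 * exp(-TE * dR2*(t)) with per-compartment gamma-variate bolus
  curves and a 20 s pre-bolus baseline,
* masks (CE = enhancing rim, FLAIR hypersignal = rim + margin by default,
  hemispheres, normal-appearing white matter) and a truth record (pre-noise
  compartment means, generating dR2* curves, volumes in mL, and the
  peripheral-volume percentages of the truth modality masks vs CE).

Everything is deterministic given the config seed, so each pipeline stage is
closed-loop testable without patient data.  Default geometry and timing
mirror a 1.5-T DSC protocol: 35 repetitions, TR 2.28 s, TE 60 ms,
2.19 x 2.19 mm pixels, 7 mm slices, 20 s injection delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dsc_perfusion import gamma_variate, gamma_variate_auc
from .imaging_io import BinaryMask, DynamicSeries, VolumeImage
from .spatial_metrics import peripheral_volume_pct, volume_ml

__all__ = [
    "BolusParams",
    "ModalityParams",
    "PhantomConfig",
    "PhantomCase",
    "make_phantom",
    "make_dsc_series",
]

COMPARTMENTS = ("core", "rim", "margin")


@dataclass
class BolusParams:
    """Gamma-variate bolus for the DSC forward model (dR2* in ms^-1)."""

    K: float = 0.002
    t0_s: float = 24.0
    alpha: float = 3.0
    beta_s: float = 1.5

    def curve(self, time_s: np.ndarray) -> np.ndarray:
        return gamma_variate(time_s, self.K, self.t0_s, self.alpha, self.beta_s)

    @property
    def auc(self) -> float:
        return gamma_variate_auc(self.K, self.alpha, self.beta_s)


@dataclass
class ModalityParams:
    """Static uptake model for one PET modality (SUV g/mL units).

    ``background_mean`` may be a scalar or a (left, right) pair for
    hemisphere-specific background; ``compartment_means`` overrides the
    background inside each tumor compartment; ``avid_compartments`` defines
    the ground-truth tumor ROI for this modality.
    """

    background_mean: float | tuple[float, float] = 1.0
    noise_sd: float = 0.1
    compartment_means: dict[str, float] = field(default_factory=dict)
    avid_compartments: tuple[str, ...] = ("rim",)

    def bg(self, side: str) -> float:
        if isinstance(self.background_mean, (tuple, list)):
            return float(self.background_mean[0 if side == "left" else 1])
        return float(self.background_mean)


def _default_flt() -> ModalityParams:
    # low healthy-brain FLT uptake; proliferation extends through the margin
    return ModalityParams(
        background_mean=0.4, noise_sd=0.08,
        compartment_means={"core": 0.5, "rim": 2.2, "margin": 2.1},
        avid_compartments=("core", "rim", "margin"),
    )


def _default_fmiso() -> ModalityParams:
    # average uptake with a large SD in healthy parenchyma, poor contrast
    return ModalityParams(
        background_mean=1.0, noise_sd=0.18,
        compartment_means={"core": 2.0, "rim": 1.9, "margin": 1.1},
        avid_compartments=("core", "rim"),
    )


@dataclass
class PhantomConfig:
    grid_dims: tuple[int, int, int] = (48, 48, 14)
    spacing_mm: tuple[float, float, float] = (2.19, 2.19, 7.0)
    #: tumor center in mm; None puts it mid-hemisphere on the right side
    tumor_center_mm: tuple[float, float, float] | None = None
    core_radius_mm: float = 8.0
    rim_radius_mm: float = 14.0
    margin_radius_mm: float = 17.0
    flt: ModalityParams = field(default_factory=_default_flt)
    fmiso: ModalityParams = field(default_factory=_default_fmiso)
    #: compartments included in the FLAIR hypersignal / CE masks
    flair_compartments: tuple[str, ...] = ("core", "rim", "margin")
    ce_compartments: tuple[str, ...] = ("rim",)
    # DSC acquisition
    tr_s: float = 2.28
    te_ms: float = 60.0
    n_frames: int = 35
    injection_delay_s: float = 20.0
    s0: float = 1000.0
    dsc_noise_sd: float = 0.0
    background_bolus: BolusParams = field(default_factory=BolusParams)
    #: bolus amplitude relative to background per compartment
    bolus_amplitude_factors: dict[str, float] = field(
        default_factory=lambda: {"core": 0.3, "rim": 3.0, "margin": 1.0})
    psf_fwhm_mm: float | None = None
    nawm_radius_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = (self.core_radius_mm, self.rim_radius_mm, self.margin_radius_mm)
        if any(r <= 0 for r in radii):
            raise ValueError("compartment radii must be > 0")
        if not (radii[0] < radii[1] < radii[2]):
            raise ValueError("compartments must nest: core < rim < margin")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dsc_noise_sd < 0 or self.flt.noise_sd < 0 \
                or self.fmiso.noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.s0 <= 0:
            raise ValueError("S0 must be > 0")
        if self.injection_delay_s < self.tr_s:
            raise ValueError("need injection_delay_s >= tr_s")


@dataclass
class PhantomCase:
    flt: VolumeImage
    fmiso: VolumeImage
    dsc: DynamicSeries
    masks: dict[str, BinaryMask]
    truth: dict
    config: PhantomConfig


def _coords_mm(dims, spacing):
    axes = [np.arange(n) * s for n, s in zip(dims, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _sphere(coords, center, radius):
    """Center-of-voxel inclusion: voxel centers within radius of center."""
    d2 = sum((c - c0) ** 2 for c, c0 in zip(coords, center))
    return d2 <= radius ** 2


def make_phantom(config: PhantomConfig) -> PhantomCase:
    """Build a full phantom case (SUV maps, DSC series, masks, truth)."""
    dims, spacing = config.grid_dims, config.spacing_mm
    extent = [n * s for n, s in zip(dims, spacing)]
    coords = _coords_mm(dims, spacing)

    # brain: centered ellipsoid; hemispheres split along the left-right axis
    center = [e / 2 for e in extent]
    brain_vox = sum(
        ((c - c0) / (0.47 * e)) ** 2
        for c, c0, e in zip(coords, center, extent)
    ) <= 1.0
    half = extent[0] / 2
    left_vox = brain_vox & (coords[0] < half)
    right_vox = brain_vox & (coords[0] >= half)

    if config.tumor_center_mm is None:
        tumor_center = (0.72 * extent[0], center[1], center[2])
    else:
        tumor_center = config.tumor_center_mm
    margin_all = _sphere(coords, tumor_center, config.margin_radius_mm)
    rim_all = _sphere(coords, tumor_center, config.rim_radius_mm)
    core = _sphere(coords, tumor_center, config.core_radius_mm) & brain_vox
    rim = rim_all & ~core & brain_vox
    margin = margin_all & ~rim_all & brain_vox
    if not (margin_all & brain_vox).any():
        raise ValueError("tumor compartments fall outside the brain/grid")
    comp = {"core": core, "rim": rim, "margin": margin}

    def union(names):
        out = np.zeros(dims, dtype=bool)
        for n in names:
            out |= comp[n]
        return out

    ce_vox = union(config.ce_compartments)
    flair_vox = union(config.flair_compartments)
    tumor_side = "right" if tumor_center[0] >= half else "left"
    tumor_hemi = right_vox if tumor_side == "right" else left_vox

    # NAWM: mirror of the tumor center into the healthy hemisphere
    nawm_vox = _sphere(coords, (extent[0] - tumor_center[0],
                                tumor_center[1], tumor_center[2]),
                       config.nawm_radius_mm) & brain_vox & ~flair_vox

    def mk(vox):
        return BinaryMask(voxels=vox, spacing=spacing)

    masks = {
        "brain": mk(brain_vox),
        "left_hemisphere": mk(left_vox),
        "right_hemisphere": mk(right_vox),
        "tumor_hemisphere": mk(tumor_hemi),
        "core": mk(core), "rim": mk(rim), "margin": mk(margin),
        "ce": mk(ce_vox), "flair": mk(flair_vox), "nawm": mk(nawm_vox),
    }

    # reproducible substreams per modality
    ss = np.random.SeedSequence(config.seed)
    rng_flt, rng_fmiso, rng_dsc = (
        np.random.default_rng(s) for s in ss.spawn(3))

    def suv(params: ModalityParams, rng) -> VolumeImage:
        vals = np.zeros(dims)
        vals[left_vox] = params.bg("left")
        vals[right_vox] = params.bg("right")
        for name in COMPARTMENTS:
            if name in params.compartment_means:
                vals[comp[name]] = params.compartment_means[name]
        if config.psf_fwhm_mm:
            sigma_vox = [config.psf_fwhm_mm / 2.3548 / s for s in spacing]
            vals = ndimage.gaussian_filter(vals, sigma=sigma_vox)
        if params.noise_sd > 0:
            vals = vals + rng.normal(0, params.noise_sd, size=dims)
        vals[~brain_vox] = 0.0
        return VolumeImage(voxels=vals, spacing=spacing, units="SUV g/mL")

    flt_img = suv(config.flt, rng_flt)
    fmiso_img = suv(config.fmiso, rng_fmiso)
    dsc, true_curves = make_dsc_series(config, masks, rng=rng_dsc)

    truth_masks = {
        "FLT": mk(union(config.flt.avid_compartments)),
        "FMISO": mk(union(config.fmiso.avid_compartments)),
        "rCBV": mk(union(tuple(
            n for n, f in config.bolus_amplitude_factors.items() if f > 1.0))),
    }
    truth = {
        "compartment_means": {
            "FLT": dict(config.flt.compartment_means),
            "FMISO": dict(config.fmiso.compartment_means),
        },
        "background_means": {
            "FLT": {s: config.flt.bg(s) for s in ("left", "right")},
            "FMISO": {s: config.fmiso.bg(s) for s in ("left", "right")},
        },
        "deltaR2star_curves": true_curves,
        "bolus_auc": {
            name: config.background_bolus.auc
            * config.bolus_amplitude_factors.get(name, 1.0)
            for name in COMPARTMENTS
        },
        "background_bolus_auc": config.background_bolus.auc,
        "volumes_ml": {name: volume_ml(m) for name, m in masks.items()},
        "modality_masks": truth_masks,
        "peripheral_volume_pct": {
            label: peripheral_volume_pct(m, masks["ce"])
            for label, m in truth_masks.items()
        },
        "tumor_side": tumor_side,
    }
    return PhantomCase(flt=flt_img, fmiso=fmiso_img, dsc=dsc,
                       masks=masks, truth=truth, config=config)


def make_dsc_series(config: PhantomConfig, masks: dict[str, BinaryMask],
                    rng: np.random.Generator | None = None,
                    ) -> tuple[DynamicSeries, dict[str, np.ndarray]]:
    """Forward DSC signal model on the phantom grid.

    Each compartment (and the background brain) follows a gamma-variate
    dR2*(t) curve; the measured signal is S(t) = S0 * exp(-TE * dR2*(t)),
    constant at S0 before bolus arrival, plus optional Gaussian noise.
    Returns the series and the generating per-compartment curves.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dims = config.grid_dims
    time_s = np.arange(config.n_frames) * config.tr_s
    bg = config.background_bolus
    base_curve = bg.curve(time_s)

    curves = {"background": base_curve}
    for name in COMPARTMENTS:
        factor = config.bolus_amplitude_factors.get(name, 1.0)
        curves[name] = factor * base_curve

    dr2 = np.zeros((config.n_frames,) + tuple(dims))
    brain_vox = masks["brain"].voxels
    dr2[:, brain_vox] = base_curve[:, None]
    for name in COMPARTMENTS:
        vox = masks[name].voxels
        dr2[:, vox] = curves[name][:, None]

    frames = config.s0 * np.exp(-config.te_ms * dr2)
    frames[:, ~brain_vox] = config.s0 * 0.05  # faint extracranial signal
    if config.dsc_noise_sd > 0:
        frames = frames + rng.normal(0, config.dsc_noise_sd, size=frames.shape)
    series = DynamicSeries(
        frames=frames, tr_s=config.tr_s, te_ms=config.te_ms,
        injection_delay_s=config.injection_delay_s,
        spacing=config.spacing_mm,
    )
    return series, curves
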