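"""Per-case orchestration: phantom/ingest -> rCBV -> segmentation -> hot
spots -> peripheral metrics -> report, plus cohort summaries.

Defaults follow the per-modality tuning: FLT segmented with FLAB (2 or 3
classes), FMISO with Mean Contra + 3.3 SDs restricted to the FLAIR
hypersignal, rCBV with Mean Contra + 1.96 SDs restricted to FLAIR; hot spots
at the 95th percentile within FLAIR for every modality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dsc_perfusion import (compute_cbv, contralateral_reference_mask,
                            normalize_rcbv, signal_to_deltaR2star)
from .imaging_io import (BinaryMask, DynamicSeries, VolumeImage, read_mask,
                         read_series, read_volume, resample_to_reference,
                         write_mask, write_volume)
from .segmentation import (contralateral_stats, flab_roi_from_flair, flab_seg,
                           hotspot_seg, stat_threshold_seg)
from .spatial_metrics import metrics_table, overlap_summary
from .synthetic_phantom import PhantomCase, PhantomConfig, make_phantom

log = logging.getLogger(__name__)

COHORT_BIN_EDGES = (0.0, 20.0, 40.0, np.inf)
COHORT_BIN_LABELS = ("0-20%", "20-40%", ">40%")


@dataclass
class ModalityMethod:
    method: str = "stat"  # stat | flab | percent_max | ratio
    k: float = 3.3
    n_classes: int = 2
    fraction: float = 0.4
    factor: float = 1.2
    restrict_to_flair: bool = True


@dataclass
class CaseConfig:
    """Inputs and per-modality method choices for one case.

    Either ``simulate`` is True (inputs come from the phantom generator) or
    the path fields point to co-registered NIfTI files.
    """

    case_id: str = "case"
    simulate: bool = True
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # paths used when simulate is False
    dsc_path: str | None = None
    flt_path: str | None = None
    fmiso_path: str | None = None
    ce_path: str | None = None
    flair_path: str | None = None
    brain_path: str | None = None
    tumor_hemisphere_path: str | None = None
    # per-modality segmentation tuning
    flt_method: ModalityMethod = field(
        default_factory=lambda: ModalityMethod(method="flab", n_classes=2))
    fmiso_method: ModalityMethod = field(
        default_factory=lambda: ModalityMethod(method="stat", k=3.3))
    rcbv_method: ModalityMethod = field(
        default_factory=lambda: ModalityMethod(method="stat", k=1.96))
    hotspot_percentile: float = 95.0
    seed: int = 0


@dataclass
class CaseReport:
    case_id: str
    metrics: pd.DataFrame
    thresholds: dict
    qc: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "metrics": self.metrics.to_dict(orient="records"),
            "thresholds": self.thresholds,
            "qc": self.qc,
            "provenance": self.provenance,
        }


def _config_hash(config: CaseConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        return str(o)
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: CaseConfig):
    if config.simulate:
        cfg = dataclasses.replace(config.phantom, seed=config.seed)
        case = make_phantom(cfg)
        return case
    masks = {
        "ce": read_mask(config.ce_path),
        "flair": read_mask(config.flair_path),
        "brain": read_mask(config.brain_path),
        "tumor_hemisphere": read_mask(config.tumor_hemisphere_path),
    }
    return PhantomCase(
        flt=read_volume(config.flt_path, units="SUV g/mL"),
        fmiso=read_volume(config.fmiso_path, units="SUV g/mL"),
        dsc=read_series(config.dsc_path),
        masks=masks, truth={}, config=None,
    )


def run_case(config: CaseConfig, out_dir: str | Path | None = None) -> CaseReport:
    """Run the full multiparametric analysis for one case.

    Deterministic given config and seed; if ``out_dir`` is given, all
    intermediate maps/masks plus ``report.json`` and a CSV row are written so
    every reported number is recomputable from saved artifacts.
    """
    case = _load_inputs(config)
    masks = case.masks
    ref = case.flt  # reference grid: the FLT PET grid (configurable upstream)
    thresholds: dict = {}
    qc: dict = {}

    def on_ref(img, mode):
        return resample_to_reference(img, ref, mode=mode)

    ce = on_ref(masks["ce"], "nearest")
    flair = on_ref(masks["flair"], "nearest")
    brain = on_ref(masks["brain"], "nearest")
    tumor_hemi = on_ref(masks["tumor_hemisphere"], "nearest")
    contra = contralateral_reference_mask(brain, tumor_hemi, flair)

    # --- rCBV from the DSC series -----------------------------------------
    log.info("[%s] rCBV stage", config.case_id)
    dsc_brain = resample_to_reference(
        brain, case.dsc.spatial_reference(), mode="nearest")
    conc = signal_to_deltaR2star(case.dsc, dsc_brain)
    cbv, fit_qc = compute_cbv(conc)
    qc["dsc_fit"] = fit_qc
    dsc_contra = resample_to_reference(
        contra, case.dsc.spatial_reference(), mode="nearest")
    rcbv = normalize_rcbv(cbv, dsc_contra)
    rcbv = on_ref(rcbv, "trilinear")

    # --- per-modality tumor volumes ---------------------------------------
    maps = {"FLT": case.flt, "FMISO": on_ref(case.fmiso, "trilinear"),
            "rCBV": rcbv}
    methods = {"FLT": config.flt_method, "FMISO": config.fmiso_method,
               "rCBV": config.rcbv_method}
    seg_masks, hot_masks = {}, {}
    for label, img in maps.items():
        m = methods[label]
        restrict = flair if m.restrict_to_flair else None
        if m.method == "flab":
            roi = flab_roi_from_flair(flair)
            res = flab_seg(img, m.n_classes, roi, seed=config.seed)
        elif m.method == "stat":
            stats = contralateral_stats(img, contra, source="mirror")
            res = stat_threshold_seg(img, stats, m.k, restrict=restrict)
            qc[f"contralateral_{label}"] = {
                "mean": stats.mean, "sd": stats.sd, "n": stats.n_voxels}
        else:
            raise ValueError(
                f"unsupported method {m.method!r} for {label} in run_case")
        seg_masks[label] = res.mask
        thresholds[label] = {
            "method": res.method, "threshold_value": res.threshold_value,
            "params": {k: v for k, v in res.params.items()
                       if not isinstance(v, list)},
        }
        hot = hotspot_seg(img, flair, percentile=config.hotspot_percentile)
        hot_masks[label] = hot.mask
        thresholds[f"{label}_hotspot"] = {
            "method": hot.method, "threshold_value": hot.threshold_value,
            "params": hot.params,
        }

    rows = overlap_summary(seg_masks, ce, hotspots=hot_masks)
    table = metrics_table(rows)
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "simulated": config.simulate,
    }
    report = CaseReport(case_id=config.case_id, metrics=table,
                        thresholds=thresholds, qc=qc, provenance=provenance)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(rcbv, out / "rcbv.nii.gz")
        write_volume(cbv, out / "cbv.nii.gz")
        for label, m in seg_masks.items():
            write_mask(m, out / f"seg_{label.lower()}.nii.gz")
        for label, m in hot_masks.items():
            write_mask(m, out / f"hotspot_{label.lower()}.nii.gz")
        write_mask(ce, out / "ce.nii.gz")
        write_mask(flair, out / "flair.nii.gz")
        write_mask(contra, out / "contralateral.nii.gz")
        (out / "report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2, sort_keys=True))
        table.assign(case_id=config.case_id).to_csv(
            out / "metrics.csv", index=False)
    return report


def summarize_cohort(reports: list[CaseReport]) -> pd.DataFrame:
    """Per-modality min/max/median peripheral volume % and binned counts.

    Bins follow the reporting convention 0-20%, 20-40%, >40%.
    """
    if not reports:
        raise ValueError("no case reports to summarize")
    frames = [r.metrics.assign(case_id=r.case_id) for r in reports]
    all_rows = pd.concat(frames, ignore_index=True)
    out = []
    for label, grp in all_rows.groupby("modality", sort=True):
        vals = grp["peripheral_volume_pct"].to_numpy()
        counts = np.histogram(vals, bins=COHORT_BIN_EDGES)[0]
        row = {
            "modality": label,
            "n_cases": len(vals),
            "min_pct": float(vals.min()),
            "median_pct": float(np.median(vals)),
            "max_pct": float(vals.max()),
        }
        row.update({f"bin_{lab}": int(c)
                    for lab, c in zip(COHORT_BIN_LABELS, counts)})
        out.append(row)
    return pd.DataFrame(out)
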