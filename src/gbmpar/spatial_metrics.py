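"""Volumes and peripheral-volume / peripheral-hot-spot percentages.

The two headline per-patient statistics compare each modality's segmented
ROI with the contrast-enhancement (CE) ROI on T1w-Gd MRI:

    peripheral volume (%)   = 100 * |modality NOT CE| / |CE|
    peripheral hot spot (%) = 100 * |hot spot NOT CE| / |CE|

The denominator is always the CE volume, which is why peripheral volume can
exceed 100% when a modality's ROI extends far beyond the enhancing rim.
Percentages are computed from voxel counts on the shared grid (exact);
volumes in mL are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .imaging_io import BinaryMask, mask_ops

__all__ = [
    "PeripheralMetrics",
    "volume_ml",
    "peripheral_volume_pct",
    "peripheral_hotspot_pct",
    "overlap_summary",
]


@dataclass
class PeripheralMetrics:
    modality: str
    volume_ml: float
    ce_volume_ml: float
    overlap_ml: float
    peripheral_volume_pct: float
    peripheral_hotspot_pct: float | None = None
    hotspot_volume_ml: float | None = None


def volume_ml(mask: BinaryMask) -> float:
    """True-voxel count times voxel volume (mm^3), in mL."""
    return mask.count * mask.voxel_volume_mm3 / 1000.0


def _check_ce(modality: BinaryMask, ce: BinaryMask) -> None:
    modality.check_geometry(ce)
    if ce.count == 0:
        raise ValueError("CE mask is empty: peripheral percentage undefined")


def peripheral_volume_pct(modality: BinaryMask, ce: BinaryMask) -> float:
    """100 * |modality AND NOT ce| / |ce| (voxel counts, shared grid)."""
    _check_ce(modality, ce)
    outside = mask_ops(modality, ce, "NOT").count
    return 100.0 * outside / ce.count


def peripheral_hotspot_pct(hotspot: BinaryMask, ce: BinaryMask) -> float:
    """100 * |hotspot AND NOT ce| / |ce|."""
    return peripheral_volume_pct(hotspot, ce)


def overlap_summary(masks: dict[str, BinaryMask], ce: BinaryMask,
                    hotspots: dict[str, BinaryMask] | None = None,
                    ) -> list[PeripheralMetrics]:
    """One PeripheralMetrics row per labelled modality mask.

    ``hotspots`` maps the same labels to hot-spot masks where available.
    """
    hotspots = hotspots or {}
    rows = []
    for label, mask in masks.items():
        _check_ce(mask, ce)
        overlap = mask_ops(mask, ce, "AND")
        row = PeripheralMetrics(
            modality=label,
            volume_ml=volume_ml(mask),
            ce_volume_ml=volume_ml(ce),
            overlap_ml=volume_ml(overlap),
            peripheral_volume_pct=peripheral_volume_pct(mask, ce),
        )
        hs = hotspots.get(label)
        if hs is not None:
            row.peripheral_hotspot_pct = peripheral_hotspot_pct(hs, ce)
            row.hotspot_volume_ml = volume_ml(hs)
        rows.append(row)
    return rows


def metrics_table(rows: list[PeripheralMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])
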