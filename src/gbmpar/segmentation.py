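"""Tumor-volume and hot-spot segmentation on SUV and rCBV maps.

Four delineation families, each tuned per modality:

* statistical contralateral threshold — Mean Contra + k SDs (k = 3.3 for
  FMISO SUV, 1.96 for rCBV), optionally restricted to the FLAIR hypersignal;
* percent-of-maximum — e.g. 40% of SUVmax for FLT;
* reference-ratio — e.g. 1.2 tissue-to-blood for FMISO, 2-3x the
  normal-appearing white-matter signal for CBV;
* FLAB — fuzzy locally adaptive Bayesian classification with 2 or 3
  intensity classes, the FLT default.

Hot spots are the voxels at or above the 95th percentile of the map's
histogram within the FLAIR hypersignal ROI.

Threshold strictness: statistical and ratio rules use strict ``>``;
percentile and percent-of-max use ``>=`` so a constant ROI yields a full,
not empty, hot spot.  Invalid (non-finite) voxels are excluded from every
statistic and never selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import BinaryMask, VolumeImage

__all__ = [
    "ContralateralStats",
    "SegmentationResult",
    "contralateral_stats",
    "stat_threshold_seg",
    "percent_max_seg",
    "ratio_seg",
    "flab_seg",
    "flab_roi_from_flair",
    "hotspot_seg",
    "suv_map",
]


@dataclass
class ContralateralStats:
    """Mean and sample SD of a map over a contralateral (healthy) ROI."""

    mean: float
    sd: float
    n_voxels: int
    source: str = ""


@dataclass
class SegmentationResult:
    """A binary tumor/hot-spot mask with its method and realized threshold.

    The mask is reproducible from ``threshold_value`` and the recorded rule;
    FLAB has no scalar threshold (``threshold_value`` is None).
    """

    mask: BinaryMask
    method: str  # stat_threshold | percent_max | ratio | flab | hotspot
    threshold_value: float | None
    params: dict = field(default_factory=dict)


def _finite(map_: VolumeImage) -> np.ndarray:
    return np.isfinite(map_.voxels)


def contralateral_stats(map_: VolumeImage, contra: BinaryMask,
                        source: str = "") -> ContralateralStats:
    """Mean and sample SD (ddof=1) of map values in the contralateral ROI."""
    map_.check_geometry(contra)
    sel = contra.voxels & _finite(map_)
    vals = map_.voxels[sel]
    if vals.size < 2:
        raise ValueError("contralateral ROI must contain >= 2 finite voxels")
    return ContralateralStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_voxels=int(vals.size),
        source=source,
    )


def stat_threshold_seg(map_: VolumeImage, stats: ContralateralStats,
                       k: float,
                       restrict: BinaryMask | None = None) -> SegmentationResult:
    """Select voxels with value strictly above Mean Contra + k SDs.

    With Gaussian background this keeps the upper-tail fraction Phi-bar(k) of
    healthy voxels — 2.5% at k = 1.96, 4.83e-4 at k = 3.3 — which is the
    statistical meaning the modality thresholds rely on.  ``restrict``
    (typically the FLAIR hypersignal) is intersected with the result.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    thr = stats.mean + k * stats.sd
    sel = _finite(map_) & (map_.voxels > thr)
    if restrict is not None:
        map_.check_geometry(restrict)
        sel &= restrict.voxels
    return SegmentationResult(
        mask=BinaryMask.like(map_, sel),
        method="stat_threshold",
        threshold_value=float(thr),
        params={"k": k, "mean": stats.mean, "sd": stats.sd,
                "restricted": restrict is not None},
    )


def percent_max_seg(map_: VolumeImage, fraction: float,
                    search: BinaryMask) -> SegmentationResult:
    """Select voxels in the search ROI at or above fraction * max."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    map_.check_geometry(search)
    sel0 = search.voxels & _finite(map_)
    if not sel0.any():
        raise ValueError("empty search region")
    thr = fraction * float(map_.voxels[sel0].max())
    sel = sel0 & (map_.voxels >= thr)
    return SegmentationResult(
        mask=BinaryMask.like(map_, sel),
        method="percent_max",
        threshold_value=thr,
        params={"fraction": fraction},
    )


def ratio_seg(map_: VolumeImage, reference_value: float, factor: float,
              restrict: BinaryMask | None = None) -> SegmentationResult:
    """Select voxels strictly above factor * reference_value.

    ``reference_value`` is e.g. the blood-pool activity (tissue-to-blood
    segmentation, factor 1.2) or the normal-appearing white-matter mean
    (CBV segmentation, factor 2 or 3).
    """
    if reference_value <= 0:
        raise ValueError("reference_value must be > 0")
    if factor <= 0:
        raise ValueError("factor must be > 0")
    thr = factor * reference_value
    sel = _finite(map_) & (map_.voxels > thr)
    if restrict is not None:
        map_.check_geometry(restrict)
        sel &= restrict.voxels
    return SegmentationResult(
        mask=BinaryMask.like(map_, sel),
        method="ratio",
        threshold_value=float(thr),
        params={"reference_value": reference_value, "factor": factor},
    )


# ---------------------------------------------------------------------------
# FLAB


def flab_roi_from_flair(flair: BinaryMask, dilate: int = 2) -> BinaryMask:
    """Default FLAB operator ROI: the FLAIR bounding box dilated by 2 voxels."""
    if not flair.voxels.any():
        raise ValueError("empty FLAIR mask")
    box = np.zeros_like(flair.voxels)
    sl = ndimage.find_objects(flair.voxels.astype(np.int8))[0]
    box[sl] = True
    return flair.with_voxels(ndimage.binary_dilation(box, iterations=dilate))


def flab_seg(map_: VolumeImage, n_classes: int, roi: BinaryMask,
             n_fuzzy_levels: int = 3, max_iter: int = 100,
             tol: float = 1e-6, seed: int = 0) -> SegmentationResult:
    """Fuzzy locally adaptive Bayesian class segmentation.

    Voxels inside the ROI are modelled with ``n_classes`` Gaussian intensity
    classes plus fuzzy transition levels between adjacent classes (mixed
    voxels at the class interface, mean and variance interpolated between the
    two pure classes).  Class parameters are re-estimated iteratively from
    posterior responsibilities; a locally adaptive step re-weights each
    voxel's class prior by the label composition of its 3x3x3 neighborhood,
    so isolated misclassifications in noisy regions are suppressed.  The
    tumor mask is the highest-mean pure class plus the fuzzy voxels leaning
    toward it.  Deterministic given ``seed`` (used only for parameter
    initialisation jitter on degenerate starts).
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    map_.check_geometry(roi)
    region = roi.voxels & _finite(map_)
    vals = map_.voxels[region]
    if vals.size < 10 * n_classes:
        raise ValueError(
            f"ROI too small for {n_classes}-class FLAB ({vals.size} voxels)"
        )
    if np.ptp(vals) == 0:
        raise ValueError("constant intensities in ROI: FLAB is degenerate")

    # pure-class init from quantiles of the ROI histogram
    qs = np.linspace(0, 1, n_classes + 2)[1:-1]
    means = np.quantile(vals, qs).astype(float)
    if np.ptp(means) == 0:
        rng = np.random.default_rng(seed)
        means = means + rng.normal(0, vals.std() / 10, size=n_classes)
        means.sort()
    sds = np.full(n_classes, max(vals.std() / n_classes, 1e-12))
    priors = np.full(n_classes, 1.0 / n_classes)

    # fuzzy levels between adjacent pure classes: weight w toward upper class
    ws = np.linspace(0, 1, n_fuzzy_levels + 2)[1:-1]

    def component_params(means, sds):
        mu = list(means)
        sg = list(sds)
        comp_pair = [None] * n_classes  # pure
        for c in range(n_classes - 1):
            for w in ws:
                mu.append((1 - w) * means[c] + w * means[c + 1])
                sg.append(np.sqrt((1 - w) * sds[c] ** 2 + w * sds[c + 1] ** 2))
                comp_pair.append((c, c + 1, w))
        return np.array(mu), np.array(sg), comp_pair

    def comp_priors(priors):
        # fuzzy components share a fixed fraction of the adjacent priors
        out = list(priors * 0.8)
        for c in range(n_classes - 1):
            share = 0.2 * (priors[c] + priors[c + 1]) / (2 * n_fuzzy_levels)
            out.extend([share] * n_fuzzy_levels)
        arr = np.array(out)
        return arr / arr.sum()

    x = vals
    converged = False
    for _ in range(max_iter):
        mu, sg, comp_pair = component_params(means, sds)
        pr = comp_priors(priors)
        sg = np.maximum(sg, 1e-12)
        logp = (-0.5 * ((x[:, None] - mu[None, :]) / sg[None, :]) ** 2
                - np.log(sg[None, :]) + np.log(pr[None, :]))
        logp -= logp.max(axis=1, keepdims=True)
        resp = np.exp(logp)
        resp /= resp.sum(axis=1, keepdims=True)

        # fold fuzzy responsibilities back into the pure classes by weight
        class_resp = resp[:, :n_classes].copy()
        for j in range(n_classes, resp.shape[1]):
            c_lo, c_hi, w = comp_pair[j]
            class_resp[:, c_lo] += (1 - w) * resp[:, j]
            class_resp[:, c_hi] += w * resp[:, j]

        new_means = np.empty(n_classes)
        new_sds = np.empty(n_classes)
        for c in range(n_classes):
            wts = class_resp[:, c]
            tot = wts.sum()
            if tot <= 1e-12:
                new_means[c], new_sds[c] = means[c], sds[c]
                continue
            new_means[c] = np.average(x, weights=wts)
            new_sds[c] = np.sqrt(
                np.average((x - new_means[c]) ** 2, weights=wts))
        new_priors = class_resp.mean(axis=0)
        new_priors /= new_priors.sum()
        order = np.argsort(new_means)
        new_means, new_sds, new_priors = (
            new_means[order], new_sds[order], new_priors[order])
        shift = np.max(np.abs(new_means - means))
        means, sds, priors = new_means, np.maximum(new_sds, 1e-12), new_priors
        if shift < tol * max(np.ptp(vals), 1e-12):
            converged = True
            break

    # final responsibilities with locally adaptive prior re-weighting
    mu, sg, comp_pair = component_params(means, sds)
    pr = comp_priors(priors)
    sg = np.maximum(sg, 1e-12)
    logp = (-0.5 * ((x[:, None] - mu[None, :]) / sg[None, :]) ** 2
            - np.log(sg[None, :]) + np.log(pr[None, :]))
    labels = np.argmax(logp, axis=1)

    # voxel class weight toward each pure class
    class_w = np.zeros((x.size, n_classes))
    for j in range(len(mu)):
        isj = labels == j
        if j < n_classes:
            class_w[isj, j] = 1.0
        else:
            c_lo, c_hi, w = comp_pair[j]
            class_w[isj, c_lo] = 1 - w
            class_w[isj, c_hi] = w

    # local adaptation: smooth class weights over the 3^3 neighborhood and
    # use them as a spatial prior on a second labelling pass
    wmaps = np.zeros(map_.voxels.shape + (n_classes,))
    for c in range(n_classes):
        tmp = np.zeros(map_.voxels.shape)
        tmp[region] = class_w[:, c]
        cnt = ndimage.uniform_filter(region.astype(float), size=3)
        sm = ndimage.uniform_filter(tmp, size=3)
        with np.errstate(invalid="ignore", divide="ignore"):
            wmaps[..., c] = np.where(cnt > 0, sm / cnt, 0.0)
    local_prior = np.clip(wmaps[region], 1e-3, None)
    local_prior /= local_prior.sum(axis=1, keepdims=True)
    logp_pure = (-0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
                 - np.log(sds[None, :]) + np.log(local_prior))
    final_class = np.argmax(logp_pure, axis=1)

    tumor = final_class == (n_classes - 1)
    sel = np.zeros_like(region)
    sel[region] = tumor
    return SegmentationResult(
        mask=BinaryMask.like(map_, sel),
        method="flab",
        threshold_value=None,
        params={
            "n_classes": n_classes,
            "class_means": means.tolist(),
            "class_sds": sds.tolist(),
            "class_priors": priors.tolist(),
            "converged": bool(converged),
            "n_fuzzy_levels": n_fuzzy_levels,
        },
    )


def hotspot_seg(map_: VolumeImage, flair: BinaryMask,
                percentile: float = 95.0) -> SegmentationResult:
    """Hot spot: voxels at or above the given percentile of the map's
    histogram within the FLAIR hypersignal ROI.

    The percentile is linearly interpolated between order statistics; the
    ``>=`` rule means a constant ROI yields a full hot spot.  The result is
    always a subset of the FLAIR mask.
    """
    map_.check_geometry(flair)
    sel0 = flair.voxels & _finite(map_)
    if not sel0.any():
        raise ValueError("empty FLAIR ROI")
    thr = float(np.percentile(map_.voxels[sel0], percentile))
    sel = sel0 & (map_.voxels >= thr)
    return SegmentationResult(
        mask=BinaryMask.like(map_, sel),
        method="hotspot",
        threshold_value=thr,
        params={"percentile": percentile},
    )


def suv_map(activity: VolumeImage, injected_activity_kbq: float,
            body_weight_g: float) -> VolumeImage:
    """Standardized uptake value: tissue activity (kBq/mL) divided by the
    injected activity per gram of body weight (kBq/g); units g/mL."""
    if injected_activity_kbq <= 0:
        raise ValueError("injected_activity_kbq must be > 0")
    if body_weight_g <= 0:
        raise ValueError("body_weight_g must be > 0")
    dose_per_g = injected_activity_kbq / body_weight_g
    return activity.with_voxels(activity.voxels / dose_per_g,
                                units="SUV g/mL")
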