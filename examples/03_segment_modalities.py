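"""Segment tumor volumes with the per-modality methods.

FLT with FLAB (2 classes), FMISO with Mean Contra + 3.3 SDs within FLAIR,
and a 95th-percentile hot spot within the FLAIR hypersignal.
"""

from gbmpar import (PhantomConfig, contralateral_stats, flab_seg, hotspot_seg,
                    make_phantom, stat_threshold_seg, volume_ml)
from gbmpar.dsc_perfusion import contralateral_reference_mask
from gbmpar.segmentation import flab_roi_from_flair

case = make_phantom(PhantomConfig(seed=1))
flair = case.masks["flair"]
contra = contralateral_reference_mask(
    case.masks["brain"], case.masks["tumor_hemisphere"], flair)

flab = flab_seg(case.flt, 2, flab_roi_from_flair(flair))
print(f"FLT / FLAB        : {volume_ml(flab.mask):6.2f} mL "
      f"(class means {['%.2f' % m for m in flab.params['class_means']]})")

stats = contralateral_stats(case.fmiso, contra)
stat = stat_threshold_seg(case.fmiso, stats, k=3.3, restrict=flair)
print(f"FMISO / +3.3 SD   : {volume_ml(stat.mask):6.2f} mL "
      f"(threshold {stat.threshold_value:.3f} SUV; "
      f"contra {stats.mean:.2f} +- {stats.sd:.2f})")

hot = hotspot_seg(case.flt, flair, percentile=95)
print(f"FLT hot spot      : {volume_ml(hot.mask):6.2f} mL "
      f"(95th-percentile threshold {hot.threshold_value:.3f} SUV)")
print("Each mask is reproducible from its recorded threshold and rule.")
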