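"""Generate a digital glioblastoma phantom case and inspect its ground truth.

The phantom is a two-hemisphere brain with a tumor built from nested
compartments (necrotic core, enhancing rim, infiltrative margin), FLT/FMISO
SUV maps, a DSC-MRI series, and every mask the pipeline needs.
"""

from gbmpar import PhantomConfig, make_phantom

case = make_phantom(PhantomConfig(seed=1))

print("grid:", case.flt.shape, "spacing (mm):", case.flt.spacing)
print("volumes (mL):")
for name in ("brain", "ce", "flair", "core", "rim", "margin"):
    print(f"  {name:8s} {case.truth['volumes_ml'][name]:8.2f}")
print("truth peripheral volume % vs CE (the fraction of each modality's")
print("true ROI lying outside the contrast-enhancing rim):")
for label, pct in case.truth["peripheral_volume_pct"].items():
    print(f"  {label:6s} {pct:6.1f} %")
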