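"""Inpainting ablation and parameter sweeps on a phantom suite.

The ablation runs the pipeline with and without the BSCB stage and
compares paired F-scores: the method's claim is that filling the
vessels first makes the cup more uniform and the segmentation better.
The sweep harness mirrors the structuring-element / median-window size
studies.

Scaled-down phantoms (240 px) keep this demo around a minute.
"""

from cupseg import PhantomSpec, ablation_inpainting, make_suite, parameter_sweep

base = PhantomSpec(
    height=240, width=240, disc_center=(120.0, 120.0),
    disc_axes=(55.0, 62.0), cup_axes=(27.0, 31.0),
    rim_softness=4.0, vessel_width=2.0,
)
suite = make_suite(6, base, seed=3)

report = ablation_inpainting(suite)
print("inpainting ablation (paired F-scores):")
for pair in report["pairs"]:
    print(f"  phantom {pair['index']}: with={pair['f_with']:.3f}  without={pair['f_without']:.3f}")
print(f"median F with inpainting   : {report['median_f_with']:.3f}")
print(f"median F without inpainting: {report['median_f_without']:.3f}")

rows = parameter_sweep(suite[:3], None, "vessels.median_size", [5, 9, 13])
print("\nmedian-window sweep (mean F over 3 phantoms):")
for row in rows:
    print(f"  {row['value']:2d} px: F = {row['f_mean']:.3f} +- {row['f_sd']:.3f}")

# A higher median F with inpainting than without reproduces the central
# claim; the sweep typically peaks at an interior window size rather
# than growing monotonically.
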