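"""Measure inflammation as the percent area covered by macrophage staining.

Macrophages aggregate in necrotic regions, so individual cells cannot be
counted; coverage of the frame is the reported quantity.
"""

from myohisto import SceneParams, default_config, generate_scene, render_fluorescence, run_cd68

params = SceneParams(n_fibers=100, aggregate_count=16, aggregate_radius=13, seed=1)
truth = generate_scene(params)
image = render_fluorescence(truth, "cd68", params)

result = run_cd68(image, default_config("cd68"))

print(f"true painted area    : {truth.summary['marker_pct_area']:.2f}% of the frame")
print(f"measured marker area : {result.percent['pct_area']:.2f}% of the frame")
print(f"foreground pixels    : {result.counts['foreground_pixels']}"
      f" / {result.counts['total_pixels']}")
# Segmentation uses minimum-cross-entropy thresholding of the marker
# channel; the denominator is the full image frame.
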