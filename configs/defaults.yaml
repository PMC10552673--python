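# Annotated default configuration for the myohisto assay pipelines.
#
# Any file passed via --config (or myohisto.load_config) may contain a
# subset of these keys; whatever is omitted keeps the assay's built-in
# default. The `assay` key selects which built-in defaults to start from
# (it can also be given on the command line / function call instead).
#
# All intensities are on the [0, 1] scale; all diameters and sigmas are
# in pixels. Diameters are *area-equivalent* diameters, 2*sqrt(area/pi).

assay: ebd            # one of: ebd, emyhc, cd68, collagen

# Which stain sits in which channel. Staining conventions differ between
# assays (ebd: laminin green / dye red; emyhc & cd68: laminin red /
# marker green), so this is explicit configuration, never hardcoded.
channel_roles:
  laminin: green
  ebd: red

# Exponent of the pixel-power masking step (ebd assay only). Squaring
# darkens mid-gray pixels so dye-positive fibers drop out of the
# "dye-negative" identification pass; a larger exponent masks harder.
square_exponent: 2

# Fiber-scale identification (the "all muscle cells" passes).
cell_params:
  min_diameter: 8       # objects below this equivalent diameter are discarded
  max_diameter: 250
  declump: true         # split touching fibers by smoothed-distance watershed
  smoothing_sigma: 8    # Gaussian sigma on the distance transform; larger
                        #   merges over-segmented fibers, smaller splits
                        #   under-segmented clumps ("auto" = min_diameter/4)
  min_seed_distance: 40 # minimum spacing of watershed seeds ("auto" = min_diameter/2)
  fill_holes: true
  discard_border: false # border-clipped fibers are counted
  threshold:
    method: robust_background   # or min_cross_entropy, manual
    n_sd: 2                     # threshold = trimmed mean + n_sd * trimmed SD
    trim_low: 0.05              # dimmest fraction discarded before the stats
    trim_high: 0.05             # brightest fraction discarded (the foreground)
    lower_bound: 0.5            # clamp range for the selected threshold; the
    upper_bound: 0.7            #   first knob to adjust when detection fails
    # manual_value: 0.5         # required iff method is manual
    # bins: 256                 # histogram resolution for min_cross_entropy
    # pre_apply_sigma: 0        # blur before threshold *application* only

# Marker-scale identification (emyhc positives, cd68 aggregates,
# collagen). Unused by the ebd assay, whose two passes share cell_params
# so that the count subtraction compares like with like.
marker_params:
  min_diameter: 10
  max_diameter: 150
  declump: false
  fill_holes: true
  threshold:
    method: robust_background
    lower_bound: 0.3
    upper_bound: 0.6
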