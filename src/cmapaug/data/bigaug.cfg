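# strategy: bigaug
# use_colormap: false
# Benchmark stack: three transform families (image quality, image
# appearance, spatial), fewer members than the extensive stack but with
# stronger magnitudes.  These ranges are a configuration choice, not a
# tabulated reference.
gaussian_blur p=0.5 sigma=0.25..1.5
sharpen p=0.5 alpha=0.1..0.5
gaussian_noise p=0.5 var=0.01..0.1
brightness_contrast p=0.5 brightness=-0.3..0.3 contrast=0
brightness_contrast p=0.5 brightness=0 contrast=-0.3..0.3
intensity_shift p=0.5 shift=-0.2..0.2
rotation p=0.5 angle=-20..20
affine_scale p=0.5 scale=0.6..1.4
elastic p=0.5 alpha=10 sigma=3 alpha_affine=-4..4
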