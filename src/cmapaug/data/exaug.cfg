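# strategy: exaug
# use_colormap: false
# 14 transforms in application order; ranges are uniform sampling bounds.
# The optical distortion upper bound of 5 is shipped as tabulated; it may be
# a typo for 0.5 in the original table, which cannot be settled from text.
centercrop_resize p=0.5 size=200..220 out=256
rotation p=0.5 angle=-10..10
affine_scale p=0.5 scale=0.8..1.2
affine_translate p=0.5 px=5..10
optical_distortion p=0.5 distort_limit=-0.5..5 shift_limit=0
elastic p=0.5 alpha=4 sigma=2 alpha_affine=-2..2
oneof p=0.5
    sharpen p=0.3 alpha=0.1..0.3
    gaussian_blur p=0.2 sigma=0.25..1.5
    gaussian_noise p=0.3 var=0.005..0.01
    motion_blur p=0.2 ksize=3..7
intensity_shift p=0.5 shift=-0.1..0.1
oneof p=0.5
    brightness_contrast p=0.5 brightness=-0.1..0.1 contrast=0
    gamma p=0.5 gamma=50..150
    color_jitter p=0.5 brightness=0.6..1.5 contrast=0.6..1.5 saturation=0.6..1.5 hue=-0.25..0.25
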