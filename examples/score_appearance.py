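"""Score the appearance of a cooked-rice image via its yellow area.

Builds a synthetic frame with a known fraction of yellow-hued grain
pixels, then runs the HSV-threshold classifier and reports the yellow
area as a percentage of the frame.  Larger yellow area means duller,
yellower rice — worse sensory appearance.
"""

from riceq import ImageSpec, make_image, rgb_to_hsv, yellow_area_percent, yellow_mask

# a frame emulating a low-appearance sample: about half the frame yellow
spec = ImageSpec(yellow_fraction=0.53, seed=42)
image, truth = make_image(spec)

mask = yellow_mask(rgb_to_hsv(image), hue_threshold=0.167)
percent = yellow_area_percent(mask)

print(f"frame: {image.shape[0]}x{image.shape[1]} px")
print(f"ground-truth yellow area: {truth.yellow_area_percent:.2f}%")
print(f"recovered yellow area:    {percent:.2f}%")
print(f"yellow pixels: {mask.n_yellow} of {mask.n_total}")
print()
print("A yellow area near 53% is typical of rice a panel scores around -2")
print("on the -3..+3 appearance scale; near 7% corresponds to white,")
print("glossy rice the panel scores positively.")
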