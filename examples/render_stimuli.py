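"""Render the three stimulus classes used in the experiment.

Shows the luminance mapping of a contrast-scaled sketch, a drifting noisy
Gabor (motion task), and the 10 Hz uniform flicker adapter.
"""

import numpy as np

from fastvision import (
    FlickerSpec,
    GaborSpec,
    Sketch,
    make_flicker_frames,
    make_gabor_frames,
    michelson_contrast,
    render_at_contrast,
)
from fastvision.sketch import BACKGROUND, BLACK, WHITE

# a toy sketch: one black and one white pixel on background
px = np.full((5, 5), BACKGROUND, dtype=np.int8)
px[1, 1], px[3, 3] = BLACK, WHITE
sketch = Sketch(px)
for c in (0.0, 0.5, 1.0):
    lum = render_at_contrast(sketch, c)
    print(
        f"contrast {c:.1f}: black pixel {lum[1,1]:5.1f} cd/m^2, "
        f"white pixel {lum[3,3]:5.1f} cd/m^2, background {lum[0,0]:.1f}"
    )
print(f"full-contrast Michelson contrast: {michelson_contrast(22, 7):.3f}")

gabor = GaborSpec(spatial_freq=1.0, temporal_freq=10.0, size=5.0, contrast=0.1)
stack = make_gabor_frames(gabor, duration=25.0, frame_rate=120.0, direction="right")
print(f"motion stimulus: {len(stack)} frames of {stack.frames.shape[1:]} px "
      f"(25 ms at 120 Hz), clipped fraction {stack.clip_fraction:.3f}")

adapter = make_flicker_frames(FlickerSpec(), duration=2000.0, frame_rate=120.0)
levels = adapter.frames[:, 0, 0]
print(f"flicker adapter: {len(adapter)} frames, first 13 luminances: {levels[:13]}")
# 6 high frames then 6 low frames = one 10 Hz alternation cycle at 120 Hz.
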