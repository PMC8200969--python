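import numpy as np

from dermaflux.core_io import SkinImage


def as_calibrated(img: SkinImage) -> SkinImage:
    """Mark a synthetic raw image as calibrated without changing pixels.

    Generator output with unit gains is already in the calibrated frame;
    this skips the tip round-trip for tests that do not exercise it.
    """
    return SkinImage(
        pixels=img.pixels,
        bit_depth_origin=img.bit_depth_origin,
        color_state="calibrated",
        meta=img.meta,
    )


def constant_image(value=0.5, shape=(128, 128), rgb=None) -> SkinImage:
    px = np.empty(shape + (3,))
    px[:] = rgb if rgb is not None else (value, value, value)
    return SkinImage(pixels=px, bit_depth_origin=16, color_state="calibrated")
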