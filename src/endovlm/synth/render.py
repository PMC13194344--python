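"""Glyph-coded frame rendering and the rule-based decoding oracle.

Each landmark class owns a fixed colour and a home cell on a regular grid.
A present class is drawn as a filled square glyph at its home cell with a
seeded positional jitter, over a dark textured background with additive
pixel noise.  `oracle_decode_frame` recovers the landmark vector from
pixels by colour/position matching — a non-learned proof that the images
carry the label information the classification task needs.
"""

from __future__ import annotations

import colorsys

import numpy as np

from .config import GeneratorConfig
from .procedures import LandmarkVector

BACKGROUND = np.array([70.0, 45.0, 40.0])   # dark reddish cavity tone
GLYPH_FRACTION = 0.55                        # glyph side / cell side
COLOR_TOLERANCE = 60.0                       # Euclidean RGB match radius


def _grid(config: GeneratorConfig) -> tuple[int, int]:
    cells = int(np.ceil(np.sqrt(config.n_classes)))
    return cells, config.image_size // cells


def glyph_palette(n_classes: int) -> np.ndarray:
    """(n, 3) distinct saturated colours, evenly spaced in hue."""
    cols = [colorsys.hsv_to_rgb(j / n_classes, 1.0, 1.0) for j in range(n_classes)]
    return np.array(cols) * 255.0


def _geometry(config: GeneratorConfig):
    cells, cell = _grid(config)
    glyph = max(3, int(cell * GLYPH_FRACTION) | 1)
    jitter = max(0, (cell - glyph) // 2 - 1)
    return cells, cell, glyph, jitter


def render_frame(lv: LandmarkVector, config: GeneratorConfig,
                 frame_seed: int) -> np.ndarray:
    """Render a (H, W, 3) uint8 frame encoding the given landmark vector."""
    if len(lv) != config.n_classes:
        raise ValueError("landmark vector length must equal n_classes")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x1F9, frame_seed]))
    size = config.image_size
    cells, cell, glyph, jitter = _geometry(config)
    palette = glyph_palette(config.n_classes)
    img = np.tile(BACKGROUND, (size, size, 1))
    # draw one glyph per present class at its jittered home position
    for j in np.flatnonzero(np.asarray(lv.bits)):
        r, c = divmod(int(j), cells)
        cy = r * cell + cell // 2 + int(rng.integers(-jitter, jitter + 1))
        cx = c * cell + cell // 2 + int(rng.integers(-jitter, jitter + 1))
        h = glyph // 2
        img[cy - h:cy + h + 1, cx - h:cx + h + 1] = palette[j]
    img += rng.normal(0.0, config.noise_sd * 255.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def oracle_decode_frame(image: np.ndarray, config: GeneratorConfig
                        ) -> LandmarkVector:
    """Rule-based (non-learned) recovery of the landmark vector.

    For every class, count the pixels of its home cell whose colour lies
    within tolerance of the class colour; the class is present when at least
    half a glyph's area matches.
    """
    image = np.asarray(image)
    size = config.image_size
    if image.shape != (size, size, 3):
        raise ValueError(f"expected ({size}, {size}, 3) image, got {image.shape}")
    cells, cell, glyph, _ = _geometry(config)
    palette = glyph_palette(config.n_classes)
    pix = image.astype(float)
    bits = np.zeros(config.n_classes, dtype=np.int8)
    for j in range(config.n_classes):
        r, c = divmod(j, cells)
        window = pix[r * cell:(r + 1) * cell, c * cell:(c + 1) * cell]
        dist = np.linalg.norm(window - palette[j], axis=-1)
        if int((dist < COLOR_TOLERANCE).sum()) >= (glyph * glyph) // 2:
            bits[j] = 1
    return LandmarkVector(bits)
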