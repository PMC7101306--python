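"""Render a patient record as one colour-block raster, and decode it back.

Rendering is a pure function of (record, rules, palette, layout): every
block rectangle is filled with the palette colour of its field's category,
everything else is background, and the output is byte-identical across runs.
Decoding inverts this by nearest-palette-colour matching on each block's
centre region, which lets tests verify ``decode(render(r)) ==
discretize(r)`` for every field, and lets the augmentation guard check
clones through actual pixels rather than through the code path that
produced them.

The "ablation" variants blank out either the 30 joint blocks or the 14
clinical squares, producing the joints-only and clinical-only images used
to ask which half of the canvas carries the diagnostic signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .layout import LayoutSpec, default_layout
from .records import PatientRecord, get_field
from .rules import Category, Palette, RuleSet, default_palette, default_rules

logger = logging.getLogger(__name__)

ABLATION_MODES = ("cruciform_only", "clinical_only")


class UnrecognizedColourError(ValueError):
    """A block's colour is too far from every palette entry to decode."""


@dataclass
class TDAImage:
    """An RGB raster plus provenance of how it was produced."""

    array: np.ndarray  # (height, width, 3) uint8
    provenance: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.array.shape[1]

    @property
    def height(self) -> int:
        return self.array.shape[0]


def render_tda(record: PatientRecord,
               rules: RuleSet | None = None,
               palette: Palette | None = None,
               layout: LayoutSpec | None = None) -> TDAImage:
    """Render ``record`` as a colour-block image under the given layout."""
    rules = rules or default_rules()
    palette = palette or default_palette()
    layout = layout or default_layout()

    canvas = np.empty((layout.height, layout.width, 3), dtype=np.uint8)
    canvas[:] = palette[Category.BACKGROUND]
    for fid, (x, y, w, h) in layout.blocks.items():
        value = get_field(record, fid)
        category = rules.categorize(fid, value)
        if category is Category.MISSING:
            logger.warning("record %s: field %s missing, rendered grey",
                           record.patient_id, fid)
        canvas[y:y + h, x:x + w] = palette[category]
    return TDAImage(array=canvas, provenance={
        "patient_id": record.patient_id,
        "layout_version": layout.version,
        "ruleset_version": rules.version,
    })


def _as_array(image) -> np.ndarray:
    return image.array if isinstance(image, TDAImage) else np.asarray(image)


def decode_tda(image,
               layout: LayoutSpec | None = None,
               palette: Palette | None = None,
               fields: list[str] | None = None) -> dict[str, Category]:
    """Nearest-colour category of every block in ``image``.

    Raises :class:`UnrecognizedColourError` if any block's centre-region mean
    colour is farther than half the minimum palette distance from every
    decodable category (background is not a valid block state).  ``fields``
    restricts decoding to a subset of block ids, e.g. only the joint blocks
    of a joints-only ablation image.
    """
    layout = layout or default_layout()
    palette = palette or default_palette()
    arr = _as_array(image)
    if arr.shape[:2] != (layout.height, layout.width):
        raise ValueError(f"image shape {arr.shape[:2]} does not match layout "
                         f"{(layout.height, layout.width)}")

    candidates = [c for c in palette.colors if c is not Category.BACKGROUND]
    limit = palette.min_distance() / 2.0
    wanted = layout.blocks if fields is None else {
        fid: layout.blocks[fid] for fid in fields}
    out: dict[str, Category] = {}
    for fid, (x, y, w, h) in wanted.items():
        x0, x1 = x + w // 4, x + w - w // 4
        y0, y1 = y + h // 4, y + h - h // 4
        mean = arr[y0:y1, x0:x1].reshape(-1, 3).mean(axis=0)
        best, best_d = None, math.inf
        for cat in candidates:
            d = math.dist(mean, palette[cat])
            if d < best_d:
                best, best_d = cat, d
        if best_d > limit:
            raise UnrecognizedColourError(
                f"block {fid}: colour {tuple(np.round(mean, 1))} is farther "
                f"than {limit:.1f} from every palette category")
        out[fid] = best
    return out


def split_ablation(source, mode: str,
                   rules: RuleSet | None = None,
                   palette: Palette | None = None,
                   layout: LayoutSpec | None = None) -> TDAImage:
    """Joints-only or clinical-only variant of a record or rendered image.

    ``cruciform_only`` keeps the 30 joint blocks and blanks the 14 clinical
    squares; ``clinical_only`` does the reverse.
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {mode!r}; "
                         f"expected one of {ABLATION_MODES}")
    palette = palette or default_palette()
    layout = layout or default_layout()
    if isinstance(source, PatientRecord):
        image = render_tda(source, rules=rules, palette=palette, layout=layout)
    else:
        src = _as_array(source)
        decode_tda(src, layout, palette)  # must be a decodable image
        image = TDAImage(array=src.copy(),
                         provenance=dict(getattr(source, "provenance", {})))
    blanked = (layout.clinical_ids() if mode == "cruciform_only"
               else layout.joint_ids())
    for fid in blanked:
        x, y, w, h = layout.blocks[fid]
        image.array[y:y + h, x:x + w] = palette[Category.BACKGROUND]
    image.provenance["ablation"] = mode
    return image


def write_image(image, path, format: str | None = None) -> None:
    """Write the raster losslessly as TIFF (default) or PNG."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "tiff").lower()
    if fmt not in ("tiff", "tif", "png"):
        raise ValueError(f"unsupported format {fmt!r}; use tiff or png")
    arr = _as_array(image)
    pil = Image.fromarray(arr, mode="RGB")
    pil.save(path, format="PNG" if fmt == "png" else "TIFF")


def read_image(path) -> np.ndarray:
    """Read a raster written by :func:`write_image` back as uint8 RGB."""
    with Image.open(path) as pil:
        return np.asarray(pil.convert("RGB"))
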