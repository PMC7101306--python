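"""Pixel geometry of the 871 x 494 colour-block canvas.

The canvas holds two mirrored hand panels in its upper part — one plus-shaped
("cruciform") block per joint site, five 18-px sub-squares each (a top,
b left, c centre, d right, e bottom) — and two rows of seven 48-px clinical
squares beneath them.  The left-hand panel is the exact horizontal mirror of
the right-hand panel, so swapping a patient's left/right findings mirrors the
joint colours.

The published figure shows the block arrangement only graphically; the exact
pixel coordinates here are this package's own versioned stand-in, fixed so
renders are bit-exact.  A layout can be round-tripped through YAML for
archival or customisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .records import CLINICAL_FIELDS, JOINT_CHANNELS, SITES, joint_field_id

Rect = tuple[int, int, int, int]  # x, y, width, height

CANVAS_W, CANVAS_H = 871, 494

_SUB = 18          # cruciform sub-square side, px
_GAP = 6           # gap between cruciform blocks
_PITCH = 3 * _SUB + _GAP
_PANEL_MARGIN = 40
_PANEL_TOP = 30
_CLIN_SIZE = 48
_CLIN_ROWS_Y = (270, 350)
_CLIN_X0, _CLIN_PITCH = 76, 104

#: site grid of one hand panel, fingertip rows on top, wrist at bottom right
_GRID = (
    ("DIP2", "DIP3", "DIP4", "DIP5", "IP"),
    ("PIP2", "PIP3", "PIP4", "PIP5", "MCP1"),
    ("MCP2", "MCP3", "MCP4", "MCP5", "wrist"),
)

#: sub-square offsets within a cruciform block, in units of _SUB
_CRUCIFORM_OFFSETS = {"a": (1, 0), "b": (0, 1), "c": (1, 1), "d": (2, 1), "e": (1, 2)}


@dataclass(frozen=True)
class LayoutSpec:
    """Versioned pixel rectangles for all 164 colour blocks."""

    width: int
    height: int
    blocks: dict[str, Rect] = field(default_factory=dict)
    version: str = "layout-v1"

    def joint_ids(self) -> list[str]:
        return [fid for fid in self.blocks if fid.startswith("J_")]

    def clinical_ids(self) -> list[str]:
        return [fid for fid in self.blocks if not fid.startswith("J_")]

    def mirror_rect(self, rect: Rect) -> Rect:
        x, y, w, h = rect
        return (self.width - x - w, y, w, h)

    def validate(self) -> list[str]:
        problems = []
        rects = list(self.blocks.items())
        for fid, (x, y, w, h) in rects:
            if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
                problems.append(f"{fid}: rectangle leaves the canvas")
        for i, (fa, ra) in enumerate(rects):
            ax, ay, aw, ah = ra
            for fb, rb in rects[i + 1:]:
                bx, by, bw, bh = rb
                if ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah:
                    problems.append(f"{fa} overlaps {fb}")
        for site in SITES:
            for ch in JOINT_CHANNELS:
                right = self.blocks.get(joint_field_id("right", site, ch))
                left = self.blocks.get(joint_field_id("left", site, ch))
                if right is None or left is None:
                    problems.append(f"missing joint block {site}/{ch}")
                elif left != self.mirror_rect(right):
                    problems.append(f"{site}/{ch}: panels not mirrored")
        return problems

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "version": self.version,
            "canvas": {"width": self.width, "height": self.height},
            "blocks": {fid: list(rect) for fid, rect in self.blocks.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "LayoutSpec":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(width=payload["canvas"]["width"],
                   height=payload["canvas"]["height"],
                   blocks={fid: tuple(rect)
                           for fid, rect in payload["blocks"].items()},
                   version=payload["version"])


def default_layout() -> LayoutSpec:
    """Build the shipped 871 x 494 layout."""
    blocks: dict[str, Rect] = {}

    panel_w = 5 * _PITCH - _GAP
    right_x0 = CANVAS_W - _PANEL_MARGIN - panel_w
    for r, row in enumerate(_GRID):
        for c, site in enumerate(row):
            bx = right_x0 + c * _PITCH
            by = _PANEL_TOP + r * _PITCH
            for ch, (ox, oy) in _CRUCIFORM_OFFSETS.items():
                rect = (bx + ox * _SUB, by + oy * _SUB, _SUB, _SUB)
                blocks[joint_field_id("right", site, ch)] = rect
                blocks[joint_field_id("left", site, ch)] = (
                    CANVAS_W - rect[0] - _SUB, rect[1], _SUB, _SUB)

    for i, fid in enumerate(CLINICAL_FIELDS):
        row, col = divmod(i, 7)
        blocks[fid] = (_CLIN_X0 + col * _CLIN_PITCH, _CLIN_ROWS_Y[row],
                       _CLIN_SIZE, _CLIN_SIZE)

    layout = LayoutSpec(width=CANVAS_W, height=CANVAS_H, blocks=blocks)
    assert not layout.validate()
    return layout
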