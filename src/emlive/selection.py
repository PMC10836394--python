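"""Threshold filtering and lasso (polygon) selection over metadata tables.

These are the headless equivalents of live-filtering thresholds and the
in-plot lasso: declarative, pure filters over loop tables that never
mutate their input.  Filtered subsets re-export as STAR files that can
be imported straight back into RELION.

Conventions (documented because the boundary cases matter in practice):

* threshold bounds are **inclusive** — with a maximum accumulated motion
  of 50 Å, a micrograph at exactly 50 Å is kept ("over 50 Å" is
  discarded);
* points on the polygon boundary count as selected;
* a NaN in a thresholded column discards the row (fail-safe for
  partially processed micrographs) with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import shapely

from .star_io import (
    LoopTable,
    StarBlock,
    StarDocument,
    write_star_file,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdRule",
    "ThresholdSet",
    "PolygonSelection",
    "SelectionError",
    "apply_thresholds",
    "point_in_polygon",
    "lasso_select",
    "export_selection",
    "three_variable_view",
    "ThreeVariableView",
]


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdRule:
    """Keep rows with min <= value <= max; an absent bound is unbounded."""

    label: str
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min is not None and self.max is not None and self.min > self.max:
            raise SelectionError(
                f"rule for {self.label!r}: min {self.min} > max {self.max}"
            )


@dataclass
class ThresholdSet:
    rules: List[ThresholdRule] = field(default_factory=list)

    @classmethod
    def from_config_text(cls, text: str) -> "ThresholdSet":
        """Parse a simple config: one ``label min max`` per line.

        ``-`` (or ``none``) marks an absent bound; blank lines and
        ``#`` comments are ignored.
        """
        rules = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 3:
                raise SelectionError(
                    f"line {lineno}: expected 'label min max', got {s!r}"
                )
            label, lo, hi = parts

            def bound(tok: str) -> Optional[float]:
                return None if tok.lower() in ("-", "none", "nan") else float(tok)

            rules.append(ThresholdRule(label, bound(lo), bound(hi)))
        return cls(rules)


def _numeric_column(table: LoopTable, label: str) -> np.ndarray:
    values = table.column(label)
    for v in values:
        if not isinstance(v, (int, float)):
            raise SelectionError(
                f"column {table.resolve_label(label)!r} is not numeric "
                f"(found {v!r})"
            )
    return np.array(values, dtype=float)


def apply_thresholds(
    table: LoopTable, thresholds: ThresholdSet
) -> Tuple[LoopTable, LoopTable]:
    """Partition a table into (kept, discarded) by the threshold rules.

    A row is kept iff every rule's bounds contain its value (inclusive).
    Row order is preserved in both outputs; the two outputs always
    partition the input.  An empty rule set keeps everything.
    """
    n = table.n_rows
    keep = np.ones(n, dtype=bool)
    for rule in thresholds.rules:
        col = _numeric_column(table, rule.label)
        nan_mask = np.isnan(col)
        if nan_mask.any():
            logger.warning(
                "%d NaN value(s) in %r discarded by thresholding",
                int(nan_mask.sum()), rule.label,
            )
        ok = ~nan_mask
        if rule.min is not None:
            ok &= col >= rule.min
        if rule.max is not None:
            ok &= col <= rule.max
        keep &= ok
    kept_idx = [i for i in range(n) if keep[i]]
    disc_idx = [i for i in range(n) if not keep[i]]
    return table.subset(kept_idx), table.subset(disc_idx)


@dataclass
class PolygonSelection:
    """A simple (non-self-intersecting) closed polygon over two labels."""

    x_label: str
    y_label: str
    vertices: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise SelectionError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        self._geom = shapely.Polygon(self.vertices)
        # a bowtie's signed area cancels to zero, so judge degeneracy on
        # the repaired geometry before judging simplicity
        if shapely.make_valid(self._geom).area == 0:
            raise SelectionError("degenerate polygon (zero area)")
        if not self._geom.is_valid:
            raise SelectionError("polygon is self-intersecting (must be simple)")

    @property
    def geometry(self) -> shapely.Polygon:
        return self._geom


def point_in_polygon(p: Tuple[float, float], polygon: PolygonSelection) -> bool:
    """True iff the point is inside the polygon or on its boundary."""
    return bool(shapely.intersects_xy(polygon.geometry, p[0], p[1]))


def lasso_select(table: LoopTable, sel: PolygonSelection) -> LoopTable:
    """Rows whose (x, y) metadata point falls inside the lasso polygon."""
    if table.n_rows == 0:
        return table.subset([])
    xs = _numeric_column(table, sel.x_label)
    ys = _numeric_column(table, sel.y_label)
    inside = shapely.intersects_xy(sel.geometry, xs, ys)
    return table.subset([i for i in range(table.n_rows) if inside[i]])


def export_selection(
    table: LoopTable,
    path,
    optics: Optional[StarBlock] = None,
    block_name: Optional[str] = None,
) -> None:
    """Write a selection as a RELION-importable STAR file.

    With an optics block the file follows the particle-file layout
    (``data_optics`` then ``data_particles``); without, a single
    ``data_micrographs`` block.  Re-parsing the file yields an identical
    table.
    """
    if block_name is None:
        block_name = "particles" if optics is not None else "micrographs"
    blocks = []
    if optics is not None:
        blocks.append(optics)
    blocks.append(StarBlock(name=block_name, table=table))
    write_star_file(StarDocument(blocks), path)


@dataclass
class ThreeVariableView:
    """Aligned plotting columns; row_id maps a point back to its image."""

    x: np.ndarray
    y: np.ndarray
    color: Optional[np.ndarray]
    row_id: List[str]
    x_label: str
    y_label: str
    color_label: Optional[str]


def three_variable_view(
    table: LoopTable,
    x_label: str,
    y_label: str,
    color_label: Optional[str] = None,
) -> ThreeVariableView:
    """Extract up to three aligned metadata vectors for a scatter plot.

    ``row_id`` uses the table's first ``*Name`` column (micrograph or
    image name) when present, so a rendered point can be traced back to
    its micrograph/particle; otherwise the row index is used.
    """
    x = _numeric_column(table, x_label)
    y = _numeric_column(table, y_label)
    color: Optional[np.ndarray] = None
    resolved_color = None
    if color_label is not None:
        resolved_color = table.resolve_label(color_label)
        color = np.array(
            [float(v) if isinstance(v, (int, float)) else math.nan
             for v in table.column(color_label)]
        )
    name_label = next((lbl for lbl in table.labels if lbl.endswith("Name")), None)
    if name_label is not None:
        row_id = [str(v) for v in table.column(name_label)]
    else:
        row_id = [str(i) for i in range(table.n_rows)]
    return ThreeVariableView(
        x=x,
        y=y,
        color=color,
        row_id=row_id,
        x_label=table.resolve_label(x_label),
        y_label=table.resolve_label(y_label),
        color_label=resolved_color,
    )
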