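"""Feature expansion for maximum-entropy niche models.

Environmental layers are transformed into model features following the
conventions of presence-only maxent modelling: continuous layers yield
linear, quadratic, product, hinge and threshold features; categorical
layers yield one 0/1 indicator per category code.  Every feature is
min-max scaled to [0, 1] over the background so the regularization budget
is comparable across feature classes.

Which classes are active under ``classes="auto"`` depends on the presence
sample size, mirroring the widely used default tiers:

    n < 10        linear
    10 <= n < 15  + quadratic
    15 <= n < 80  + hinge
    n >= 80       + product + threshold
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .layers import LayerStack

__all__ = ["FeatureDescriptor", "FeatureMatrix", "expand_features", "auto_classes"]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold", "category")

#: knots per layer for hinge / threshold features (each knot gives a
#: forward and reverse hinge, or one step function)
DEFAULT_N_KNOTS = 8


@dataclass(frozen=True)
class FeatureDescriptor:
    """What a feature column is: source layer(s), class, and parameter."""

    source: tuple[str, ...]
    klass: str
    param: float | int | None = None

    def label(self) -> str:
        src = "*".join(self.source)
        return f"{self.klass}({src})" if self.param is None else f"{self.klass}({src};{self.param:g})"


@dataclass
class FeatureMatrix:
    """Per-cell feature values for the valid cells of a stack.

    ``values`` has one row per valid cell (order given by ``cell_ids``,
    the row-major flat indices into the grid) and one column per feature,
    scaled to [0, 1] over the background extent.
    """

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    cell_ids: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.descriptors)):
            raise ValueError("feature matrix shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows_for_cells(self, cell_ids: Sequence[int]) -> np.ndarray:
        """Row positions of the given flat cell ids (all must be valid cells)."""
        order = np.argsort(self.cell_ids)
        pos = np.searchsorted(self.cell_ids, cell_ids, sorter=order)
        rows = order[np.clip(pos, 0, len(order) - 1)]
        if not np.array_equal(self.cell_ids[rows], np.asarray(cell_ids)):
            raise KeyError("some cell ids are not valid cells of this stack")
        return rows


def auto_classes(n_presence: int) -> list[str]:
    """Active feature classes for a given presence sample size."""
    classes = ["linear"]
    if n_presence >= 10:
        classes.append("quadratic")
    if n_presence >= 15:
        classes.append("hinge")
    if n_presence >= 80:
        classes += ["product", "threshold"]
    return classes


def _scale01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("constant feature cannot be scaled")
    return (x - lo) / (hi - lo)


def expand_features(
    stack: LayerStack,
    n_presence: int,
    classes: str | Sequence[str] = "auto",
    n_knots: int = DEFAULT_N_KNOTS,
) -> FeatureMatrix:
    """Expand a layer stack into a scaled feature matrix over valid cells.

    Constant layers contribute no features (warned).  Categorical layers
    always expand to category indicators regardless of ``classes``.
    """
    if classes == "auto":
        active = auto_classes(n_presence)
    else:
        active = list(classes)
        unknown = set(active) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature class(es): {sorted(unknown)}")

    valid = stack.validity_mask
    if not valid.any():
        raise ValueError("stack has no valid cells; cannot build features")
    cell_ids = np.flatnonzero(valid.ravel())

    cols: list[np.ndarray] = []
    desc: list[FeatureDescriptor] = []
    continuous: list[tuple[str, np.ndarray]] = []

    for lyr in stack.layers:
        vals = lyr.values[valid]
        if lyr.kind == "categorical":
            for code in lyr.categories or ():
                cols.append((vals == code).astype(float))
                desc.append(FeatureDescriptor((lyr.name,), "category", int(code)))
            continue
        if np.min(vals) == np.max(vals):
            warnings.warn(f"layer {lyr.name!r} is constant over valid cells; "
                          "no features generated", stacklevel=2)
            continue
        z = _scale01(vals)
        continuous.append((lyr.name, z))
        if "linear" in active:
            cols.append(z)
            desc.append(FeatureDescriptor((lyr.name,), "linear"))
        if "quadratic" in active:
            cols.append(z ** 2)
            desc.append(FeatureDescriptor((lyr.name,), "quadratic"))
        if "hinge" in active:
            knots = np.quantile(z, np.linspace(0, 1, n_knots + 2)[1:-1])
            for k in np.unique(knots):
                if k < 1.0:  # forward hinge rises from the knot to the max
                    cols.append(np.maximum(0.0, z - k) / (1.0 - k))
                    desc.append(FeatureDescriptor((lyr.name,), "hinge", float(k)))
                if k > 0.0:  # reverse hinge falls from the min to the knot
                    cols.append(np.maximum(0.0, k - z) / k)
                    desc.append(FeatureDescriptor((lyr.name,), "hinge", float(-k)))
        if "threshold" in active:
            knots = np.quantile(z, np.linspace(0, 1, n_knots + 2)[1:-1])
            for k in np.unique(knots):
                if 0.0 < k < 1.0:
                    cols.append((z > k).astype(float))
                    desc.append(FeatureDescriptor((lyr.name,), "threshold", float(k)))

    if "product" in active:
        for i in range(len(continuous)):
            for j in range(i + 1, len(continuous)):
                (na, za), (nb, zb) = continuous[i], continuous[j]
                prod = za * zb
                if np.min(prod) < np.max(prod):
                    cols.append(_scale01(prod))
                    desc.append(FeatureDescriptor((na, nb), "product"))

    values = np.column_stack(cols) if cols else np.empty((len(cell_ids), 0))
    return FeatureMatrix(values=values, descriptors=desc, cell_ids=cell_ids,
                         grid_shape=stack.grid.shape)
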