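"""Two deliberately distinct n-dimensional image representations.

:class:`DenseImage` is a contiguous n-d grid (a numpy array plus an element
kind); :class:`PlanarImage` stores a stack of independent 2-D planes.  Both
describe the same pixels for 3-D data, but they are *different types* to the
matching engine, so bridging them genuinely exercises parameter conversion.

Conventions: 0-based indices, axis order slowest to fastest (the planar axis
leads), half-open intervals.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError, ParameterError

_KIND_DTYPES = {"uint8": np.uint8, "float64": np.float64}


def _kind_of(dtype: np.dtype) -> str:
    for kind, dt in _KIND_DTYPES.items():
        if dtype == np.dtype(dt):
            return kind
    raise ParameterError(f"unsupported element dtype {dtype}; use uint8 or float64")


class DenseImage:
    """Contiguous n-dimensional image with element kind uint8 or float64."""

    __slots__ = ("values",)

    def __init__(self, values) -> None:
        arr = np.asarray(values)
        if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.float64)):
            arr = arr.astype(np.float64)
        self.values = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def element_kind(self) -> str:
        return _kind_of(self.values.dtype)

    @classmethod
    def zeros(cls, shape, element_kind: str = "float64") -> "DenseImage":
        if element_kind not in _KIND_DTYPES:
            raise ParameterError(f"unknown element kind {element_kind!r}")
        return cls(np.zeros(shape, dtype=_KIND_DTYPES[element_kind]))

    def copy(self) -> "DenseImage":
        return DenseImage(self.values.copy())

    def __repr__(self) -> str:
        return f"DenseImage(shape={self.shape}, kind={self.element_kind})"


class PlanarImage:
    """Image stored as an ordered list of 2-D planes sharing one plane shape."""

    __slots__ = ("planes",)

    def __init__(self, planes) -> None:
        planes = [np.asarray(p) for p in planes]
        if not planes:
            raise ParameterError("a planar image needs at least one plane")
        shape = planes[0].shape
        dtype = planes[0].dtype
        for p in planes:
            if p.ndim != 2 or p.shape != shape:
                raise DimensionError(
                    f"all planes must be 2-D with shape {shape}; got {p.shape}"
                )
            if p.dtype != dtype:
                raise ParameterError("all planes must share one element kind")
        _kind_of(dtype)  # validates the kind
        self.planes = planes

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def element_kind(self) -> str:
        return _kind_of(self.planes[0].dtype)

    @classmethod
    def zeros(cls, n_planes: int, plane_shape, element_kind: str = "float64") -> "PlanarImage":
        dt = _KIND_DTYPES[element_kind]
        return cls([np.zeros(plane_shape, dtype=dt) for _ in range(n_planes)])

    def __repr__(self) -> str:
        return (
            f"PlanarImage({self.n_planes} planes of {self.plane_shape}, "
            f"kind={self.element_kind})"
        )
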