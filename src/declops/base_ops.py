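"""Engine-support op implementations.

These are ordinary ops — registered through the same YAML descriptor
mechanism as everything else (``descriptors/base.yaml``) — that give the
engine its recursive extensibility: creation of pre-allocated containers,
copying, type conversion, shape adaptation (including element-wise lifting),
type descriptions, scalar arithmetic, and the overhead micro-benchmark op.

Adapter implementations share one calling convention: they receive the inner
executable, a dict of resolved helper executables (create/copy), and a meta
dict filled in by the matcher, and return the adapted executable.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError, ParameterError
from .images import DenseImage, PlanarImage
from .typesys import TypeRegistry

# ---------------------------------------------------------------------------
# Default type registry
# ---------------------------------------------------------------------------

def _is_float_seq(v) -> bool:
    return (isinstance(v, (list, tuple)) and len(v) > 0
            and all(isinstance(x, float) for x in v))


def _is_int_seq(v) -> bool:
    return (isinstance(v, (list, tuple)) and len(v) > 0
            and all(isinstance(x, int) and not isinstance(x, bool) for x in v))


def default_registry() -> TypeRegistry:
    """Types, subtype edges and runtime recognizers of the stock environment."""
    reg = TypeRegistry()
    reg.register("number")
    reg.register("real", parents=["number"])
    reg.register("integer", parents=["real"],
                 recognizer=lambda v: isinstance(v, (int, np.integer))
                 and not isinstance(v, bool))
    reg.register("float64", parents=["real"],
                 recognizer=lambda v: isinstance(v, (float, np.floating)))
    reg.register("uint8", parents=["integer"])
    reg.register("boolean", recognizer=lambda v: isinstance(v, bool))
    reg.register("text", recognizer=lambda v: isinstance(v, str))
    reg.register("image")
    reg.register("dense-image", parents=["image"],
                 recognizer=lambda v: isinstance(v, DenseImage))
    reg.register("planar-image", parents=["image"],
                 recognizer=lambda v: isinstance(v, PlanarImage))
    reg.register("byte-sequence",
                 recognizer=lambda v: isinstance(v, (bytearray, bytes)))
    reg.register("real-sequence", recognizer=_is_float_seq)
    reg.register("int-list", recognizer=_is_int_seq)
    reg.register("complex-grid",
                 recognizer=lambda v: isinstance(v, np.ndarray)
                 and np.iscomplexobj(v))
    reg.register("histogram",
                 recognizer=lambda v: type(v).__name__ == "Histogram")
    reg.register("threshold-result",
                 recognizer=lambda v: type(v).__name__ == "ThresholdResult")
    return reg


# ---------------------------------------------------------------------------
# engine.create / engine.copy
# ---------------------------------------------------------------------------

def create_like(reference):
    """New zero-filled value of the same structure as the reference; no
    storage is shared."""
    if isinstance(reference, DenseImage):
        return DenseImage.zeros(reference.shape, reference.element_kind)
    if isinstance(reference, PlanarImage):
        return PlanarImage.zeros(reference.n_planes, reference.plane_shape,
                                 reference.element_kind)
    if isinstance(reference, (bytearray, bytes)):
        return bytearray(len(reference))
    if isinstance(reference, (list, tuple)):
        return [0.0] * len(reference)
    raise ParameterError(f"cannot create a container like {type(reference).__name__}")


def copy_into(source, target) -> None:
    """Copy source elements into the pre-allocated target (shapes must agree)."""
    if isinstance(source, DenseImage) and isinstance(target, DenseImage):
        if source.shape != target.shape:
            raise DimensionError(f"shape mismatch: {source.shape} vs {target.shape}")
        target.values[...] = source.values.astype(target.values.dtype, copy=False)
        return
    if isinstance(source, PlanarImage) and isinstance(target, PlanarImage):
        if source.n_planes != target.n_planes or \
                source.plane_shape != target.plane_shape:
            raise DimensionError(
                f"shape mismatch: {source.n_planes}x{source.plane_shape} vs "
                f"{target.n_planes}x{target.plane_shape}")
        for s, t in zip(source.planes, target.planes):
            t[...] = s
        return
    if isinstance(source, (bytearray, bytes, list, tuple)) and \
            isinstance(target, (bytearray, list)):
        if len(source) != len(target):
            raise DimensionError(f"length mismatch: {len(source)} vs {len(target)}")
        for i, v in enumerate(source):
            target[i] = v
        return
    raise ParameterError(
        f"cannot copy {type(source).__name__} into {type(target).__name__}")


# ---------------------------------------------------------------------------
# engine.convert
# ---------------------------------------------------------------------------

def dense_to_planar(x: DenseImage) -> PlanarImage:
    """3-D dense image -> planar stack; plane p, row r, col c <-> dense (p, r, c)."""
    if len(x.shape) != 3:
        raise ParameterError(
            f"dense->planar conversion needs a 3-D image, got {len(x.shape)} axes")
    return PlanarImage([x.values[p].copy() for p in range(x.shape[0])])


def planar_to_dense(x: PlanarImage) -> DenseImage:
    return DenseImage(np.stack(x.planes, axis=0))


def widen_elements(x):
    """uint8 structure -> float64 structure, exactly."""
    if isinstance(x, DenseImage):
        return DenseImage(x.values.astype(np.float64))
    if isinstance(x, PlanarImage):
        return PlanarImage([p.astype(np.float64) for p in x.planes])
    if isinstance(x, (bytearray, bytes)):
        return [float(v) for v in x]
    return [float(v) for v in x]


def _narrow_value(v: float) -> int:
    # round half-up, then clamp to the uint8 range
    return int(min(255, max(0, np.floor(v + 0.5))))


def narrow_elements(x):
    """float64 structure -> uint8 structure, rounding half-up and clamping."""
    if isinstance(x, DenseImage):
        return DenseImage(np.clip(np.floor(x.values + 0.5), 0, 255).astype(np.uint8))
    if isinstance(x, PlanarImage):
        return PlanarImage(
            [np.clip(np.floor(p + 0.5), 0, 255).astype(np.uint8) for p in x.planes])
    return bytearray(_narrow_value(v) for v in x)


# ---------------------------------------------------------------------------
# engine.adapt — runtime wrappers (applicability lives in the engine's rule
# table; these only do the work)
# ---------------------------------------------------------------------------

def adapt_computer_to_function(inner, helpers, meta):
    create = helpers["create"]
    ref = meta["ref_index"]

    def fn(*ins):
        container = create(ins[ref])
        inner(*ins, container)
        return container
    return fn


def adapt_function_to_computer(inner, helpers, meta):
    copy = helpers["copy"]

    def computer(*args):
        *ins, container = args
        copy(inner(*ins), container)
    return computer


def adapt_inplace_to_computer(inner, helpers, meta):
    copy = helpers["copy"]
    m = meta["mutable_index"]

    def computer(*args):
        *ins, container = args
        copy(ins[m], container)
        ins = list(ins)
        ins[m] = container
        inner(*ins)
    return computer


def adapt_computer_to_inplace(inner, helpers, meta):
    create, copy = helpers["create"], helpers["copy"]
    m = meta["mutable_index"]

    def inplace(*ins):
        temp = create(ins[m])
        inner(*ins, temp)
        copy(temp, ins[m])
    return inplace


def adapt_inplace_to_function(inner, helpers, meta):
    create, copy = helpers["create"], helpers["copy"]
    m = meta["mutable_index"]

    def fn(*ins):
        buf = create(ins[m])
        copy(ins[m], buf)
        ins = list(ins)
        ins[m] = buf
        inner(*ins)
        return buf
    return fn


def adapt_lift_elementwise(inner, helpers, meta):
    """Lift a scalar function (arity 1 or 2) to dense images, element-wise."""
    def fn(*imgs):
        arrays = [np.asarray(im.values, dtype=np.float64) for im in imgs]
        shape = arrays[0].shape
        for a in arrays[1:]:
            if a.shape != shape:
                raise DimensionError(
                    f"image arguments must share a shape: {shape} vs {a.shape}")
        out = np.empty(shape, dtype=np.float64)
        for idx in np.ndindex(shape):
            out[idx] = inner(*(a[idx] for a in arrays))
        return DenseImage(out)
    return fn


# ---------------------------------------------------------------------------
# engine.describe
# ---------------------------------------------------------------------------

def describe_image(type_name=None) -> str:
    return "image"


def describe_number(type_name=None) -> str:
    return "number"


def describe_sequence(type_name=None) -> str:
    return "sequence"


def describe_text(type_name=None) -> str:
    return "text"


def describe_flag(type_name=None) -> str:
    return "flag"


def describe_spectrum(type_name=None) -> str:
    return "spectrum"


def describe_histogram(type_name=None) -> str:
    return "histogram"


def describe_threshold(type_name=None) -> str:
    return "threshold"


# ---------------------------------------------------------------------------
# math scalar ops
# ---------------------------------------------------------------------------

def math_add(a, b):
    return a + b


def math_sub(a, b):
    return a - b


def math_mul(a, b):
    return a * b


def math_div(a, b):
    if b == 0:
        raise ZeroDivisionError("math.div: division by zero")
    return a / b


# ---------------------------------------------------------------------------
# benchmark op
# ---------------------------------------------------------------------------

def increment_first(data) -> None:
    """Increment element 0 modulo 256 (unsigned byte semantics); other
    elements untouched."""
    if len(data) == 0:
        raise ParameterError("benchmark.increment: empty sequence")
    data[0] = (data[0] + 1) % 256
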