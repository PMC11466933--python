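# declops

A declarative, extensible registry of algorithm plugins ("ops") for
biological image analysis, matched to user requests by **name and parameter
types** through a deterministic engine.

## The problem

Image analysts combine algorithms from many libraries, each with its own
data structures and calling conventions.  Rather than hard-coding which
implementation runs, `declops` lets the user state *what* they want —
"a Gaussian blur of this image with this sigma" — and lets an engine pick
the best registered implementation.  Implementations are plain callables
declared in YAML metadata descriptor files (or via doc-comment annotations),
so existing library code can be registered without modification, and adding
a better implementation later automatically upgrades every workflow and
every op that depends on it.

## The model

Every op has a dotted **name** (`filter.gauss`), a **functional shape**, an
ordered, typed parameter list, and a **priority**:

- **function** — consumes inputs, allocates and returns a new output;
- **computer** — writes its output into a pre-allocated *container*;
- **inplace** — overwrites one *mutable* argument.

A request `name(shape, in-types, out-type)` is resolved by four matching
routines attempted in a fixed order:

1. **direct** — name, shape and all types assignable (subtype DAG);
2. **adaptation** — one `engine.adapt` op bridges a shape difference
   (e.g. run a computer as a function, or lift a scalar op element-wise
   across an image);
3. **conversion** — single-hop `engine.convert` ops bridge mismatched
   parameter types, with copy-back through `engine.copy` for written-to
   arguments;
4. **adaptation + conversion** combined.

Within a routine, candidates are ranked by priority (higher first), then by
fewer wrapper ops, then lexicographically by source locator — so matching
is a pure function of the request, independent of registration order.  Op
**dependencies** (e.g. Difference of Gaussians needing two blurs and a
subtraction) are themselves requests, resolved recursively.  Every match is
recorded as an **InfoTree** (root op + wrappers + dependency subtrees), and
every execution that writes an output appends a record to the **OpHistory**,
so provenance is reconstructable.

All engine capabilities — create, copy, convert, adapt, describe — are
themselves ordinary ops registered through the same YAML mechanism.

## Worked example

```python
from declops import default_environment
from declops.image_ops import synthetic_image

env = default_environment()
img = synthetic_image((64, 64), n_spots=6, spot_sigma=2.0, noise_sd=4.0,
                      seed=1, element_kind="uint8")

blurred = env.op("filter.gauss").input(img, 2.0).apply()
band    = env.op("filter.dog").input(img, 2.0, 5.0).apply()
result  = env.op("threshold.otsu").input(img).apply()

print("blurred:", blurred)
print("band-pass extrema: %.2f .. %.2f" % (band.values.min(), band.values.max()))
print("otsu threshold:", result.threshold,
      "| foreground pixels:", int(result.mask.values.sum()))
print(env.help("filter.gauss"))
```

prints

```
blurred: DenseImage(shape=(64, 64), kind=uint8)
band-pass extrema: -18.00 .. 76.00
otsu threshold: 58.0 | foreground pixels: 189
filter.gauss(input: image, sigma: number, output: image) -> image
```

Note what happened under the hood: `filter.gauss` is registered as a
*computer*, so the `apply()` call was satisfied by the
`engine.adapt.computer_to_function` op (allocating the output via
`engine.create`).  `filter.dog` declared its two blurs and the subtraction
as engine-resolved dependencies; the scalar `math.sub` was lifted
element-wise across the image by `engine.adapt.lift_elementwise`.  The Otsu
threshold 58.0 separates the 189 spot pixels from background, and its
histogram is itself a matched `image.histogram` dependency.  The help line
shows *simple* type names ("image", "number") supplied by `engine.describe`
ops instead of package-specific type names.

There is also a CLI:

```sh
ops list filter
ops help math.add --verbose
ops run filter.gauss --in spots.tif --param sigma=2 --out blur.tif
ops index mylib.py -o ops.yaml
ops benchmark --reps 1000
```

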