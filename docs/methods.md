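# Methods

This note documents the design of `declops`: the matching model and its
guarantees, the numerical conventions of the image ops, what the synthetic
fixtures emulate, and the choices made where the design was genuinely open.

## The op model

An op is a named, typed algorithm plugin in one of three functional shapes:
*function* (pure; allocates its output), *computer* (writes into a
pre-allocated container), *inplace* (overwrites one mutable argument).
Structural invariants are enforced at registration: a function has exactly
one declared output, a computer exactly one container, an inplace exactly
one mutable; optional flags are allowed only on plain inputs.

Ops are declared in YAML descriptor files whose schema is normative for
this package (see `declops/descriptors/*.yaml` for the reference form).
Descriptors can also be produced by scanning doc comments: a
`@implNote op names="..." type=...` line plus structured
`@param`/`@container`/`@mutable`/`@return` lines.  The annotation grammar is
a deliberate minimal re-interpretation of doc-tag conventions so the
indexer is testable token by token; indexing is idempotent, and duplicate
names are kept by design — competing implementations are the point of
matching, and priority breaks ties.

### Optional parameters

Optional inputs forming a contiguous trailing block are expanded into
reduced signatures, dropped one by one right to left (`filter.fft(input,
fftType, borderSize?, fast?)` yields arities 4, 3 and 2).  Reductions are
materialized eagerly at registration — they are ordinary ops to the matcher,
which keeps determinism trivially inspectable — and inherit the parent's
priority unchanged, since reduction changes arity, not quality.  Declared
defaults are injected at instantiation time.  An optional parameter
followed by a required one is legal but never droppable (logged at
reduction).  A droppable optional must declare a default; otherwise
registration fails.

## Types

Matching is name-based over a registry of semantic type names with subtype
edges forming a DAG; assignability is the reflexive-transitive closure.
The stock registry has a numeric spine (`uint8 → integer → real → number`,
`float64 → real`), two deliberately distinct image representations
(`dense-image`, `planar-image`, both under `image`), sequences, and a few
result types.  Each type may carry a recognizer predicate so builder
arguments can be resolved to type names at run time; the deepest
recognizing type wins and an ambiguity at equal depth is an error, not a
guess.  The engine deliberately discriminates on parameter *types*, never
values — two ops of the same name cannot be selected by, say, kernel size.
Generic/parameterized type variance is out of scope.

## Matching

Four routines run in a fixed order: direct → adaptation → conversion →
adaptation + conversion.  The first routine with at least one candidate
wins.  Adaptation precedes conversion because it never touches user data;
the selected routine is logged per match so any divergence from other
engines is observable.  Constraints that bound the search:

- at most one adaptation per match; adapters do not compose;
- conversion is single-hop — exactly one `engine.convert` op per parameter,
  no converter chaining;
- a converted container (or mutable) additionally requires a single-hop
  back-converter and an `engine.copy` op for the user's type, so results
  can be copied back exactly; absence of either disqualifies the candidate;
- adapter helper ops (`engine.create`, `engine.copy`) and the back-converter
  are resolved by *direct* matching only, and the best-ranked helper is used
  rather than enumerated into the candidate set;
- a request may omit its output type (wildcard).

Ranking within a routine is a total order: higher priority, then fewer
wrapper ops (adaptation + conversions), then lexicographic comparison of
canonical source locators (including wrapper sources).  Because no rule
references registration order, matching is a pure function of the request —
the property the test suite checks by shuffling registration order and by
comparing against a brute-force enumerator over all op × adapter ×
converter combinations on small random environments.

A deliberate consequence of routine precedence: a low-priority direct match
always beats a high-priority op reachable only through adaptation or
conversion.  Priority ranks candidates *within* a routine, never across
routines.

Dependencies declare a slot name, an op name, a shape and (optionally)
parameter types, and are resolved recursively as ordinary requests — never
hard-linked.  Resolution is guarded by a depth cap of 100 and a stack that
rejects revisiting the same (op, shape) pair, which turns dependency cycles
into a named-chain error instead of a hang.

### Cache

`match_cached` memoizes trees under a canonical request key
(`name|shape|in=t1,t2,...|out=t`; a computer's container type is appended
last to `in=` and repeated as `out=`; an inplace mutable type carries a `~`
prefix; `*` marks wildcards).  Any register/unregister bumps a generation
counter and clears the cache, so a hit is always equal to a fresh match —
cache transparency is asserted against a cache-disabled twin environment
across interleaved mutations.

### Provenance

Every match produces an InfoTree (root, adaptation, conversions,
dependency subtrees) with a canonical serialization; two trees are equal
iff their canonical forms are.  The history stores a 16-hex-digit SHA-1
digest of that serialization rather than the tree itself — bounded memory,
still reconstructable by replaying the match.  Executions through `apply()`
log too (not only container writes), making provenance total over builder
use.

## Image op numerics

- **Gaussian filter**: separable convolution per axis, discrete kernel
  `exp(-x²/2σ²)` truncated at half-width `ceil(4σ)` and normalized to
  sum 1; mirror borders; accumulation in float64 with a final cast (uint8
  rounds half-up and clamps).  These conventions are normative here; they
  are checked against a non-separable dense 2-D convolution oracle.
- **Difference of Gaussians**: literally `sub(gauss(x, σ1), gauss(x, σ2))`
  through engine-resolved dependencies, so it is bit-identical to the
  manual composition and inherits any upgraded `filter.gauss` automatically.
- **Histogram**: counting with floor bin assignment
  `floor((v − lo)/width)`; uint8 bins over [0, 256) (257 edges at the
  default 256 bins), float bins over [min, max] with the last bin
  right-closed.
- **Otsu**: maximizes between-class variance over the 256-bin histogram;
  ties break to the lowest threshold (plain strict comparison, matching
  exhaustive-search semantics exactly); the mask is strictly
  `input > threshold`.  Constant images are rejected as degenerate.
- **FFT**: mirror padding by `borderSize` per axis; with `fast`, each
  padded axis is rounded up to the next {2,3,5,7}-smooth length (a typical
  radix set).  Reduced signatures behave identically to explicit defaults
  (`borderSize=0`, `fast=true`).
- **pnorm / significance mask**: the standard normal CDF (via
  `scipy.special.ndtr`, cross-checked against numeric integration of the
  density); the colocalization significance mask is one-sided upper-tail,
  `(1 − Φ(z)) < α`, with no multiple-testing adjustment — colocalization
  strength is a one-sided quantity, and the z-score computation itself is
  outside this package's scope, so the mask consumes any z image.

Coordinates are 0-based, axes ordered slowest to fastest (the planar axis
leads 3-D data), intervals half-open; the TIFF/PNG readers and writers
follow the same order (multi-page TIFF maps to the leading axis).

## Synthetic fixtures

`fixtures.synthetic_image` emulates a fluorescence spot image: `n_spots`
isotropic Gaussian peaks (amplitude 200, typical of a bright spot on an
8-bit scale) at uniform random positions plus Gaussian pixel noise, all
driven by one seed, clipped/rounded for uint8 output.  It reproduces the
features the ops care about — localized blobs, a noise floor, a bimodal
intensity distribution for thresholding — but not realistic detector
physics (no Poisson shot noise, PSF anisotropy, background gradients or
saturation).  Passing tests therefore demonstrate the *engine's* contracts
and the filters' numerics, not robustness to real microscope data.

Test and acceptance problem sizes (24×24 to 64×64 images, 20 seeds,
200 random environments of ≤10 ops) were chosen as the smallest sizes at
which the checked properties are non-trivial — matching is type-level, and
the numeric identities are size-independent.

## Benchmarking

`benchmark.increment` (increment the first byte, modulo 256 — unsigned-byte
wraparound, decided here since overflow behavior is otherwise unspecified)
isolates dispatch overhead.  Absolute microsecond values are
hardware-dependent and never asserted; the framework claims only orderings:
a cached lookup undercuts uncached matching, a direct static call undercuts
every engine pathway, and the combined adaptation+conversion pathway costs
at least as much as either alone.

## Known limitations

- Reproducibility of op *implementations* is not enforceable by the
  framework; the stock collection is deterministic by construction.
- Converting arguments between types copies data; the matcher does not
  model conversion cost beyond counting wrappers.
- The dense→planar converter is declared at the type level, so a non-3-D
  dense image fails at execution rather than being excluded during
  matching (type names carry no rank information).
- Neighborhood-wise lifting (e.g. running a patch-wise op across an image)
  is a natural future adapter but is not implemented.
- Adapted inplace ops do not preserve aliasing: the mutable argument's
  *contents* are updated via copy-back, but intermediate buffers exist.
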