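"""Dispatch-overhead micro-benchmark.

Times the ``benchmark.increment`` op — whose runtime is almost pure
overhead — through each execution pathway: a direct static call, engine
matching (cache disabled), engine matching with the match cache, and the
adaptation / conversion / combined routines.  Absolute times are
hardware-dependent; only relative orderings are meaningful, and
:func:`check_relative_properties` states which ones the framework claims.
"""

from __future__ import annotations

import statistics
import time

from .base_ops import increment_first
from .environment import default_environment

PATHWAYS = (
    "direct call",
    "engine direct",
    "engine cached",
    "engine adaptation",
    "engine conversion",
    "engine adaptation+conversion",
)


def _time_us(fn, reps: int) -> dict:
    times = []
    for _ in range(reps):
        t0 = time.perf_counter()
        fn()
        times.append((time.perf_counter() - t0) * 1e6)
    return {"mean_us": statistics.fmean(times),
            "min_us": min(times), "max_us": max(times)}


def run_benchmark(reps: int = 1000, include_cached: bool = True) -> list[dict]:
    """Benchmark every pathway; returns one row dict per pathway.

    All engine pathways except "engine cached" run with the match cache
    disabled so the matcher itself is measured."""
    env_nc = default_environment(cache_enabled=False)
    env_c = default_environment(cache_enabled=True)
    byte_buf = bytearray([0])
    real_buf = [0.0]

    cases = {
        "direct call": lambda: increment_first(byte_buf),
        "engine direct":
            lambda: env_nc.op("benchmark.increment").input(byte_buf).mutate(),
        "engine cached":
            lambda: env_c.op("benchmark.increment").input(byte_buf).mutate(),
        # a function request forces the inplace->function adapter
        "engine adaptation":
            lambda: env_nc.op("benchmark.increment").input(byte_buf).apply(),
        # a real-sequence argument forces narrow/widen converters + copy-back
        "engine conversion":
            lambda: env_nc.op("benchmark.increment").input(real_buf).mutate(),
        "engine adaptation+conversion":
            lambda: env_nc.op("benchmark.increment").input(real_buf).apply(),
    }
    rows = []
    for pathway in PATHWAYS:
        if pathway == "engine cached" and not include_cached:
            continue
        fn = cases[pathway]
        fn()  # warm up imports / the cache before timing
        rows.append({"pathway": pathway, "reps": reps, **_time_us(fn, reps)})
    return rows


def check_relative_properties(rows: list[dict]) -> list[str]:
    """Hardware-independent ordering claims; returns violated ones (empty = ok)."""
    mean = {r["pathway"]: r["mean_us"] for r in rows}
    violations = []
    if "engine cached" in mean and mean["engine cached"] >= mean["engine direct"]:
        violations.append("cached mean overhead should be below uncached mean")
    for pathway, m in mean.items():
        if pathway != "direct call" and mean["direct call"] >= m:
            violations.append(f"direct static call should undercut {pathway!r}")
    combined = mean.get("engine adaptation+conversion")
    if combined is not None:
        if combined < max(mean["engine adaptation"], mean["engine conversion"]):
            violations.append(
                "adaptation+conversion should cost at least max(adaptation, conversion)")
    return violations


def format_table(rows: list[dict]) -> str:
    """Machine-readable TSV table with a header row."""
    header = "pathway\treps\tmean_us\tmin_us\tmax_us"
    lines = [header]
    for r in rows:
        lines.append(f"{r['pathway']}\t{r['reps']}\t{r['mean_us']:.3f}"
                     f"\t{r['min_us']:.3f}\t{r['max_us']:.3f}")
    return "\n".join(lines)
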