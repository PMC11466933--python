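"""Assembly of the stock op environment from the bundled YAML descriptors."""

from __future__ import annotations

from importlib import resources

from .base_ops import default_registry
from .engine import OpEnvironment

BUILTIN_DESCRIPTORS = ("base.yaml", "image.yaml")


def builtin_descriptor_text(name: str) -> str:
    return (resources.files("declops") / "descriptors" / name).read_text()


def default_environment(cache_enabled: bool = True,
                        include: tuple[str, ...] = BUILTIN_DESCRIPTORS) -> OpEnvironment:
    """Environment holding the bundled engine-support and image op collections.

    ``include`` selects which bundled descriptor files to load — dropping
    ``base.yaml`` removes the engine-support ops and with them every
    adaptation/conversion capability, which is occasionally what you want to
    demonstrate.
    """
    env = OpEnvironment(registry=default_registry(), cache_enabled=cache_enabled)
    for name in include:
        env.register_yaml(builtin_descriptor_text(name))
    return env
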