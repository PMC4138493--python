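"""Named configuration presets (flat YAML files shipped with the package)."""

from __future__ import annotations

from importlib import resources

import yaml


def available_presets() -> list[str]:
    pkg = resources.files("neurodeep") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a named preset (e.g. ``aod_rbm64``, ``smri_dbn_50_50_100``)."""
    path = resources.files("neurodeep") / "presets" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; have {available_presets()}")
    return yaml.safe_load(text)
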