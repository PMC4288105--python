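"""Loaders for the editable configuration shipped with the package:
drug taxonomy, comorbidity→ICD9 map, report layout, and the demo KB.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "load_yaml_resource",
    "default_taxonomy_config",
    "default_comorbidity_config",
    "default_layout_config",
    "demo_kb_source",
]


def _data_text(name: str) -> str:
    return (resources.files("neurocds") / "data" / name).read_text(
        encoding="utf-8")


def load_yaml_resource(name: str, path: Optional[Path] = None) -> dict:
    """Load a YAML config, from ``path`` if given else the packaged default."""
    if path is not None:
        return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return yaml.safe_load(_data_text(name))


def default_taxonomy_config(path: Optional[Path] = None) -> dict:
    return load_yaml_resource("drug_taxonomy.yaml", path)


def default_comorbidity_config(path: Optional[Path] = None) -> dict:
    return load_yaml_resource("comorbidity_map.yaml", path)


def default_layout_config(path: Optional[Path] = None) -> dict:
    return load_yaml_resource("locations.yaml", path)


def demo_kb_source() -> str:
    return _data_text("demo.kb")
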