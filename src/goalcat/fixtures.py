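"""Frozen worked-example assets shared across the test suites and docs.

Fixtures are plain data files (YAML/JSON) inside the package so that ports in
other languages can reuse them verbatim. Each declares oracle values with a
provenance field — ``literature`` for counts quoted from the theory's worked
examples, ``computed`` for values derived by an independent procedure (stated
alongside), ``direct`` for values true by construction — and the test suite
re-derives every one of them from live computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import yaml

from .envsim import worldspec_from_mapping
from .gm_core import model_from_dict
from .model_zoo import StructureConfig

__all__ = ["Fixture", "FixtureNotFoundError", "load_fixture", "available_fixtures"]

_PACKAGE_DIR = "fixtures_data"


class FixtureNotFoundError(KeyError):
    pass


@dataclass(frozen=True)
class Fixture:
    name: str
    kind: str  # structure_config | world_spec | model
    payload: object
    oracles: dict[str, dict]
    doc: str

    def oracle(self, name: str) -> float:
        return self.oracles[name]["value"]


def _parse(raw: dict) -> Fixture:
    kind = raw["kind"]
    payload = raw["payload"]
    if kind == "structure_config":
        payload = StructureConfig.from_mapping(payload)
    elif kind == "world_spec":
        payload = worldspec_from_mapping(payload)
    elif kind == "model":
        payload = model_from_dict(payload)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    oracles = {o["name"]: o for o in raw.get("oracles", [])}
    return Fixture(raw["name"], kind, payload, oracles, raw.get("doc", ""))


def available_fixtures() -> list[str]:
    root = resources.files(__package__) / _PACKAGE_DIR
    return sorted(
        p.name.rsplit(".", 1)[0]
        for p in root.iterdir()
        if p.name.endswith((".yaml", ".json"))
    )


def load_fixture(name: str) -> Fixture:
    root = resources.files(__package__) / _PACKAGE_DIR
    for ext, loader in ((".yaml", yaml.safe_load), (".json", json.loads)):
        candidate = root / f"{name}{ext}"
        if candidate.is_file():
            return _parse(loader(candidate.read_text()))
    raise FixtureNotFoundError(
        f"no fixture named {name!r}; available: {available_fixtures()}"
    )
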