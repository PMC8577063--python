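"""Access to the default parameter tables (shipped YAML) with overrides."""

import copy
from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def _defaults():
    text = (resources.files("ca1rhythms") / "params" / "defaults.yaml").read_text()
    return yaml.safe_load(text)


def defaults():
    """Deep copy of the full default parameter tree."""
    return copy.deepcopy(_defaults())


def deep_merge(base, override):
    """Recursively merge ``override`` into ``base`` (returns a new dict)."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out
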