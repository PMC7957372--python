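"""State → CDC Centers-of-Excellence region assignment.

The five regions (named for their hub states Colorado, Minnesota, New York,
Tennessee and Washington) partition the 50 states plus DC, Puerto Rico, the
U.S. Virgin Islands and Guam.  The packaged fixture is loaded once; any state
code outside the map resolves to ``unassigned``.
"""
from __future__ import annotations

import importlib.resources
from functools import lru_cache
from pathlib import Path

import yaml

from .data_model import UNASSIGNED_REGION

REGION_NAMES = ("Colorado", "Minnesota", "New York", "Tennessee", "Washington")


@lru_cache(maxsize=4)
def load_region_map(path: str | None = None) -> dict[str, str]:
    """Return the state→region mapping, from ``path`` or the packaged fixture.

    The file maps each region name to a list of 2-letter state/territory codes.
    """
    if path is None:
        text = (importlib.resources.files("cgmtrends") / "data" / "regions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict[str, str] = {}
    for region, states in raw.items():
        for st in states:
            if st in out:
                raise ValueError(f"state {st} mapped to both {out[st]} and {region}")
            out[st] = region
    return out


def assign_region(state: str, region_map: dict[str, str] | None = None) -> str:
    """Region label for a state code; ``unassigned`` if the state is unmapped."""
    if region_map is None:
        region_map = load_region_map()
    return region_map.get(state.upper(), UNASSIGNED_REGION)
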