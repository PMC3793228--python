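"""Packaged data: the published Páramo lineage table and the eight-hotspot
metadata table, transcribed from the printed study tables.

``load_paramo_lineages`` returns the 13 Páramo clades with species
counts, crown-age brackets (min/mean/max, Ma) and Pleistocene
divergence counts; ``load_hotspot_metadata`` returns the eight hotspots
with area, richness and the printed summary cells (kept so the package
can cross-check them against its own recomputation).
"""

from __future__ import annotations

from importlib import resources
from typing import List

from .hotspots import HotspotMeta
from .io import read_hotspot_csv, read_lineage_csv
from .rates import LineageRecord


def _data_path(name: str):
    return resources.files("paramodiv.data") / name


def load_paramo_lineages() -> List[LineageRecord]:
    """The 13 Páramo plant lineages with richness and crown ages."""
    with resources.as_file(_data_path("paramo_lineages.csv")) as p:
        return read_lineage_csv(p)


def load_hotspot_metadata() -> List[HotspotMeta]:
    """The eight biodiversity hotspots: area (km²), richness, printed cells."""
    with resources.as_file(_data_path("hotspots.csv")) as p:
        return read_hotspot_csv(p)
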