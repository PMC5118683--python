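"""Land-cover class legend: codes, names, the analysis subset, and the forest merge.

The default scheme follows the MODIS-era mapping convention for temperate
East Asia: five forest types (deciduous/evergreen x broadleaf/needleleaf,
plus mixed), two shrubland densities, grassland, sparse vegetation,
agriculture, urban, bare ground, permanent snow, and water.  Hotspot
analysis merges the five forest types into a single FORE super-class and
tracks eight classes: AGRI, BARE, CLSH, FORE, GRAS, OPSH, SPAS, URBN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class ClassLegend:
    """Mapping between integer raster codes and class names.

    Parameters
    ----------
    entries : dict[int, str]
        Raster code -> class name.  Codes must be unique (dict enforces);
        names should be unique too.
    analysis_set : tuple[str, ...]
        Names of the classes carried into trend analysis.
    forest_merge : tuple[str, ...]
        Names of the classes relabelled to ``merge_target`` by
        :func:`lcluc.aggregate.merge_classes`.
    merge_target : str
        Name of the merged forest super-class.
    nodata_code : int
        Code reserved for missing observations; never a legend entry.
    """

    entries: dict[int, str]
    analysis_set: tuple[str, ...] = ()
    forest_merge: tuple[str, ...] = ()
    merge_target: str = "FORE"
    nodata_code: int = 0

    _name_to_code: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = list(self.entries.values())
        if len(set(names)) != len(names):
            raise ValueError("legend class names must be unique")
        if self.nodata_code in self.entries:
            raise ValueError(f"nodata code {self.nodata_code} collides with a legend entry")
        missing = [n for n in self.analysis_set if n not in names]
        if missing:
            raise ValueError(f"analysis_set names not in legend: {missing}")
        missing = [n for n in self.forest_merge if n not in names]
        if missing:
            raise ValueError(f"forest_merge names not in legend: {missing}")
        if self.forest_merge and self.merge_target not in names:
            raise ValueError(f"merge target {self.merge_target!r} not in legend")
        object.__setattr__(self, "_name_to_code", {v: k for k, v in self.entries.items()})

    # -- lookups ---------------------------------------------------------

    def code(self, name: str) -> int:
        return self._name_to_code[name]

    def name(self, code: int) -> str:
        return self.entries[code]

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(self.entries)

    @property
    def analysis_codes(self) -> tuple[int, ...]:
        return tuple(self._name_to_code[n] for n in self.analysis_set)

    @property
    def forest_merge_codes(self) -> tuple[int, ...]:
        return tuple(self._name_to_code[n] for n in self.forest_merge)

    @property
    def merge_target_code(self) -> int:
        return self._name_to_code[self.merge_target]

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "entries": [[c, n] for c, n in sorted(self.entries.items())],
            "analysis_set": list(self.analysis_set),
            "forest_merge": list(self.forest_merge),
            "merge_target": self.merge_target,
            "nodata_code": self.nodata_code,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassLegend":
        doc = json.loads(Path(path).read_text())
        return cls(
            entries={int(c): str(n) for c, n in doc["entries"]},
            analysis_set=tuple(doc.get("analysis_set", ())),
            forest_merge=tuple(doc.get("forest_merge", ())),
            merge_target=doc.get("merge_target", "FORE"),
            nodata_code=int(doc.get("nodata_code", 0)),
        )


#: The eight classes tracked by hotspot trend analysis.
ANALYSIS_CLASSES = ("AGRI", "BARE", "CLSH", "FORE", "GRAS", "OPSH", "SPAS", "URBN")

#: Forest types collapsed into FORE before fraction aggregation.
FOREST_TYPES = ("DBLE", "DNLE", "EBLE", "ENLE", "MIXED")


def default_legend() -> ClassLegend:
    """The 15-class legend (14 mapped types plus the FORE super-class)."""
    names = (
        "AGRI", "BARE", "CLSH", "DBLE", "DNLE", "EBLE", "ENLE", "MIXED",
        "GRAS", "OPSH", "SNOW", "SPAS", "URBN", "WATR", "FORE",
    )
    return ClassLegend(
        entries={i + 1: n for i, n in enumerate(names)},
        analysis_set=ANALYSIS_CLASSES,
        forest_merge=FOREST_TYPES,
        merge_target="FORE",
        nodata_code=0,
    )
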