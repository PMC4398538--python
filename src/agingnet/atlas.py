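"""Bilateral cortical parcellation and its grouping into anatomical lobes.

The default atlas carries 34 named cortical structures per hemisphere grouped
into six lobes (prefrontal; motor and sensory; occipital; lateral temporal;
medial temporal; parietal) plus two subcortical placeholder regions per
hemisphere (striatum, thalamus) assigned to the ``other`` lobe, for 72 regions
in total.  Region order — all left-hemisphere regions in table order, then the
right hemisphere — defines the row/column order of every connectivity matrix
downstream.  ``other``-lobe regions are never included in lobe-strength
statistics.

Two assignments are deliberately non-standard anatomically and are kept as the
grouping prints them: pericalcarine and posterior cingulate sit in the
parietal group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


class Hemisphere(str, Enum):
    LEFT = "lh"
    RIGHT = "rh"


class Lobe(str, Enum):
    PREFRONTAL = "prefrontal"
    MOTOR_SENSORY = "motor_sensory"
    OCCIPITAL = "occipital"
    LATERAL_TEMPORAL = "lateral_temporal"
    MEDIAL_TEMPORAL = "medial_temporal"
    PARIETAL = "parietal"
    OTHER = "other"


#: Named lobes used in strength statistics ("other" is excluded).
NAMED_LOBES = tuple(l for l in Lobe if l is not Lobe.OTHER)

# One hemisphere's worth of the default parcellation, in table order.
_DEFAULT_GROUPS: tuple[tuple[Lobe, tuple[str, ...]], ...] = (
    (Lobe.PREFRONTAL, (
        "superior frontal",
        "caudal middle frontal",
        "rostral middle frontal",
        "pars opercularis",
        "pars triangularis",
        "pars orbitalis",
        "lateral orbitofrontal",
        "medial orbitofrontal",
        "frontal pole",
        "anterior cingulate",
    )),
    (Lobe.MOTOR_SENSORY, (
        "precentral",
        "paracentral",
        "postcentral gyrus",
        "insular",
    )),
    (Lobe.OCCIPITAL, (
        "lateral occipital",
        "lingual gyrus",
        "cuneus",
    )),
    (Lobe.LATERAL_TEMPORAL, (
        "superior temporal",
        "transverse temporal",
        "middle temporal",
        "banks of superior temporal",
        "fusiform",
        "inferior temporal",
    )),
    (Lobe.MEDIAL_TEMPORAL, (
        "parahippocampus",
        "temporal pole",
        "entorhinal",
        "hippocampus",
        "amygdala",
    )),
    (Lobe.PARIETAL, (
        "superior parietal",
        "supramarginal",
        "inferior parietal",
        "pericalcarine",
        "precuneus",
        "posterior cingulate",
    )),
    # Placeholder subcortical regions completing 36 per hemisphere; excluded
    # from all lobe-strength statistics.
    (Lobe.OTHER, (
        "striatum",
        "thalamus",
    )),
)


class AtlasSchemaError(ValueError):
    """Raised when an atlas definition violates the schema."""


@dataclass(frozen=True)
class Region:
    """One parcellation unit: a named structure in one hemisphere."""

    name: str
    hemisphere: Hemisphere
    lobe: Lobe
    index: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.hemisphere.value)


class Atlas:
    """Ordered, validated collection of :class:`Region`.

    Parameters
    ----------
    regions
        Regions with contiguous indices 0..R-1 in list order.
    """

    def __init__(self, regions: Sequence[Region]):
        regions = list(regions)
        seen_keys: set[tuple[str, str]] = set()
        for pos, r in enumerate(regions):
            if r.index != pos:
                raise AtlasSchemaError(
                    f"region {r.name!r}/{r.hemisphere.value} has index {r.index}, "
                    f"expected contiguous index {pos}"
                )
            if r.key in seen_keys:
                raise AtlasSchemaError(
                    f"duplicate region {r.name!r} in hemisphere {r.hemisphere.value!r}"
                )
            seen_keys.add(r.key)
        self.regions: tuple[Region, ...] = tuple(regions)
        self._by_key = {r.key: r for r in self.regions}

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def __len__(self) -> int:
        return self.n_regions

    def __iter__(self):
        return iter(self.regions)

    def __eq__(self, other) -> bool:
        return isinstance(other, Atlas) and self.regions == other.regions

    def region(self, name: str, hemisphere: Hemisphere | str) -> Region:
        hemi = Hemisphere(hemisphere)
        try:
            return self._by_key[(name, hemi.value)]
        except KeyError:
            raise KeyError(f"no region {name!r} in hemisphere {hemi.value!r}") from None

    def region_instances(self, name: str) -> list[Region]:
        """All hemisphere instances of a named structure, in index order."""
        out = [r for r in self.regions if r.name == name]
        if not out:
            raise KeyError(f"unknown region name {name!r}")
        return out

    def regions_in_lobe(
        self, lobe: Lobe | str, hemisphere: Hemisphere | str | None = None
    ) -> list[Region]:
        lobe = Lobe(lobe)
        hemi = Hemisphere(hemisphere) if hemisphere is not None else None
        return [
            r
            for r in self.regions
            if r.lobe is lobe and (hemi is None or r.hemisphere is hemi)
        ]

    def lobe_indices(
        self, lobe: Lobe | str, hemisphere: Hemisphere | str | None = None
    ) -> list[int]:
        return [r.index for r in self.regions_in_lobe(lobe, hemisphere)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> list[dict]:
        return [
            {"name": r.name, "hemisphere": r.hemisphere.value, "lobe": r.lobe.value}
            for r in self.regions
        ]

    @classmethod
    def from_dict(cls, entries: Iterable[dict]) -> "Atlas":
        regions = []
        for i, e in enumerate(entries):
            try:
                hemi = Hemisphere(e["hemisphere"])
            except ValueError:
                raise AtlasSchemaError(
                    f"unknown hemisphere label {e.get('hemisphere')!r} at entry {i}"
                ) from None
            try:
                lobe = Lobe(e["lobe"])
            except ValueError:
                raise AtlasSchemaError(
                    f"unknown lobe label {e.get('lobe')!r} at entry {i}"
                ) from None
            regions.append(Region(name=str(e["name"]), hemisphere=hemi, lobe=lobe, index=i))
        if not regions:
            raise AtlasSchemaError("atlas has no regions")
        return cls(regions)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        """Interoperability export: index, name, hemisphere, lobe."""
        lines = ["index\tname\themisphere\tlobe"]
        lines += [
            f"{r.index}\t{r.name}\t{r.hemisphere.value}\t{r.lobe.value}"
            for r in self.regions
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def default_atlas() -> Atlas:
    """The bundled 72-region bilateral atlas."""
    entries = []
    for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
        for lobe, names in _DEFAULT_GROUPS:
            for name in names:
                entries.append(
                    {"name": name, "hemisphere": hemi.value, "lobe": lobe.value}
                )
    return Atlas.from_dict(entries)


def default_atlas_path() -> Path:
    """Path of the bundled default atlas JSON (package data)."""
    return Path(resources.files("agingnet").joinpath("data/default_atlas.json"))


def load_atlas(path: str | Path) -> Atlas:
    """Load and validate an atlas JSON file.

    The schema is a JSON array of objects with fields ``name``,
    ``hemisphere`` ("lh"/"rh") and ``lobe``; array order defines matrix order.
    """
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AtlasSchemaError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(entries, list):
        raise AtlasSchemaError(f"{path}: top-level value must be a JSON array")
    return Atlas.from_dict(entries)


def regions_in_lobe(
    atlas: Atlas, lobe: Lobe | str, hemisphere: Hemisphere | str | None = None
) -> list[Region]:
    """All regions of ``atlas`` in ``lobe`` (optionally one hemisphere), in index order."""
    return atlas.regions_in_lobe(lobe, hemisphere)
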