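"""Region atlas: 24 grey-matter regions with hemisphere pairing and group tags.

The atlas covers four anatomical groups — brainstem, cerebellar, subcortical
and cortical. Brainstem structures, the cerebellar vermis and the corpus
callosum are treated as midline (unpaired); every other region carries left
and right columns in raw scan tables (suffixes ``_L``/``_R``) that are summed
into a single combined volume before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class SchemaError(ValueError):
    """Raised when scan data do not match the region schema."""


#: (region name, group, paired?) — the canonical 24-region grey-matter atlas.
_DEFAULT_REGIONS: list[tuple[str, str, bool]] = [
    ("medulla", "brainstem", False),
    ("pons", "brainstem", False),
    ("scp", "brainstem", False),
    ("midbrain", "brainstem", False),
    ("cerebellar_cortex", "cerebellar", True),
    ("dentate_nucleus", "cerebellar", True),
    ("vermis", "cerebellar", False),
    ("thalamus", "subcortical", True),
    ("globus_pallidus", "subcortical", True),
    ("caudate", "subcortical", True),
    ("putamen", "subcortical", True),
    ("ventral_dc", "subcortical", True),
    ("hippocampus", "subcortical", True),
    ("amygdala", "subcortical", True),
    ("nucleus_accumbens", "subcortical", True),
    ("basal_forebrain", "cortical", True),
    ("cingulate", "cortical", True),
    ("corpus_callosum", "cortical", False),
    ("frontal_anterior", "cortical", True),
    ("frontal_posterior", "cortical", True),
    ("insula", "cortical", True),
    ("temporal", "cortical", True),
    ("parietal", "cortical", True),
    ("occipital", "cortical", True),
]


@dataclass(frozen=True)
class RegionSchema:
    """Named regions, their anatomical group, and which are left/right paired.

    Parameters
    ----------
    regions
        Combined region names, in canonical order.
    groups
        Anatomical group tag per region (same order as ``regions``).
    paired
        Region names that carry separate left/right volumes in raw data.
    """

    regions: tuple[str, ...]
    groups: tuple[str, ...]
    paired: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.regions) != len(set(self.regions)):
            raise SchemaError("region names must be unique")
        if len(self.groups) != len(self.regions):
            raise SchemaError("one group tag required per region")
        unknown = self.paired - set(self.regions)
        if unknown:
            raise SchemaError(f"paired regions not in schema: {sorted(unknown)}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def group_of(self, region: str) -> str:
        try:
            return self.groups[self.regions.index(region)]
        except ValueError:
            raise SchemaError(f"unknown region: {region!r}") from None

    def is_paired(self, region: str) -> bool:
        if region not in self.regions:
            raise SchemaError(f"unknown region: {region!r}")
        return region in self.paired

    def raw_columns(self) -> list[str]:
        """Column names for a raw scan table: ``_L``/``_R`` for paired regions."""
        cols: list[str] = []
        for r in self.regions:
            if r in self.paired:
                cols.extend([f"{r}_L", f"{r}_R"])
            else:
                cols.append(r)
        return cols

    def sides(self, region: str) -> tuple[str, ...]:
        """Raw column name(s) holding the volume(s) of ``region``."""
        if region in self.paired:
            return (f"{region}_L", f"{region}_R")
        if region in self.regions:
            return (region,)
        raise SchemaError(f"unknown region: {region!r}")

    def validate_regions(self, names) -> None:
        missing = [n for n in names if n not in self.regions]
        if missing:
            raise SchemaError(f"regions not in schema: {missing}")


def default_schema() -> RegionSchema:
    """The canonical 24-region grey-matter atlas."""
    names = tuple(r for r, _, _ in _DEFAULT_REGIONS)
    groups = tuple(g for _, g, _ in _DEFAULT_REGIONS)
    paired = frozenset(r for r, _, p in _DEFAULT_REGIONS if p)
    return RegionSchema(regions=names, groups=groups, paired=paired)
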