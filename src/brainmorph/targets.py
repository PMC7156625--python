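"""Fixed 165-target registry and FreeSurfer statistics-file ingestion.

The regression target of the morphometry network is a fixed, ordered vector of
165 measures: 29 subcortical/global volumes (mm³), 68 cortical mean
thicknesses (mm) and 68 cortical mean curvatures (mm⁻¹), the cortical entries
being the 34 Desikan-Killiany parcellations per hemisphere.  Reference values
("silver standard") are read from the text statistics files FreeSurfer emits:
``aseg.stats`` for volumes and ``lh.aparc.stats`` / ``rh.aparc.stats`` for the
surface averages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROIDescriptor",
    "TargetRegistry",
    "MorphometryVector",
    "build_registry",
    "parse_aseg",
    "parse_aparc",
    "assemble_vector",
    "CompletenessError",
    "StatsParseError",
    "DK_PARCELLATIONS",
    "ASEG_VOLUME_ROSTER",
    "CC_SUBREGIONS",
]


class StatsParseError(ValueError):
    """A statistics file row could not be interpreted."""


class CompletenessError(KeyError):
    """A required structure/parcellation is absent from the input."""

    def __init__(self, missing: Sequence[str], source: str = "input"):
        self.missing = list(missing)
        super().__init__(f"{source} is missing required entries: {', '.join(self.missing)}")


#: The 34 Desikan-Killiany cortical parcellations, in aparc.stats file order.
DK_PARCELLATIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Corpus-callosum sub-regions whose volumes are summed into one target.
CC_SUBREGIONS: tuple[str, ...] = (
    "CC_Anterior",
    "CC_Mid_Anterior",
    "CC_Central",
    "CC_Mid_Posterior",
    "CC_Posterior",
)

#: Versioned 29-name volume roster (registry name, aseg source, hemisphere).
#: Global measures (total GM, cerebral WM) come from aseg.stats "# Measure"
#: header lines; the rest from table rows.  Corpus callosum is the sum of its
#: five sub-regions.
ASEG_VOLUME_ROSTER: tuple[tuple[str, str], ...] = (
    ("TotalGray", "none"),
    ("CerebralWhiteMatter", "none"),
    ("Left-Lateral-Ventricle", "left"),
    ("Right-Lateral-Ventricle", "right"),
    ("Left-Inf-Lat-Vent", "left"),
    ("Right-Inf-Lat-Vent", "right"),
    ("Left-Thalamus-Proper", "left"),
    ("Right-Thalamus-Proper", "right"),
    ("Left-Caudate", "left"),
    ("Right-Caudate", "right"),
    ("Left-Putamen", "left"),
    ("Right-Putamen", "right"),
    ("Left-Pallidum", "left"),
    ("Right-Pallidum", "right"),
    ("Left-Hippocampus", "left"),
    ("Right-Hippocampus", "right"),
    ("Left-Amygdala", "left"),
    ("Right-Amygdala", "right"),
    ("Left-Accumbens-area", "left"),
    ("Right-Accumbens-area", "right"),
    ("Left-VentralDC", "left"),
    ("Right-VentralDC", "right"),
    ("Left-Cerebellum-Cortex", "left"),
    ("Right-Cerebellum-Cortex", "right"),
    ("3rd-Ventricle", "none"),
    ("4th-Ventricle", "none"),
    ("Brain-Stem", "none"),
    ("CorpusCallosum", "none"),
    ("WM-hypointensities", "none"),
)

_UNITS = {"volume": "mm^3", "thickness": "mm", "curvature": "mm^-1"}


@dataclass(frozen=True)
class ROIDescriptor:
    """One morphometric target: a named region with a measure category."""

    name: str
    category: str  # volume | thickness | curvature
    hemisphere: str  # left | right | none
    index: int

    def __post_init__(self):
        if self.category not in _UNITS:
            raise ValueError(f"unknown category {self.category!r}")
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    @property
    def units(self) -> str:
        return _UNITS[self.category]


@dataclass(frozen=True)
class TargetRegistry:
    """Immutable ordered collection of the 165 ROI descriptors."""

    descriptors: tuple[ROIDescriptor, ...]

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, i: int) -> ROIDescriptor:
        return self.descriptors[i]

    def index_of(self, name: str, category: str, hemisphere: str | None = None) -> int:
        """Index of a descriptor.

        Volume names are globally unique so ``hemisphere`` may be omitted;
        cortical names exist in both hemispheres and resolve to the left one
        unless ``hemisphere`` says otherwise.
        """
        try:
            lookup = self._lookup
        except AttributeError:
            lookup = {(d.name, d.category, d.hemisphere): d.index for d in self.descriptors}
            object.__setattr__(self, "_lookup", lookup)
        if hemisphere is not None:
            return lookup[(name, category, hemisphere)]
        for hemi in ("none", "left", "right"):
            key = (name, category, hemi)
            if key in lookup:
                return lookup[key]
        raise KeyError((name, category))

    def names(self, category: str | None = None) -> list[str]:
        return [d.name for d in self.descriptors if category is None or d.category == category]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.category] = counts.get(d.category, 0) + 1
        return counts

    def content_hash(self) -> str:
        """Stable hash of the full descriptor table (for checkpoints/manifests)."""
        payload = json.dumps(
            [(d.name, d.category, d.hemisphere, d.units, d.index) for d in self.descriptors]
        ).encode()
        return hashlib.sha256(payload).hexdigest()


def build_registry() -> TargetRegistry:
    """Build the fixed 165-target registry.

    Ordering: the 29 volumes in the pinned roster order, then left-hemisphere
    thicknesses, right thicknesses, left curvatures, right curvatures, the
    cortical blocks each in Desikan-Killiany file order.
    """
    descs: list[ROIDescriptor] = []
    for name, hemi in ASEG_VOLUME_ROSTER:
        descs.append(ROIDescriptor(name, "volume", hemi, len(descs)))
    for category in ("thickness", "curvature"):
        for hemi in ("left", "right"):
            for name in DK_PARCELLATIONS:
                descs.append(ROIDescriptor(name, category, hemi, len(descs)))
    return TargetRegistry(tuple(descs))


@dataclass
class MorphometryVector:
    """165 values aligned to a :class:`TargetRegistry`.

    ``mask`` marks populated entries; unbound entries (e.g. phantom targets the
    generator does not emulate) are flagged absent rather than set to zero.
    """

    values: np.ndarray
    registry: TargetRegistry
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.registry),):
            raise ValueError(
                f"expected {len(self.registry)} values, got shape {self.values.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(len(self.registry), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.values)

    def get(self, name: str, category: str, hemisphere: str | None = None) -> float:
        return float(self.values[self.registry.index_of(name, category, hemisphere)])

    def to_frame(self) -> pd.DataFrame:
        reg = self.registry
        return pd.DataFrame(
            {
                "name": [d.name for d in reg],
                "category": [d.category for d in reg],
                "hemisphere": [d.hemisphere for d in reg],
                "units": [d.units for d in reg],
                "value": self.values,
                "present": self.mask,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, registry: TargetRegistry | None = None) -> "MorphometryVector":
        registry = registry or build_registry()
        df = pd.read_csv(path)
        values = np.full(len(registry), np.nan)
        mask = np.zeros(len(registry), dtype=bool)
        for _, row in df.iterrows():
            i = registry.index_of(str(row["name"]), str(row["category"]),
                                  str(row["hemisphere"]) if "hemisphere" in df else None)
            values[i] = float(row["value"])
            mask[i] = bool(row.get("present", True))
        return cls(values, registry, mask)

    def to_json(self) -> str:
        return self.to_frame().to_json(orient="records")


# ---------------------------------------------------------------------------
# FreeSurfer stats-file parsing


def _data_lines(text: str) -> Iterable[tuple[int, str]]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, stripped


def _measure_lines(text: str) -> Iterable[str]:
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("# Measure"):
            yield stripped


def parse_aseg(text: str) -> dict[str, float]:
    """Parse an ``aseg.stats`` file into ``{registry name: volume mm³}``.

    Handles both the whitespace-delimited table section (column 5 is
    ``Volume_mm3``, column 4 ``StructName``) and the ``# Measure`` header
    lines used for the global measures (total gray, cerebral white matter).
    The corpus callosum is reported as the sum of its five sub-regions.

    Raises
    ------
    StatsParseError
        for a malformed table row (with its line number).
    CompletenessError
        if any roster structure is absent.
    """
    volumes: dict[str, float] = {}
    for meas in _measure_lines(text):
        # "# Measure TotalGray, TotalGrayVol, Total gray matter volume, 611442.1, mm^3"
        body = meas[len("# Measure") :].strip()
        parts = [p.strip() for p in body.split(",")]
        if len(parts) >= 4:
            try:
                volumes[parts[0]] = float(parts[-2])
            except ValueError:
                continue
    for lineno, line in _data_lines(text):
        fields = line.split()
        if len(fields) < 5:
            raise StatsParseError(f"line {lineno}: expected >=5 columns, got {len(fields)}")
        name = fields[4]
        try:
            vol = float(fields[3])
        except ValueError as exc:
            raise StatsParseError(f"line {lineno}: bad volume field {fields[3]!r}") from exc
        volumes[name] = vol

    cc_missing = [s for s in CC_SUBREGIONS if s not in volumes]
    if not cc_missing:
        volumes["CorpusCallosum"] = sum(volumes[s] for s in CC_SUBREGIONS)

    required = [name for name, _ in ASEG_VOLUME_ROSTER]
    missing = [n for n in required if n not in volumes]
    if missing:
        raise CompletenessError(missing, source="aseg.stats")
    return {n: volumes[n] for n in required}


# aparc.stats default column layout when no "# ColHeaders" line is present
_APARC_DEFAULT_COLS = (
    "StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv "
    "GausCurv FoldInd CurvInd"
).split()


def parse_aparc(text: str, hemisphere: str) -> dict[str, tuple[float, float]]:
    """Parse ``?h.aparc.stats`` into ``{parcellation: (thickness, curvature)}``.

    Columns are located from the ``# ColHeaders`` comment when present,
    otherwise the standard FreeSurfer layout is assumed.  Exactly the 34
    Desikan-Killiany parcellations must be present.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be left/right, got {hemisphere!r}")
    cols = _APARC_DEFAULT_COLS
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("# ColHeaders"):
            cols = stripped[len("# ColHeaders") :].split()
    try:
        i_name = cols.index("StructName")
        i_thick = cols.index("ThickAvg")
        i_curv = cols.index("MeanCurv")
    except ValueError as exc:
        raise StatsParseError(f"required columns absent from header: {cols}") from exc

    out: dict[str, tuple[float, float]] = {}
    for lineno, line in _data_lines(text):
        fields = line.split()
        if len(fields) <= max(i_name, i_thick, i_curv):
            raise StatsParseError(f"line {lineno}: too few columns ({len(fields)})")
        name = fields[i_name]
        if name not in DK_PARCELLATIONS:
            raise StatsParseError(f"line {lineno}: unknown parcellation {name!r}")
        try:
            out[name] = (float(fields[i_thick]), float(fields[i_curv]))
        except ValueError as exc:
            raise StatsParseError(f"line {lineno}: non-numeric thickness/curvature") from exc

    missing = [n for n in DK_PARCELLATIONS if n not in out]
    if missing:
        raise CompletenessError(missing, source=f"{hemisphere} aparc.stats")
    return out


def assemble_vector(
    aseg_map: Mapping[str, float],
    lh_map: Mapping[str, tuple[float, float]],
    rh_map: Mapping[str, tuple[float, float]],
    registry: TargetRegistry | None = None,
) -> MorphometryVector:
    """Place parsed stats values into registry order."""
    registry = registry or build_registry()
    values = np.full(len(registry), np.nan)
    missing: list[str] = []
    for d in registry:
        if d.category == "volume":
            if d.name in aseg_map:
                values[d.index] = aseg_map[d.name]
            else:
                missing.append(d.name)
        else:
            src = lh_map if d.hemisphere == "left" else rh_map
            if d.name in src:
                pair = src[d.name]
                values[d.index] = pair[0] if d.category == "thickness" else pair[1]
            else:
                missing.append(f"{d.hemisphere}/{d.name}")
    if missing:
        raise CompletenessError(sorted(set(missing)), source="assembled maps")
    return MorphometryVector(values, registry)


def ingest_stats(aseg_text: str, lh_text: str, rh_text: str) -> MorphometryVector:
    """End-to-end: parse the three stats files and assemble the 165-vector."""
    return assemble_vector(
        parse_aseg(aseg_text),
        parse_aparc(lh_text, "left"),
        parse_aparc(rh_text, "right"),
    )
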