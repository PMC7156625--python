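"""Shared fixtures: programmatically synthesized FreeSurfer stats files and
small phantom objects."""

from __future__ import annotations

import numpy as np
import pytest

from brainmorph.targets import (
    ASEG_VOLUME_ROSTER,
    CC_SUBREGIONS,
    DK_PARCELLATIONS,
    build_registry,
)


def make_aseg_text(
    volumes: dict[str, float] | None = None,
    cc_volumes: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0, 500.0),
    drop: tuple[str, ...] = (),
) -> str:
    """Synthesize an aseg.stats file covering the pinned roster.

    Measure-header structures (total gray, cerebral WM) are emitted as
    ``# Measure`` lines; everything else as table rows in the standard
    whitespace-delimited layout.
    """
    rng = np.random.default_rng(7)
    vals = {name: float(rng.uniform(500, 20000)) for name, _ in ASEG_VOLUME_ROSTER}
    vals.update(volumes or {})
    lines = [
        "# Title Segmentation Statistics",
        "# generating_program mri_segstats",
        f"# Measure TotalGray, TotalGrayVol, Total gray matter volume, {vals['TotalGray']}, mm^3",
        "# Measure CerebralWhiteMatter, CerebralWhiteMatterVol, "
        f"Total cerebral white matter volume, {vals['CerebralWhiteMatter']}, mm^3",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean normStdDev normMin normMax normRange",
    ]
    idx = 1
    table_names = [
        n for n, _ in ASEG_VOLUME_ROSTER
        if n not in ("TotalGray", "CerebralWhiteMatter", "CorpusCallosum")
    ] + list(CC_SUBREGIONS)
    for name in table_names:
        if name in drop:
            continue
        if name in CC_SUBREGIONS:
            vol = cc_volumes[CC_SUBREGIONS.index(name)]
        else:
            vol = vals[name]
        nvox = int(vol)
        lines.append(
            f"{idx:3d} {idx:3d} {nvox:8d} {vol:10.1f} {name:<30s} 100.0 10.0 50.0 150.0 100.0"
        )
        idx += 1
    return "\n".join(lines) + "\n"


def make_aparc_text(
    values: dict[str, tuple[float, float]] | None = None,
    drop: tuple[str, ...] = (),
) -> str:
    """Synthesize a ?h.aparc.stats file with all 34 DK parcellations."""
    rng = np.random.default_rng(11)
    rows = {
        name: (float(rng.uniform(1.5, 3.5)), float(rng.uniform(0.08, 0.2)))
        for name in DK_PARCELLATIONS
    }
    rows.update(values or {})
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd",
    ]
    for name, (thick, curv) in rows.items():
        if name in drop:
            continue
        lines.append(
            f"{name:<28s} 5000 3000 9000 {thick:6.3f} 0.5 {curv:6.3f} 0.030 50 4.0"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture
def aseg_text():
    return make_aseg_text()


@pytest.fixture
def lh_aparc_text():
    return make_aparc_text()


@pytest.fixture
def rh_aparc_text():
    return make_aparc_text(values={"precuneus": (2.4, 0.13)})
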