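"""Simulated gel electrophoresis ("gel view") of an allele-size matrix.

Band mobility follows the standard agarose approximation — migration
distance is linear in log10 of fragment size:

    migration = well_offset + lane_height * (log10(s_max) - log10(size))
                                          / (log10(s_max) - log10(s_min))

so the largest renderable fragment sits at the well and the smallest runs
the full lane. The default ladder mimics a 25-450 bp sizing marker. Output
is deterministic SVG text plus a band table (TSV) encoding the identical
(size, migration) pairs, so images are diff-able in tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["GelParams", "Band", "GelImage", "migration", "render_gel"]

DEFAULT_LADDER = (25, 50, 75, 100, 150, 200, 250, 300, 350, 400, 450)


@dataclass(frozen=True)
class GelParams:
    lane_height: float = 400.0
    lane_width: float = 60.0
    s_min: int = 25
    s_max: int = 500
    ladder: Sequence[int] = DEFAULT_LADDER
    well_offset: float = 20.0

    def __post_init__(self) -> None:
        if self.s_min >= self.s_max:
            raise ValueError("need s_min < s_max")
        for b in self.ladder:
            if not (self.s_min <= b <= self.s_max):
                raise ValueError(f"ladder band {b} outside render range")


@dataclass(frozen=True)
class Band:
    size: float
    migration: float


@dataclass
class GelImage:
    lanes: list[tuple[str, list[Band]]]
    params: GelParams = field(default_factory=GelParams)

    def band_table(self) -> pd.DataFrame:
        rows = [
            {"lane": label, "size": b.size, "migration": round(b.migration, 3)}
            for label, bands in self.lanes
            for b in bands
        ]
        return pd.DataFrame(rows, columns=["lane", "size", "migration"])


def migration(size: float, params: GelParams | None = None) -> float:
    """Migration distance in pixels for a fragment of ``size`` bp.

    Sizes outside [s_min, s_max] are clipped to the range with a warning
    (the band renders at the gel edge).
    """
    params = params if params is not None else GelParams()
    if size < params.s_min or size > params.s_max:
        warnings.warn(
            f"fragment size {size} outside render range "
            f"[{params.s_min}, {params.s_max}]; clipping",
            stacklevel=2,
        )
        size = min(max(size, params.s_min), params.s_max)
    span = math.log10(params.s_max) - math.log10(params.s_min)
    frac = (math.log10(params.s_max) - math.log10(size)) / span
    return params.well_offset + params.lane_height * frac


def _lanes_from_matrix(matrix) -> list[tuple[str, list[float]]]:
    """Accept a mapping label -> sizes, or a PolymorphismReport (one lane
    per genotype; MISSING skipped, MULTI contributes several bands)."""
    if hasattr(matrix, "calls") and hasattr(matrix, "genotype_ids"):
        lanes: dict[str, list[float]] = {g: [] for g in matrix.genotype_ids}
        for call in matrix.calls:
            for g in matrix.genotype_ids:
                a = call.alleles[g]
                if a is None:
                    continue
                if isinstance(a, list):
                    lanes[g].extend(float(s) for s in a)
                else:
                    lanes[g].append(float(a))
        return [(g, lanes[g]) for g in matrix.genotype_ids]
    if isinstance(matrix, Mapping):
        return [(str(k), [float(s) for s in v]) for k, v in matrix.items()]
    raise TypeError("matrix must be a mapping label -> sizes or a PolymorphismReport")


def render_gel(
    matrix,
    params: GelParams | None = None,
    path: str | Path | None = None,
) -> GelImage:
    """Render lanes (ladder first) to a GelImage and optionally an SVG file.

    ``matrix``: mapping label -> list of fragment sizes (a missing allele is
    an empty list, a multi-product genotype lists several sizes), or a
    PolymorphismReport. Writes ``path`` (SVG) and ``path`` + ``.bands.tsv``
    when a path is given.
    """
    params = params if params is not None else GelParams()
    sample_lanes = _lanes_from_matrix(matrix)
    if not any(sizes for _, sizes in sample_lanes):
        raise ValueError("gel rendering needs at least one band in one lane")

    lanes: list[tuple[str, list[Band]]] = [
        ("ladder", [Band(float(s), migration(float(s), params)) for s in params.ladder])
    ]
    for label, sizes in sample_lanes:
        lanes.append(
            (label, [Band(float(s), migration(float(s), params)) for s in sorted(sizes)])
        )
    image = GelImage(lanes=lanes, params=params)
    if path is not None:
        path = Path(path)
        path.write_text(_svg(image))
        image.band_table().to_csv(path.with_suffix(path.suffix + ".bands.tsv"),
                                  sep="\t", index=False)
    return image


def _svg(image: GelImage) -> str:
    p = image.params
    n = len(image.lanes)
    pad = 10.0
    width = pad * 2 + n * p.lane_width
    height = p.well_offset + p.lane_height + 40.0
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.1f}" '
        f'height="{height:.1f}" viewBox="0 0 {width:.1f} {height:.1f}">',
        f'<rect x="0" y="0" width="{width:.1f}" height="{height:.1f}" fill="#101018"/>',
    ]
    for i, (label, bands) in enumerate(image.lanes):
        x0 = pad + i * p.lane_width
        cx = x0 + p.lane_width / 2
        parts.append(
            f'<rect x="{x0 + 4:.1f}" y="{p.well_offset:.1f}" '
            f'width="{p.lane_width - 8:.1f}" height="{p.lane_height:.1f}" '
            f'fill="#181826"/>'
        )
        parts.append(
            f'<text x="{cx:.1f}" y="{p.well_offset + p.lane_height + 24:.1f}" '
            f'fill="#cccccc" font-size="10" text-anchor="middle">{label}</text>'
        )
        for b in bands:
            parts.append(
                f'<rect x="{x0 + 6:.1f}" y="{b.migration - 1.5:.3f}" '
                f'width="{p.lane_width - 12:.1f}" height="3" fill="#e8e8f8">'
                f"<title>{b.size:g} bp</title></rect>"
            )
            if label == "ladder":
                parts.append(
                    f'<text x="{x0 + 2:.1f}" y="{b.migration + 3:.3f}" '
                    f'fill="#888899" font-size="7" text-anchor="end">{b.size:g}</text>'
                )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
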