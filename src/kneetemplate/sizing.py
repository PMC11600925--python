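"""Implant size selection and the coronal/sagittal merge rule.

A size chart maps catalogue sizes to mediolateral (ML) and anteroposterior
(AP) implant dimensions per component.  Each view recommends the largest
size whose relevant dimension still fits within the measured bone width
(no-overhang floor rule); the merged prediction takes the lesser of the
coronal and sagittal recommendations, again to prevent overhang.

The chart shipped by :func:`default_chart` is synthetic: an eight-size
ladder with plausibly spaced dimensions, standing in for vendor data that
is not public.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, StageError
from .coronal import CoronalPlan, coronal_template
from .sagittal import SagittalPlan, sagittal_template
from .scene import KneeScene

__all__ = ["ChartEntry", "ImplantSizeChart", "ComponentSizing",
           "TemplatingResult", "default_chart", "select_size", "merge_sizes",
           "template_knee"]


@dataclass(frozen=True)
class ChartEntry:
    size: int
    ml_mm: float
    ap_mm: float


@dataclass
class ImplantSizeChart:
    """Ordered size ladder for one component ("femoral" or "tibial")."""

    component: str
    entries: list[ChartEntry]

    def __post_init__(self):
        if not self.entries:
            raise ConfigurationError(f"empty size chart for {self.component}")
        self.entries = sorted(self.entries, key=lambda e: e.size)
        sizes = [e.size for e in self.entries]
        mls = [e.ml_mm for e in self.entries]
        aps = [e.ap_mm for e in self.entries]
        for seq, what in ((sizes, "size"), (mls, "ml_mm"), (aps, "ap_mm")):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ConfigurationError(
                    f"{self.component} chart {what} must be strictly increasing")

    def dims(self, dimension: str) -> list[float]:
        if dimension not in ("ml", "ap"):
            raise ConfigurationError(f"unknown dimension {dimension!r}")
        return [e.ml_mm if dimension == "ml" else e.ap_mm for e in self.entries]

    def entry(self, size: int) -> ChartEntry:
        for e in self.entries:
            if e.size == size:
                return e
        raise ConfigurationError(f"size {size} not in {self.component} chart")


def default_chart() -> dict[str, ImplantSizeChart]:
    """Synthetic eight-size chart (not vendor data)."""
    femoral = [ChartEntry(k, 58.0 + 2.5 * (k - 1), 52.0 + 2.2 * (k - 1))
               for k in range(1, 9)]
    tibial = [ChartEntry(k, 61.0 + 2.6 * (k - 1), 40.0 + 1.8 * (k - 1))
              for k in range(1, 9)]
    return {"femoral": ImplantSizeChart("femoral", femoral),
            "tibial": ImplantSizeChart("tibial", tibial)}


def load_chart_csv(path: str | Path) -> dict[str, ImplantSizeChart]:
    """Read a chart CSV with columns component,size,ml_mm,ap_mm."""
    df = pd.read_csv(path)
    required = {"component", "size", "ml_mm", "ap_mm"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"chart file must have columns {sorted(required)}")
    charts = {}
    for comp, grp in df.groupby("component"):
        entries = [ChartEntry(int(r.size), float(r.ml_mm), float(r.ap_mm))
                   for r in grp.itertuples()]
        charts[str(comp)] = ImplantSizeChart(str(comp), entries)
    return charts


def write_chart_csv(charts: dict[str, ImplantSizeChart], path: str | Path) -> None:
    rows = [{"component": c.component, "size": e.size,
             "ml_mm": e.ml_mm, "ap_mm": e.ap_mm}
            for c in charts.values() for e in c.entries]
    pd.DataFrame(rows).to_csv(path, index=False)


def select_size(width_mm: float, chart: ImplantSizeChart,
                dimension: str) -> tuple[int, str | None]:
    """Largest size whose chart dimension fits within ``width_mm``.

    Widths below the smallest entry clamp to the smallest size with an
    ``undersized_bone`` flag; above the largest entry, to the largest size
    with ``oversized_bone``.
    """
    if width_mm <= 0:
        raise ConfigurationError(f"width must be positive, got {width_mm}")
    dims = chart.dims(dimension)
    sizes = [e.size for e in chart.entries]
    if width_mm < dims[0]:
        return sizes[0], "undersized_bone"
    chosen = sizes[0]
    for s, d in zip(sizes, dims):
        if d <= width_mm:
            chosen = s
    return chosen, ("oversized_bone" if width_mm > dims[-1] else None)


def merge_sizes(coronal: int | None, sagittal: int | None) -> tuple[int, str | None]:
    """The lesser of the two view predictions (overhang prevention)."""
    if coronal is None and sagittal is None:
        raise ConfigurationError("no size prediction from either view")
    if coronal is None:
        return sagittal, "single_view"
    if sagittal is None:
        return coronal, "single_view"
    return min(coronal, sagittal), None


@dataclass
class ComponentSizing:
    component: str
    coronal_width_mm: float
    sagittal_width_mm: float
    coronal_size: int
    sagittal_size: int
    merged_size: int
    flags: list[str] = field(default_factory=list)


@dataclass
class TemplatingResult:
    femoral: ComponentSizing
    tibial: ComponentSizing
    coronal_plan: CoronalPlan
    sagittal_plan: SagittalPlan


def template_knee(ap_scene: KneeScene, lat_scene: KneeScene,
                  charts: dict[str, ImplantSizeChart] | None = None,
                  femur_resection_mm: float = 9.0,
                  tibia_offset_mm: float = 10.0,
                  min_lesser_depth_mm: float = 2.0,
                  adjusted_mpta_deg: float = 88.0,
                  slope_deg: float = 3.0) -> TemplatingResult:
    """End-to-end templating of one knee from its AP and lateral scenes."""
    charts = charts if charts is not None else default_chart()
    for comp in ("femoral", "tibial"):
        if comp not in charts:
            raise ConfigurationError(f"missing {comp} size chart")

    cor = coronal_template(ap_scene, femur_resection_mm=femur_resection_mm,
                           tibia_offset_mm=tibia_offset_mm,
                           min_lesser_depth_mm=min_lesser_depth_mm,
                           adjusted_mpta_deg=adjusted_mpta_deg)
    sag = sagittal_template(lat_scene, slope_deg=slope_deg,
                            tibia_offset_mm=tibia_offset_mm)

    def component(comp: str, ml: float, ap: float) -> ComponentSizing:
        try:
            c_size, c_flag = select_size(ml, charts[comp], "ml")
            s_size, s_flag = select_size(ap, charts[comp], "ap")
            merged, m_flag = merge_sizes(c_size, s_size)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"size_selection/{comp}", e) from e
        flags = [f"coronal:{c_flag}" for c_flag in [c_flag] if c_flag]
        flags += [f"sagittal:{s_flag}" for s_flag in [s_flag] if s_flag]
        flags += [m_flag] if m_flag else []
        return ComponentSizing(component=comp, coronal_width_mm=ml,
                               sagittal_width_mm=ap, coronal_size=c_size,
                               sagittal_size=s_size, merged_size=merged,
                               flags=flags)

    femoral = component("femoral", cor.femoral_ml_width, sag.femoral_ap_length)
    tibial = component("tibial", cor.tibial_ml_width, sag.tibial_ap_width)
    return TemplatingResult(femoral=femoral, tibial=tibial,
                            coronal_plan=cor, sagittal_plan=sag)
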