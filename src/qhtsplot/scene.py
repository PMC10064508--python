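"""Backend-agnostic 3D waterfall scene construction and rendering.

Axis convention: x = compound position (layout order), y = log10 molar
concentration, z = % response.  A scene is a plain ordered list of
traces -- one markers trace per visible record, plus one line trace per
visible fitted record -- and is serializable to JSON so tests can check
plot structure without a graphics stack.

Rendering backends: a self-contained interactive HTML file (embedded
canvas renderer: drag to rotate, wheel to zoom, shift-drag to pan) and
a static PNG raster via matplotlib's 3D axes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .model import ConfigurationError, ContractError, QHTSDataset
from .curves import partition_records, sample_curve
from .layout import default_palette


@dataclass
class PlotConfig:
    """User-facing styling and visibility controls.

    Mirrors the knobs of an interactive plotting UI: per-readout
    show/hide, point and line colors, marker size, line weight, axis
    aspect ratio, background color, and whether point-only (inactive)
    records are drawn at all.  ``points_per_curve`` sets the sampling
    density of each fitted curve's line.  ``collapse_by_comp_id``
    places records sharing a compound ID on one x slot so multi-readout
    responses (e.g. coincidence-reporter FLuc/NLuc) overlay.  Datasets
    larger than ``decimation_threshold`` records have their point-only
    markers thinned (every k-th titration point kept); fitted records
    are never decimated.
    """

    hidden_readouts: set[str] = field(default_factory=set)
    point_color: dict[str, str] = field(default_factory=dict)
    line_color: dict[str, str] = field(default_factory=dict)
    point_size: float = 3.0
    line_weight: float = 2.0
    aspect_ratio: tuple[float, float, float] = (2.0, 1.0, 1.0)
    background_color: str = "white"
    show_inactive: bool = True
    axis_labels: tuple[str, str, str] = (
        "Compound",
        "log10 concentration (M)",
        "Response (%)",
    )
    points_per_curve: int = 64
    collapse_by_comp_id: bool = True
    decimation_threshold: int = 20000

    def __post_init__(self) -> None:
        if self.point_size <= 0 or self.line_weight <= 0:
            raise ConfigurationError("point_size and line_weight must be positive")
        if len(self.aspect_ratio) != 3 or any(a <= 0 for a in self.aspect_ratio):
            raise ConfigurationError("aspect_ratio must be three positive numbers")
        if self.points_per_curve < 2:
            raise ConfigurationError("points_per_curve must be >= 2")
        self.hidden_readouts = set(self.hidden_readouts)


@dataclass
class Trace:
    """One plotted element: a record's points or its fitted curve line."""

    kind: str  # "markers" | "line"
    record_index: int
    readout: str
    x: float  # compound slot position
    y: list[float]  # log10 molar concentrations
    z: list[float]  # % responses
    color: str
    size: Optional[float] = None  # markers only
    width: Optional[float] = None  # line only


@dataclass
class Scene3D:
    """Ordered trace list plus axes/camera/style metadata."""

    traces: list[Trace] = field(default_factory=list)
    axis_labels: tuple[str, str, str] = ("Compound", "log10 concentration (M)", "Response (%)")
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    camera: dict[str, float] = field(
        default_factory=lambda: {"yaw": -1.1, "pitch": 0.35, "zoom": 1.0}
    )
    aspect_ratio: tuple[float, float, float] = (2.0, 1.0, 1.0)
    background_color: str = "white"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["axis_labels"] = list(self.axis_labels)
        d["aspect_ratio"] = list(self.aspect_ratio)
        d["ranges"] = {k: list(v) for k, v in self.ranges.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Scene3D":
        traces = [Trace(**t) for t in d.get("traces", [])]
        return cls(
            traces=traces,
            axis_labels=tuple(d["axis_labels"]),
            ranges={k: tuple(v) for k, v in d["ranges"].items()},
            camera=dict(d["camera"]),
            aspect_ratio=tuple(d["aspect_ratio"]),
            background_color=d["background_color"],
        )

    def n_traces(self, kind: Optional[str] = None) -> int:
        if kind is None:
            return len(self.traces)
        return sum(1 for t in self.traces if t.kind == kind)


def _resolve_color(
    overrides: dict[str, str],
    group: Optional[str],
    readout: str,
    palette: dict[str, str],
) -> str:
    """Config overrides win; then the group's palette color; then the readout's."""
    if group is not None and group in overrides:
        return overrides[group]
    if readout in overrides:
        return overrides[readout]
    if group is not None and group in palette:
        return palette[group]
    return palette.get(readout, "#1f77b4")


def build_scene(
    ds: QHTSDataset,
    order: Optional[list[int]] = None,
    config: Optional[PlotConfig] = None,
    groups: Optional[dict[int, str]] = None,
) -> Scene3D:
    """Assemble the waterfall scene from an ordered dataset.

    ``order`` is a permutation of record indices (identity if None);
    trace order follows it.  ``groups`` optionally maps record index to
    a label (curve class, gain/loss, ...) used for coloring.  Hidden
    readouts emit no traces; with ``show_inactive=False`` point-only
    records are dropped entirely.  Missing response cells are dropped
    pointwise, never imputed.
    """
    config = config or PlotConfig()
    n = ds.n_records
    if order is None:
        order = list(range(n))
    if sorted(order) != list(range(n)):
        raise ContractError("order must be a permutation of all record indices")

    fitted, _ = partition_records(ds)
    fitted_set = set(fitted)

    label_pool: list[str] = []
    if groups:
        label_pool.extend(groups[i] for i in order if i in groups)
    label_pool.extend(ds.records[i].readout for i in order)
    palette = default_palette(label_pool)

    # visible records in layout order
    visible: list[int] = []
    for i in order:
        rec = ds.records[i]
        if rec.readout in config.hidden_readouts:
            continue
        if i not in fitted_set and not config.show_inactive:
            continue
        visible.append(i)

    # one x slot per record, or one per distinct comp_id (first-seen order)
    slots: dict = {}
    slot_of: dict[int, int] = {}
    for i in visible:
        key = ds.records[i].comp_id if config.collapse_by_comp_id else i
        if key not in slots:
            slots[key] = len(slots)
        slot_of[i] = slots[key]

    stride = 1
    if n > config.decimation_threshold:
        stride = math.ceil(n / config.decimation_threshold)

    grid = ds.log_conc_m
    traces: list[Trace] = []
    for i in visible:
        rec = ds.records[i]
        group = groups.get(i) if groups else None
        xpos = float(slot_of[i])
        is_fitted = i in fitted_set

        idxs = range(0, len(grid), stride) if (stride > 1 and not is_fitted) else range(len(grid))
        ys, zs = [], []
        for k in idxs:
            v = rec.responses[k]
            if v is not None and math.isfinite(v):
                ys.append(float(grid[k]))
                zs.append(float(v))
        if ys:
            traces.append(
                Trace(
                    kind="markers",
                    record_index=i,
                    readout=rec.readout,
                    x=xpos,
                    y=ys,
                    z=zs,
                    color=_resolve_color(config.point_color, group, rec.readout, palette),
                    size=config.point_size,
                )
            )
        if is_fitted:
            sc = sample_curve(rec.params, grid, config.points_per_curve, record_index=i)
            traces.append(
                Trace(
                    kind="line",
                    record_index=i,
                    readout=rec.readout,
                    x=xpos,
                    y=[float(v) for v in sc.x],
                    z=[float(v) for v in sc.y],
                    color=_resolve_color(config.line_color, group, rec.readout, palette),
                    width=config.line_weight,
                )
            )

    n_slots = len(slots)
    zvals = [v for t in traces for v in t.z]
    if zvals:
        zlo, zhi = min(zvals), max(zvals)
        pad = 0.05 * (zhi - zlo) or 1.0
        zrange = (zlo - pad, zhi + pad)
    else:
        zrange = (-10.0, 110.0)
    ranges = {
        "x": (-0.5, max(n_slots - 0.5, 0.5)),
        "y": (min(grid), max(grid)),
        "z": zrange,
    }
    return Scene3D(
        traces=traces,
        axis_labels=config.axis_labels,
        ranges=ranges,
        aspect_ratio=config.aspect_ratio,
        background_color=config.background_color,
    )


def render_scene(scene: Scene3D, path: str | Path, format: Optional[str] = None) -> None:
    """Write the scene to ``path`` as interactive HTML or static PNG.

    ``format`` is inferred from the extension when omitted.  HTML output
    is fully self-contained (no network resources).  PNG defaults to
    1600x1200 pixels.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "html":
        from ._html import render_html

        path.write_text(render_html(scene), encoding="utf-8")
    elif fmt == "png":
        _render_png(scene, path)
    else:
        raise ConfigurationError(f"unsupported render format {fmt!r}; use html or png")
    if not path.exists() or path.stat().st_size == 0:
        raise IOError(f"rendering produced no output at {path}")


def _render_png(scene: Scene3D, path: Path, width: int = 1600, height: int = 1200) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dpi = 100
    fig = plt.figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    ax = fig.add_subplot(projection="3d")
    ax.set_facecolor(scene.background_color)
    fig.patch.set_facecolor(scene.background_color)
    for t in scene.traces:
        xs = [t.x] * len(t.y)
        if t.kind == "line":
            ax.plot(xs, t.y, t.z, color=t.color, linewidth=t.width or 1.0)
        else:
            ax.scatter(xs, t.y, t.z, color=t.color, s=(t.size or 3.0) ** 2, depthshade=False)
    ax.set_xlabel(scene.axis_labels[0])
    ax.set_ylabel(scene.axis_labels[1])
    ax.set_zlabel(scene.axis_labels[2])
    ax.set_xlim(*scene.ranges.get("x", (0, 1)))
    ax.set_ylim(*scene.ranges.get("y", (0, 1)))
    ax.set_zlim(*scene.ranges.get("z", (0, 1)))
    ax.set_box_aspect(scene.aspect_ratio)
    fig.savefig(path)
    plt.close(fig)
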