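"""Renderer-neutral drawing primitives and SVG serialization.

:func:`compose` turns a layout plus consensus annotation into an ordered
list of primitives (pair shades below rungs below glyphs below text);
:func:`to_svg` serializes them to SVG 1.1, flipping the y-axis from the
internal y-up convention and fitting the viewBox to the content with a
2-unit margin.  Rendering is deterministic: identical inputs give
byte-identical output.

The default palette follows the conventional tiering — strongly conserved
identities in red, then black, then gray; covariation classes as
increasingly pale shades behind the pair rung; presence-only positions as
open circles whose outline style encodes the presence tier.  Everything is
configurable through :class:`StyleMap`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np

from .consensus import ConsensusAnnotation, PairClass, format_nt_range
from .geometry import LayoutResult, PseudoknotLayout, VarArc


class RenderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# style


@dataclass
class StyleMap:
    """Colors and glyph conventions for one drawing."""

    identity_colors: dict[int, str] = field(
        default_factory=lambda: {97: "#c00000", 90: "#000000", 75: "#808080"}
    )
    presence_ring_dash: dict[int, str] = field(
        default_factory=lambda: {97: "", 90: "", 75: "3,2", 50: "1,2"}
    )
    presence_ring_width: dict[int, float] = field(
        default_factory=lambda: {97: 0.10, 90: 0.06, 75: 0.06, 50: 0.05}
    )
    pair_shades: dict[str, str] = field(
        default_factory=lambda: {
            "covarying": "#2e8b2e",
            "compatible": "#8fd08f",
            "invariant": "#d9d9d9",
        }
    )
    skeleton: bool = False
    font_family: str = "Helvetica"
    backbone_color: str = "#404040"
    rung_color: str = "#808080"
    freq_label_format: str = "{percent}"

    @classmethod
    def from_json(cls, text: str) -> "StyleMap":
        data = json.loads(text)
        style = cls()
        int_keyed = {"identity_colors", "presence_ring_dash", "presence_ring_width"}
        for key, value in data.items():
            if not hasattr(style, key):
                raise RenderError(f"unknown style key {key!r}")
            current = getattr(style, key)
            if isinstance(current, dict):
                current.update(
                    {int(k) if key in int_keyed else k: v for k, v in value.items()}
                )
            else:
                setattr(style, key, value)
        return style


# ---------------------------------------------------------------------------
# primitives


@dataclass
class Glyph:
    x: float
    y: float
    char: str  # nucleotide letter, or "" for a plain circle glyph
    color: str = "#000000"
    ring_dash: str | None = None  # presence-only glyph: open circle
    ring_width: float = 0.06


@dataclass
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    color: str = "#000000"
    width: float = 0.08
    dashed: bool = False


@dataclass
class Path:
    points: list[tuple[float, float]]
    color: str = "#000000"
    width: float = 0.12


@dataclass
class Arc:
    cx: float
    cy: float
    r: float
    theta_start: float
    theta_end: float  # clockwise traversal (theta decreasing)
    color: str = "#404040"
    width: float = 0.08
    dashed: bool = True


@dataclass
class ShadedBox:
    corners: list[tuple[float, float]]  # quadrilateral behind a pair rung
    fill: str


@dataclass
class Label:
    x: float
    y: float
    text: str
    size: float = 0.9
    color: str = "#000000"
    anchor: str = "middle"


@dataclass
class SubPanel:
    offset: tuple[float, float]
    primitives: list
    title: str = ""


Primitive = Glyph | Line | Path | Arc | ShadedBox | Label | SubPanel


@dataclass
class Drawing:
    """Ordered renderer-neutral primitives plus global style and scale."""

    primitives: list
    style: StyleMap
    scale: float = 10.0  # output points per internal unit


# ---------------------------------------------------------------------------
# composition


def _pair_shade_box(
    a: np.ndarray, b: np.ndarray, half_width: float
) -> list[tuple[float, float]]:
    u = b - a
    n = np.array([-u[1], u[0]])
    norm = float(np.hypot(*n))
    if norm < 1e-12:
        raise RenderError("degenerate pair rung")
    n = n / norm * half_width
    return [tuple(a + n), tuple(b + n), tuple(b - n), tuple(a - n)]


def _backbone_paths(layout: LayoutResult) -> list[list[tuple[float, float]]]:
    """Contiguous backbone runs (split at breaks and unplaced columns)."""
    paths: list[list[tuple[float, float]]] = []
    run: list[tuple[float, float]] = []
    for col in range(layout.n_cols):
        if layout.placed(col) and col not in layout.hidden:
            run.append(tuple(layout.xy[col]))
            if col in layout.breaks:
                if len(run) > 1:
                    paths.append(run)
                run = []
        else:
            if len(run) > 1:
                paths.append(run)
            run = []
    if len(run) > 1:
        paths.append(run)
    return paths


def _glyph_for(col: int, cc, sequence: str | None, style: StyleMap, pos) -> Glyph | None:
    if sequence is not None:
        char = sequence[col]
        if char in {"-", "."}:
            return None
        return Glyph(pos[0], pos[1], char, color="#000000")
    if cc.symbol == "absent":
        return None
    if cc.symbol in {"A", "C", "G", "U", "R", "Y"}:
        color = style.identity_colors.get(cc.identity_tier or 75, "#000000")
        return Glyph(pos[0], pos[1], cc.symbol, color=color)
    tier = cc.presence_tier or 50
    return Glyph(
        pos[0],
        pos[1],
        "",
        color="#000000",
        ring_dash=style.presence_ring_dash.get(tier, ""),
        ring_width=style.presence_ring_width.get(tier, 0.06),
    )


def compose(
    layout: LayoutResult,
    annotation: ConsensusAnnotation,
    style: StyleMap | None = None,
    *,
    sequence: str | None = None,
    pk_layouts: list[PseudoknotLayout] = (),
    modular_panels: list[tuple[str, "Drawing", float]] = (),
    var_labels: dict[tuple[int, int], str] | None = None,
    shades: list[tuple[int, int, str]] = (),
    scale: float = 10.0,
) -> Drawing:
    """Compose layout + annotation into a :class:`Drawing`.

    ``sequence`` switches from consensus glyphs to the letters of a single
    ungapped-row drawing.  ``pk_layouts`` adds in-line rungs or callout
    panels; ``modular_panels`` adds sub-panels labelled with their percent
    frequency; ``shades`` paints boxes behind the given column ranges.
    The skeleton flag on ``style`` suppresses glyphs and pair decoration
    and draws only the backbone path.
    """
    style = style or StyleMap()
    if len(annotation.columns) != layout.n_cols:
        raise RenderError(
            f"annotation covers {len(annotation.columns)} columns but the "
            f"layout has {layout.n_cols}"
        )
    prims: list = []
    d_nt = layout.params.d_nt

    # column shading behind everything else
    for start, stop, color in shades:
        for col in range(start, stop):
            if layout.placed(col):
                x, y = layout.xy[col]
                r = 0.5 * d_nt
                prims.append(
                    ShadedBox(
                        corners=[
                            (x - r, y - r),
                            (x + r, y - r),
                            (x + r, y + r),
                            (x - r, y + r),
                        ],
                        fill=color,
                    )
                )

    if style.skeleton:
        for path in _backbone_paths(layout):
            prims.append(Path(path, color=style.backbone_color))
        for arc in layout.var_arcs:
            prims.append(Arc(arc.center[0], arc.center[1], arc.radius,
                             arc.theta_start, arc.theta_end))
        return Drawing(primitives=prims, style=style, scale=scale)

    # pair shades, then rungs
    for (l, r), klass in sorted(annotation.pair_classes.items()):
        if not (layout.placed(l) and layout.placed(r)):
            continue
        a, b = layout.xy[l], layout.xy[r]
        if klass is not PairClass.UNSHADED:
            prims.append(
                ShadedBox(
                    corners=_pair_shade_box(a, b, 0.30 * d_nt),
                    fill=style.pair_shades[klass.value],
                )
            )
        shrink = 0.30 * d_nt
        u = (b - a) / float(np.linalg.norm(b - a))
        pa, pb = a + shrink * u, b - shrink * u
        prims.append(Line(pa[0], pa[1], pb[0], pb[1], color=style.rung_color))

    # variable-length arcs with their "m-M nt" labels
    var_labels = var_labels or {}
    for arc in layout.var_arcs:
        prims.append(Arc(arc.center[0], arc.center[1], arc.radius,
                         arc.theta_start, arc.theta_end))
        text = arc.label or var_labels.get(tuple(arc.cols), "")
        if text:
            mid_theta = 0.5 * (arc.theta_start + arc.theta_end)
            lx = arc.center[0] + (arc.radius + 0.9 * d_nt) * math.cos(mid_theta)
            ly = arc.center[1] + (arc.radius + 0.9 * d_nt) * math.sin(mid_theta)
            prims.append(Label(lx, ly, text, size=0.55))

    # glyphs
    for col in range(layout.n_cols):
        if not layout.placed(col) or col in layout.hidden:
            continue
        glyph = _glyph_for(col, annotation.columns[col], sequence, style, layout.xy[col])
        if glyph is not None:
            prims.append(glyph)

    # pseudoknots
    panel_count = 0
    for pk in pk_layouts:
        if pk.style == "inline":
            for l, r in pk.rungs:
                a, b = layout.xy[l], layout.xy[r]
                prims.append(
                    Line(a[0], a[1], b[0], b[1], color=style.rung_color, dashed=True)
                )
        elif pk.panel is not None:
            panel_prims: list = []
            for l, r in pk.rungs:
                a, b = pk.panel.xy[l], pk.panel.xy[r]
                klass = annotation.pair_classes.get((l, r))
                if klass is not None and klass is not PairClass.UNSHADED:
                    panel_prims.append(
                        ShadedBox(
                            corners=_pair_shade_box(a, b, 0.30 * d_nt),
                            fill=style.pair_shades[klass.value],
                        )
                    )
                panel_prims.append(Line(a[0], a[1], b[0], b[1], color=style.rung_color))
                for col, pos in ((l, a), (r, b)):
                    glyph = _glyph_for(col, annotation.columns[col], sequence, style, pos)
                    if glyph is not None:
                        panel_prims.append(glyph)
            offset = _panel_offset(layout, panel_count)
            panel_count += 1
            prims.append(SubPanel(offset=offset, primitives=panel_prims, title=pk.label))
            if pk.connector_anchor is not None:
                prims.append(
                    Line(
                        pk.connector_anchor[0],
                        pk.connector_anchor[1],
                        offset[0],
                        offset[1],
                        color="#a0a0a0",
                        width=0.05,
                        dashed=True,
                    )
                )
                prims.append(
                    Label(
                        0.5 * (pk.connector_anchor[0] + offset[0]),
                        0.5 * (pk.connector_anchor[1] + offset[1]) + 0.5 * d_nt,
                        pk.label,
                        size=0.6,
                    )
                )

    # modular-structure sub-panels, labelled with percent frequency
    for name, sub, freq in modular_panels:
        offset = _panel_offset(layout, panel_count)
        panel_count += 1
        title = style.freq_label_format.format(percent=f"{round(freq * 100):d}%")
        prims.append(SubPanel(offset=offset, primitives=list(sub.primitives), title=""))
        prims.append(Label(offset[0], offset[1] + 1.2 * d_nt, f"{name} {title}", size=0.6))

    return Drawing(primitives=prims, style=style, scale=scale)


def _panel_offset(layout: LayoutResult, ordinal: int) -> tuple[float, float]:
    """Stack sub-panels to the right of the main drawing, top to bottom."""
    cols = layout.placed_columns()
    if cols:
        xmax = float(np.nanmax(layout.xy[cols, 0]))
        ymax = float(np.nanmax(layout.xy[cols, 1]))
    else:
        xmax = ymax = 0.0
    return (xmax + 4.0, ymax - 4.0 * ordinal)


# ---------------------------------------------------------------------------
# SVG serialization


def _fmt(v: float) -> str:
    if not math.isfinite(v):
        raise RenderError("non-finite coordinate in drawing")
    return f"{v:.3f}"


def _emit(parent: ET.Element, prim, style: StyleMap, scale: float) -> None:
    """Append one primitive; coordinates flipped to SVG's y-down."""

    def X(x: float) -> str:
        return _fmt(x * scale)

    def Y(y: float) -> str:
        return _fmt(-y * scale)

    if isinstance(prim, ShadedBox):
        pts = " ".join(f"{X(x)},{Y(y)}" for x, y in prim.corners)
        ET.SubElement(parent, "polygon", points=pts, fill=prim.fill, stroke="none")
    elif isinstance(prim, Line):
        attrs = {
            "x1": X(prim.x1), "y1": Y(prim.y1),
            "x2": X(prim.x2), "y2": Y(prim.y2),
            "stroke": prim.color,
            "stroke-width": _fmt(prim.width * scale),
        }
        if prim.dashed:
            attrs["stroke-dasharray"] = f"{_fmt(0.2 * scale)},{_fmt(0.15 * scale)}"
        ET.SubElement(parent, "line", **attrs)
    elif isinstance(prim, Path):
        d = "M " + " L ".join(f"{X(x)} {Y(y)}" for x, y in prim.points)
        ET.SubElement(
            parent, "path", d=d, fill="none", stroke=prim.color,
            **{"stroke-width": _fmt(prim.width * scale), "stroke-linecap": "round"},
        )
    elif isinstance(prim, Arc):
        # clockwise in internal y-up coordinates = sweep flag 1 after y-flip
        sweep = prim.theta_start - prim.theta_end
        large = "1" if abs(sweep) > math.pi else "0"
        x1 = prim.cx + prim.r * math.cos(prim.theta_start)
        y1 = prim.cy + prim.r * math.sin(prim.theta_start)
        x2 = prim.cx + prim.r * math.cos(prim.theta_end)
        y2 = prim.cy + prim.r * math.sin(prim.theta_end)
        d = (
            f"M {X(x1)} {Y(y1)} "
            f"A {_fmt(prim.r * scale)} {_fmt(prim.r * scale)} 0 {large} "
            f"{'1' if sweep > 0 else '0'} {X(x2)} {Y(y2)}"
        )
        attrs = {"stroke-width": _fmt(prim.width * scale)}
        if prim.dashed:
            attrs["stroke-dasharray"] = f"{_fmt(0.2 * scale)},{_fmt(0.15 * scale)}"
        ET.SubElement(parent, "path", d=d, fill="none", stroke=prim.color, **attrs)
    elif isinstance(prim, Glyph):
        if prim.char:
            ET.SubElement(
                parent,
                "text",
                x=X(prim.x),
                y=Y(prim.y),
                fill=prim.color,
                **{
                    "font-family": style.font_family,
                    "font-size": _fmt(0.9 * scale),
                    "text-anchor": "middle",
                    "dominant-baseline": "central",
                },
            ).text = prim.char
        else:
            attrs = {
                "cx": X(prim.x), "cy": Y(prim.y),
                "r": _fmt(0.35 * scale),
                "fill": "none",
                "stroke": prim.color,
                "stroke-width": _fmt(prim.ring_width * scale),
            }
            if prim.ring_dash:
                attrs["stroke-dasharray"] = prim.ring_dash
            ET.SubElement(parent, "circle", **attrs)
    elif isinstance(prim, Label):
        ET.SubElement(
            parent,
            "text",
            x=X(prim.x),
            y=Y(prim.y),
            fill=prim.color,
            **{
                "font-family": style.font_family,
                "font-size": _fmt(prim.size * scale),
                "text-anchor": prim.anchor,
                "dominant-baseline": "central",
            },
        ).text = prim.text
    elif isinstance(prim, SubPanel):
        group = ET.SubElement(
            parent,
            "g",
            transform=f"translate({_fmt(prim.offset[0] * scale)},"
            f"{_fmt(-prim.offset[1] * scale)})",
        )
        for sub in prim.primitives:
            _emit(group, sub, style, scale)
    else:  # pragma: no cover
        raise RenderError(f"unknown primitive {type(prim).__name__}")


def _bbox(prim, scale: float, acc: list) -> None:
    if isinstance(prim, ShadedBox):
        for x, y in prim.corners:
            acc.append((x * scale, -y * scale))
    elif isinstance(prim, Line):
        acc.extend([(prim.x1 * scale, -prim.y1 * scale), (prim.x2 * scale, -prim.y2 * scale)])
    elif isinstance(prim, Path):
        acc.extend((x * scale, -y * scale) for x, y in prim.points)
    elif isinstance(prim, Arc):
        acc.extend(
            (
                (prim.cx - prim.r) * scale, -(prim.cy - prim.r) * scale,
            ),
        )
        acc.append(((prim.cx + prim.r) * scale, -(prim.cy + prim.r) * scale))
    elif isinstance(prim, (Glyph, Label)):
        acc.append((prim.x * scale, -prim.y * scale))
    elif isinstance(prim, SubPanel):
        sub_acc: list = []
        for p in prim.primitives:
            _bbox(p, scale, sub_acc)
        ox, oy = prim.offset[0] * scale, -prim.offset[1] * scale
        acc.extend((x + ox, y + oy) for x, y in sub_acc)


def to_svg(drawing: Drawing) -> str:
    """Serialize a :class:`Drawing` to an SVG 1.1 document string."""
    scale = drawing.scale
    root = ET.Element(
        "svg", xmlns="http://www.w3.org/2000/svg", version="1.1"
    )
    group = ET.SubElement(root, "g")
    for prim in drawing.primitives:
        _emit(group, prim, drawing.style, scale)

    pts: list[tuple[float, float]] = []
    for prim in drawing.primitives:
        _bbox(prim, scale, pts)
    margin = 2.0 * scale
    if pts:
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        x0, y0 = min(xs) - margin, min(ys) - margin
        w = max(xs) - min(xs) + 2 * margin
        h = max(ys) - min(ys) + 2 * margin
    else:
        x0 = y0 = 0.0
        w = h = 2 * margin
    root.set("viewBox", f"{_fmt(x0)} {_fmt(y0)} {_fmt(w)} {_fmt(h)}")
    root.set("width", _fmt(w))
    root.set("height", _fmt(h))
    return ET.tostring(root, encoding="unicode")
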