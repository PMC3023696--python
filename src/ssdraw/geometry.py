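"""Constant-spacing planar layout of an RNA secondary structure.

Every consecutive pair of backbone positions is exactly ``d_nt`` apart and
every base pair spans exactly ``d_bp``; the two distances need not be
equal.  Stems are drawn as parallel ladders.  Loop nucleotides sit on a
common circle whose radius is found by binary search: for a radius ``r``
each chord ``d`` subtends ``2·arcsin(d/(2r))`` (the apex angle of the
isosceles triangle with sides ``r, r, d``), the angle sum is monotone
decreasing in ``r``, and the solver bisects until the sum hits the
requested total (360° for a closed loop, 180° for one side of a bulge or
internal loop).

Coordinates are y-up mathematical; the SVG renderer flips the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .stockholm_io import PairList


class LayoutError(ValueError):
    pass


class InfeasibleRadius(LayoutError):
    """A chord cannot fit on a circle of the proposed radius."""


@dataclass(frozen=True)
class LayoutParams:
    """Backbone spacing ``d_nt`` and pair span ``d_bp``, internal units."""

    d_nt: float = 1.0
    d_bp: float = 1.6

    def __post_init__(self) -> None:
        if self.d_nt <= 0 or self.d_bp <= 0:
            raise ValueError("spacings must be positive")


# ---------------------------------------------------------------------------
# structure tree


@dataclass
class Segment:
    """A run of unpaired columns inside a junction (possibly empty)."""

    cols: tuple[int, ...]


@dataclass
class Stem:
    """A maximal run of stacked pairs; ``pairs[0]`` is the outermost."""

    pairs: tuple[tuple[int, int], ...]
    inner: "Junction"

    @property
    def columns(self) -> set[int]:
        return {c for p in self.pairs for c in p}


@dataclass
class Junction:
    """Alternating unpaired segments and stems closed by ``closing``.

    ``elements`` always starts and ends with a :class:`Segment` (possibly
    empty) and alternates Segment, Stem, Segment, ...  ``closing`` is the
    innermost pair of the enclosing stem, or ``None`` at the root.
    A terminal loop is a junction with no stems; an internal loop/bulge has
    one stem; a multistem junction has two or more.
    """

    elements: list[Segment | Stem]
    closing: tuple[int, int] | None = None

    @property
    def stems(self) -> list[Stem]:
        return [e for e in self.elements if isinstance(e, Stem)]

    @property
    def segments(self) -> list[Segment]:
        return [e for e in self.elements if isinstance(e, Segment)]

    @property
    def loop_columns(self) -> set[int]:
        out = {c for s in self.segments for c in s.cols}
        if self.closing:
            out.update(self.closing)
        return out


@dataclass
class StructureTree:
    root: Junction
    n_cols: int

    def walk_junctions(self) -> Iterator[Junction]:
        stack = [self.root]
        while stack:
            junc = stack.pop()
            yield junc
            for stem in junc.stems:
                stack.append(stem.inner)


def build_structure_tree(pairs: PairList, n_cols: int) -> StructureTree:
    """Decompose nested pairs into stems, loops and junctions.

    Stems are maximal runs of stacked pairs.  Crossing pairs are rejected
    by :class:`~ssdraw.stockholm_io.PairList` itself; pseudoknots must come
    in on separate bracket lines.
    """
    partner: dict[int, int] = {}
    for left, right in pairs:
        partner[left] = right
        partner[right] = left

    def build(start: int, stop: int, closing: tuple[int, int] | None) -> Junction:
        elements: list[Segment | Stem] = []
        run: list[int] = []
        i = start
        while i < stop:
            j = partner.get(i)
            if j is None or j < i:
                if j is not None and j < start:
                    raise LayoutError(f"crossing pair at column {i}")
                run.append(i)
                i += 1
                continue
            elements.append(Segment(tuple(run)))
            run = []
            stacked = [(i, j)]
            while partner.get(stacked[-1][0] + 1) == stacked[-1][1] - 1:
                stacked.append((stacked[-1][0] + 1, stacked[-1][1] - 1))
            li, ri = stacked[-1]
            inner = build(li + 1, ri, (li, ri))
            elements.append(Stem(tuple(stacked), inner))
            i = stacked[0][1] + 1
        elements.append(Segment(tuple(run)))
        return Junction(elements, closing)

    return StructureTree(build(0, n_cols, None), n_cols)


# ---------------------------------------------------------------------------
# circle fitting


@dataclass(frozen=True)
class CircleFit:
    """A common circle for one loop: center, radius, per-chord angles."""

    center: tuple[float, float]
    radius: float
    angles: tuple[float, ...]

    @property
    def angle_sum(self) -> float:
        return float(sum(self.angles))


def step_angle(d: float, r: float) -> float:
    """Angle subtended at the center by a chord of length ``d``.

    Apex angle of the isosceles triangle with sides ``r, r, d``:
    ``2·arcsin(d/(2r))``.  ``d > 2r`` means the chord cannot fit and raises
    :class:`InfeasibleRadius` (this drives the binary search bracket).
    """
    if d <= 0:
        raise ValueError("chord length must be positive")
    ratio = d / (2.0 * r)
    if ratio > 1.0 + 1e-12:
        raise InfeasibleRadius(f"chord {d} exceeds diameter {2 * r}")
    return 2.0 * math.asin(min(ratio, 1.0))


def _angle_sum(chords: Sequence[float], r: float) -> float:
    return sum(step_angle(d, r) for d in chords)


def solve_loop_radius(
    chords: Sequence[float],
    total: float = 2.0 * math.pi,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> CircleFit:
    """Bisect for the radius at which the chord angles sum to ``total``.

    ``total`` is 2π for a closed loop, π for a bulge or one side of an
    internal loop.  At radii below the solution the angle sum exceeds the
    target and above it falls short, so plain bisection converges; the
    lower bracket is ``max(chords)/2`` (largest chord on a diameter) and
    the upper bracket is doubled until the sum drops below ``total``.
    """
    if not chords:
        raise ValueError("need at least one chord")
    if any(d <= 0 for d in chords):
        raise ValueError("chord lengths must be positive")
    lo = max(chords) / 2.0
    s_lo = _angle_sum(chords, lo)
    if s_lo < total - tol:
        raise InfeasibleRadius(
            f"chords cannot span {math.degrees(total):.0f} degrees: "
            f"angle sum at minimum radius is only {math.degrees(s_lo):.1f}"
        )
    if s_lo <= total + tol:
        r = lo
    else:
        hi = lo * 2.0
        while _angle_sum(chords, hi) > total:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - unreachable for valid chords
                raise LayoutError("radius bracket diverged")
        r = lo
        for _ in range(max_iter):
            r = 0.5 * (lo + hi)
            s = _angle_sum(chords, r)
            if abs(s - total) < tol:
                break
            if s > total:
                lo = r
            else:
                hi = r
    return CircleFit(
        center=(0.0, 0.0),
        radius=r,
        angles=tuple(step_angle(d, r) for d in chords),
    )


# ---------------------------------------------------------------------------
# layout result


@dataclass
class VarArc:
    """Geometry of a variable-length region drawn as a dashed arc."""

    cols: tuple[int, int]  # half-open column range
    start: tuple[float, float]
    end: tuple[float, float]
    center: tuple[float, float]
    radius: float
    theta_start: float
    theta_end: float  # traversal is clockwise: theta_end < theta_start
    label: str = ""


@dataclass
class LayoutResult:
    """Per-column 2-D coordinates (internal units) plus arc geometry.

    ``xy[col]`` is NaN for columns that are not drawn (hidden inside a
    variable-length region, or all-gap columns removed by annotation).
    ``breaks`` holds column indices ``i`` whose bond to ``i+1`` is not a
    plain backbone bond of length ``d_nt`` (e.g. spans a variable arc).
    """

    n_cols: int
    params: LayoutParams
    xy: np.ndarray = field(default=None)  # type: ignore[assignment]
    hidden: set[int] = field(default_factory=set)
    breaks: set[int] = field(default_factory=set)
    var_arcs: list[VarArc] = field(default_factory=list)
    circles: list[CircleFit] = field(default_factory=list)
    stem_rungs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.xy is None:
            self.xy = np.full((self.n_cols, 2), np.nan)

    def place(self, col: int, pos: tuple[float, float]) -> None:
        self.xy[col] = pos

    def placed(self, col: int) -> bool:
        return bool(np.isfinite(self.xy[col]).all())

    def placed_columns(self) -> list[int]:
        return [c for c in range(self.n_cols) if self.placed(c)]

    def directions(self) -> np.ndarray:
        """Backbone direction angle (radians) per placed column."""
        ang = np.full(self.n_cols, np.nan)
        cols = self.placed_columns()
        for a, b in zip(cols, cols[1:]):
            if b == a + 1 and a not in self.breaks:
                delta = self.xy[b] - self.xy[a]
                ang[a] = math.atan2(delta[1], delta[0])
        # trailing columns inherit the previous direction
        last = np.nan
        for c in cols:
            if np.isnan(ang[c]):
                ang[c] = last
            else:
                last = ang[c]
        return ang

    def consecutive_spacings(self) -> list[tuple[int, float]]:
        """(col, distance) for every plain backbone bond col → col+1."""
        out = []
        for c in range(self.n_cols - 1):
            if c in self.breaks or c in self.hidden or (c + 1) in self.hidden:
                continue
            if self.placed(c) and self.placed(c + 1):
                out.append((c, float(np.linalg.norm(self.xy[c + 1] - self.xy[c]))))
        return out

    def overlap_violations(self, min_sep: float | None = None) -> list[tuple[int, int, float]]:
        """Glyph-center pairs closer than ``min_sep`` (default 0.8·d_nt)."""
        if min_sep is None:
            min_sep = 0.8 * self.params.d_nt
        cols = self.placed_columns()
        pts = self.xy[cols]
        out = []
        for i in range(len(cols)):
            d = np.linalg.norm(pts[i + 1 :] - pts[i], axis=1)
            for k in np.nonzero(d < min_sep - 1e-9)[0]:
                out.append((cols[i], cols[i + 1 + int(k)], float(d[k])))
        return out

    def to_tsv(self) -> str:
        """Debug dump: column, x, y, backbone direction (degrees)."""
        dirs = self.directions()
        lines = ["col\tx\ty\tdir_deg"]
        for c in self.placed_columns():
            lines.append(
                f"{c}\t{self.xy[c, 0]:.6f}\t{self.xy[c, 1]:.6f}"
                f"\t{math.degrees(dirs[c]):.3f}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# helpers


def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _rot_cw(v: np.ndarray) -> np.ndarray:
    """Rotate a vector by -90 degrees."""
    return np.array([v[1], -v[0]])


def pair_rung_direction(stem_direction: float) -> np.ndarray:
    """Unit vector from a pair's 5' to its 3' nucleotide.

    The convention throughout: looking along the stem's propagation
    direction, the 3' partner sits 90° clockwise of the 5' strand, which
    makes every junction walk run clockwise.
    """
    return _rot_cw(_unit(stem_direction))


# ---------------------------------------------------------------------------
# directives consumed by the layout (built by ssdraw.commands)


@dataclass
class JunctionDirective:
    """User control for one multistem junction (solved as an NLP)."""

    anchor_col: int
    stem_dirs_deg: list[float]
    formulation: int = 2
    aligns: list[tuple[list[int], float]] = field(default_factory=list)
    align_centroids: list[tuple[list[int], int, float]] = field(default_factory=list)


@dataclass
class LayoutDirectives:
    """Pre-resolved layout commands (label references already columns)."""

    junctions: list[JunctionDirective] = field(default_factory=list)
    var_regions: list[tuple[int, int]] = field(default_factory=list)
    turns: dict[int, float] = field(default_factory=dict)

    def junction_for(self, junc: Junction) -> JunctionDirective | None:
        loop_cols = junc.loop_columns
        for jd in self.junctions:
            if jd.anchor_col in loop_cols:
                return jd
        return None


VAR_ARC_SPAN = 3  # backbone-length equivalents spanned by a fixed var arc


# ---------------------------------------------------------------------------
# main layout


def layout_structure(
    tree: StructureTree,
    params: LayoutParams = LayoutParams(),
    directives: LayoutDirectives | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    direction_deg: float = 0.0,
) -> LayoutResult:
    """Place every column of the structure in the plane.

    Depth-first: the 5'→3' backbone runs along a baseline from ``origin``
    in direction ``direction_deg``; stems rise perpendicular to the local
    baseline; each stem's inner loop is laid on a bisected circle or, when
    a junction directive applies, by the constrained junction solver.
    """
    directives = directives or LayoutDirectives()
    res = LayoutResult(n_cols=tree.n_cols, params=params)
    var_lookup: dict[int, tuple[int, int]] = {}
    for start, stop in directives.var_regions:
        for c in range(start, stop):
            var_lookup[c] = (start, stop)
            res.hidden.add(c)

    d_nt, d_bp = params.d_nt, params.d_bp

    def seg_items(seg: Segment) -> list[tuple[str, object]]:
        """Collapse var-region columns into single 'var' items."""
        items: list[tuple[str, object]] = []
        seen_regions: set[tuple[int, int]] = set()
        for col in seg.cols:
            region = var_lookup.get(col)
            if region is None:
                items.append(("nt", col))
            elif region not in seen_regions:
                seen_regions.add(region)
                items.append(("var", region))
        return items

    def place_baseline(junc: Junction, start: np.ndarray, dir_rad: float) -> None:
        pos: np.ndarray | None = None
        prev_col: int | None = None
        for elem in junc.elements:
            if isinstance(elem, Segment):
                for kind, payload in seg_items(elem):
                    if kind == "nt":
                        col = payload  # type: ignore[assignment]
                        if col in directives.turns:
                            dir_rad = math.radians(directives.turns[col])
                        pos = (
                            start.copy()
                            if pos is None
                            else pos + d_nt * _unit(dir_rad)
                        )
                        res.place(col, tuple(pos))
                        prev_col = col
                    else:
                        region = payload  # type: ignore[assignment]
                        a = (start.copy() if pos is None else pos + d_nt * _unit(dir_rad))
                        span = VAR_ARC_SPAN * d_nt
                        b = a + span * _unit(dir_rad)
                        mid = 0.5 * (a + b)
                        sag_center = mid + 0.5 * d_nt * _rot_cw(_unit(dir_rad))
                        radius = math.hypot(span / 2.0, 0.5 * d_nt)
                        res.var_arcs.append(
                            VarArc(
                                cols=region,
                                start=tuple(a),
                                end=tuple(b),
                                center=tuple(sag_center),
                                radius=radius,
                                theta_start=math.atan2(*(a - sag_center)[::-1]),
                                theta_end=math.atan2(*(b - sag_center)[::-1]),
                            )
                        )
                        pos = b
                        if prev_col is not None:
                            res.breaks.add(prev_col)
                        res.breaks.add(max(region) - 1)
                        prev_col = None
            else:  # Stem rising from the baseline
                p5 = start.copy() if pos is None else pos + d_nt * _unit(dir_rad)
                stem_dir = dir_rad + math.pi / 2.0
                p3 = p5 + d_bp * pair_rung_direction(stem_dir)
                place_stem(elem, p5, p3, stem_dir)
                pos = p3
                prev_col = elem.pairs[0][1]
        # no closing pair at the root

    def place_stem(stem: Stem, p5: np.ndarray, p3: np.ndarray, dir_rad: float) -> None:
        u = _unit(dir_rad)
        for k, (l, r) in enumerate(stem.pairs):
            res.place(l, tuple(p5 + k * d_nt * u))
            res.place(r, tuple(p3 + k * d_nt * u))
            res.stem_rungs.append((l, r))
        li, ri = stem.pairs[-1]
        place_junction(stem.inner, res.xy[li].copy(), res.xy[ri].copy(), dir_rad)

    def place_junction(
        junc: Junction, q5: np.ndarray, q3: np.ndarray, dir_rad: float
    ) -> None:
        jd = directives.junction_for(junc)
        if jd is not None and len(junc.stems) >= 2:
            place_junction_nlp(junc, q5, q3, dir_rad, jd)
            return
        # plain circular layout: every loop participant on one circle
        items: list[tuple[str, object]] = []
        for elem in junc.elements:
            if isinstance(elem, Segment):
                items.extend(seg_items(elem))
            else:
                items.append(("stem", elem))
        if not items:
            if junc.closing:
                res.breaks.add(junc.closing[0])
            return
        chords: list[float] = []
        for kind, _ in items:
            if kind == "nt":
                chords.append(d_nt)
            elif kind == "var":
                chords.extend([d_nt] * VAR_ARC_SPAN)
            else:
                chords.append(d_nt)  # entry bond to the stem's 5' nt
                chords.append(d_bp)  # the stem's base-pair chord
        chords.append(d_nt)  # bond back to the closing 3' nt
        chords.append(d_bp)  # the closing pair chord
        fit = solve_loop_radius(chords, 2.0 * math.pi)
        r = fit.radius
        h = math.sqrt(max(r * r - (d_bp / 2.0) ** 2, 0.0))
        center = 0.5 * (q5 + q3) + h * _unit(dir_rad)
        res.circles.append(replace(fit, center=tuple(center)))
        theta = math.atan2(*(q5 - center)[::-1])

        def advance(chord: float) -> np.ndarray:
            nonlocal theta
            theta -= step_angle(chord, r)
            return center + r * _unit(theta)

        prev_col = junc.closing[0] if junc.closing else None
        for kind, payload in items:
            if kind == "nt":
                col = payload  # type: ignore[assignment]
                res.place(col, tuple(advance(d_nt)))
                prev_col = col
            elif kind == "var":
                region = payload  # type: ignore[assignment]
                a = advance(d_nt)
                t0 = theta
                for _ in range(VAR_ARC_SPAN - 1):
                    advance(d_nt)
                b = center + r * _unit(theta)
                res.var_arcs.append(
                    VarArc(
                        cols=region,
                        start=tuple(a),
                        end=tuple(b),
                        center=tuple(center),
                        radius=r,
                        theta_start=t0,
                        theta_end=theta,
                    )
                )
                if prev_col is not None:
                    res.breaks.add(prev_col)
                res.breaks.add(max(region) - 1)
                prev_col = None
            else:
                stem = payload  # type: ignore[assignment]
                s5 = advance(d_nt)
                s3 = advance(d_bp)
                mid = 0.5 * (s5 + s3)
                out = mid - center
                out_dir = math.atan2(out[1], out[0])
                place_stem(stem, s5, s3, out_dir)
                prev_col = stem.pairs[0][1]

    def place_junction_nlp(
        junc: Junction,
        q5: np.ndarray,
        q3: np.ndarray,
        dir_rad: float,
        jd: JunctionDirective,
    ) -> None:
        from . import junction_solver as js

        spec = js.junction_spec_from_tree(
            junc, q5, q3, dir_rad, jd, params, seg_items
        )
        problem = {
            1: js.formulation1,
            2: js.formulation2,
            3: js.formulation3,
        }[jd.formulation](spec)
        problem = js.add_alignment_constraints(problem, spec)
        sol = js.solve(problem)
        for col, pos in sol.nt_positions.items():
            res.place(col, tuple(pos))
        for arc in sol.var_arcs:
            res.var_arcs.append(arc)
            if arc.cols:
                res.breaks.add(arc.cols[0] - 1)
                res.breaks.add(arc.cols[1] - 1)
        for stem, (s5, s3, out_dir) in zip(junc.stems, sol.stem_anchors):
            place_stem(stem, np.asarray(s5), np.asarray(s3), out_dir)
            res.breaks.discard(stem.pairs[0][1])
        res.circles.append(
            CircleFit(center=tuple(sol.center), radius=sol.radius, angles=())
        )

    place_baseline(tree.root, np.asarray(origin, dtype=float), math.radians(direction_deg))
    return res


# ---------------------------------------------------------------------------
# pseudoknots


class InlineInfeasible(LayoutError):
    """In-line pseudoknot drawing would overlap; use the callout style."""


@dataclass
class PseudoknotLayout:
    """Additions for one pseudoknot: rungs in-line, or a callout panel."""

    name: str
    style: str  # "inline" | "callout"
    rungs: list[tuple[int, int]] = field(default_factory=list)
    panel: LayoutResult | None = None
    connector_anchor: tuple[float, float] | None = None
    label: str = "pseudoknot"


def layout_pseudoknot(
    layout: LayoutResult,
    pk_pairs: PairList,
    style: str = "callout",
    params: LayoutParams | None = None,
    name: str = "pk",
) -> PseudoknotLayout:
    """Lay out one pseudoknot's pairings against an existing main layout.

    ``inline`` draws pair rungs between the partners where the main layout
    already put them; it is judged infeasible (error suggesting the
    callout) when partners are too far apart to connect cleanly.
    ``callout`` builds a small separate duplex panel, to be joined to the
    main drawing with a connector line labelled "pseudoknot".
    """
    if style not in {"inline", "callout"}:
        raise ValueError(f"unknown pseudoknot style {style!r}")
    params = params or layout.params
    pairs = list(pk_pairs)
    if not pairs:
        return PseudoknotLayout(name=name, style=style)
    if style == "inline":
        max_span = 2.5 * params.d_bp
        for l, r in pairs:
            if not (layout.placed(l) and layout.placed(r)):
                raise InlineInfeasible(
                    f"pseudoknot column {l if not layout.placed(l) else r} "
                    "is not drawn; try the callout style"
                )
            span = float(np.linalg.norm(layout.xy[r] - layout.xy[l]))
            if span > max_span:
                raise InlineInfeasible(
                    f"pseudoknot pair ({l},{r}) spans {span:.2f} units in the "
                    "main layout; in-line rungs would cross the drawing — "
                    "try the callout style"
                )
        return PseudoknotLayout(name=name, style="inline", rungs=pairs)
    # callout: a plain ladder panel of the pseudoknot duplex
    panel = LayoutResult(n_cols=layout.n_cols, params=params)
    for k, (l, r) in enumerate(pairs):
        panel.place(l, (k * params.d_nt, 0.0))
        panel.place(r, (k * params.d_nt, -params.d_bp))
        panel.stem_rungs.append((l, r))
    anchor_col = pairs[0][0]
    anchor = tuple(layout.xy[anchor_col]) if layout.placed(anchor_col) else None
    return PseudoknotLayout(
        name=name,
        style="callout",
        rungs=pairs,
        panel=panel,
        connector_anchor=anchor,
    )
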