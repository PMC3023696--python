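"""Multistem-junction layout as a constrained non-linear program.

A junction's unpaired nucleotides should approximately follow a circle
while every stem on the junction points in a direction fixed by the user
(fixing directions up front avoids a much harder global optimization).
Three formulations express "approximately a circle":

1. Unpaired nucleotides are constrained to lie exactly on a common circle
   whose radius is a variable; paired nucleotides are off-circle but the
   line connecting the two nucleotides of each pair must intersect the
   circle, at a point given by an intersection parameter in [0, 1] (0 at
   the 5' nucleotide, 1 at the 3').  Walking clockwise around the
   junction, the angles swept at the center between consecutive
   nucleotides must total 360°.  The objective penalizes sudden changes
   of radius: each base-paired nucleotide n with backbone neighbor a
   contributes (d_n - d_a)^2, the d's being distances to the center.
2. Nothing is constrained to the main circle.  The free variables are the
   main circle (center, radius) and the 5'-nucleotide position of each
   stem (a single bond angle when two paired nucleotides are consecutive).
   Each run of unpaired nucleotides lies on its own circle, fully
   determined by its flanking paired positions and the constant backbone
   spacing.  The objective sums (d_pc - r)^2 over N+2+3V sample points per
   run (N unpaired nucleotides, 2 flanks, 3 per variable-length region).
3. Same geometry as 2, but the objective targets slope deviations: at
   each sample point it compares the direction to the main center with
   the direction to the run's own center, summing (cos θ - 1)^2.

Variable-length regions are drawn as arcs and their lengths (in backbone
units) are additional variables in every formulation.  Alignment
constraints (equal scalar projection onto the normal of an arbitrary
axis, optionally of centroids) can be attached to any formulation.

The problems are solved with a sequential-quadratic-programming solver
(scipy's SLSQP) using finite-difference gradients, warm-started from the
plain circular layout that ignores stem directions, with a fixed list of
perturbed restarts to escape local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    InfeasibleRadius,
    Junction,
    JunctionDirective,
    LayoutParams,
    Segment,
    VarArc,
    pair_rung_direction,
    solve_loop_radius,
    step_angle,
)

TWO_PI = 2.0 * math.pi
FEAS_TOL = 1e-6
PENALTY = 1e6
VAR_LEN_BOUNDS = (0.5, 10.0)  # backbone-unit equivalents per region
DEFAULT_VAR_LEN = 3.0


class JunctionError(RuntimeError):
    pass


class JunctionInfeasible(JunctionError):
    """No feasible junction layout found; try another formulation."""


@dataclass
class StemSpec:
    """One stem on the junction: its user-fixed outward direction."""

    direction: float  # radians


@dataclass
class JunctionSpec:
    """Geometry of one junction plus its user constraints.

    ``segments`` has ``len(stems) + 1`` entries; entry ``i`` is the run of
    items between pair ``i`` and pair ``i+1`` (pair 0 is the enclosing
    pair, fixed in the plane at ``q5``/``q3``).  Items are ``("nt", col)``
    or ``("var", (start, stop))``.
    """

    q5: np.ndarray
    q3: np.ndarray
    enclosing_dir: float  # radians, pointing into the junction
    stems: list[StemSpec]
    segments: list[list[tuple]]
    d_nt: float = 1.0
    d_bp: float = 1.6
    aligns: list[tuple[list[int], float]] = field(default_factory=list)
    align_centroids: list[tuple[list[int], int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.q5 = np.asarray(self.q5, dtype=float)
        self.q3 = np.asarray(self.q3, dtype=float)
        if len(self.segments) != len(self.stems) + 1:
            raise ValueError("need one segment per gap between pairs")
        if len(self.stems) + 1 < 2:
            raise ValueError("a multistem junction needs at least 2 stems")

    @property
    def n_pairs(self) -> int:
        return 1 + len(self.stems)

    @property
    def var_regions(self) -> list[tuple[int, tuple[int, int]]]:
        """(segment index, column range) per variable-length region."""
        out = []
        for i, seg in enumerate(self.segments):
            for kind, payload in seg:
                if kind == "var":
                    out.append((i, payload))
        return out

    def rung(self, pair_index: int) -> np.ndarray:
        """Unit vector 5'→3' across pair ``pair_index`` (0 = enclosing)."""
        if pair_index == 0:
            return (self.q3 - self.q5) / self.d_bp
        return pair_rung_direction(self.stems[pair_index - 1].direction)


@dataclass
class JunctionSolution:
    nt_positions: dict[int, np.ndarray]
    stem_anchors: list[tuple[np.ndarray, np.ndarray, float]]  # (q5, q3, out dir)
    var_arcs: list[VarArc]
    center: np.ndarray
    radius: float
    objective: float
    max_violation: float
    swept_deg: float


@dataclass
class NLPProblem:
    """A constrained NLP plus the decoder back to junction geometry."""

    spec: JunctionSpec
    x0: np.ndarray
    bounds: list[tuple[float, float]]
    objective: Callable[[np.ndarray], float]
    eq_constraints: list[Callable[[np.ndarray], np.ndarray]]
    decode: Callable[[np.ndarray], JunctionSolution]
    anchor_points: Callable[[np.ndarray], list[np.ndarray]]
    extra_starts: list[np.ndarray] = field(default_factory=list)
    #: formulation-2/3 only: objective sample points at a given x
    sample_points: Callable[[np.ndarray], list[np.ndarray]] | None = None

    @property
    def n_vars(self) -> int:
        return len(self.x0)

    def eq_all(self, x: np.ndarray) -> np.ndarray:
        if not self.eq_constraints:
            return np.zeros(0)
        return np.concatenate([np.atleast_1d(f(x)) for f in self.eq_constraints])


# ---------------------------------------------------------------------------
# shared geometry helpers


def _angle(v: np.ndarray) -> float:
    return math.atan2(v[1], v[0])


def _unit(a: float) -> np.ndarray:
    return np.array([math.cos(a), math.sin(a)])


def _cw_delta(a_from: float, a_to: float) -> float:
    """Clockwise angle from ``a_from`` to ``a_to``, wrapped to (-pi, pi]."""
    d = (a_from - a_to) % TWO_PI
    if d > math.pi:
        d -= TWO_PI
    return d


def _circle_circle_cw(
    center: np.ndarray, r: float, p: np.ndarray, d: float, ref: np.ndarray
) -> np.ndarray | None:
    """Intersection of Circle(center, r) with Circle(p, d), advancing
    clockwise (as seen from ``center``) past the reference point ``ref``.
    Returns ``None`` when the circles do not intersect."""
    e = p - center
    L = float(np.hypot(e[0], e[1]))
    if L < 1e-12:
        return None
    a = (L * L + r * r - d * d) / (2.0 * L)
    h2 = r * r - a * a
    if h2 < 0:
        return None
    h = math.sqrt(h2)
    eu = e / L
    base = center + a * eu
    off = h * np.array([-eu[1], eu[0]])
    c1, c2 = base + off, base - off
    ref_ang = _angle(ref - center)
    d1 = (ref_ang - _angle(c1 - center)) % TWO_PI
    d2 = (ref_ang - _angle(c2 - center)) % TWO_PI
    return c1 if d1 <= d2 else c2


def _warm_circle(spec: JunctionSpec):
    """Plain circular layout ignoring stem directions; the warm start.

    Returns (center, radius, entry/exit points per pair, swept walk info).
    """
    d_nt, d_bp = spec.d_nt, spec.d_bp
    chords: list[float] = []
    for i, seg in enumerate(spec.segments):
        for kind, _ in seg:
            if kind == "nt":
                chords.append(d_nt)
            else:
                chords.extend([d_nt] * (1 + int(DEFAULT_VAR_LEN)))
        if i < len(spec.stems):
            chords.append(d_nt)
            chords.append(d_bp)
    chords.append(d_nt)
    chords.append(d_bp)
    fit = solve_loop_radius(chords, TWO_PI)
    r = fit.radius
    h = math.sqrt(max(r * r - (d_bp / 2.0) ** 2, 0.0))
    center = 0.5 * (spec.q5 + spec.q3) + h * _unit(spec.enclosing_dir)
    # walk to collect child-pair anchor estimates
    theta = _angle(spec.q5 - center)
    anchors = []
    idx = 0
    for i, seg in enumerate(spec.segments):
        for kind, _ in seg:
            steps = 1 if kind == "nt" else 1 + int(DEFAULT_VAR_LEN)
            for _ in range(steps):
                theta -= step_angle(chords[idx], r)
                idx += 1
        if i < len(spec.stems):
            theta -= step_angle(d_nt, r)
            idx += 1
            s5 = center + r * _unit(theta)
            theta -= step_angle(d_bp, r)
            idx += 1
            s3 = center + r * _unit(theta)
            anchors.append((s5, s3))
    return center, r, anchors


# ---------------------------------------------------------------------------
# formulation 1


def formulation1(spec: JunctionSpec) -> NLPProblem:
    """On-circle formulation: variables (r, start angle, intersection
    parameter per pair, variable-region lengths)."""
    d_nt, d_bp = spec.d_nt, spec.d_bp
    n_pairs = spec.n_pairs
    n_var = len(spec.var_regions)
    c0, r0, _ = _warm_circle(spec)

    def unpack(x):
        r, alpha = x[0], x[1]
        ts = x[2 : 2 + n_pairs]
        lams = x[2 + n_pairs :]
        return r, alpha, ts, lams

    def walk(x):
        """Derive all junction geometry from the variables.

        Returns (cycle, nt_pos, anchors, arcs, center, r) or None when the
        geometry is infeasible.  ``cycle`` is the ordered list of
        (is_paired, pair_role, point) around the junction, starting at the
        enclosing 5' nucleotide and ending at the enclosing 3'.
        """
        r, alpha, ts, lams = unpack(x)
        if r <= max(d_nt, d_bp) / 2.0:
            return None
        ua = _unit(alpha)
        x0pt = spec.q5 + ts[0] * (spec.q3 - spec.q5)
        w = x0pt - spec.q5
        b = float(w @ ua)
        disc = b * b - float(w @ w) + r * r
        if disc < 0:
            return None
        rho = -b + math.sqrt(disc)
        if rho <= 0:
            return None
        center = spec.q5 - rho * ua
        delta_nt = step_angle(d_nt, r)
        cycle: list[tuple[bool, str, np.ndarray]] = [(True, "p5", spec.q5)]
        nt_pos: dict[int, np.ndarray] = {}
        anchors: list[tuple[np.ndarray, np.ndarray, float]] = []
        arcs: list[VarArc] = []
        p = spec.q5
        var_i = 0
        for i, seg in enumerate(spec.segments):
            for kind, payload in seg:
                if kind == "nt":
                    nxt = _circle_circle_cw(center, r, p, d_nt, p)
                    if nxt is None:
                        return None
                    nt_pos[payload] = nxt
                    cycle.append((False, "nt", nxt))
                    p = nxt
                else:
                    start = _circle_circle_cw(center, r, p, d_nt, p)
                    if start is None:
                        return None
                    th0 = _angle(start - center)
                    sweep = lams[var_i] * delta_nt
                    th1 = th0 - sweep
                    end = center + r * _unit(th1)
                    arcs.append(
                        VarArc(
                            cols=payload,
                            start=tuple(start),
                            end=tuple(end),
                            center=tuple(center),
                            radius=r,
                            theta_start=th0,
                            theta_end=th1,
                        )
                    )
                    cycle.append((False, "arc", start))
                    cycle.append((False, "arc", end))
                    p = end
                    var_i += 1
            if i < len(spec.stems):
                j = i + 1
                nj = spec.rung(j)
                target = _circle_circle_cw(center, r, p + ts[j] * d_bp * nj, d_nt, p)
                if target is None:
                    return None
                q5j = target - ts[j] * d_bp * nj
                q3j = q5j + d_bp * nj
                anchors.append((q5j, q3j, spec.stems[i].direction))
                cycle.append((True, "p5", q5j))
                cycle.append((True, "p3", q3j))
                p = q3j
        cycle.append((True, "p3", spec.q3))
        return cycle, nt_pos, anchors, arcs, center, r

    def residuals(x) -> np.ndarray:
        state = walk(x)
        if state is None:
            return np.array([PENALTY, PENALTY])
        cycle, _, _, _, center, r = state
        p_last = cycle[-2][2]
        close = float(np.linalg.norm(cycle[-1][2] - p_last)) - d_nt
        pts = [pt for _, _, pt in cycle] + [cycle[0][2]]
        angs = [_angle(pt - center) for pt in pts]
        swept = sum(_cw_delta(a, b) for a, b in zip(angs, angs[1:]))
        return np.array([close, swept - TWO_PI])

    def objective(x) -> float:
        state = walk(x)
        if state is None:
            return PENALTY
        cycle, _, _, _, center, _ = state
        total = 0.0
        n = len(cycle)
        for k, (is_paired, role, pt) in enumerate(cycle):
            if not is_paired:
                continue
            # backbone neighbor: enclosing 5' looks forward, enclosing 3'
            # backward; child 5' backward, child 3' forward
            if k == 0:
                adj = cycle[1][2]
            elif k == n - 1:
                adj = cycle[n - 2][2]
            elif role == "p5":
                adj = cycle[k - 1][2]
            else:
                adj = cycle[k + 1][2]
            d_n = float(np.linalg.norm(pt - center))
            d_a = float(np.linalg.norm(adj - center))
            total += (d_n - d_a) ** 2
        return total

    def decode(x) -> JunctionSolution:
        state = walk(x)
        if state is None:
            raise JunctionInfeasible("formulation 1 geometry infeasible at point")
        cycle, nt_pos, anchors, arcs, center, r = state
        res = residuals(x)
        pts = [pt for _, _, pt in cycle] + [cycle[0][2]]
        angs = [_angle(pt - center) for pt in pts]
        swept = sum(_cw_delta(a, b) for a, b in zip(angs, angs[1:]))
        return JunctionSolution(
            nt_positions=nt_pos,
            stem_anchors=anchors,
            var_arcs=arcs,
            center=center,
            radius=r,
            objective=objective(x),
            max_violation=float(np.max(np.abs(res))),
            swept_deg=math.degrees(swept),
        )

    def anchor_points(x) -> list[np.ndarray]:
        state = walk(x)
        if state is None:
            return [np.array([PENALTY, PENALTY])] * spec.n_pairs
        _, _, anchors, _, _, _ = state
        pts = [0.5 * (spec.q5 + spec.q3)]
        pts.extend(0.5 * (a + b) for a, b, _ in anchors)
        return pts

    alpha0 = _angle(spec.q5 - c0)
    x0 = np.concatenate(
        [[r0, alpha0], np.full(n_pairs, 0.5), np.full(n_var, DEFAULT_VAR_LEN)]
    )
    bounds = (
        [(max(d_nt, d_bp) / 2.0 + 1e-6, 1e3), (alpha0 - TWO_PI, alpha0 + TWO_PI)]
        + [(0.0, 1.0)] * n_pairs
        + [VAR_LEN_BOUNDS] * n_var
    )
    # corner starts: the whole-pair-on-circle optimum sits at t = 0 or 1
    extra = []
    for t_corner in (0.0, 1.0):
        xc = x0.copy()
        xc[2 : 2 + n_pairs] = t_corner
        extra.append(xc)
    return NLPProblem(
        spec=spec,
        x0=x0,
        bounds=bounds,
        objective=objective,
        eq_constraints=[residuals],
        decode=decode,
        anchor_points=anchor_points,
        extra_starts=extra,
    )


# ---------------------------------------------------------------------------
# formulations 2 and 3


def _segment_circle(E: np.ndarray, N: np.ndarray, m: float, d_nt: float):
    """Circle through flanks E, N carrying ``m`` backbone-unit chords.

    Solves the wrap angle theta from ``d_nt·sin(θ/2)/sin(θ/2m) = |EN|``
    (monotone decreasing in θ), then returns (center, radius, theta,
    theta_E) with clockwise traversal from E to N.  None when infeasible.
    """
    L = float(np.linalg.norm(N - E))
    if L < 1e-12 or m <= 1.0 or L >= m * d_nt * (1.0 - 1e-12):
        return None

    def chord(theta: float) -> float:
        return d_nt * math.sin(theta / 2.0) / math.sin(theta / (2.0 * m))

    lo, hi = 1e-9, TWO_PI - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if chord(mid) > L:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    r_s = d_nt / (2.0 * math.sin(theta / (2.0 * m)))
    u = (N - E) / L
    right = np.array([u[1], -u[0]])
    center = 0.5 * (E + N) + r_s * math.cos(theta / 2.0) * right
    theta_E = _angle(E - center)
    return center, r_s, theta, theta_E


def _formulation23(spec: JunctionSpec, use_slope: bool) -> NLPProblem:
    d_nt, d_bp = spec.d_nt, spec.d_bp
    n_child = len(spec.stems)
    c0, r0, warm_anchors = _warm_circle(spec)

    # a child stem preceded by an empty segment uses one bond-angle
    # variable; otherwise free x, y of its 5' nucleotide
    uses_angle = [len(spec.segments[j]) == 0 for j in range(n_child)]
    var_regions = spec.var_regions
    n_var = len(var_regions)

    slots: list[tuple[int, int]] = []  # (offset, width) per child
    off = 3
    for j in range(n_child):
        w = 1 if uses_angle[j] else 2
        slots.append((off, w))
        off += w
    lam_off = off

    def anchors_of(x):
        """(q5, q3) per pair including the fixed enclosing pair 0."""
        out = [(spec.q5, spec.q3)]
        for j in range(n_child):
            o, w = slots[j]
            nj = spec.rung(j + 1)
            if w == 1:
                prev_q3 = out[-1][1]
                q5 = prev_q3 + d_nt * _unit(x[o])
            else:
                q5 = np.array([x[o], x[o + 1]])
            out.append((q5, q5 + d_bp * nj))
        return out

    def segment_flanks(x):
        """Per segment i: (exit point, entry point)."""
        anc = anchors_of(x)
        out = []
        for i in range(len(spec.segments)):
            E = anc[i][0] if i == 0 else anc[i][1]
            N = anc[i + 1][0] if i < n_child else anc[0][1]
            out.append((E, N))
        return out

    def seg_m(i: int, lams) -> float:
        m = 1.0
        vi = 0
        for si, _ in var_regions:
            if si == i:
                m += lams[vi] + 1.0
            vi += 1
        m += sum(1 for kind, _ in spec.segments[i] if kind == "nt")
        return m

    def seg_geometry(x):
        """Segment circles, nucleotide positions and sample points."""
        lams = x[lam_off:]
        flanks = segment_flanks(x)
        nt_pos: dict[int, np.ndarray] = {}
        arcs: list[VarArc] = []
        samples: list[tuple[np.ndarray, np.ndarray | None]] = []  # (pt, seg center)
        penalty = 0.0
        vi_global = 0
        for i, seg in enumerate(spec.segments):
            E, N = flanks[i]
            m = seg_m(i, lams)
            if m <= 1.0 + 1e-12:
                # direct bond: exact via the bond-angle variable for
                # child stems; the closing bond is an equality constraint
                samples.append((E, None))
                samples.append((N, None))
                continue
            geo = _segment_circle(E, N, m, d_nt)
            if geo is None:
                L = float(np.linalg.norm(N - E))
                penalty += PENALTY * (1.0 + max(0.0, L - m * d_nt))
                samples.append((E, None))
                samples.append((N, None))
                continue
            cs, rs, theta, th = geo
            delta = theta / m
            samples.append((E, cs))
            for kind, payload in seg:
                if kind == "nt":
                    th -= delta
                    pt = cs + rs * _unit(th)
                    nt_pos[payload] = pt
                    samples.append((pt, cs))
                else:
                    lam = lams[vi_global]
                    th -= delta  # bond onto the arc start
                    th_start = th
                    sweep = lam * delta
                    for frac in (0.25, 0.5, 0.75):
                        samples.append((cs + rs * _unit(th_start - frac * sweep), cs))
                    th = th_start - sweep
                    arcs.append(
                        VarArc(
                            cols=payload,
                            start=tuple(cs + rs * _unit(th_start)),
                            end=tuple(cs + rs * _unit(th)),
                            center=tuple(cs),
                            radius=rs,
                            theta_start=th_start,
                            theta_end=th,
                        )
                    )
                    vi_global += 1
            samples.append((N, cs))
        return nt_pos, arcs, samples, penalty

    def objective(x) -> float:
        C = x[:2]
        r = x[2]
        _, _, samples, penalty = seg_geometry(x)
        total = penalty
        for pt, cs in samples:
            if use_slope:
                if cs is None:
                    continue
                v1 = C - pt
                v2 = cs - pt
                n1 = float(np.linalg.norm(v1))
                n2 = float(np.linalg.norm(v2))
                if n1 < 1e-12 or n2 < 1e-12:
                    total += PENALTY
                    continue
                cosang = float(v1 @ v2) / (n1 * n2)
                total += (cosang - 1.0) ** 2
            else:
                total += (float(np.linalg.norm(pt - C)) - r) ** 2
        return total

    def decode(x) -> JunctionSolution:
        nt_pos, arcs, _, penalty = seg_geometry(x)
        anc = anchors_of(x)
        anchors = [
            (q5, q3, spec.stems[j].direction)
            for j, (q5, q3) in enumerate(anc[1:])
        ]
        C = np.array(x[:2])
        cycle = [anc[0][0]]
        for i in range(len(spec.segments)):
            for kind, payload in spec.segments[i]:
                if kind == "nt":
                    cycle.append(nt_pos[payload])
            if i < n_child:
                cycle.extend(anc[i + 1])
        cycle.append(anc[0][1])
        cycle.append(anc[0][0])
        angs = [_angle(pt - C) for pt in cycle]
        swept = sum(_cw_delta(a, b) for a, b in zip(angs, angs[1:]))
        return JunctionSolution(
            nt_positions=nt_pos,
            stem_anchors=anchors,
            var_arcs=arcs,
            center=C,
            radius=float(x[2]),
            objective=objective(x),
            max_violation=float(math.sqrt(penalty)) if penalty > 0 else 0.0,
            swept_deg=math.degrees(swept),
        )

    def anchor_points(x) -> list[np.ndarray]:
        return [0.5 * (q5 + q3) for q5, q3 in anchors_of(x)]

    eq_constraints: list[Callable[[np.ndarray], np.ndarray]] = []
    if not spec.segments[-1]:
        # empty closing run: the bond from the last child's 3' nucleotide
        # back to the enclosing 3' nucleotide must have length d_nt
        def closing_bond(x) -> np.ndarray:
            E, N = segment_flanks(x)[-1]
            return np.array([float(np.linalg.norm(N - E)) - d_nt])

        eq_constraints.append(closing_bond)

    x0_parts = [c0, [r0]]
    bounds: list[tuple[float, float]] = [(-1e3, 1e3), (-1e3, 1e3), (d_nt / 2.0, 1e3)]
    for j in range(n_child):
        s5, s3 = warm_anchors[j]
        if uses_angle[j]:
            prev = spec.q5 if j == 0 else warm_anchors[j - 1][1]
            ang = _angle(s5 - prev)
            x0_parts.append([ang])
            bounds.append((ang - math.pi, ang + math.pi))
        else:
            x0_parts.append(list(s5))
            bounds.extend([(-1e3, 1e3), (-1e3, 1e3)])
    x0_parts.append([DEFAULT_VAR_LEN] * n_var)
    bounds.extend([VAR_LEN_BOUNDS] * n_var)
    x0 = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in x0_parts])
    return NLPProblem(
        spec=spec,
        x0=x0,
        bounds=bounds,
        objective=objective,
        eq_constraints=eq_constraints,
        decode=decode,
        anchor_points=anchor_points,
        sample_points=lambda x: [pt for pt, _ in seg_geometry(x)[2]],
    )


def formulation2(spec: JunctionSpec) -> NLPProblem:
    """Free-circle formulation with radial-distance objective."""
    return _formulation23(spec, use_slope=False)


def formulation3(spec: JunctionSpec) -> NLPProblem:
    """Free-circle formulation with slope-deviation objective."""
    return _formulation23(spec, use_slope=True)


# ---------------------------------------------------------------------------
# alignment constraints


def add_alignment_constraints(problem: NLPProblem, spec: JunctionSpec) -> NLPProblem:
    """Append scalar-projection alignment constraints to a problem.

    For axis angle φ (degrees) and anchor points p, q the constraint is
    ``(p - q) · n̂ = 0`` with ``n̂`` the unit normal of the axis, i.e. all
    points share the same offset across the axis; φ = 0 aligns
    horizontally (equal y), φ = 90 vertically (equal x).  Centroid
    variants equate the projection of a group's centroid with a target
    anchor's projection.
    """
    if not spec.aligns and not spec.align_centroids:
        return problem
    n_pairs = spec.n_pairs

    def check(idx: int) -> int:
        if not 0 <= idx < n_pairs:
            raise JunctionError(
                f"alignment constraint references stem {idx}, but the "
                f"junction has {n_pairs} stems"
            )
        return idx

    funcs = list(problem.eq_constraints)
    for group, phi_deg in spec.aligns:
        group = [check(i) for i in group]
        if len(group) < 2:
            raise JunctionError("alignment needs at least two stems")
        phi = math.radians(phi_deg)
        normal = np.array([-math.sin(phi), math.cos(phi)])

        def fn(x, group=group, normal=normal):
            pts = problem.anchor_points(x)
            base = float(pts[group[0]] @ normal)
            return np.array([float(pts[i] @ normal) - base for i in group[1:]])

        funcs.append(fn)
    for group, target, phi_deg in spec.align_centroids:
        group = [check(i) for i in group]
        target = check(target)
        phi = math.radians(phi_deg)
        normal = np.array([-math.sin(phi), math.cos(phi)])

        def fn(x, group=group, target=target, normal=normal):
            pts = problem.anchor_points(x)
            cent = np.mean([pts[i] for i in group], axis=0)
            return np.array([float(cent @ normal) - float(pts[target] @ normal)])

        funcs.append(fn)
    return NLPProblem(
        spec=problem.spec,
        x0=problem.x0,
        bounds=problem.bounds,
        objective=problem.objective,
        eq_constraints=funcs,
        decode=problem.decode,
        anchor_points=problem.anchor_points,
    )


# ---------------------------------------------------------------------------
# solving


RESTART_SEEDS = tuple(range(1, 9))


def solve(
    problem: NLPProblem,
    seeds: Sequence[int] = RESTART_SEEDS,
    feas_tol: float = FEAS_TOL,
) -> JunctionSolution:
    """Solve a junction NLP with SLSQP plus fixed perturbed restarts.

    The first attempt starts from the plain-circular warm start; on
    failure up to ``len(seeds)`` Gaussian-perturbed restarts (σ = 0.1·r₀)
    are tried.  A solution is accepted when every equality constraint is
    met to ``feas_tol`` and no internal geometry penalty is active.
    Raises :class:`JunctionInfeasible` when nothing feasible is found.
    """
    r0 = problem.x0[2] if len(problem.x0) > 2 else 1.0
    scale = 0.1 * abs(float(r0)) or 0.1
    best: JunctionSolution | None = None

    cons = (
        [{"type": "eq", "fun": problem.eq_all}] if problem.eq_constraints else []
    )

    def attempt(x_start: np.ndarray) -> JunctionSolution | None:
        result = minimize(
            problem.objective,
            x_start,
            method="SLSQP",
            bounds=problem.bounds,
            constraints=cons,
            options={"maxiter": 400, "ftol": 1e-12},
        )
        x = result.x
        viol = float(np.max(np.abs(problem.eq_all(x)))) if problem.eq_constraints else 0.0
        obj = problem.objective(x)
        if not np.isfinite(obj) or obj >= PENALTY or viol >= feas_tol:
            return None
        try:
            sol = problem.decode(x)
        except JunctionError:
            return None
        sol.max_violation = max(sol.max_violation, viol)
        if sol.max_violation >= feas_tol:
            return None
        # reject degenerate geometry (e.g. contradictory alignment
        # constraints satisfied by collapsing stems onto each other)
        mids = [0.5 * (problem.spec.q5 + problem.spec.q3)]
        mids.extend(0.5 * (np.asarray(a) + np.asarray(b)) for a, b, _ in sol.stem_anchors)
        for i in range(len(mids)):
            for j in range(i + 1, len(mids)):
                if float(np.linalg.norm(mids[i] - mids[j])) < 0.5 * problem.spec.d_bp:
                    return None
        return sol

    # deterministic starts: warm start plus formulation-specific corners
    for x_start in [problem.x0, *problem.extra_starts]:
        sol = attempt(x_start)
        if sol is not None and (best is None or sol.objective < best.objective):
            best = sol
    # perturbed restarts only when nothing feasible was found
    if best is None:
        lo = np.array([b[0] for b in problem.bounds])
        hi = np.array([b[1] for b in problem.bounds])
        for seed in seeds:
            rng = np.random.default_rng(seed)
            pert = np.clip(
                problem.x0 + rng.normal(0.0, scale, size=problem.n_vars), lo, hi
            )
            best = attempt(pert)
            if best is not None:
                break
    if best is None:
        raise JunctionInfeasible(
            "no feasible junction layout found under the given stem "
            "directions and alignment constraints; it is sometimes useful "
            "to try a different formulation (1, 2 or 3)"
        )
    return best


# ---------------------------------------------------------------------------
# bridge from the structure tree (used by geometry.layout_structure)


def junction_spec_from_tree(
    junc: Junction,
    q5: np.ndarray,
    q3: np.ndarray,
    enclosing_dir: float,
    directive: JunctionDirective,
    params: LayoutParams,
    seg_items: Callable[[Segment], list[tuple]],
) -> JunctionSpec:
    """Build a :class:`JunctionSpec` for a tree junction plus directive."""
    stems = junc.stems
    if len(directive.stem_dirs_deg) != len(stems):
        raise JunctionError(
            f"junction has {len(stems)} emanating stems but "
            f"{len(directive.stem_dirs_deg)} directions were given"
        )

    def col_to_index(col: int) -> int:
        if junc.closing and col in junc.closing:
            return 0
        for j, stem in enumerate(stems):
            if col in stem.columns:
                return j + 1
        raise JunctionError(
            f"alignment constraint column {col} is not on a stem of this junction"
        )

    return JunctionSpec(
        q5=q5,
        q3=q3,
        enclosing_dir=enclosing_dir,
        stems=[StemSpec(math.radians(d)) for d in directive.stem_dirs_deg],
        segments=[seg_items(s) for s in junc.segments],
        d_nt=params.d_nt,
        d_bp=params.d_bp,
        aligns=[([col_to_index(c) for c in cols], deg) for cols, deg in directive.aligns],
        align_centroids=[
            ([col_to_index(c) for c in cols], col_to_index(t), deg)
            for cols, t, deg in directive.align_centroids
        ],
    )
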