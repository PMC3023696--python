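import math

import numpy as np
import pytest

from conftest import symmetric_junction_spec
from ssdraw.commands import build_directives
from ssdraw.fixtures import FixtureSpec, generate_fixture
from ssdraw.geometry import build_structure_tree, layout_structure
from ssdraw.junction_solver import (
    JunctionInfeasible,
    JunctionSpec,
    StemSpec,
    _warm_circle,
    add_alignment_constraints,
    formulation1,
    formulation2,
    formulation3,
    solve,
)

FORMULATIONS = [formulation1, formulation2, formulation3]


def anchor_mids(sol):
    return [0.5 * (np.asarray(a) + np.asarray(b)) for a, b, _ in sol.stem_anchors]


# ---------------------------------------------------------------------------
# problem construction


class TestProblemConstruction:
    def test_formulation1_variable_count(self):
        # radius + start angle + one intersection parameter per pair
        spec = symmetric_junction_spec(n_stems=4, n_unpaired=3)
        assert formulation1(spec).n_vars == 1 + 1 + 4

    def test_variable_length_region_adds_one_variable(self):
        spec = symmetric_junction_spec(n_stems=3, n_unpaired=2)
        spec.segments[1].append(("var", (50, 53)))
        assert formulation1(spec).n_vars == 1 + 1 + 3 + 1

    def test_zero_unpaired_junction_still_builds(self):
        spec = symmetric_junction_spec(n_stems=3, n_unpaired=0)
        problem = formulation1(spec)
        assert problem.n_vars == 1 + 1 + 3
        assert len(problem.eq_constraints) == 1  # closing bond + angle sum vector

    @pytest.mark.parametrize("n_unpaired,n_var,expected", [(4, 0, 6), (0, 1, 5), (2, 1, 7)])
    def test_formulation2_sample_point_count_is_n_plus_2_plus_3v(
        self, n_unpaired, n_var, expected
    ):
        spec = symmetric_junction_spec(n_stems=3, n_unpaired=n_unpaired)
        if n_var:
            spec.segments[0].append(("var", (50, 53)))
        # point the stems along the warm circle's radial directions so the
        # warm start itself is a consistent geometry
        _, _, warm_anchors = _warm_circle(spec)
        c0, _, _ = _warm_circle(spec)
        spec.stems = [
            StemSpec(math.atan2(*(0.5 * (s5 + s3) - c0)[::-1]))
            for s5, s3 in warm_anchors
        ]
        problem = formulation2(spec)
        samples = problem.sample_points(problem.x0)
        # three segments; segment 0 carries the var region
        per_segment = [n_unpaired + 2 + 3 * n_var, n_unpaired + 2, n_unpaired + 2]
        assert len(samples) == sum(per_segment)


# ---------------------------------------------------------------------------
# solutions


class TestSolve:
    @pytest.mark.parametrize("formulation", FORMULATIONS)
    def test_feasibility_contract(self, formulation):
        spec = symmetric_junction_spec(n_stems=4, n_unpaired=3)
        sol = solve(formulation(spec))
        assert sol.max_violation < 1e-6
        assert sol.objective >= 0.0

    def test_formulation1_angle_closure(self):
        for n_stems, n_unpaired in [(3, 4), (4, 3), (5, 2)]:
            spec = symmetric_junction_spec(n_stems=n_stems, n_unpaired=n_unpaired)
            sol = solve(formulation1(spec))
            assert sol.swept_deg == pytest.approx(360.0, abs=1e-5)

    @pytest.mark.parametrize("formulation", FORMULATIONS)
    def test_perfect_circle_oracle_equivalence(self, formulation):
        """Stems placed tangent to a known circle are recovered exactly.

        The symmetric spec's directions equal the radial directions of the
        plain circular layout, so that circle satisfies every constraint;
        all three formulations must find it (objective ~ 0) and reproduce
        its stem anchor positions.
        """
        spec = symmetric_junction_spec(n_stems=3, n_unpaired=4)
        _, _, oracle_anchors = _warm_circle(spec)
        sol = solve(formulation(spec))
        assert sol.objective < 1e-8
        for (a5, a3, _), (w5, w3) in zip(sol.stem_anchors, oracle_anchors):
            assert np.linalg.norm(np.asarray(a5) - w5) < 1e-4
            assert np.linalg.norm(np.asarray(a3) - w3) < 1e-4

    def test_asymmetric_directions_solve_and_respect_them(self):
        spec = symmetric_junction_spec(n_stems=4, n_unpaired=3)
        spec.stems = [StemSpec(math.radians(d)) for d in (200.0, 90.0, 10.0)]
        sol = solve(formulation2(spec))
        assert sol.max_violation < 1e-6
        # the rung of each child stem is perpendicular to its direction
        for (a5, a3, direction) in sol.stem_anchors:
            rung = (np.asarray(a3) - np.asarray(a5)) / spec.d_bp
            stem_dir = np.array([math.cos(direction), math.sin(direction)])
            assert abs(float(rung @ stem_dir)) < 1e-9

    def test_objective_invariant_under_global_rotation(self):
        """Rotating the whole spec maps the objective surface onto itself.

        Checked at the variable level: a point x for the original problem,
        rotated into the rotated problem's frame, gives the identical
        objective value.  (All child anchors are free x,y slots here.)
        """
        theta = math.radians(33.0)
        R = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        spec = symmetric_junction_spec(n_stems=4, n_unpaired=3)
        spec.stems = [StemSpec(math.radians(d)) for d in (200.0, 90.0, 10.0)]
        rotated = JunctionSpec(
            q5=R @ spec.q5,
            q3=R @ spec.q3,
            enclosing_dir=spec.enclosing_dir + theta,
            stems=[StemSpec(s.direction + theta) for s in spec.stems],
            segments=spec.segments,
            d_nt=spec.d_nt,
            d_bp=spec.d_bp,
        )
        p = formulation2(spec)
        p_rot = formulation2(rotated)
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = p.x0 + rng.normal(0.0, 0.05, size=p.n_vars)
            x_rot = x.copy()
            x_rot[0:2] = R @ x[0:2]  # main circle center
            for k in range(3):  # three child stems, free (x, y) slots
                sl = slice(3 + 2 * k, 5 + 2 * k)
                x_rot[sl] = R @ x[sl]
            assert p_rot.objective(x_rot) == pytest.approx(
                p.objective(x), abs=1e-9
            )

    def test_solution_rotates_with_the_spec(self):
        theta = math.radians(90.0)
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        spec = symmetric_junction_spec(n_stems=3, n_unpaired=4)
        rotated = JunctionSpec(
            q5=R @ spec.q5,
            q3=R @ spec.q3,
            enclosing_dir=spec.enclosing_dir + theta,
            stems=[StemSpec(s.direction + theta) for s in spec.stems],
            segments=spec.segments,
        )
        sol = solve(formulation2(spec))
        sol_rot = solve(formulation2(rotated))
        assert sol_rot.objective == pytest.approx(sol.objective, abs=1e-8)
        for (a5, _, _), (b5, _, _) in zip(sol.stem_anchors, sol_rot.stem_anchors):
            assert np.linalg.norm(R @ np.asarray(a5) - np.asarray(b5)) < 1e-4

    def test_deterministic_given_fixed_seed_list(self):
        spec = symmetric_junction_spec(n_stems=4, n_unpaired=3)
        a = solve(formulation2(spec))
        b = solve(formulation2(spec))
        for (a5, a3, _), (b5, b3, _) in zip(a.stem_anchors, b.stem_anchors):
            assert np.array_equal(np.asarray(a5), np.asarray(b5))
            assert np.array_equal(np.asarray(a3), np.asarray(b3))

    def test_variable_length_region_is_solved(self):
        spec = symmetric_junction_spec(n_stems=3, n_unpaired=2)
        spec.segments[1] = [("nt", 110), ("var", (50, 53)), ("nt", 111)]
        sol = solve(formulation2(spec))
        assert sol.max_violation < 1e-6
        assert len(sol.var_arcs) == 1
        arc = sol.var_arcs[0]
        assert arc.theta_start > arc.theta_end  # clockwise sweep


class TestAlignmentConstraints:
    def _spec(self):
        spec = symmetric_junction_spec(n_stems=4, n_unpaired=3)
        spec.stems = [StemSpec(math.radians(d)) for d in (180.0, 90.0, 0.0)]
        return spec

    def test_horizontal_alignment_equalizes_y(self):
        spec = self._spec()
        spec.aligns = [([1, 3], 0.0)]
        sol = solve(add_alignment_constraints(formulation2(spec), spec))
        mids = anchor_mids(sol)
        assert mids[0][1] == pytest.approx(mids[2][1], abs=1e-6)

    def test_vertical_alignment_equalizes_x(self):
        spec = self._spec()
        spec.aligns = [([0, 2], 90.0)]
        sol = solve(add_alignment_constraints(formulation2(spec), spec))
        mids = anchor_mids(sol)
        enclosing_mid = 0.5 * (spec.q5 + spec.q3)
        assert enclosing_mid[0] == pytest.approx(mids[1][0], abs=1e-6)

    def test_centroid_alignment_on_vertical_axis(self):
        spec = self._spec()
        spec.align_centroids = [([1, 3], 2, 90.0)]
        sol = solve(add_alignment_constraints(formulation2(spec), spec))
        mids = anchor_mids(sol)
        centroid_x = 0.5 * (mids[0][0] + mids[2][0])
        assert centroid_x == pytest.approx(mids[1][0], abs=1e-6)

    def test_contradictory_constraints_raise_infeasible(self):
        spec = self._spec()
        # pin two distinct child stems onto the enclosing stem's midpoint
        spec.aligns = [([0, 2], 90.0), ([0, 2], 0.0), ([0, 1], 90.0), ([0, 1], 0.0)]
        with pytest.raises(JunctionInfeasible, match="formulation"):
            solve(add_alignment_constraints(formulation2(spec), spec))

    def test_unknown_stem_reference_is_an_error(self):
        spec = self._spec()
        spec.aligns = [([1, 9], 0.0)]
        from ssdraw.junction_solver import JunctionError

        with pytest.raises(JunctionError, match="stem 9"):
            add_alignment_constraints(formulation2(spec), spec)


# ---------------------------------------------------------------------------
# through the layout pipeline


class TestPipelineIntegration:
    @pytest.mark.parametrize("template", ["junction3", "junction4"])
    def test_commanded_junction_keeps_layout_invariants(self, template):
        aln = generate_fixture(
            FixtureSpec(template=template, n_seqs=5, seed=2, junction_command=True)
        )
        directives = build_directives(aln)
        tree = build_structure_tree(aln.pairs(), aln.n_cols)
        lay = layout_structure(tree, directives=directives.layout)
        spacings = lay.consecutive_spacings()
        assert max(abs(d - 1.0) for _, d in spacings) < 1e-6
        assert lay.overlap_violations() == []

    def test_stems_point_in_commanded_directions(self):
        aln = generate_fixture(
            FixtureSpec(template="junction4", n_seqs=5, seed=2, junction_command=True)
        )
        directives = build_directives(aln)
        tree = build_structure_tree(aln.pairs(), aln.n_cols)
        lay = layout_structure(tree, directives=directives.layout)
        jd = directives.layout.junctions[0]
        enclosing = tree.root.stems[0]
        for stem, want_deg in zip(enclosing.inner.stems, jd.stem_dirs_deg):
            (l0, r0), (l1, r1) = stem.pairs[0], stem.pairs[1]
            axis = lay.xy[l1] - lay.xy[l0]
            got = math.degrees(math.atan2(axis[1], axis[0])) % 360.0
            assert got == pytest.approx(want_deg % 360.0, abs=1e-4)
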