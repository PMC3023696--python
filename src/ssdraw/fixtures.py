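"""Synthetic annotated alignments for tests and demos.

The generator emulates the style of a tiny contrived RNA family: a known
true structure (hairpin, internal loop, 3- or 4-way junction, or a simple
H-type pseudoknot), a consensus sequence drawn once from the seed, and
controlled injection of covariation, gaps and an optional modular hairpin.
Because substitutions always swap a canonical pair for a canonical pair
differing at both positions, the expected covariation class of every pair
is known by construction: rate 0 leaves every pair invariant, any
intermediate rate makes pairs covarying, and row 0 always carries the
reference pair type so that both types are observed even at rate 1.

Everything is driven by a single integer seed; the same spec always
yields the identical alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stockholm_io import AnnotatedAlignment, LayoutCommand

CANONICAL = ("AU", "UA", "GC", "CG", "GU", "UG")

#: canonical partner differing at both positions, used for covariation
ALT_PAIR = {"AU": "GC", "GC": "AU", "UA": "CG", "CG": "UA", "GU": "CG", "UG": "GC"}

TEMPLATES = ("hairpin", "internal", "junction3", "junction4", "pk")

#: default outward stem directions (degrees) for junction templates
JUNCTION_DIRS = {"junction3": [150.0, 30.0], "junction4": [180.0, 90.0, 0.0]}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic alignment."""

    n_seqs: int = 10
    template: str = "hairpin"
    covariation_rate: float = 0.0
    modular_fraction: float = 0.0
    gap_rate: float = 0.0
    seed: int = 1
    junction_command: bool = False

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        for rate in (self.covariation_rate, self.modular_fraction, self.gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_seqs < 1:
            raise ValueError("need at least one sequence")


def _template_structure(template: str) -> tuple[str, dict[str, str]]:
    """SS_cons plus extra #=GC lines for the template."""
    if template == "hairpin":
        return "..<<<<....>>>>..", {}
    if template == "internal":
        return "..<<<..<<<....>>>..>>>..", {}
    if template == "junction3":
        return "..<<<..<<<<....>>>>..<<<<....>>>>..>>>..", {}
    if template == "junction4":
        return (
            "..<<<..<<<<....>>>>..<<<<....>>>>..<<<<....>>>>..>>>..",
            {},
        )
    if template == "pk":
        ss = "..<<<<.....>>>>........."
        pk = ".......<<<......>>>....."
        return ss, {"A": pk}
    raise ValueError(template)


def generate_fixture(spec: FixtureSpec) -> AnnotatedAlignment:
    """Generate a seeded alignment whose true structure is the template."""
    rng = np.random.default_rng(spec.seed)
    ss_cons, pk_lines = _template_structure(spec.template)
    n_cols = len(ss_cons)

    # optional modular hairpin appended at the 3' end
    module_cols: list[int] = []
    if spec.modular_fraction > 0:
        module = "..<<<...>>>"
        module_cols = list(range(n_cols, n_cols + len(module)))
        ss_cons = ss_cons + module
        pk_lines = {k: v + "." * len(module) for k, v in pk_lines.items()}
        n_cols += len(module)

    # reference consensus: one canonical type per pair, random letters elsewhere
    from .stockholm_io import match_brackets

    pairs = list(match_brackets(ss_cons))
    for line in pk_lines.values():
        pairs.extend(match_brackets(line))
    ref = [""] * n_cols
    pair_type: dict[tuple[int, int], str] = {}
    for l, r in pairs:
        ptype = CANONICAL[int(rng.integers(len(CANONICAL)))]
        pair_type[(l, r)] = ptype
        ref[l], ref[r] = ptype[0], ptype[1]
    unpaired = [c for c in range(n_cols) if not ref[c]]
    for c in unpaired:
        ref[c] = "ACGU"[int(rng.integers(4))]

    n_module = round(spec.modular_fraction * spec.n_seqs)
    rows: list[str] = []
    for i in range(spec.n_seqs):
        row = list(ref)
        if i > 0:
            for (l, r), ptype in pair_type.items():
                if rng.random() < spec.covariation_rate:
                    alt = ALT_PAIR[ptype]
                    row[l], row[r] = alt[0], alt[1]
            for c in unpaired:
                if c not in module_cols and rng.random() < spec.gap_rate:
                    row[c] = "-"
        if module_cols and i >= n_module:
            for c in module_cols:
                row[c] = "-"
        rows.append("".join(row))

    labels: dict[str, int] = {}
    commands: list[LayoutCommand] = []
    if module_cols:
        labels["M"] = module_cols[2]  # first paired column of the module
        commands.append(LayoutCommand("modular", ("hp", "predicate", "col:M=ACGU")))
    if spec.junction_command and spec.template in JUNCTION_DIRS:
        # anchor on the first unpaired column inside the junction loop
        labels["j"] = ss_cons.index("<", ss_cons.index("<") + 3) - 1
        dirs = ",".join(f"{d:g}" for d in JUNCTION_DIRS[spec.template])
        commands.append(LayoutCommand("multistem_junction", ("j", "dirs", dirs)))

    aln = AnnotatedAlignment(
        seq_names=[f"seq{i + 1}" for i in range(spec.n_seqs)],
        rows=rows,
        ss_cons=ss_cons,
        labels=labels,
        pk_lines=pk_lines,
        commands=commands,
    )
    aln.validate()
    return aln
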