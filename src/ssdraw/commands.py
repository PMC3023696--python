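"""Resolution of layout/annotation commands against an alignment.

Supported grammar, one command per ``#=GF R2R`` line (label references are
single characters from the ``#=GC R2R_LABEL`` line)::

    label <char> <col>
    multistem_junction <label> dirs <deg,deg,...>
        [align <label,label,...> <deg>]
        [align_centroid <label,label,...>:<label> <deg>]
        [formulation 1|2|3]
    var_backbone_range <label1> <label2>
    var_hairpin <label> predicate <expr...>
    modular <name> predicate <expr...>
    pk <name> style inline|callout
    skeleton on
    turn <label> <deg>
    thresholds <t50> <t75> <t90> <t97>
    shade <label1> <label2> <color>

Predicates use the expression language of
:func:`ssdraw.consensus.compile_predicate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import JunctionDirective, LayoutDirectives
from .stockholm_io import AnnotatedAlignment, StockholmError


@dataclass
class ModularDirective:
    name: str
    predicate: str
    anchor_col: int | None = None  # labeled hairpin anchor for var_hairpin


@dataclass
class Directives:
    """Everything the pipeline needs from the command lines."""

    layout: LayoutDirectives = field(default_factory=LayoutDirectives)
    skeleton: bool = False
    thresholds: tuple[float, float, float, float] | None = None
    pk_styles: dict[str, str] = field(default_factory=dict)
    modulars: list[ModularDirective] = field(default_factory=list)
    shades: list[tuple[int, int, str]] = field(default_factory=list)  # half-open


def build_directives(aln: AnnotatedAlignment) -> Directives:
    """Resolve the alignment's commands into concrete directives.

    ``label`` commands extend the label table before any other command is
    resolved, so order between ``label`` and its uses does not matter.
    """
    for cmd in aln.commands:
        if cmd.verb == "label":
            if len(cmd.args) != 2:
                raise StockholmError("label command needs <char> <col>")
            char, col = cmd.args[0], int(cmd.args[1])
            if char in aln.labels and aln.labels[char] != col:
                raise StockholmError(f"duplicate label character {char!r}")
            if not 0 <= col < aln.n_cols:
                raise StockholmError(f"label column {col} out of range")
            aln.labels[char] = col

    out = Directives()
    for cmd in aln.commands:
        args = list(cmd.args)
        if cmd.verb == "label":
            continue
        elif cmd.verb == "multistem_junction":
            out.layout.junctions.append(_parse_junction(aln, args))
        elif cmd.verb == "var_backbone_range":
            a, b = (aln.resolve_label(t) for t in args[:2])
            if b < a:
                a, b = b, a
            out.layout.var_regions.append((a, b + 1))
        elif cmd.verb == "turn":
            out.layout.turns[aln.resolve_label(args[0])] = float(args[1])
        elif cmd.verb == "skeleton":
            out.skeleton = not args or args[0].lower() in {"on", "true", "1"}
        elif cmd.verb == "thresholds":
            vals = tuple(float(t) for t in args[:4])
            if len(vals) != 4 or any(
                not 0 < v < 1 for v in vals
            ) or list(vals) != sorted(set(vals)):
                raise StockholmError(
                    "thresholds must be four strictly increasing values in (0,1)"
                )
            out.thresholds = vals  # type: ignore[assignment]
        elif cmd.verb == "pk":
            if len(args) != 3 or args[1] != "style" or args[2] not in {
                "inline",
                "callout",
            }:
                raise StockholmError("pk command needs <name> style inline|callout")
            if args[0] not in aln.pk_lines:
                raise StockholmError(f"unknown pseudoknot {args[0]!r}")
            out.pk_styles[args[0]] = args[2]
        elif cmd.verb == "modular":
            if len(args) < 3 or args[1] != "predicate":
                raise StockholmError("modular command needs <name> predicate <expr>")
            out.modulars.append(ModularDirective(args[0], " ".join(args[2:])))
        elif cmd.verb == "var_hairpin":
            if len(args) < 3 or args[1] != "predicate":
                raise StockholmError("var_hairpin command needs <label> predicate <expr>")
            col = aln.resolve_label(args[0])
            out.modulars.append(
                ModularDirective(f"hairpin@{args[0]}", " ".join(args[2:]), anchor_col=col)
            )
        elif cmd.verb == "shade":
            a, b = (aln.resolve_label(t) for t in args[:2])
            if b < a:
                a, b = b, a
            out.shades.append((a, b + 1, args[2]))
        else:  # pragma: no cover - parse_stockholm already rejects these
            raise StockholmError(f"unknown command verb {cmd.verb!r}")
    return out


def _parse_junction(aln: AnnotatedAlignment, args: list[str]) -> JunctionDirective:
    if len(args) < 3 or args[1] != "dirs":
        raise StockholmError(
            "multistem_junction needs <label> dirs <deg,...> [align ...] "
            "[align_centroid ...] [formulation 1|2|3]"
        )
    jd = JunctionDirective(
        anchor_col=aln.resolve_label(args[0]),
        stem_dirs_deg=[float(t) for t in args[2].split(",")],
    )
    i = 3
    while i < len(args):
        word = args[i]
        if word == "align":
            cols = [aln.resolve_label(t) for t in args[i + 1].split(",")]
            jd.aligns.append((cols, float(args[i + 2])))
            i += 3
        elif word == "align_centroid":
            group_s, _, target_s = args[i + 1].partition(":")
            if not target_s:
                raise StockholmError(
                    "align_centroid needs <labels>:<label> <deg>"
                )
            cols = [aln.resolve_label(t) for t in group_s.split(",")]
            jd.align_centroids.append(
                (cols, aln.resolve_label(target_s), float(args[i + 2]))
            )
            i += 3
        elif word == "formulation":
            jd.formulation = int(args[i + 1])
            if jd.formulation not in (1, 2, 3):
                raise StockholmError("formulation must be 1, 2 or 3")
            i += 2
        else:
            raise StockholmError(f"unknown multistem_junction clause {word!r}")
    return jd
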