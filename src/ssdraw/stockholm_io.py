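"""Reading and writing annotated Stockholm alignments.

The dialect understood here is Stockholm 1.0 with the column annotations
used for structure drawing:

* ``#=GC SS_cons`` — consensus secondary structure; matched angle brackets
  ``<`` and ``>`` mark base pairs, any other character is unpaired.
* ``#=GC R2R_LABEL`` — single-character column labels referenced by layout
  commands.
* ``#=GC SS_cons_pk<NAME>`` — one additional, independently nested bracket
  line per pseudoknot.
* ``#=GF R2R <verb> <args...>`` — whitespace-tokenized layout/annotation
  commands (one command per line).
* ``#=GS <seqname> R2R <verb> <args...>`` — per-sequence commands.

Interleaved (wrapped) alignments are concatenated on read; output is always
a single block.  Column indices are 0-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

SEQ_ALPHABET = set("ACGUTNRY-.")
GAP_CHARS = {"-", "."}

#: Verbs of the supported command grammar (one command per ``#=GF R2R`` line).
KNOWN_VERBS = frozenset(
    {
        "label",
        "multistem_junction",
        "var_backbone_range",
        "var_hairpin",
        "modular",
        "pk",
        "skeleton",
        "turn",
        "thresholds",
        "shade",
    }
)


class StockholmError(ValueError):
    """Raised for malformed Stockholm input."""


@dataclass(frozen=True)
class LayoutCommand:
    """A single layout/annotation command.

    Parameters
    ----------
    verb:
        Command name; must be one of :data:`KNOWN_VERBS`.
    args:
        Raw whitespace-separated tokens following the verb.
    seq_name:
        For per-sequence (``#=GS``) commands, the sequence the command
        applies to; ``None`` for file-level commands.
    """

    verb: str
    args: tuple[str, ...] = ()
    seq_name: str | None = None

    def __post_init__(self) -> None:
        if self.verb not in KNOWN_VERBS:
            raise StockholmError(f"unknown command verb: {self.verb!r}")


@dataclass(frozen=True)
class PairList:
    """Nested (non-crossing) base pairs from one bracket line.

    ``pairs`` holds ``(left, right)`` column tuples with ``left < right``,
    sorted by left column; each column occurs in at most one pair.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for left, right in self.pairs:
            if left >= right:
                raise ValueError(f"pair ({left},{right}) not left<right")
            if left in seen or right in seen:
                raise ValueError(f"column reused in pair ({left},{right})")
            seen.update((left, right))
        for a in self.pairs:
            for b in self.pairs:
                # proper nesting: no interleaving a.left < b.left < a.right < b.right
                if a[0] < b[0] < a[1] < b[1]:
                    raise ValueError(f"crossing pairs {a} and {b}")

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_brackets(self, n_cols: int) -> str:
        """Serialize back to a bracket string of length ``n_cols``."""
        chars = ["."] * n_cols
        for left, right in self.pairs:
            chars[left] = "<"
            chars[right] = ">"
        return "".join(chars)


@dataclass
class AnnotatedAlignment:
    """A Stockholm alignment plus the drawing annotation it carries."""

    seq_names: list[str]
    rows: list[str]
    ss_cons: str
    labels: dict[str, int] = field(default_factory=dict)
    pk_lines: dict[str, str] = field(default_factory=dict)
    commands: list[LayoutCommand] = field(default_factory=list)
    extra_gf: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return len(self.ss_cons)

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def validate(self) -> None:
        n = self.n_cols
        if len(self.seq_names) != len(self.rows):
            raise StockholmError("sequence name/row count mismatch")
        for name, row in zip(self.seq_names, self.rows):
            if len(row) != n:
                raise StockholmError(
                    f"row {name!r} has {len(row)} columns, expected {n}"
                )
            bad = set(row) - SEQ_ALPHABET
            if bad:
                raise StockholmError(
                    f"row {name!r} contains characters outside the "
                    f"alphabet: {sorted(bad)}"
                )
        for pk_name, line in self.pk_lines.items():
            if len(line) != n:
                raise StockholmError(
                    f"pseudoknot line {pk_name!r} has {len(line)} columns, "
                    f"expected {n}"
                )
            match_brackets(line)
        for char, col in self.labels.items():
            if not 0 <= col < n:
                raise StockholmError(f"label {char!r} at invalid column {col}")
        match_brackets(self.ss_cons)

    def resolve_label(self, char: str) -> int:
        try:
            return self.labels[char]
        except KeyError:
            raise StockholmError(f"unknown column label {char!r}") from None

    def pairs(self) -> PairList:
        """Base pairs of the main consensus structure."""
        return match_brackets(self.ss_cons)

    def pk_pairs(self, name: str) -> PairList:
        return match_brackets(self.pk_lines[name])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedAlignment):
            return NotImplemented
        return (
            self.seq_names == other.seq_names
            and self.rows == other.rows
            and self.ss_cons == other.ss_cons
            and self.labels == other.labels
            and self.pk_lines == other.pk_lines
            and self.commands == other.commands
        )


def match_brackets(bracket_line: str) -> PairList:
    """Match ``<`` / ``>`` brackets in an aligned annotation line.

    Matching is innermost-first via a stack; every non-bracket character is
    unpaired.  Raises :class:`StockholmError` with the failing column on an
    unbalanced line.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for col, char in enumerate(bracket_line):
        if char == "<":
            stack.append(col)
        elif char == ">":
            if not stack:
                raise StockholmError(
                    f"unbalanced brackets: close with no open at column {col}"
                )
            pairs.append((stack.pop(), col))
    if stack:
        raise StockholmError(
            f"unbalanced brackets: unclosed open at column {stack[-1]}"
        )
    pairs.sort()
    return PairList(tuple(pairs))


def _parse_labels(label_line: str) -> dict[str, int]:
    labels: dict[str, int] = {}
    for col, char in enumerate(label_line):
        if char in GAP_CHARS:
            continue
        if char in labels:
            raise StockholmError(
                f"duplicate label character {char!r} "
                f"(columns {labels[char]} and {col})"
            )
        labels[char] = col
    return labels


def parse_stockholm(text: str) -> AnnotatedAlignment:
    """Parse a Stockholm document into an :class:`AnnotatedAlignment`.

    ``T`` is normalized to ``U`` and lowercase to uppercase in sequence
    rows.  Wrapped alignments (the same sequence appearing in several
    blocks) are concatenated.  Unknown ``#=GF`` tags are kept in
    ``extra_gf`` and logged; unknown command verbs are an error.
    """
    seq_order: list[str] = []
    seqs: dict[str, str] = {}
    gc: dict[str, str] = {}
    commands: list[LayoutCommand] = []
    extra_gf: list[tuple[str, str]] = []

    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("# STOCKHOLM") or line.strip() == "//":
            continue
        if line.startswith("#=GC"):
            parts = line.split(None, 2)
            if len(parts) < 3:
                raise StockholmError(f"malformed #=GC line: {line!r}")
            _, tag, value = parts
            gc[tag] = gc.get(tag, "") + value
        elif line.startswith("#=GF"):
            parts = line.split(None, 2)
            if len(parts) < 3:
                raise StockholmError(f"malformed #=GF line: {line!r}")
            _, tag, value = parts
            if tag == "R2R":
                tokens = value.split()
                commands.append(LayoutCommand(tokens[0], tuple(tokens[1:])))
            else:
                log.warning("ignoring unknown #=GF tag %r", tag)
                extra_gf.append((tag, value))
        elif line.startswith("#=GS"):
            parts = line.split(None, 3)
            if len(parts) < 4:
                raise StockholmError(f"malformed #=GS line: {line!r}")
            _, seq_name, tag, value = parts
            if tag == "R2R":
                tokens = value.split()
                commands.append(
                    LayoutCommand(tokens[0], tuple(tokens[1:]), seq_name=seq_name)
                )
            else:
                log.warning("ignoring unknown #=GS tag %r", tag)
        elif line.startswith("#"):
            continue
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise StockholmError(f"malformed sequence line: {line!r}")
            name, chunk = parts
            if name not in seqs:
                seq_order.append(name)
                seqs[name] = ""
            seqs[name] += chunk

    if "SS_cons" not in gc:
        raise StockholmError("no consensus structure (#=GC SS_cons line missing)")
    if not seq_order:
        raise StockholmError("no sequence rows found")

    rows = []
    for name in seq_order:
        row = seqs[name].upper().replace("T", "U")
        bad = set(row) - SEQ_ALPHABET
        if bad:
            raise StockholmError(
                f"row {name!r} contains characters outside the alphabet: "
                f"{sorted(bad)}"
            )
        rows.append(row)

    labels = _parse_labels(gc["R2R_LABEL"]) if "R2R_LABEL" in gc else {}
    if "R2R_LABEL" in gc and len(gc["R2R_LABEL"]) != len(gc["SS_cons"]):
        raise StockholmError("#=GC R2R_LABEL length differs from SS_cons")

    pk_lines = {
        tag[len("SS_cons_pk") :]: value
        for tag, value in gc.items()
        if tag.startswith("SS_cons_pk")
    }

    aln = AnnotatedAlignment(
        seq_names=seq_order,
        rows=rows,
        ss_cons=gc["SS_cons"],
        labels=labels,
        pk_lines=pk_lines,
        commands=commands,
        extra_gf=extra_gf,
    )
    aln.validate()
    return aln


def write_stockholm(aln: AnnotatedAlignment) -> str:
    """Serialize an alignment; round-trips through :func:`parse_stockholm`."""
    aln.validate()
    lines = ["# STOCKHOLM 1.0", ""]
    for cmd in aln.commands:
        body = " ".join((cmd.verb, *cmd.args))
        if cmd.seq_name is None:
            lines.append(f"#=GF R2R {body}")
        else:
            lines.append(f"#=GS {cmd.seq_name} R2R {body}")
    for tag, value in aln.extra_gf:
        lines.append(f"#=GF {tag} {value}")
    width = max(
        [len(n) for n in aln.seq_names]
        + [len("#=GC SS_cons_pk") + max((len(k) for k in aln.pk_lines), default=0)]
    )
    width = max(width, len("#=GC R2R_LABEL")) + 2
    for name, row in zip(aln.seq_names, aln.rows):
        lines.append(f"{name:<{width}}{row}")
    lines.append(f"{'#=GC SS_cons':<{width}}{aln.ss_cons}")
    if aln.labels:
        chars = ["."] * aln.n_cols
        for char, col in aln.labels.items():
            chars[col] = char
        lines.append(f"{'#=GC R2R_LABEL':<{width}}{''.join(chars)}")
    for pk_name in sorted(aln.pk_lines):
        tag = f"#=GC SS_cons_pk{pk_name}"
        lines.append(f"{tag:<{width}}{aln.pk_lines[pk_name]}")
    lines.append("//")
    return "\n".join(lines) + "\n"
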