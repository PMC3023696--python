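"""Weighted consensus annotation of an aligned RNA family.

Sequences are weighted by the GSC (Gerstein-Sonnhammer-Chothia) tree-based
scheme on a UPGMA guide tree, so that clusters of near-identical sequences
do not dominate the consensus.  Weighted frequencies then drive

* per-column conservation tiers — a specific nucleotide when its weighted
  frequency exceeds 75% (sub-tiers at 90% and 97%), else purine/pyrimidine
  (R/Y) at the same thresholds, else "nucleotide present" tiers at
  50/75/90/97%, else the position is not shown;
* per-pair covariation classes — *covarying* when two sequences form
  canonical pairs differing at both positions, *compatible* when they
  differ at one, *invariant* when only one pair type occurs, and no shading
  at all when non-canonical pairs exceed 10%;
* occurrence frequencies of modular sub-structures and the length range of
  variable-length regions.

All thresholds use strict inequality ("exceeds") and are adjustable.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .stockholm_io import AnnotatedAlignment, GAP_CHARS, StockholmError

DEFAULT_THRESHOLDS = (0.50, 0.75, 0.90, 0.97)

#: Watson-Crick plus G-U wobble pairs.
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

PURINES = ("A", "G")
PYRIMIDINES = ("C", "U")


# ---------------------------------------------------------------------------
# sequence weighting


@dataclass(frozen=True)
class SequenceWeights:
    """Non-negative per-sequence weights normalized to sum to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any():
            raise ValueError("negative sequence weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum()}, expected 1")

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, i):
        return self.weights[i]


def pairwise_identity_distances(aln: AnnotatedAlignment) -> np.ndarray:
    """Fractional-identity distance matrix between aligned rows.

    ``d(i, j) = 1 - matches / shared`` where *shared* counts columns in
    which both rows are non-gap and *matches* counts shared columns with
    identical characters.  Rows with no shared columns are at distance 1.
    """
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    gap = np.array([c.encode() for c in GAP_CHARS])
    nongap = [~np.isin(r, gap) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = int(both.sum())
            if shared == 0:
                dij = 1.0
            else:
                matches = int((rows[i][both] == rows[j][both]).sum())
                dij = 1.0 - matches / shared
            d[i, j] = d[j, i] = dij
    return d


@dataclass
class GuideTreeNode:
    """Node of a rooted ultrametric guide tree."""

    height: float
    children: list["GuideTreeNode"] = field(default_factory=list)
    leaf: int | None = None

    @property
    def n_leaves(self) -> int:
        if self.leaf is not None:
            return 1
        return sum(c.n_leaves for c in self.children)

    def leaves(self) -> list[int]:
        if self.leaf is not None:
            return [self.leaf]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def upgma_tree(distances: np.ndarray) -> GuideTreeNode:
    """Build a rooted UPGMA guide tree from a symmetric distance matrix.

    Average linkage with cluster-size weighting; ties are broken by merging
    the lexicographically smallest pair of cluster indices (clusters are
    numbered in creation order, leaves first), which makes the tree — and
    hence the GSC weights — deterministic.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    nodes: dict[int, GuideTreeNode] = {
        i: GuideTreeNode(height=0.0, leaf=i) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = min(
            ((dist[(i, j)], (i, j)) for k, i in enumerate(active) for j in active[k + 1 :]),
            key=lambda t: (t[0], t[1]),
        )
        dij, (i, j) = best
        height = dij / 2.0
        merged = GuideTreeNode(height=height, children=[nodes[i], nodes[j]])
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / (
                sizes[i] + sizes[j]
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return nodes[active[0]]


def gsc_weights(
    distances: np.ndarray,
    tree_builder: Callable[[np.ndarray], GuideTreeNode] = upgma_tree,
) -> SequenceWeights:
    """GSC sequence weights from a guide tree over the distance matrix.

    Each tree edge's length is split evenly among the leaves below it; a
    leaf's raw weight is the sum of its shares along the path to the root.
    Weights are normalized to sum to 1; a degenerate tree of identical
    sequences (all edges zero) yields uniform weights.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n == 1:
        return SequenceWeights(np.array([1.0]))
    tree = tree_builder(d)
    raw = np.zeros(n)

    def visit(node: GuideTreeNode, acc: float) -> None:
        if node.leaf is not None:
            raw[node.leaf] = acc
            return
        for child in node.children:
            edge = node.height - child.height
            visit(child, acc + edge / child.n_leaves)

    visit(tree, 0.0)
    total = raw.sum()
    if total <= 0:
        raw = np.full(n, 1.0 / n)
    else:
        raw = raw / total
    return SequenceWeights(raw)


def alignment_weights(aln: AnnotatedAlignment) -> SequenceWeights:
    """Convenience: GSC weights straight from an alignment."""
    return gsc_weights(pairwise_identity_distances(aln))


# ---------------------------------------------------------------------------
# conservation tiers


@dataclass(frozen=True)
class ColumnConservation:
    """Conservation call for one alignment column.

    ``symbol`` is a specific nucleotide (``A/C/G/U``), a degenerate class
    (``R`` purine / ``Y`` pyrimidine), ``"present"`` (only the presence of
    a nucleotide is conserved) or ``"absent"`` (position not shown).
    ``identity_tier`` / ``presence_tier`` give the highest percent
    threshold strictly exceeded, or ``None``.
    """

    symbol: str
    identity_tier: int | None = None
    presence_tier: int | None = None

    def __post_init__(self) -> None:
        if self.symbol not in {"A", "C", "G", "U", "R", "Y", "present", "absent"}:
            raise ValueError(f"bad symbol {self.symbol!r}")
        if self.identity_tier is not None and self.symbol in {"present", "absent"}:
            raise ValueError("identity tier requires a nucleotide or R/Y symbol")
        if self.symbol == "absent" and self.presence_tier is not None:
            raise ValueError("absent column cannot carry a presence tier")

    @property
    def shown(self) -> bool:
        return self.symbol != "absent"


def _column_freqs(
    aln: AnnotatedAlignment, weights: SequenceWeights, col: int
) -> tuple[dict[str, float], float]:
    """Weighted identity frequencies among non-gap rows, and presence."""
    w = weights.weights
    chars = [row[col] for row in aln.rows]
    nongap = np.array([c not in GAP_CHARS for c in chars])
    presence = float(w[nongap].sum())
    freqs = {c: 0.0 for c in "ACGURYN"}
    if presence > 0:
        for wi, c, ng in zip(w, chars, nongap):
            if ng:
                freqs[c] += wi / presence
    return freqs, presence


def _tier(freq: float, cuts: Sequence[float], labels: Sequence[int]) -> int | None:
    best = None
    for cut, label in zip(cuts, labels):
        if freq > cut:
            best = label
    return best


def column_conservation(
    aln: AnnotatedAlignment,
    weights: SequenceWeights,
    col: int,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ColumnConservation:
    """Classify one column's conservation (strict-inequality cascade).

    ``thresholds`` is ``(t50, t75, t90, t97)``: ``t50`` gates whether the
    position is shown at all; the other three are the identity/presence
    sub-tiers.  Identity frequencies are taken among non-gap rows; presence
    is the weighted non-gap fraction over all rows.
    """
    if not 0 <= col < aln.n_cols:
        raise IndexError(f"column {col} out of range")
    t50, t75, t90, t97 = thresholds
    freqs, presence = _column_freqs(aln, weights, col)
    if presence > 0:
        best_nt = max("ACGU", key=lambda c: freqs[c])
        if freqs[best_nt] > t75:
            return ColumnConservation(
                best_nt,
                identity_tier=_tier(freqs[best_nt], (t75, t90, t97), (75, 90, 97)),
                presence_tier=_tier(presence, (t50, t75, t90, t97), (50, 75, 90, 97)),
            )
        # R counts toward purines, Y toward pyrimidines; N toward neither
        pur = sum(freqs[c] for c in PURINES) + freqs["R"]
        pyr = sum(freqs[c] for c in PYRIMIDINES) + freqs["Y"]
        degen, dfreq = ("R", pur) if pur >= pyr else ("Y", pyr)
        if dfreq > t75:
            return ColumnConservation(
                degen,
                identity_tier=_tier(dfreq, (t75, t90, t97), (75, 90, 97)),
                presence_tier=_tier(presence, (t50, t75, t90, t97), (50, 75, 90, 97)),
            )
    ptier = _tier(presence, (t50, t75, t90, t97), (50, 75, 90, 97))
    if ptier is None:
        return ColumnConservation("absent")
    return ColumnConservation("present", presence_tier=ptier)


# ---------------------------------------------------------------------------
# covariation classes


class PairClass(enum.Enum):
    """Covariation class of a predicted base pair."""

    COVARYING = "covarying"
    COMPATIBLE = "compatible"
    INVARIANT = "invariant"
    UNSHADED = "unshaded"


def classify_pair(
    aln: AnnotatedAlignment,
    weights: SequenceWeights,
    left: int,
    right: int,
    noncanonical_cutoff: float = 0.10,
) -> PairClass:
    """Classify the covariation evidence for an annotated pair of columns.

    A row is canonical when its two characters form a Watson-Crick or G-U
    pair (a gap at either position is non-canonical).  If the weighted
    non-canonical frequency strictly exceeds ``noncanonical_cutoff`` the
    pair is unshaded.  Otherwise, among the canonical rows: two observed
    pair types differing at both positions → covarying; differing at
    exactly one → compatible; a single type → invariant.
    """
    annotated = set(aln.pairs())
    for name in aln.pk_lines:
        annotated.update(aln.pk_pairs(name))
    if (left, right) not in annotated:
        raise StockholmError(f"columns ({left},{right}) are not an annotated pair")

    w = weights.weights
    noncanon = 0.0
    observed: dict[str, float] = {}
    for wi, row in zip(w, aln.rows):
        duo = row[left] + row[right]
        if duo in CANONICAL_PAIRS:
            observed[duo] = observed.get(duo, 0.0) + wi
        else:
            noncanon += wi
    if noncanon > noncanonical_cutoff:
        return PairClass.UNSHADED
    types = sorted(observed)
    best = PairClass.INVARIANT
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            ndiff = (a[0] != b[0]) + (a[1] != b[1])
            if ndiff == 2:
                return PairClass.COVARYING
            if ndiff == 1:
                best = PairClass.COMPATIBLE
    return best


# ---------------------------------------------------------------------------
# modular structures and variable-length regions


_PRED_TOKEN = re.compile(r"\(|\)|\S+")


def compile_predicate(
    expr: str, aln: AnnotatedAlignment
) -> Callable[[int], bool]:
    """Compile a membership predicate over alignment rows.

    Grammar (whitespace-tokenized, shortest-first precedence ``not`` >
    ``and`` > ``or``, parentheses allowed)::

        name:<regex>            sequence name matches the regex
        col:<label>=<chars>     row character at the labeled column is one
                                of <chars> ('-' matches any gap)

    Returns a function of the row index.  Referencing an unknown label is
    an error at compile time.
    """
    tokens = _PRED_TOKEN.findall(expr)

    def atom(tok: str) -> Callable[[int], bool]:
        if tok.startswith("name:"):
            rx = re.compile(tok[len("name:") :])
            return lambda i: bool(rx.search(aln.seq_names[i]))
        if tok.startswith("col:"):
            body = tok[len("col:") :]
            if "=" not in body:
                raise StockholmError(f"malformed column test {tok!r}")
            label, charset = body.split("=", 1)
            col = aln.resolve_label(label)
            chars = set(charset.upper().replace("T", "U"))
            if "-" in chars:
                chars |= GAP_CHARS
            return lambda i: aln.rows[i][col] in chars
        raise StockholmError(f"unknown predicate atom {tok!r}")

    pos = 0

    def parse_or() -> Callable[[int], bool]:
        nonlocal pos
        left = parse_and()
        while pos < len(tokens) and tokens[pos] == "or":
            pos += 1
            right = parse_and()
            left = (lambda a, b: lambda i: a(i) or b(i))(left, right)
        return left

    def parse_and() -> Callable[[int], bool]:
        nonlocal pos
        left = parse_not()
        while pos < len(tokens) and tokens[pos] == "and":
            pos += 1
            right = parse_not()
            left = (lambda a, b: lambda i: a(i) and b(i))(left, right)
        return left

    def parse_not() -> Callable[[int], bool]:
        nonlocal pos
        if pos < len(tokens) and tokens[pos] == "not":
            pos += 1
            inner = parse_not()
            return lambda i: not inner(i)
        return parse_atom()

    def parse_atom() -> Callable[[int], bool]:
        nonlocal pos
        if pos >= len(tokens):
            raise StockholmError(f"truncated predicate {expr!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            inner = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise StockholmError(f"unbalanced parentheses in {expr!r}")
            pos += 1
            return inner
        pos += 1
        return atom(tok)

    fn = parse_or()
    if pos != len(tokens):
        raise StockholmError(f"trailing tokens in predicate {expr!r}")
    return fn


def modular_frequency(
    aln: AnnotatedAlignment,
    weights: SequenceWeights,
    predicate: Callable[[int], bool] | str,
) -> float:
    """Weighted fraction of rows satisfying a membership predicate.

    ``predicate`` is either a callable of the row index or a predicate
    expression (see :func:`compile_predicate`).  For display the fraction
    is rounded to a whole percent (:func:`format_percent`).
    """
    if isinstance(predicate, str):
        predicate = compile_predicate(predicate, aln)
    return float(
        sum(wi for i, wi in enumerate(weights.weights) if predicate(i))
    )


def format_percent(fraction: float) -> str:
    return f"{round(fraction * 100):d}%"


def var_region_range(
    aln: AnnotatedAlignment, columns: tuple[int, int]
) -> tuple[int, int]:
    """(min, max) count of non-gap characters per row over a column range.

    ``columns`` is half-open ``(start, stop)``.  Rendered via
    :func:`format_nt_range` as ``"m-M nt"`` (or ``"m nt"`` when m = M).
    """
    start, stop = columns
    if stop <= start:
        raise ValueError("empty column range")
    counts = [
        sum(1 for c in row[start:stop] if c not in GAP_CHARS) for row in aln.rows
    ]
    return min(counts), max(counts)


def format_nt_range(lo: int, hi: int) -> str:
    return f"{lo} nt" if lo == hi else f"{lo}-{hi} nt"


# ---------------------------------------------------------------------------
# whole-alignment annotation


@dataclass
class ConsensusAnnotation:
    """Conservation and covariation annotation for a whole alignment."""

    columns: list[ColumnConservation]
    pair_classes: dict[tuple[int, int], PairClass]

    def to_tsv(self) -> str:
        """Per-column tier/class table (one row per column)."""
        partner: dict[int, tuple[int, PairClass]] = {}
        for (l, r), klass in self.pair_classes.items():
            partner[l] = (r, klass)
            partner[r] = (l, klass)
        lines = ["col\tsymbol\tidentity_tier\tpresence_tier\tpartner\tpair_class"]
        for col, cc in enumerate(self.columns):
            p = partner.get(col)
            lines.append(
                "\t".join(
                    [
                        str(col),
                        cc.symbol,
                        str(cc.identity_tier or ""),
                        str(cc.presence_tier or ""),
                        str(p[0]) if p else "",
                        p[1].value if p else "",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def annotate_alignment(
    aln: AnnotatedAlignment,
    weights: SequenceWeights | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    noncanonical_cutoff: float = 0.10,
) -> ConsensusAnnotation:
    """Compute the full consensus annotation for an alignment."""
    if weights is None:
        weights = alignment_weights(aln)
    columns = [
        column_conservation(aln, weights, c, thresholds) for c in range(aln.n_cols)
    ]
    pair_classes: dict[tuple[int, int], PairClass] = {}
    for l, r in aln.pairs():
        pair_classes[(l, r)] = classify_pair(
            aln, weights, l, r, noncanonical_cutoff
        )
    for name in aln.pk_lines:
        for l, r in aln.pk_pairs(name):
            pair_classes[(l, r)] = classify_pair(
                aln, weights, l, r, noncanonical_cutoff
            )
    return ConsensusAnnotation(columns=columns, pair_classes=pair_classes)
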