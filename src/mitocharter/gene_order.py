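"""Signed circular gene-order comparison.

A mitogenome's gene arrangement is a signed circular permutation: each
gene token carries an orientation (+ for the heavy strand, - for the
light strand) and the circle has no preferred origin or reading
direction. Two orders are therefore compared up to rotation and up to
reflection-with-sign-flip.

Provided analyses: canonical normalization, order equality, breakpoint
distance (signed adjacencies of one order not conserved, directly or
inverted, in the other), maximal conserved blocks, and a bounded
breadth-first search for a shortest script of reversals / block swaps
turning one order into another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .model import MitoAnnotation, PCG_TOKENS, RRNA_TOKENS

__all__ = [
    "SignedGeneOrder", "RearrangementOp", "extract_order", "normalize",
    "same_order", "breakpoint_count", "shared_blocks",
    "explain_rearrangement", "apply_op", "SUBSETS",
]

SUBSETS = {
    "pcg": set(PCG_TOKENS),
    "pcg+rrna": set(PCG_TOKENS) | set(RRNA_TOKENS),
    "all": None,  # no filtering
}

Signed = tuple[str, int]  # (gene token, +1 | -1)


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular list of (gene, orientation) pairs.

    The stored tuple is one linear representative of the circular
    equivalence class; use :func:`normalize` for a canonical one.
    """

    genes: tuple[Signed, ...]
    subset: str = "custom"

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene order must be non-empty")
        tokens = [g for g, _ in self.genes]
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate gene tokens in order")
        for g, s in self.genes:
            if s not in (1, -1):
                raise ValueError(f"{g}: orientation must be +1 or -1")

    def __len__(self):
        return len(self.genes)

    def tokens(self) -> set[str]:
        return {g for g, _ in self.genes}

    def rotate(self, k: int) -> "SignedGeneOrder":
        k %= len(self.genes)
        return SignedGeneOrder(self.genes[k:] + self.genes[:k], self.subset)

    def reflect(self) -> "SignedGeneOrder":
        """Read the circle in the other direction: reverse and flip signs."""
        return SignedGeneOrder(tuple((g, -s) for g, s in reversed(self.genes)),
                               self.subset)

    def restrict(self, keep: set[str]) -> "SignedGeneOrder":
        kept = tuple(p for p in self.genes if p[0] in keep)
        if not kept:
            raise ValueError("restriction leaves no genes")
        return SignedGeneOrder(kept, self.subset)

    def __str__(self):
        return " ".join(f"{'-' if s < 0 else ''}{g}" for g, s in self.genes)


def extract_order(annotation: MitoAnnotation,
                  subset: Union[str, Iterable[str]] = "pcg+rrna"
                  ) -> SignedGeneOrder:
    """Gene order of an annotation: genes by start position, orientation
    + for strand H and - for L. ``subset`` is "pcg", "pcg+rrna", "all"
    or an explicit set of tokens."""
    if isinstance(subset, str):
        if subset not in SUBSETS:
            raise ValueError(f"unknown subset {subset!r}")
        keep = SUBSETS[subset]
        label = subset
    else:
        keep, label = set(subset), "custom"
    genes = tuple((f.name, 1 if f.strand == "H" else -1)
                  for f in annotation.features
                  if keep is None or f.name in keep)
    if not genes:
        raise ValueError(f"subset {label!r} matches no feature")
    return SignedGeneOrder(genes, label)


def normalize(order: SignedGeneOrder, anchor: str = "cox1") -> SignedGeneOrder:
    """Canonical representative of the circular equivalence class.

    The order is rotated so ``anchor`` comes first; if the anchor is on
    the - strand the circle is first reflected (reverse + sign flip) so
    the anchor reads +. All 2n linear representatives of a circular
    order normalize to the same result.
    """
    tokens = [g for g, _ in order.genes]
    if anchor not in tokens:
        raise ValueError(f"anchor {anchor!r} not in order; available: "
                         f"{sorted(tokens)}")
    idx = tokens.index(anchor)
    if order.genes[idx][1] < 0:
        order = order.reflect()
        tokens = [g for g, _ in order.genes]
        idx = tokens.index(anchor)
    return order.rotate(idx)


def _canonical_key(order: SignedGeneOrder) -> tuple:
    return normalize(order, anchor=min(order.tokens())).genes


def _common(o1: SignedGeneOrder, o2: SignedGeneOrder
            ) -> tuple[SignedGeneOrder, SignedGeneOrder]:
    common = o1.tokens() & o2.tokens()
    if common == o1.tokens() and common == o2.tokens():
        return o1, o2
    if not common:
        raise ValueError("orders share no genes")
    return o1.restrict(common), o2.restrict(common)


def same_order(o1: SignedGeneOrder, o2: SignedGeneOrder) -> bool:
    """True iff the two circular signed orders are equal up to rotation
    and reflection-with-sign-flip (intersecting to common genes first)."""
    a, b = _common(o1, o2)
    if len(a) != len(b):
        return False
    return _canonical_key(a) == _canonical_key(b)


def _adjacencies(order: SignedGeneOrder) -> set[tuple[Signed, Signed]]:
    n = len(order.genes)
    out = set()
    for i in range(n):
        a = order.genes[i]
        b = order.genes[(i + 1) % n]
        out.add((a, b))
    return out


def _conserved(adj: tuple[Signed, Signed],
               other: set[tuple[Signed, Signed]]) -> bool:
    (ga, sa), (gb, sb) = adj
    return adj in other or ((gb, -sb), (ga, -sa)) in other


def breakpoint_count(o1: SignedGeneOrder, o2: SignedGeneOrder) -> int:
    """Number of signed circular adjacencies of o1 not conserved in o2.

    An adjacency (a, b) is conserved if o2 contains (a, b) or its
    reading-direction mirror (-b, -a). Symmetric; zero iff same_order;
    invariant under rotation/reflection of either argument.
    """
    a, b = _common(o1, o2)
    if len(a) < 2:
        raise ValueError("breakpoint distance needs >= 2 common genes")
    other = _adjacencies(b)
    return sum(0 if _conserved(adj, other) else 1
               for adj in ((a.genes[i], a.genes[(i + 1) % len(a)])
                           for i in range(len(a))))


@dataclass(frozen=True)
class Block:
    """A maximal run of genes contiguous in both orders."""
    genes: tuple[Signed, ...]   # as they appear in the first order
    reversed_in_other: bool


def shared_blocks(o1: SignedGeneOrder, o2: SignedGeneOrder) -> list[Block]:
    """Partition the common genes into maximal conserved blocks.

    A block is a run of genes that appears contiguously in both circular
    orders, either with identical order and signs or exactly inverted
    (reversed order, flipped signs). Blocks are reported in o1 order;
    the orientation tag is relative to o2's representation.
    """
    a, b = _common(o1, o2)
    n = len(a)
    other = _adjacencies(b)
    if n == 1:
        (g, s1), = a.genes
        s2 = dict(b.genes)[g]
        return [Block(genes=a.genes, reversed_in_other=s1 != s2)]
    conserved = [
        _conserved((a.genes[i], a.genes[(i + 1) % n]), other)
        for i in range(n)
    ]  # conserved[i]: adjacency between position i and i+1 survives
    if all(conserved):
        return [Block(genes=a.genes, reversed_in_other=False)]
    # cut the circle at the first breakpoint, then split linearly
    start = (conserved.index(False) + 1) % n
    ring = a.genes[start:] + a.genes[:start]
    cons = conserved[start:] + conserved[:start]  # cons[i]: ring[i]-ring[i+1]
    blocks, run = [], [ring[0]]
    for i in range(1, n):
        if cons[i - 1]:
            run.append(ring[i])
        else:
            blocks.append(tuple(run))
            run = [ring[i]]
    blocks.append(tuple(run))
    sign_in_b = dict(b.genes)
    out = []
    for blk in blocks:
        g0, s0 = blk[0]
        out.append(Block(genes=blk, reversed_in_other=sign_in_b[g0] != s0))
    return out


# --------------------------------------------------------------------------
# Rearrangement operations and bounded search

@dataclass(frozen=True)
class RearrangementOp:
    """A reversal of one segment or a swap of two disjoint segments.

    Segments are index ranges (inclusive) into a linear representative
    of the order. A reversal flips the orientation of every gene in the
    segment; a block swap exchanges the two segments, leaving the genes
    between them in place.
    """

    kind: str                      # "reversal" | "block-swap"
    segment: tuple[int, int]
    segment2: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.kind not in ("reversal", "block-swap"):
            raise ValueError(f"unknown op kind {self.kind!r}")
        i, j = self.segment
        if i > j:
            raise ValueError("segment start exceeds end")
        if self.kind == "block-swap":
            if self.segment2 is None:
                raise ValueError("block-swap needs two segments")
            k, l = self.segment2
            if k > l:
                raise ValueError("segment start exceeds end")
            if not (j < k or l < i):
                raise ValueError("block-swap segments overlap")


def apply_op(order: SignedGeneOrder, op: RearrangementOp) -> SignedGeneOrder:
    """Apply a rearrangement to a linear representative of the order."""
    genes = list(order.genes)
    n = len(genes)
    i, j = op.segment
    if not (0 <= i <= j < n):
        raise ValueError(f"segment {op.segment} out of bounds for n={n}")
    if op.kind == "reversal":
        genes[i:j + 1] = [(g, -s) for g, s in reversed(genes[i:j + 1])]
        return SignedGeneOrder(tuple(genes), order.subset)
    k, l = op.segment2
    if not (0 <= k <= l < n):
        raise ValueError(f"segment {op.segment2} out of bounds for n={n}")
    if l < i:  # store segments left-to-right
        (i, j), (k, l) = (k, l), (i, j)
    new = genes[:i] + genes[k:l + 1] + genes[j + 1:k] + genes[i:j + 1] + genes[l + 1:]
    return SignedGeneOrder(tuple(new), order.subset)


def _invert_op(op: RearrangementOp) -> RearrangementOp:
    """The op undoing ``op`` (indices valid on the op's output)."""
    if op.kind == "reversal":
        return op
    (i, j), (k, l) = sorted([op.segment, op.segment2])
    return RearrangementOp("block-swap", (i, i + l - k), (i + l - j, l))


def _enumerate_ops(n: int):
    """All candidate ops in deterministic order (reversals first)."""
    for i in range(n):
        for j in range(i, n):
            if i == 0 and j == n - 1:
                continue  # full-circle reversal == reflection == identity
            yield RearrangementOp("reversal", (i, j))
    for i in range(n):
        for j in range(i, n):
            for k in range(j + 1, n):
                for l in range(k, n):
                    yield RearrangementOp("block-swap", (i, j), (k, l))


def explain_rearrangement(o1: SignedGeneOrder, o2: SignedGeneOrder,
                          max_ops: int = 2
                          ) -> Optional[list[RearrangementOp]]:
    """Shortest script of <= max_ops reversals / block swaps turning o1
    into o2 (as circular orders), or None if none exists within the
    bound.

    Bidirectional breadth-first search with deterministic tie-breaking:
    ops are enumerated in sorted index order and the first hit at the
    smallest script length wins.
    """
    if max_ops < 0 or max_ops > 3:
        raise ValueError("max_ops must be in [0, 3]")
    a, b = _common(o1, o2)
    if a.tokens() != b.tokens():
        raise ValueError("orders must share their gene set")
    if same_order(a, b):
        return []
    if max_ops == 0:
        return None
    target_key = _canonical_key(b)

    # depth 1: single op on o1 (lazy scan: stop at the first hit)
    ops: list[RearrangementOp] = []
    for op in _enumerate_ops(len(a)):
        ops.append(op)
        if _canonical_key(apply_op(a, op)) == target_key:
            return [op]
    if max_ops == 1:
        return None

    def _verify(script: list[RearrangementOp]) -> bool:
        state = a
        for op in script:
            state = apply_op(state, op)
        return _canonical_key(state) == target_key

    # one backward step: states one op away from o2, with the undoing op.
    # Op indices bind to a linear representative, so every meet found via
    # canonical keys is re-verified by applying the full script to o1.
    backward: dict[tuple, list[RearrangementOp]] = {}
    for op in ops:
        key = _canonical_key(apply_op(b, op))
        backward.setdefault(key, [_invert_op(op)])

    def _finish(head: list[RearrangementOp],
                state: SignedGeneOrder,
                tail: list[RearrangementOp]) -> Optional[list[RearrangementOp]]:
        if _verify(head + tail):
            return head + tail
        # the meet was found on a different linear representative;
        # complete with a fresh one-op search from this state
        for op in ops:
            if _canonical_key(apply_op(state, op)) == target_key:
                return head + [op]
        return None

    # depth 2: forward one op, meet the backward map
    fw1 = []
    for op in ops:
        state = apply_op(a, op)
        fw1.append((op, state))
        tail = backward.get(_canonical_key(state))
        if tail is not None:
            found = _finish([op], state, tail)
            if found:
                return found
    if max_ops == 2:
        return None

    # depth 3: forward two ops, meet the backward map
    for op1, state1 in fw1:
        for op2 in ops:
            state2 = apply_op(state1, op2)
            tail = backward.get(_canonical_key(state2))
            if tail is not None:
                found = _finish([op1, op2], state2, tail)
                if found:
                    return found
    return None
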