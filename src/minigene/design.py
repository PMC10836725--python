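"""Minigene antigen-library design.

Proteins are tiled into overlapping fragments ("minigenes") so that every
residue — and every peptide epitope shorter than the overlap — is contained
intact in at least one fragment.  Programmed substitutions (e.g. Q->E
deamidation edits that create celiac-disease epitopes) are applied in source
coordinates before tiling.  Fragments are assembled into expression
constructs, optionally fused N-terminally to a processing-enhancing leader
sequence and joined by flexible linkers.  Positive fragments are refined
hierarchically into progressively smaller intervals until the minimal
epitope-containing region is localized by interval intersection.

All coordinates are 1-based and inclusive: the fragment labelled
``612-1011`` has length 400.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import (
    InconsistentEpitopes,
    InvalidConfigError,
    InvalidInputError,
    NoPositiveFragments,
    ProvenanceError,
    RefinementExhausted,
)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _check_aa(seq: str, what: str, allow_empty: bool = False) -> None:
    if not seq and not allow_empty:
        raise InvalidInputError(f"{what} must be non-empty")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise InvalidInputError(
            f"{what} contains characters outside the 20-letter amino-acid "
            f"alphabet: {sorted(bad)}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A source protein: id, 20-letter amino-acid sequence, description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        _check_aa(self.sequence, f"protein {self.id!r} sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentSpec:
    """A contiguous interval of a source protein, 1-based inclusive.

    ``sequence`` must equal the source subsequence at ``[start, end]``;
    :func:`fragment_from_interval` derives it and is the preferred
    constructor.
    """

    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InvalidInputError(
                f"invalid interval [{self.start}, {self.end}] (1-based inclusive)"
            )
        _check_aa(self.sequence, f"fragment {self.name} sequence")
        if len(self.sequence) != self.end - self.start + 1:
            raise InvalidInputError(
                f"fragment {self.name}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start + 1}"
            )

    @property
    def name(self) -> str:
        return f"{self.source_id}_{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start + 1


def fragment_from_interval(protein: ProteinRecord, start: int, end: int) -> FragmentSpec:
    """Slice ``protein`` at the 1-based inclusive interval ``[start, end]``."""
    if not (1 <= start <= end <= len(protein)):
        raise InvalidInputError(
            f"interval [{start}, {end}] outside protein {protein.id!r} "
            f"of length {len(protein)}"
        )
    return FragmentSpec(
        source_id=protein.id,
        start=start,
        end=end,
        sequence=protein.sequence[start - 1 : end],
    )


@dataclass(frozen=True)
class SubstitutionSpec:
    """A single programmed point substitution in source coordinates."""

    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InvalidInputError("substitution position must be >= 1")
        for aa, what in ((self.from_aa, "from_aa"), (self.to_aa, "to_aa")):
            if len(aa) != 1 or aa not in AA_ALPHABET:
                raise InvalidInputError(f"{what} must be a single amino-acid letter")


@dataclass(frozen=True)
class ConstructSpec:
    """An assembled expression construct: optional N-terminal leader,
    fragments joined by a (possibly empty) flexible linker."""

    construct_id: str
    fragments: tuple[FragmentSpec, ...]
    linker: str
    assembled_sequence: str
    leader_id: Optional[str] = None
    leader_sequence: str = ""

    def __len__(self) -> int:
        return len(self.assembled_sequence)


@dataclass
class RefinementNode:
    """A fragment in the hierarchical refinement tree.

    Children are strictly contained in their parent's interval and sit one
    level deeper; ``outcome`` records the screen result for the fragment.
    """

    fragment: FragmentSpec
    parent: Optional["RefinementNode"] = None
    level: int = 0
    outcome: str = "untested"

    _OUTCOMES = ("untested", "positive", "negative")

    def __post_init__(self) -> None:
        if self.outcome not in self._OUTCOMES:
            raise InvalidInputError(f"outcome must be one of {self._OUTCOMES}")
        if self.parent is not None:
            p = self.parent.fragment
            c = self.fragment
            strictly_inside = (p.start <= c.start and c.end <= p.end
                               and (c.start, c.end) != (p.start, p.end))
            if not strictly_inside:
                raise InvalidInputError(
                    f"child interval [{c.start},{c.end}] not strictly contained "
                    f"in parent [{p.start},{p.end}]"
                )
            if self.level != self.parent.level + 1:
                raise InvalidInputError("child level must be parent level + 1")


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def n_tiles(length: int, window: int, min_overlap: int) -> int:
    """Closed-form minimum number of fragments of length <= ``window``
    covering ``length`` residues with adjacent overlap >= ``min_overlap``."""
    if length <= window:
        return 1
    return math.ceil((length - window) / (window - min_overlap)) + 1


def tile_intervals(length: int, window: int, min_overlap: int) -> list[tuple[int, int]]:
    """1-based inclusive tiling intervals over ``[1, length]``.

    Uses the minimum fragment count; when the leftover does not divide evenly
    across junctions the extra overlap is spread as evenly as possible
    (larger steps first), which is deterministic.
    """
    if window < 1:
        raise InvalidConfigError("window must be >= 1")
    if not (0 < min_overlap < window):
        raise InvalidConfigError(
            f"require 0 < min_overlap < window, got overlap={min_overlap}, "
            f"window={window}"
        )
    if length < 1:
        raise InvalidInputError("cannot tile an empty sequence")
    n = n_tiles(length, window, min_overlap)
    if n == 1:
        return [(1, length)]
    # n-1 steps between fragment starts, summing to length - window, each
    # step in [1, window - min_overlap].
    total_step = length - window
    base, extra = divmod(total_step, n - 1)
    starts = [1]
    for junction in range(n - 1):
        step = base + (1 if junction < extra else 0)
        starts.append(starts[-1] + step)
    return [(s, s + window - 1) for s in starts]


def tile_protein(protein: ProteinRecord, window: int, min_overlap: int) -> list[FragmentSpec]:
    """Tile a protein into the minimum number of overlapping fragments.

    Fragments have length <= ``window``, adjacent fragments overlap by at
    least ``min_overlap`` residues (so any epitope up to ``min_overlap``
    residues long survives intact in at least one fragment), the first
    fragment starts at residue 1 and the last ends at the C terminus.
    """
    intervals = tile_intervals(len(protein), window, min_overlap)
    return [fragment_from_interval(protein, s, e) for s, e in intervals]


# ---------------------------------------------------------------------------
# Substitutions
# ---------------------------------------------------------------------------

def apply_substitutions(
    protein: ProteinRecord, subs: Sequence[SubstitutionSpec]
) -> ProteinRecord:
    """Apply programmed point substitutions, verifying provenance.

    Each substitution's ``from_aa`` must match the source residue at its
    position; duplicated positions are rejected.  Returns a new record whose
    sequence differs from the input exactly at the substituted positions.
    """
    positions = [s.position for s in subs]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise InvalidInputError(f"duplicate substitution positions: {dupes}")
    seq = list(protein.sequence)
    for sub in subs:
        if sub.position > len(seq):
            raise InvalidInputError(
                f"substitution position {sub.position} beyond protein length {len(seq)}"
            )
        actual = seq[sub.position - 1]
        if actual != sub.from_aa:
            raise ProvenanceError(
                f"position {sub.position} of {protein.id!r} is {actual!r}, "
                f"not {sub.from_aa!r}"
            )
        seq[sub.position - 1] = sub.to_aa
    return ProteinRecord(protein.id, "".join(seq), protein.description)


# ---------------------------------------------------------------------------
# Construct assembly
# ---------------------------------------------------------------------------

def assemble_construct(
    fragments: Sequence[FragmentSpec],
    leader: str = "",
    linker: str = "",
    construct_id: Optional[str] = None,
    leader_id: Optional[str] = None,
) -> ConstructSpec:
    """Assemble leader + fragment1 + linker + fragment2 + ...

    The leader (a processing-enhancing sequence, when used) goes at the N
    terminus; the linker appears only between fragments, never terminally.
    """
    if not fragments:
        raise InvalidInputError("assemble_construct requires at least one fragment")
    _check_aa(leader, "leader", allow_empty=True)
    _check_aa(linker, "linker", allow_empty=True)
    assembled = leader + linker.join(f.sequence for f in fragments)
    if construct_id is None:
        construct_id = "+".join(f.name for f in fragments)
        if leader_id:
            construct_id = f"{leader_id}-{construct_id}"
    return ConstructSpec(
        construct_id=construct_id,
        fragments=tuple(fragments),
        linker=linker,
        assembled_sequence=assembled,
        leader_id=leader_id,
        leader_sequence=leader,
    )


# ---------------------------------------------------------------------------
# Hierarchical refinement
# ---------------------------------------------------------------------------

def refine_fragment(
    parent: FragmentSpec | RefinementNode,
    n_children: int = 2,
    min_overlap: int = 15,
    min_length: int = 20,
) -> list[RefinementNode]:
    """Split a positive fragment into ``n_children`` smaller overlapping
    fragments for the next round of screening.

    The children tile the parent interval with window
    ``ceil((len + (n_children-1)*min_overlap) / n_children)`` and inherit
    source coordinates.  Raises :class:`RefinementExhausted` when children
    would fall below ``min_length`` (the caller stops recursing).
    """
    if n_children < 2:
        raise InvalidConfigError("n_children must be >= 2")
    node = parent if isinstance(parent, RefinementNode) else RefinementNode(parent)
    frag = node.fragment
    length = len(frag)
    if length <= min_length:
        raise RefinementExhausted(
            f"fragment {frag.name} (length {length}) is at or below "
            f"min_length {min_length}"
        )
    window = math.ceil((length + (n_children - 1) * min_overlap) / n_children)
    if window < min_length:
        raise RefinementExhausted(
            f"splitting {frag.name} into {n_children} would give windows of "
            f"{window} < min_length {min_length}"
        )
    if window >= length:
        raise RefinementExhausted(
            f"fragment {frag.name} too short to split into {n_children} "
            f"children with overlap {min_overlap}"
        )
    intervals = tile_intervals(length, window, min_overlap)
    children = []
    for s, e in intervals:
        sub = FragmentSpec(
            source_id=frag.source_id,
            start=frag.start + s - 1,
            end=frag.start + e - 1,
            sequence=frag.sequence[s - 1 : e],
        )
        children.append(RefinementNode(sub, parent=node, level=node.level + 1))
    return children


def epitope_interval(positive_nodes: Iterable[RefinementNode]) -> tuple[int, int]:
    """Localize the epitope as the intersection of positive intervals at the
    deepest tested level.

    An empty intersection signals inconsistent outcomes — most plausibly two
    distinct epitopes in the parent fragment — and raises
    :class:`InconsistentEpitopes`.
    """
    positives = [n for n in positive_nodes if n.outcome == "positive"]
    if not positives:
        raise NoPositiveFragments("no fragment tested positive")
    sources = {n.fragment.source_id for n in positives}
    if len(sources) > 1:
        raise InvalidInputError(
            f"positive fragments span multiple source proteins: {sorted(sources)}"
        )
    deepest = max(n.level for n in positives)
    at_depth = [n.fragment for n in positives if n.level == deepest]
    lo = max(f.start for f in at_depth)
    hi = min(f.end for f in at_depth)
    if lo > hi:
        raise InconsistentEpitopes(
            "positive fragments at the deepest level are disjoint; the parent "
            "likely carries multiple distinct epitopes"
        )
    return lo, hi
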