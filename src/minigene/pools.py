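"""Combinatorial pooled-array design with guaranteed deconvolution.

Targets are assigned to wells so that (i) every target appears in at least
``min_replicates`` wells, (ii) no well holds more than ``pool_size_max``
targets, and (iii) no two targets co-occur in more than one well.  Under
(i) with min_replicates >= 2 and (iii), well signatures (the set of wells
containing a target) are automatically pairwise distinct: two signatures of
size >= 2 that shared all wells would co-occur at least twice.  The pattern
of positive wells in a screen therefore uniquely identifies the responsible
target.

For min_replicates == 2 the problem is exactly embedding targets as
distinct edges of a simple graph on the wells with maximum degree
``pool_size_max``; such an embedding exists iff
``n_targets <= min(floor(n_wells * pool_size_max / 2), C(n_wells, 2))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleDesignError, InvalidInputError, PartialDesignError


@dataclass
class PoolDesign:
    """Assignment of ``n_targets`` targets (ids 0..n-1) to wells."""

    n_targets: int
    wells: list[frozenset[int]]
    pool_size_max: int
    min_replicates: int
    seed: int

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def signature(self, target_id: int) -> frozenset[int]:
        """The set of well indices containing ``target_id``."""
        if not (0 <= target_id < self.n_targets):
            raise InvalidInputError(
                f"target {target_id} outside 0..{self.n_targets - 1}"
            )
        return frozenset(w for w, pool in enumerate(self.wells) if target_id in pool)

    def signatures(self) -> list[frozenset[int]]:
        sigs: list[set[int]] = [set() for _ in range(self.n_targets)]
        for w, pool in enumerate(self.wells):
            for t in pool:
                sigs[t].add(w)
        return [frozenset(s) for s in sigs]


def signature(design: PoolDesign, target_id: int) -> frozenset[int]:
    """Module-level alias for :meth:`PoolDesign.signature`."""
    return design.signature(target_id)


# ---------------------------------------------------------------------------
# Feasibility
# ---------------------------------------------------------------------------

def max_feasible_targets(n_wells: int, pool_size_max: int, min_replicates: int) -> int:
    """Upper bound on the number of placeable targets.

    Slot counting gives floor(n_wells * pool_size_max / min_replicates);
    for min_replicates == 2 the graph correspondence tightens this with the
    C(n_wells, 2) distinct-edge bound (sharper bounds exist for r > 2 but
    signature distinctness there is enforced directly by the solver).
    """
    bound = (n_wells * pool_size_max) // min_replicates
    if min_replicates == 2:
        bound = min(bound, math.comb(n_wells, 2))
    return bound


def _check_feasibility(n_targets, n_wells, pool_size_max, min_replicates) -> None:
    if min_replicates < 1:
        raise InvalidInputError("min_replicates must be >= 1")
    if pool_size_max < 1 or n_wells < 1 or n_targets < 0:
        raise InvalidInputError("n_targets >= 0, n_wells >= 1, pool_size_max >= 1 required")
    if min_replicates > n_wells:
        raise InfeasibleDesignError(
            f"min_replicates={min_replicates} exceeds n_wells={n_wells}"
        )
    slots_needed = n_targets * min_replicates
    slots_available = n_wells * pool_size_max
    if slots_needed > slots_available:
        raise InfeasibleDesignError(
            f"needs {slots_needed} slots > {slots_available} available "
            f"({n_wells} wells x pool size {pool_size_max})"
        )
    if min_replicates == 2 and n_targets > math.comb(n_wells, 2):
        raise InfeasibleDesignError(
            f"{n_targets} targets exceed C({n_wells},2)="
            f"{math.comb(n_wells, 2)} distinct well pairs"
        )


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def design_pools(
    n_targets: int,
    n_wells: int,
    pool_size_max: int = 5,
    min_replicates: int = 2,
    seed: int = 0,
    node_budget: int = 2_000_000,
) -> PoolDesign:
    """Generate a pooled-array design satisfying all invariants.

    Deterministic per seed.  Raises :class:`InfeasibleDesignError` naming
    the violated bound when the parameters provably cannot work, and
    :class:`PartialDesignError` if the backtracking search exhausts its
    node budget (it never silently returns an invalid design).
    """
    _check_feasibility(n_targets, n_wells, pool_size_max, min_replicates)
    rng = np.random.default_rng(seed)
    load = [0] * n_wells
    # pair_used[u][v]: some target already occupies both wells u and v
    pair_used = [[False] * n_wells for _ in range(n_wells)]
    signatures: list[tuple[int, ...]] = []
    # Seeded tie-break order over wells, fixed for the whole search so the
    # DFS is deterministic.
    well_order = list(rng.permutation(n_wells))
    nodes = 0

    def candidate_subsets(r: int):
        """r-subsets of wells, least-loaded first, valid under the caps."""
        usable = [w for w in well_order if load[w] < pool_size_max]
        usable.sort(key=lambda w: (load[w], well_order.index(w)))
        for combo in itertools.combinations(usable, r):
            ok = True
            for u, v in itertools.combinations(combo, 2):
                if pair_used[u][v]:
                    ok = False
                    break
            if ok:
                yield combo

    def place(t: int) -> bool:
        nonlocal nodes
        if t == n_targets:
            return True
        for combo in candidate_subsets(min_replicates):
            nodes += 1
            if nodes > node_budget:
                raise PartialDesignError(
                    f"search budget exhausted after placing {t} of "
                    f"{n_targets} targets"
                )
            for w in combo:
                load[w] += 1
            for u, v in itertools.combinations(combo, 2):
                pair_used[u][v] = pair_used[v][u] = True
            signatures.append(combo)
            if place(t + 1):
                return True
            signatures.pop()
            for w in combo:
                load[w] -= 1
            for u, v in itertools.combinations(combo, 2):
                pair_used[u][v] = pair_used[v][u] = False
        return False

    if not place(0):
        raise InfeasibleDesignError(
            f"exhaustive search found no design for n_targets={n_targets}, "
            f"n_wells={n_wells}, pool_size_max={pool_size_max}, "
            f"min_replicates={min_replicates}"
        )

    wells: list[set[int]] = [set() for _ in range(n_wells)]
    for t, combo in enumerate(signatures):
        for w in combo:
            wells[w].add(t)
    return PoolDesign(
        n_targets=n_targets,
        wells=[frozenset(w) for w in wells],
        pool_size_max=pool_size_max,
        min_replicates=min_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Independent checker (shares no code with the solver)
# ---------------------------------------------------------------------------

@dataclass
class DesignReport:
    max_pair_cooccurrence: int
    min_observed_replicates: int
    n_unique_signatures: int
    max_pool_size: int

    def satisfies(self, design: PoolDesign) -> bool:
        return (
            self.max_pair_cooccurrence <= 1
            and self.min_observed_replicates >= design.min_replicates
            and self.n_unique_signatures == design.n_targets
            and self.max_pool_size <= design.pool_size_max
        )


def verify_design(design: PoolDesign) -> DesignReport:
    """Brute-force re-derivation of every design invariant.

    Enumerates all C(n_targets, 2) pairs and counts shared wells directly
    from the well contents, independent of how the design was built.
    """
    n = design.n_targets
    if n == 0:
        return DesignReport(0, 0, 0, max((len(p) for p in design.wells), default=0))
    membership = [
        tuple(w for w, pool in enumerate(design.wells) if t in pool) for t in range(n)
    ]
    max_cooc = 0
    for a, b in itertools.combinations(range(n), 2):
        shared = len(set(membership[a]) & set(membership[b]))
        max_cooc = max(max_cooc, shared)
    return DesignReport(
        max_pair_cooccurrence=max_cooc,
        min_observed_replicates=min(len(m) for m in membership),
        n_unique_signatures=len({frozenset(m) for m in membership}),
        max_pool_size=max((len(p) for p in design.wells), default=0),
    )


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

_PLATE_DIMS = {96: (8, 12), 384: (16, 24)}


def well_name(index: int, plate_format: int) -> str:
    """Row-major well coordinate (A1, A2, ... H12 on a 96-well plate)."""
    rows, cols = _PLATE_DIMS[plate_format]
    if not (0 <= index < rows * cols):
        raise InvalidInputError(f"well index {index} outside a {plate_format}-well plate")
    return f"{chr(ord('A') + index // cols)}{index % cols + 1}"


@dataclass
class PlateLayout:
    """Physical pipetting scheme for a pooled design.

    Each pool occupies ``technical_replicates`` consecutive assay wells in
    row-major order (pool i -> assay wells 2i, 2i+1 for duplicates,
    mirroring a 96-to-384-well split).  Masses: per-construct ng, per-well
    total in ug.
    """

    plate_format: int
    technical_replicates: int
    per_construct_mass_ng: float
    assignments: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.assignments)


def to_plate_layout(
    design: PoolDesign,
    per_construct_mass_ng: float = 65.0,
    plate_format: int = 96,
    technical_replicates: int = 1,
    target_names: list[str] | None = None,
) -> PlateLayout:
    """Export a design as a pipetting scheme on a 96- or 384-well plate."""
    if plate_format not in _PLATE_DIMS:
        raise InvalidInputError("plate_format must be 96 or 384")
    if technical_replicates < 1:
        raise InvalidInputError("technical_replicates must be >= 1")
    rows, cols = _PLATE_DIMS[plate_format]
    capacity = rows * cols
    needed = design.n_wells * technical_replicates
    if needed > capacity:
        raise InvalidInputError(
            f"{design.n_wells} pools x {technical_replicates} replicates = "
            f"{needed} wells exceed the {plate_format}-well plate"
        )
    if target_names is None:
        target_names = [f"target_{t}" for t in range(design.n_targets)]
    layout = PlateLayout(
        plate_format=plate_format,
        technical_replicates=technical_replicates,
        per_construct_mass_ng=per_construct_mass_ng,
    )
    for pool_idx, pool in enumerate(design.wells):
        constructs = sorted(pool)
        total_ug = per_construct_mass_ng * len(constructs) / 1000.0
        for rep in range(technical_replicates):
            idx = pool_idx * technical_replicates + rep
            layout.assignments.append(
                {
                    "well": well_name(idx, plate_format),
                    "pool_index": pool_idx,
                    "technical_replicate": rep + 1,
                    "construct_ids": ";".join(target_names[t] for t in constructs),
                    "n_constructs": len(constructs),
                    "mass_per_construct_ng": per_construct_mass_ng,
                    "total_mass_ug": total_ug,
                }
            )
    return layout
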