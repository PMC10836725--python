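"""Synthetic-screen generators.

Everything the analysis modules consume can be generated here with known
ground truth: random proteins for tiling and backtranslation, pooled-screen
well signals with a planted cognate target, log-normal flow-cytometry event
populations for Overton estimation, and microscopy-like well images with an
exact positive-area mask.  All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ProteinRecord
from .errors import InvalidConfigError, InvalidInputError
from .pools import PoolDesign
from .screen import WellReadout

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Random proteins
# ---------------------------------------------------------------------------

def random_protein(length: int, seed: int = 0, record_id: str | None = None) -> ProteinRecord:
    """A protein with residues uniform over the 20-letter alphabet."""
    if length < 1:
        raise InvalidInputError("protein length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AA_LETTERS), size=length)
    return ProteinRecord(
        id=record_id or f"synthetic_{length}aa_seed{seed}",
        sequence="".join(letters),
        description="synthetic random protein",
    )


# ---------------------------------------------------------------------------
# Pooled-screen signals
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Noise model for a simulated pooled screen.

    Wells whose pool contains a true target emit Normal(mu_pos, sigma)
    signals unless the pool drops out (probability ``dropout_rate``, e.g. a
    failed transduction, in which case all its technical replicates read as
    negative); all other wells emit Normal(mu_neg, sigma).  Signals are
    floored at zero.  A log-normal noise variant is available via
    ``lognormal=True`` (the configured mu/sigma then parameterize the
    underlying normal of log-signal).
    """

    design: PoolDesign
    true_targets: frozenset[int]
    mu_pos: float = 10.0
    mu_neg: float = 1.0
    sigma: float = 1.0
    dropout_rate: float = 0.0
    replicates: int = 2
    seed: int = 0
    lognormal: bool = False

    def __post_init__(self) -> None:
        self.true_targets = frozenset(self.true_targets)
        if not self.true_targets:
            raise InvalidConfigError("at least one true target required")
        for t in self.true_targets:
            if not (0 <= t < self.design.n_targets):
                raise InvalidConfigError(f"true target {t} not in design")
        if not (self.mu_pos > self.mu_neg >= 0):
            raise InvalidConfigError("require mu_pos > mu_neg >= 0")
        if not (0 <= self.dropout_rate <= 1):
            raise InvalidConfigError("dropout_rate must be in [0, 1]")
        if self.sigma < 0 or self.replicates < 1:
            raise InvalidConfigError("sigma >= 0 and replicates >= 1 required")


@dataclass
class ScreenTruth:
    """Ground truth serialized alongside simulated readouts."""

    true_targets: frozenset[int]
    signal_pools: frozenset[int]
    dropped_pools: frozenset[int]
    seed: int

    def to_dict(self) -> dict:
        return {
            "true_targets": sorted(self.true_targets),
            "signal_pools": sorted(self.signal_pools),
            "dropped_pools": sorted(self.dropped_pools),
            "seed": self.seed,
        }


def simulate_screen(cfg: ScreenSimConfig) -> tuple[list[WellReadout], ScreenTruth]:
    """Simulate per-well replicate signals for a pooled screen."""
    rng = np.random.default_rng(cfg.seed)
    signal_pools = {
        w
        for w, pool in enumerate(cfg.design.wells)
        if pool & cfg.true_targets
    }
    dropped = {w for w in sorted(signal_pools) if rng.random() < cfg.dropout_rate}
    readouts = []
    for pool_idx in range(cfg.design.n_wells):
        hot = pool_idx in signal_pools and pool_idx not in dropped
        mu = cfg.mu_pos if hot else cfg.mu_neg
        for rep in range(1, cfg.replicates + 1):
            raw = rng.normal(mu, cfg.sigma)
            signal = float(np.exp(raw)) if cfg.lognormal else max(0.0, float(raw))
            readouts.append(WellReadout(pool_index=pool_idx, replicate=rep, signal=signal))
    truth = ScreenTruth(
        true_targets=cfg.true_targets,
        signal_pools=frozenset(signal_pools),
        dropped_pools=frozenset(dropped),
        seed=cfg.seed,
    )
    return readouts, truth


# ---------------------------------------------------------------------------
# Flow-cytometry events
# ---------------------------------------------------------------------------

@dataclass
class FlowSimConfig:
    """Log-normal intensity mixture for Overton ground truth.

    Control events: exp(Normal(location, scale)).  Sample events: a
    ``shifted_fraction`` mixture drawn with ``shift`` added to the
    location, matching the log-scaled appearance of cytometry histograms.
    """

    n_events: int = 10_000
    location: float = 4.0
    scale: float = 0.5
    shifted_fraction: float = 0.5
    shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shifted_fraction <= 1.0):
            raise InvalidConfigError("shifted_fraction must be in [0, 1]")
        if self.n_events < 1 or self.scale <= 0:
            raise InvalidConfigError("n_events >= 1 and scale > 0 required")


def simulate_flow_events(cfg: FlowSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (sample, control) event vectors.

    For a large shift the Overton estimate on these populations converges
    to ``100 * shifted_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    control = np.exp(rng.normal(cfg.location, cfg.scale, size=cfg.n_events))
    n_shifted = rng.binomial(cfg.n_events, cfg.shifted_fraction)
    base = np.exp(rng.normal(cfg.location, cfg.scale, size=cfg.n_events - n_shifted))
    shifted = np.exp(rng.normal(cfg.location + cfg.shift, cfg.scale, size=n_shifted))
    sample = rng.permutation(np.concatenate([base, shifted]))
    return sample, control


# ---------------------------------------------------------------------------
# Well images
# ---------------------------------------------------------------------------

def simulate_well_image(
    n_rows: int,
    n_cols: int,
    n_cells: int,
    cell_radius: int,
    intensity: float = 100.0,
    background: float = 10.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """A microscopy-like well: non-overlapping bright discs on a flat
    background.  Returns (image, mask); the mask is the exact ground-truth
    positive area."""
    if n_rows < 1 or n_cols < 1:
        raise InvalidInputError("image must have >= 1 row and column")
    if n_cells < 0 or cell_radius < 1:
        raise InvalidInputError("n_cells >= 0 and cell_radius >= 1 required")
    rng = np.random.default_rng(seed)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise InvalidConfigError(
                f"could not place {n_cells} non-overlapping discs of radius "
                f"{cell_radius} on a {n_rows}x{n_cols} field"
            )
        cy = int(rng.integers(cell_radius, n_rows - cell_radius)) if n_rows > 2 * cell_radius else n_rows // 2
        cx = int(rng.integers(cell_radius, n_cols - cell_radius)) if n_cols > 2 * cell_radius else n_cols // 2
        if any((cy - oy) ** 2 + (cx - ox) ** 2 <= (2 * cell_radius) ** 2 for oy, ox in centers):
            continue
        centers.append((cy, cx))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
    image = np.full((n_rows, n_cols), float(background))
    image[mask] += intensity
    return image, mask
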