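"""Constrained codon-optimized backtranslation.

Converts amino-acid sequences into synthesizable DNA coding sequences by
seeded weighted sampling of codons proportional to a usage table, followed
by a localized repair loop that eliminates forbidden motifs (restriction
sites, on either strand), homopolymer stretches, and sliding-window GC or
pyrimidine content outside configured bounds.  AT-rich stretches are
excluded by the lower GC bound.  Output is deterministic for a fixed seed
and always round-trips to the input protein under the standard genetic code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np

from .design import AA_ALPHABET, ProteinRecord, _check_aa
from .errors import InvalidConfigError, InvalidInputError, UnsatisfiableConstraints

# Standard genetic code (DNA codons); '*' marks stop codons.
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(
    (b1, b2, b3) for b1 in _BASES for b2 in _BASES for b3 in _BASES
):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA_TABLE[_i]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a DNA coding sequence with the standard genetic code.

    Minigene ORFs are fused in frame to a downstream reporter, so an
    internal stop codon is an error rather than a terminator.
    """
    if len(dna) % 3 != 0:
        raise InvalidInputError(f"DNA length {len(dna)} not divisible by 3")
    dna = dna.upper()
    bad = set(dna) - set("ACGT")
    if bad:
        raise InvalidInputError(f"non-ACGT characters in DNA: {sorted(bad)}")
    out = []
    for i in range(0, len(dna), 3):
        aa = GENETIC_CODE[dna[i : i + 3]]
        if aa == "*":
            raise InvalidInputError(f"internal stop codon at nucleotide {i + 1}")
        out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# Codon table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonTable:
    """Relative synonymous codon usage: codon -> (amino acid, fraction
    within its amino acid).  All 61 sense codons must be present and
    per-amino-acid fractions sum to 1."""

    organism: str
    entries: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        sense = {c for c, aa in GENETIC_CODE.items() if aa != "*"}
        if set(self.entries) != sense:
            missing = sorted(sense - set(self.entries))
            extra = sorted(set(self.entries) - sense)
            raise InvalidConfigError(
                f"codon table must contain exactly the 61 sense codons "
                f"(missing {missing}, unexpected {extra})"
            )
        sums: dict[str, float] = {}
        for codon, (aa, frac) in self.entries.items():
            if GENETIC_CODE[codon] != aa:
                raise InvalidConfigError(
                    f"codon {codon} assigned to {aa} but encodes {GENETIC_CODE[codon]}"
                )
            if frac < 0:
                raise InvalidConfigError(f"negative frequency for {codon}")
            sums[aa] = sums.get(aa, 0.0) + frac
        for aa, total in sums.items():
            if abs(total - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"frequencies for {aa} sum to {total}, not 1"
                )

    def codons_for(self, aa: str) -> list[tuple[str, float]]:
        """Synonymous codons of ``aa`` with their fractions, sorted by
        descending fraction then alphabetically (a stable preference order)."""
        items = [(c, f) for c, (a, f) in self.entries.items() if a == aa]
        return sorted(items, key=lambda cf: (-cf[1], cf[0]))

    def frequency(self, codon: str) -> float:
        return self.entries[codon][1]


def load_codon_table(path=None, organism: str = "human") -> CodonTable:
    """Load a codon usage table from TSV (codon, aa, fraction).

    With no path, loads the packaged human table.  Fractions are normalized
    per amino acid so tables printed at 2 decimals are accepted.
    """
    if path is None:
        path = importlib.resources.files("minigene.data") / "human_codon_usage.tsv"
    raw: dict[str, tuple[str, float]] = {}
    with open(str(path)) as fh:
        header = fh.readline()
        if header.split() != ["codon", "aa", "fraction"]:
            raise InvalidInputError("codon table TSV must have header: codon aa fraction")
        for line in fh:
            if not line.strip():
                continue
            codon, aa, frac = line.split()
            raw[codon.upper()] = (aa.upper(), float(frac))
    sums: dict[str, float] = {}
    for codon, (aa, frac) in raw.items():
        sums[aa] = sums.get(aa, 0.0) + frac
    entries = {c: (aa, f / sums[aa]) for c, (aa, f) in raw.items()}
    return CodonTable(organism=organism, entries=entries)


# ---------------------------------------------------------------------------
# Configuration and validation report
# ---------------------------------------------------------------------------

# SpeI and BamHI are the library cloning sites, so internal copies must be
# absent from every synthesized insert.
DEFAULT_FORBIDDEN_MOTIFS = ("ACTAGT", "GGATCC")


@dataclass(frozen=True)
class BacktranslationConfig:
    """Synthesis constraints for backtranslation.

    GC and pyrimidine content are bounded in sliding windows (step 1,
    complete windows only); homopolymer runs longer than ``max_homopolymer``
    and any forbidden motif on either strand are disallowed.
    """

    gc_min: float = 0.40
    gc_max: float = 0.60
    gc_window: int = 50
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    max_homopolymer: int = 5
    max_pyrimidine_fraction: float = 0.75
    pyrimidine_window: int = 30
    min_codon_frequency: float = 0.0
    seed: int = 0
    max_repair_iterations: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.gc_min < self.gc_max < 1):
            raise InvalidConfigError("require 0 < gc_min < gc_max < 1")
        if self.gc_window < 10 or self.pyrimidine_window < 10:
            raise InvalidConfigError("windows must be >= 10 nt")
        if self.max_homopolymer < 3:
            raise InvalidConfigError("max_homopolymer must be >= 3")
        for m in self.forbidden_motifs:
            if not m or set(m) - set("ACGT"):
                raise InvalidConfigError(
                    f"forbidden motif {m!r} must be non-empty uppercase ACGT"
                )


@dataclass
class ValidationReport:
    """Exhaustive scan results; all-empty lists and round_trip_ok define PASS."""

    round_trip_ok: bool
    motif_hits: list[tuple[str, int]] = field(default_factory=list)
    homopolymer_violations: list[tuple[str, int, int]] = field(default_factory=list)
    gc_window_violations: list[tuple[int, float]] = field(default_factory=list)
    pyrimidine_violations: list[tuple[int, float]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return (
            self.round_trip_ok
            and not self.motif_hits
            and not self.homopolymer_violations
            and not self.gc_window_violations
            and not self.pyrimidine_violations
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _find_motifs(dna: str, motifs: tuple[str, ...]) -> list[tuple[str, int]]:
    """1-based positions of each motif on the given strand or its reverse
    complement (reported as the forward-strand position of the hit)."""
    hits = []
    for motif in motifs:
        patterns = {motif, reverse_complement(motif)}
        for pat in patterns:
            start = dna.find(pat)
            while start != -1:
                hits.append((motif, start + 1))
                start = dna.find(pat, start + 1)
    # deduplicate palindromic motifs and sort by position
    return sorted(set(hits), key=lambda h: (h[1], h[0]))


def _find_homopolymers(dna: str, max_run: int) -> list[tuple[str, int, int]]:
    out = []
    i = 0
    n = len(dna)
    while i < n:
        j = i
        while j < n and dna[j] == dna[i]:
            j += 1
        if j - i > max_run:
            out.append((dna[i], i + 1, j - i))
        i = j
    return out


def _window_fractions(is_member: np.ndarray, window: int) -> np.ndarray:
    """Fraction of True per complete sliding window of size ``window``."""
    if len(is_member) < window:
        return np.empty(0)
    csum = np.concatenate([[0], np.cumsum(is_member)])
    return (csum[window:] - csum[:-window]) / window


def validate_dna(
    dna: str, protein: str, config: BacktranslationConfig
) -> ValidationReport:
    """Exhaustively scan a candidate coding sequence against the constraint
    set and check that it translates back to ``protein``."""
    if len(dna) != 3 * len(protein):
        raise InvalidInputError(
            f"DNA length {len(dna)} != 3 x protein length {len(protein)}"
        )
    dna = dna.upper()
    try:
        round_trip_ok = translate(dna) == protein
    except InvalidInputError:
        round_trip_ok = False
    arr = np.frombuffer(dna.encode(), dtype="S1")
    gc = (arr == b"G") | (arr == b"C")
    pyr = (arr == b"C") | (arr == b"T")

    report = ValidationReport(round_trip_ok=round_trip_ok)
    report.motif_hits = _find_motifs(dna, config.forbidden_motifs)
    report.homopolymer_violations = _find_homopolymers(dna, config.max_homopolymer)
    gc_frac = _window_fractions(gc, config.gc_window)
    for i in np.flatnonzero((gc_frac < config.gc_min - 1e-12) | (gc_frac > config.gc_max + 1e-12)):
        report.gc_window_violations.append((int(i) + 1, float(gc_frac[i])))
    pyr_frac = _window_fractions(pyr, config.pyrimidine_window)
    for i in np.flatnonzero(pyr_frac > config.max_pyrimidine_fraction + 1e-12):
        report.pyrimidine_violations.append((int(i) + 1, float(pyr_frac[i])))
    return report


# ---------------------------------------------------------------------------
# Backtranslation
# ---------------------------------------------------------------------------

def _allowed_codons(table: CodonTable, min_freq: float) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per amino acid: usable codons (frequency >= min_freq) and their
    renormalized sampling probabilities."""
    allowed: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in sorted(AA_ALPHABET):
        pairs = [(c, f) for c, f in table.codons_for(aa) if f >= min_freq]
        if not pairs:
            raise InvalidConfigError(
                f"min_codon_frequency={min_freq} excludes every codon for {aa}"
            )
        codons = [c for c, _ in pairs]
        probs = np.array([f for _, f in pairs], dtype=float)
        allowed[aa] = (codons, probs / probs.sum())
    return allowed


def _violation_regions(report: ValidationReport, config: BacktranslationConfig) -> list[tuple[int, int]]:
    """0-based nt spans [a, b) of every violation, earliest first."""
    regions = []
    for motif, pos in report.motif_hits:
        regions.append((pos - 1, pos - 1 + len(motif)))
    for _base, start, run in report.homopolymer_violations:
        regions.append((start - 1, start - 1 + run))
    for start, _f in report.gc_window_violations:
        regions.append((start - 1, start - 1 + config.gc_window))
    for start, _f in report.pyrimidine_violations:
        regions.append((start - 1, start - 1 + config.pyrimidine_window))
    return sorted(regions)


def _local_score(codons: list[str], lo_c: int, hi_c: int, protein: str,
                 config: BacktranslationConfig) -> int:
    """Number of constraint violations in the codon slice [lo_c, hi_c)."""
    sub_dna = "".join(codons[lo_c:hi_c])
    sub_prot = protein[lo_c:hi_c]
    rep = validate_dna(sub_dna, sub_prot, config)
    return (
        len(rep.motif_hits)
        + len(rep.homopolymer_violations)
        + len(rep.gc_window_violations)
        + len(rep.pyrimidine_violations)
    )


def backtranslate(
    protein: str | ProteinRecord,
    table: CodonTable | None = None,
    config: BacktranslationConfig | None = None,
) -> str:
    """Backtranslate an amino-acid sequence to constraint-compliant DNA."""
    dna, _repaired = backtranslate_detailed(protein, table, config)
    return dna


def backtranslate_detailed(
    protein: str | ProteinRecord,
    table: CodonTable | None = None,
    config: BacktranslationConfig | None = None,
) -> tuple[str, set[int]]:
    """Backtranslate and also report which codon positions the repair loop
    touched (0-based indices); those positions no longer follow the usage
    table's sampling distribution.

    Codons are drawn by seeded weighted sampling proportional to usage,
    then a repair loop walks the earliest remaining violation: every
    single-codon synonymous swap overlapping the offending region is scored
    by the number of violations left in a widened local context, and the
    best-improving swap is applied (ties broken by higher codon frequency,
    then alphabetical codon, then position).  When no single swap improves,
    the region is resampled.  Raises :class:`UnsatisfiableConstraints` with
    the stuck window if the iteration budget is exhausted.
    """
    if isinstance(protein, ProteinRecord):
        protein = protein.sequence
    _check_aa(protein, "protein")
    if table is None:
        table = load_codon_table()
    if config is None:
        config = BacktranslationConfig()
    allowed = _allowed_codons(table, config.min_codon_frequency)
    rng = np.random.default_rng(config.seed)

    codons: list[str] = []
    for aa in protein:
        options, probs = allowed[aa]
        codons.append(options[rng.choice(len(options), p=probs)])

    repaired: set[int] = set()
    pad = max(config.gc_window, config.pyrimidine_window)
    for _iteration in range(config.max_repair_iterations):
        dna = "".join(codons)
        report = validate_dna(dna, protein, config)
        if report.passed:
            return dna, repaired
        regions = _violation_regions(report, config)
        a, b = regions[0]
        lo_c = max(0, (a - pad) // 3)
        hi_c = min(len(codons), -(-(b + pad) // 3))
        region_lo_c = a // 3
        region_hi_c = min(len(codons), -(-b // 3))
        current = _local_score(codons, lo_c, hi_c, protein, config)

        best: tuple[int, float, str, int] | None = None  # (score, -freq, codon, idx)
        for idx in range(region_lo_c, region_hi_c):
            original = codons[idx]
            for alt, _p in zip(*[allowed[protein[idx]][0], allowed[protein[idx]][1]]):
                if alt == original:
                    continue
                codons[idx] = alt
                score = _local_score(codons, lo_c, hi_c, protein, config)
                key = (score, -table.frequency(alt), alt, idx)
                if best is None or key < best:
                    best = key
            codons[idx] = original
        if best is not None and best[0] < current:
            codons[best[3]] = best[2]
            repaired.add(best[3])
        else:
            # no single swap helps; resample the region to escape
            for idx in range(region_lo_c, region_hi_c):
                options, probs = allowed[protein[idx]]
                codons[idx] = options[rng.choice(len(options), p=probs)]
                repaired.add(idx)

    raise UnsatisfiableConstraints(
        f"could not satisfy constraints within {config.max_repair_iterations} "
        f"repair iterations; stuck near nucleotides {a + 1}-{b}",
        stuck_window=(a + 1, b),
    )


def derive_record_seed(base_seed: int, record_id: str) -> int:
    """Stable per-record seed below 2**31 derived from (base seed, id)."""
    import zlib

    return (zlib.crc32(f"{base_seed}:{record_id}".encode()) ^ base_seed) % (2**31)


def batch_backtranslate(
    proteins: list[ProteinRecord],
    table: CodonTable | None = None,
    config: BacktranslationConfig | None = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Backtranslate a FASTA-set of proteins independently.

    Each record gets its own seed derived from (config.seed, record id) so
    results do not depend on batch composition or order.  Per-record
    failures are collected rather than aborting the batch.

    Returns ``(records, failures)`` where records is a list of
    (id, dna) in input order (failed ids omitted) and failures maps id to
    the error message.
    """
    if table is None:
        table = load_codon_table()
    if config is None:
        config = BacktranslationConfig()
    out: list[tuple[str, str]] = []
    failures: dict[str, str] = {}
    for rec in proteins:
        rec_config = replace(config, seed=derive_record_seed(config.seed, rec.id))
        try:
            out.append((rec.id, backtranslate(rec.sequence, table, rec_config)))
        except (UnsatisfiableConstraints, InvalidInputError, InvalidConfigError) as exc:
            failures[rec.id] = str(exc)
    return out, failures
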