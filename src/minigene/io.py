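"""File-format plumbing: FASTA via biopython, tabular I/O via pandas,
JSON manifests for designs and screen results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ConstructSpec, FragmentSpec, ProteinRecord, SubstitutionSpec
from .errors import InvalidInputError
from .pools import PoolDesign
from .screen import ScreenResult, WellReadout


def read_proteins(path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq).upper(), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, description: str = "") -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(seq), id=rid, description=description) for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_fragments_fasta(fragments: Sequence[FragmentSpec], path) -> None:
    """Fragments named ``{source_id}_{start}-{end}``."""
    write_fasta([(f.name, f.sequence) for f in fragments], path)


def read_substitutions(path) -> list[SubstitutionSpec]:
    """CSV with columns position, from_aa, to_aa (header required)."""
    df = pd.read_csv(path)
    required = {"position", "from_aa", "to_aa"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"substitution CSV needs columns {sorted(required)}")
    return [
        SubstitutionSpec(int(row.position), str(row.from_aa), str(row.to_aa))
        for row in df.itertuples()
    ]


def construct_manifest(constructs: Sequence[ConstructSpec]) -> list[dict]:
    """JSON-ready provenance manifest for assembled constructs."""
    out = []
    for c in constructs:
        out.append(
            {
                "construct_id": c.construct_id,
                "leader_id": c.leader_id,
                "leader_sequence": c.leader_sequence,
                "linker": c.linker,
                "length": len(c),
                "assembled_sequence": c.assembled_sequence,
                "fragments": [
                    {
                        "source_id": f.source_id,
                        "start": f.start,
                        "end": f.end,
                        "name": f.name,
                    }
                    for f in c.fragments
                ],
            }
        )
    return out


def design_to_dict(design: PoolDesign) -> dict:
    return {
        "n_targets": design.n_targets,
        "pool_size_max": design.pool_size_max,
        "min_replicates": design.min_replicates,
        "seed": design.seed,
        "wells": [sorted(pool) for pool in design.wells],
    }


def design_from_dict(d: dict) -> PoolDesign:
    return PoolDesign(
        n_targets=int(d["n_targets"]),
        wells=[frozenset(pool) for pool in d["wells"]],
        pool_size_max=int(d["pool_size_max"]),
        min_replicates=int(d["min_replicates"]),
        seed=int(d["seed"]),
    )


def save_design(design: PoolDesign, path) -> None:
    Path(path).write_text(json.dumps(design_to_dict(design), indent=2))


def load_design(path) -> PoolDesign:
    return design_from_dict(json.loads(Path(path).read_text()))


def read_readouts(path) -> list[WellReadout]:
    """CSV with columns pool_index (or pool), replicate, signal."""
    df = pd.read_csv(path)
    if "pool" in df.columns and "pool_index" not in df.columns:
        df = df.rename(columns={"pool": "pool_index"})
    required = {"pool_index", "replicate", "signal"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"readout CSV needs columns {sorted(required)}")
    return [
        WellReadout(int(r.pool_index), int(r.replicate), float(r.signal))
        for r in df.itertuples()
    ]


def write_readouts(readouts: Sequence[WellReadout], path) -> None:
    pd.DataFrame([asdict(r) for r in readouts]).to_csv(path, index=False)


def read_events(path) -> "pd.Series":
    """Single-column (value) or (population,value) CSV of flow events."""
    df = pd.read_csv(path)
    col = "value" if "value" in df.columns else df.columns[-1]
    return df[col].astype(float)


def screen_result_to_dict(result: ScreenResult) -> dict:
    return {
        "z_by_well": [
            {"pool_index": p, "replicate": r, "z": z}
            for (p, r), z in sorted(result.z_by_well.items())
        ],
        "score_by_pool": {str(p): s for p, s in sorted(result.score_by_pool.items())},
        "positive_pools": sorted(result.positive_pools),
        "candidates": [asdict(c) for c in result.candidates],
    }
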