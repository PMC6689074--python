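"""Package-level I/O: FASTA input, BED/bedGraph/TSV output, run configs.

Every output file carries a provenance comment header (tool version, seed,
config hash) so that runs are attributable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .scan import BindingSite


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class RunConfig:
    fasta: str | None = None
    model_paths: list[str] = field(default_factory=list)
    threshold: float = 0.05
    seed: int = 0
    outdir: str = "."
    verbosity: int = 0
    extras: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: data.pop(k) for k in list(data) if k in cls.__dataclass_fields__}
        known["extras"] = data
        return cls(**known)


def provenance_header(config: RunConfig | None = None, seed: int | None = None) -> str:
    seed = seed if seed is not None else (config.seed if config else 0)
    chash = config.config_hash() if config else "none"
    return f"# hoxcrm v{__version__} seed={seed} config={chash}\n"


def read_fasta(path) -> dict[str, str]:
    """Named, uppercased sequences from a (multi-)FASTA file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path, *, width: int = 70,
                config: RunConfig | None = None, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def bed_score(affinity: float) -> int:
    return int(round(1000 * min(max(affinity, 0.0), 1.0)))


def write_bed(sites: list[BindingSite], path, *, chrom: str = "seq",
              config: RunConfig | None = None, seed: int | None = None) -> None:
    """BED6: chrom, start, end, name=model[:class], score=round(1000*affinity),
    strand; 0-based half-open, deterministic site order."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        for s in sites:
            name = s.model_name if s.class_label is None else f"{s.model_name}:{s.class_label}"
            fh.write(
                f"{chrom}\t{s.start}\t{s.end}\t{name}\t{bed_score(s.affinity)}\t{s.strand}\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3],
                         int(parts[4]), parts[5]))
    return rows


def write_bedgraph(track: np.ndarray, path, *, chrom: str = "seq",
                   config: RunConfig | None = None, seed: int | None = None) -> None:
    """Per-window-start affinity track as 1-bp bedGraph intervals."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        for start, value in enumerate(np.asarray(track, dtype=float)):
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{value:.6g}\n")


def write_tsv(table, path, *, config: RunConfig | None = None,
              seed: int | None = None) -> None:
    """DataFrame to TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        table.to_csv(fh, sep="\t", index=False)
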