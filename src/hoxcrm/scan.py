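"""Both-strand window scanning, per-position affinity profiles, exact-core
localisation, and overlap relationships between called sites."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .energy import BASE_INDEX, EnergyModel
from .registry import (
    ABDB_MONOMER_CORES,
    GENERIC_MONOMER_CORE,
    MONOMER_ARCHITECTURE,
    Registry,
    SiteArchitecture,
)
from .seqs import revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSite:
    """A scored, strand-aware interval (0-based, half-open).

    ``window`` is the sequence as scored: for minus-strand sites it is the
    reverse complement of the plus-strand slice ``sequence[start:end]``.
    ``class_label`` is set only when the window's core positions exactly
    match a registered class core (dimer mode) or a monomer core.
    """

    model_name: str
    start: int
    end: int
    strand: str
    window: str
    affinity: float
    class_label: str | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def key(self) -> tuple:
        return (self.model_name, self.start, self.strand)


def _encode(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else to 4."""
    out = np.full(len(sequence), 4, dtype=np.int64)
    for base, idx in BASE_INDEX.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, model: EnergyModel) -> np.ndarray:
    """Raw affinities of all plus-orientation windows of an encoded strand.

    Windows containing a non-ACGT code score 0.
    """
    L = model.footprint
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    pen = np.hstack([model.penalties, np.full((L, 1), np.inf)])  # column 4: bad base
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    total = pen[np.arange(L)[None, :], win].sum(axis=1)
    with np.errstate(over="ignore"):
        return np.where(np.isfinite(total), np.exp(-total) / model.norm_max, 0.0)


def _classify(window: str, model: EnergyModel, registry: Registry | None) -> str | None:
    if registry is None:
        return None
    arch = model.architecture
    if model.mode == "dimer":
        arch = arch or registry.architecture
        if arch.footprint != model.footprint:
            return None
        return registry.classify_window(arch.core_of(window))
    arch = arch or MONOMER_ARCHITECTURE
    if arch.footprint != model.footprint:
        return None
    core = arch.core_of(window)
    if core == GENERIC_MONOMER_CORE or core in ABDB_MONOMER_CORES:
        return "monomer"
    return None


def scan(
    sequence: str,
    model: EnergyModel,
    threshold: float = 0.05,
    *,
    registry: Registry | None = None,
) -> list[BindingSite]:
    """All windows on both strands with affinity >= threshold.

    Sites are sorted by (descending affinity, ascending start, + before −).
    A sequence shorter than the footprint yields an empty list (logged).
    """
    sequence = sequence.upper()
    # negative thresholds are clamped; a threshold above 1 is allowed and
    # simply returns no sites (nothing exceeds the normalised optimum)
    threshold = max(float(threshold), 0.0)
    L = model.footprint
    if len(sequence) < L:
        log.info("sequence length %d shorter than footprint %d; no windows", len(sequence), L)
        return []
    codes = _encode(sequence)
    plus = _window_scores(codes, model)
    rc = revcomp(sequence)
    minus_rc = _window_scores(_encode(rc), model)  # indexed in revcomp coordinates
    n = len(plus)
    sites: list[BindingSite] = []
    skipped = 0
    for start in range(n):
        for strand, aff in (("+", plus[start]), ("-", minus_rc[n - 1 - start])):
            if aff <= 0.0:
                window = sequence[start : start + L]
                if set(window) - set("ACGT"):
                    skipped += 1
                continue
            if aff < threshold:
                continue
            window = sequence[start : start + L]
            if strand == "-":
                window = revcomp(window)
            sites.append(
                BindingSite(
                    model_name=model.name,
                    start=start,
                    end=start + L,
                    strand=strand,
                    window=window,
                    affinity=float(aff),
                    class_label=_classify(window, model, registry),
                )
            )
    if skipped:
        log.info("skipped %d windows containing non-ACGT characters", skipped)
    sites.sort(key=lambda s: (-s.affinity, s.start, 0 if s.strand == "+" else 1))
    return sites


def best_affinity(sequence: str, model: EnergyModel) -> float:
    """Maximum window affinity over both strands (0.0 if no window fits)."""
    profile = affinity_profile(sequence, model)
    return float(profile.max()) if len(profile) else 0.0


def affinity_profile(sequence: str, model: EnergyModel) -> np.ndarray:
    """Per-window-start track: max of plus/minus strand affinity."""
    sequence = sequence.upper()
    L = model.footprint
    if len(sequence) < L:
        log.info("sequence length %d shorter than footprint %d; empty profile", len(sequence), L)
        return np.zeros(0)
    plus = _window_scores(_encode(sequence), model)
    minus = _window_scores(_encode(revcomp(sequence)), model)[::-1]
    return np.maximum(plus, minus)


@dataclass(frozen=True)
class CoreHit:
    """Exact occurrence of a registered core motif."""

    label: str
    core: str
    start: int
    end: int
    strand: str


def find_cores(
    sequence: str, registry: Registry, *, include_monomer: bool = False
) -> list[CoreHit]:
    """Exact class-core (and optionally monomer-core) matches on both strands."""
    sequence = sequence.upper()
    hits = []
    for label, core in registry.core_motifs(include_monomer=include_monomer).items():
        for motif, strand in ((core, "+"), (revcomp(core), "-")):
            start = sequence.find(motif)
            while start != -1:
                hits.append(CoreHit(label, core, start, start + len(core), strand))
                start = sequence.find(motif, start + 1)
    hits.sort(key=lambda h: (h.start, h.label, h.strand))
    return hits


def find_overlaps(
    sites_a: list[BindingSite] | list[CoreHit],
    sites_b: list[BindingSite] | list[CoreHit],
    min_shared_bp: int = 1,
) -> list[tuple]:
    """All cross pairs whose half-open intervals share >= min_shared_bp bases.

    Returns (site_a, site_b, (shared_start, shared_end)) triples.
    """
    pairs = []
    for a in sites_a:
        for b in sites_b:
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if hi - lo >= min_shared_bp:
                pairs.append((a, b, (lo, hi)))
    return pairs
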