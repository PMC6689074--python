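"""Mononucleotide free-energy binding models and relative-affinity scoring.

A model assigns each (position, base) a nonnegative free-energy increment in
dimensionless RT units.  The relative affinity of a window is

    a(w) = exp(-sum_i penalty[i, w_i]) / norm_max

so with the anchoring convention (per-position minimum penalty exactly 0)
the optimal window scores 1.0 when ``norm_max`` is 1.  ``norm_max`` can be
reset against a reference sequence set, emulating normalisation relative to
a genomic maximum; it corresponds to a different and unknown dissociation
constant for every factor, so affinities are comparable *within* one model
only.  No operation in this package combines affinities from two different
models arithmetically; cross-model results are only ever reported
side-by-side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .registry import SiteArchitecture
from .seqs import ALPHABET, SequenceError, check_dna, revcomp

SCHEMA = "hoxcrm-energy-1"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_ANCHOR_TOL = 1e-9


class ModelError(ValueError):
    """Invalid energy-model construction or file content."""


@dataclass(frozen=True)
class EnergyModel:
    """Per-position free-energy penalties for one factor and binding mode.

    penalties : (footprint, 4) array, columns in A, C, G, T order;
        all finite, >= 0, and anchored (row minimum exactly 0).
    """

    name: str
    factor: str
    mode: str  # "monomer" | "dimer"
    penalties: np.ndarray
    norm_max: float = 1.0
    architecture: SiteArchitecture | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("monomer", "dimer"):
            raise ModelError(f"mode must be monomer or dimer, got {self.mode!r}")
        p = np.asarray(self.penalties, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ModelError(f"penalties must be (L, 4), got {p.shape}")
        if not np.isfinite(p).all():
            raise ModelError("penalties must be finite")
        if (p < 0).any():
            pos = int(np.argwhere(p < 0)[0][0])
            raise ModelError(f"negative penalty at position {pos}")
        mins = p.min(axis=1)
        if (np.abs(mins) > _ANCHOR_TOL).any():
            pos = int(np.argmax(np.abs(mins) > _ANCHOR_TOL))
            raise ModelError(f"position {pos} is not anchored (min penalty {mins[pos]:.3g} != 0)")
        if not self.norm_max > 0:
            raise ModelError("norm_max must be positive")
        p.flags.writeable = False
        object.__setattr__(self, "penalties", p)

    @property
    def footprint(self) -> int:
        return self.penalties.shape[0]

    def optimal_window(self) -> str:
        """Lowest-energy window (ties broken in A,C,G,T order)."""
        return "".join(ALPHABET[i] for i in self.penalties.argmin(axis=1))


def window_affinity(model: EnergyModel, window: str) -> float:
    """Relative affinity of one window; non-ACGT windows score 0.0."""
    window = window.upper()
    if len(window) != model.footprint:
        raise SequenceError(
            f"window length {len(window)} != model footprint {model.footprint}"
        )
    total = 0.0
    for i, base in enumerate(window):
        j = BASE_INDEX.get(base)
        if j is None:
            return 0.0
        total += model.penalties[i, j]
    return math.exp(-total) / model.norm_max


def normalize_to_reference(model: EnergyModel, reference_sequences: list[str]) -> EnergyModel:
    """Copy of ``model`` whose norm_max is the best raw window affinity over
    both strands of the reference sequences, so the best reference window
    scores exactly 1.0."""
    raw = replace(model, norm_max=1.0)
    best = 0.0
    n_windows = 0
    for seq in reference_sequences:
        seq = check_dna(seq, name="reference sequence")
        for strand_seq in (seq, revcomp(seq)):
            for start in range(len(strand_seq) - model.footprint + 1):
                n_windows += 1
                best = max(best, window_affinity(raw, strand_seq[start : start + model.footprint]))
    if n_windows == 0 or best <= 0.0:
        raise ModelError("no valid reference window of model footprint length")
    return replace(model, norm_max=best)


def model_from_core(
    core: str,
    architecture: SiteArchitecture,
    core_penalty: float,
    flank_penalties=None,
    *,
    core_overrides=None,
    name: str = "",
    factor: str = "",
    mode: str = "dimer",
) -> EnergyModel:
    """Synthesize a core-anchored model.

    core_penalty : scalar applied to every non-core base at core positions.
    core_overrides : optional {template_position: {base: penalty}} replacing
        the scalar at single core positions (the anchored core base keeps
        penalty 0; a 0 entry makes an additional base equally optimal).
    flank_penalties : mapping {template_position: {base: penalty}} for flank
        positions; bases absent from a mapping default to penalty 0.
    """
    core = check_dna(core, name="core")
    if len(core) != len(architecture.core_positions):
        raise ModelError(
            f"core length {len(core)} != architecture core width "
            f"{len(architecture.core_positions)}"
        )
    scalar = float(core_penalty)
    if scalar < 0:
        raise ModelError("core_penalty must be >= 0")
    overrides = {int(k): v for k, v in (core_overrides or {}).items()}
    L = architecture.footprint
    pen = np.zeros((L, 4))
    for core_idx, tpos in enumerate(architecture.core_positions):
        if tpos in overrides:
            for base, value in overrides[tpos].items():
                pen[tpos, BASE_INDEX[base]] = float(value)
        else:
            pen[tpos, :] = scalar
        pen[tpos, BASE_INDEX[core[core_idx]]] = 0.0
    for tpos in architecture.flank_positions:
        table = (flank_penalties or {}).get(tpos, {})
        for base, value in table.items():
            pen[tpos, BASE_INDEX[base]] = float(value)
    return EnergyModel(
        name=name or f"{mode}:{core}",
        factor=factor,
        mode=mode,
        penalties=pen,
        architecture=architecture,
    )


# -- JSON round trip -------------------------------------------------------

def write_model(model: EnergyModel, path) -> None:
    payload = {
        "schema": SCHEMA,
        "name": model.name,
        "factor": model.factor,
        "mode": model.mode,
        "footprint": model.footprint,
        "penalties": model.penalties.tolist(),
        "norm_max": model.norm_max,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_model(path) -> EnergyModel:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("schema", "name", "factor", "mode", "footprint", "penalties", "norm_max"):
        if key not in payload:
            raise ModelError(f"model file missing field {key!r}")
    if payload["schema"] != SCHEMA:
        raise ModelError(f"schema: expected {SCHEMA!r}, got {payload['schema']!r}")
    pen = np.asarray(payload["penalties"], dtype=float)
    if pen.shape != (int(payload["footprint"]), 4):
        raise ModelError(
            f"penalties: shape {pen.shape} inconsistent with footprint {payload['footprint']}"
        )
    try:
        return EnergyModel(
            name=payload["name"],
            factor=payload["factor"],
            mode=payload["mode"],
            penalties=pen,
            norm_max=float(payload["norm_max"]),
        )
    except ModelError as exc:
        raise ModelError(f"penalties: {exc}") from exc
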