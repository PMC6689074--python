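"""Segment-level enhancer activation logic.

The model combines, per embryo segment, an additive Hox drive with a
positive JAK/STAT collaborator input and a negative WNT (segment-polarity)
input:

    score(segment, pos) = w_hox * Hox(segment) + w_stat * STAT(segment)
                          - w_wnt * WNT(pos),   floored at 0

Hox(segment) sums, over the Hox factors occupying the segment under the
genotype, a cofactor-dependent term (the factor's best Hox–Exd composite
site affinity on the construct; zeroed when cofactors are unavailable, as
in hth/exd loss-of-function) and a cofactor-independent monomer term
(monomer-site aggregate weighted by the factor's monomer competence; Abd-B
carries the largest default weight).  STAT is a per-segment scalar and WNT
a binary intra-segment positional mask — two positions per segment, one
inside and one outside the WNT-repressed stripe — which is the minimal
structure distinguishing segmental patches from a continuous lateral
stripe.  Scores are quantised to off/weak/strong calls by two thresholds.

Weights, thresholds and the STAT level are packaged as a frozen named
default calibration (the underlying biology constrains signs and orderings,
not magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .energy import EnergyModel
from .registry import Registry
from .scan import best_affinity, scan

CALLS = ("off", "weak", "strong")


class LogicError(ValueError):
    """Inconsistent expression-logic configuration."""


@dataclass(frozen=True)
class ModelSet:
    """Per-factor dimer (Hox–Exd) and monomer models.

    Affinities from different models are never combined arithmetically;
    each factor's drive uses only that factor's own models.
    """

    dimer: dict[str, EnergyModel]
    monomer: dict[str, EnergyModel]

    def require(self, factor: str) -> None:
        if factor not in self.dimer:
            raise LogicError(f"no dimer model configured for factor {factor!r}")
        if factor not in self.monomer:
            raise LogicError(f"no monomer model configured for factor {factor!r}")


@dataclass(frozen=True)
class LogicConfig:
    """Frozen default calibration of the activation model."""

    w_hox: float = 1.0
    w_stat: float = 1.0
    w_wnt: float = 2.0
    thresholds: tuple[float, float] = (0.3, 0.7)
    stat_level: float = 0.12
    monomer_min_affinity: float = 0.1  # floor below which monomer matches are noise
    monomer_cap: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_hox, self.w_stat, self.w_wnt) < 0:
            raise LogicError("weights must be nonnegative")
        if not self.thresholds[0] < self.thresholds[1]:
            raise LogicError("thresholds must be ordered")

    def call(self, score: float) -> str:
        if score >= self.thresholds[1]:
            return "strong"
        if score >= self.thresholds[0]:
            return "weak"
        return "off"


@dataclass
class SegmentMap:
    """Ordered segments with occupancy, STAT level and WNT positional mask."""

    segments: tuple[str, ...]
    occupancy: dict[str, tuple[str, ...]]
    stat_level: dict[str, float]
    wnt_mask: tuple[bool, ...] = (True, False)  # intra-segment positions

    @classmethod
    def default(cls, registry: Registry, config: LogicConfig | None = None) -> "SegmentMap":
        config = config or LogicConfig()
        return cls(
            segments=registry.segments,
            occupancy={s: tuple(registry.factors_in_segment(s)) for s in registry.segments},
            stat_level={s: config.stat_level for s in registry.segments},
        )


@dataclass(frozen=True)
class GenotypeSpec:
    removed_factors: frozenset[str] = frozenset()
    cofactors_available: bool = True  # False emulates hth/exd loss
    wnt_active: bool = True
    stat_active: bool = True
    ectopic_factors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for segment, factors in self.ectopic_factors.items():
            clash = self.removed_factors & set(factors)
            if clash:
                raise LogicError(
                    f"segment {segment}: factors {sorted(clash)} both removed and ectopic"
                )


WILD_TYPE = GenotypeSpec()


@dataclass
class ExpressionPrediction:
    """Per (segment, intra-segment position) activity score and ternary call."""

    scores: dict[tuple[str, int], float]
    calls: dict[tuple[str, int], str]
    segments: tuple[str, ...]
    n_positions: int

    def segment_on(self, segment: str) -> bool:
        """True if any intra-segment position is called weak or strong."""
        return any(
            self.calls[(segment, p)] != "off" for p in range(self.n_positions)
        )

    def segment_max(self, segment: str) -> float:
        return max(self.scores[(segment, p)] for p in range(self.n_positions))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"segment": seg, "position": pos, "score": self.scores[(seg, pos)],
             "call": self.calls[(seg, pos)]}
            for seg in self.segments
            for pos in range(self.n_positions)
        ]
        return pd.DataFrame(rows)


def _monomer_aggregate(sequence: str, model: EnergyModel, config: LogicConfig,
                       registry: Registry) -> float:
    sites = scan(sequence, model, threshold=config.monomer_min_affinity, registry=registry)
    return min(sum(s.affinity for s in sites), config.monomer_cap)


def _segment_factors(segment: str, segment_map: SegmentMap, genotype: GenotypeSpec) -> list[str]:
    present = [f for f in segment_map.occupancy[segment] if f not in genotype.removed_factors]
    for extra in genotype.ectopic_factors.get(segment, ()):
        if extra not in present:
            present.append(extra)
    return present


def hox_input(
    construct_sequence: str,
    segment: str,
    models: ModelSet,
    genotype: GenotypeSpec,
    registry: Registry,
    segment_map: SegmentMap | None = None,
    config: LogicConfig | None = None,
) -> float:
    """Total Hox drive of a construct in one segment (>= 0).

    Sums over the factors occupying the segment (minus removed, plus
    ectopic): best composite-site affinity when cofactors are available,
    plus monomer competence times the capped monomer-site aggregate.
    """
    config = config or LogicConfig()
    segment_map = segment_map or SegmentMap.default(registry, config)
    total = 0.0
    for factor in _segment_factors(segment, segment_map, genotype):
        models.require(factor)
        if genotype.cofactors_available:
            total += best_affinity(construct_sequence, models.dimer[factor])
        competence = registry.factors[factor].monomer_competence
        if competence > 0:
            total += competence * _monomer_aggregate(
                construct_sequence, models.monomer[factor], config, registry
            )
    return total


def predict(
    construct_sequence: str,
    models: ModelSet,
    registry: Registry,
    genotype: GenotypeSpec = WILD_TYPE,
    segment_map: SegmentMap | None = None,
    config: LogicConfig | None = None,
) -> ExpressionPrediction:
    """Per-segment, per-position activity prediction for a construct."""
    config = config or LogicConfig()
    segment_map = segment_map or SegmentMap.default(registry, config)
    scores: dict[tuple[str, int], float] = {}
    calls: dict[tuple[str, int], str] = {}
    for segment in segment_map.segments:
        hox = hox_input(
            construct_sequence, segment, models, genotype, registry, segment_map, config
        )
        stat = segment_map.stat_level[segment] if genotype.stat_active else 0.0
        for pos, wnt_on in enumerate(segment_map.wnt_mask):
            repressed = wnt_on and genotype.wnt_active
            score = config.w_hox * hox + config.w_stat * stat
            if repressed:
                score -= config.w_wnt
            score = max(score, 0.0)
            scores[(segment, pos)] = score
            calls[(segment, pos)] = config.call(score)
    return ExpressionPrediction(
        scores=scores,
        calls=calls,
        segments=segment_map.segments,
        n_positions=len(segment_map.wnt_mask),
    )


TRUNK_SEGMENTS = ("T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9")
HEAD_SEGMENTS = ("mx", "lb")


def evaluate_truth_table(
    sequences: dict[str, str],
    models: ModelSet,
    registry: Registry,
    config: LogicConfig | None = None,
) -> dict[str, bool]:
    """Qualitative genotype/construct truth table of the activation model.

    Each named check corresponds to an observed on/off pattern: cofactor
    dependence of head vs trunk activity, class-conversion gains, the
    intercalary gain of the class 1 variant and its Lab dependence, WNT
    relief and its Hox dependence, Abd-B monomer-dependent A8 activity, and
    STAT dependence graded by site strength.  ``sequences`` must contain the
    fixture-suite construct names.
    """
    config = config or LogicConfig()

    def P(name: str, genotype: GenotypeSpec = WILD_TYPE) -> ExpressionPrediction:
        return predict(sequences[name], models, registry, genotype, config=config)

    cofactorless = GenotypeSpec(cofactors_available=False)
    results: dict[str, bool] = {}

    # 1. cofactor loss abolishes head activity but not all trunk activity
    full_hth = P("vvl1+2", cofactorless)
    results["cofactor_loss_abolishes_head"] = not any(
        full_hth.segment_on(s) for s in HEAD_SEGMENTS
    )
    results["cofactor_loss_spares_some_trunk"] = any(
        full_hth.segment_on(s) for s in TRUNK_SEGMENTS
    )

    # 2. class 2 cassette construct is head-restricted; class 3 conversion
    #    gains trunk activity
    base = P("S1+55")
    results["class2_construct_head_on"] = all(base.segment_on(s) for s in HEAD_SEGMENTS)
    results["class2_construct_trunk_off"] = not any(
        base.segment_on(s) for s in TRUNK_SEGMENTS
    )
    cl3 = P("S1+55cl3")
    results["class3_conversion_gains_trunk"] = all(
        cl3.segment_on(s) for s in TRUNK_SEGMENTS
    )

    # 3. class 1 conversion gains the intercalary segment; removing Lab
    #    abolishes the gain
    results["class1_conversion_gains_ic"] = (
        not base.segment_on("ic") and P("S1+55cl1").segment_on("ic")
    )
    results["ic_gain_requires_lab"] = not P(
        "S1+55cl1", GenotypeSpec(removed_factors=frozenset({"Lab"}))
    ).segment_on("ic")

    # 4. WNT removal yields a continuous trunk stripe; additional Hox removal
    #    truncates it exactly where the removed factors acted
    wnt_off = GenotypeSpec(wnt_active=False)
    stripe = P("vvl1+2", wnt_off)
    results["wnt_loss_continuous_stripe"] = all(
        stripe.calls[(s, p)] != "off"
        for s in TRUNK_SEGMENTS
        for p in range(stripe.n_positions)
    )
    wnt_hox_off = GenotypeSpec(
        wnt_active=False, removed_factors=frozenset({"Scr", "Antp", "Ubx"})
    )
    truncated = P("vvl1+2", wnt_hox_off)
    results["wnt_hox_loss_truncates_stripe"] = (
        not any(truncated.segment_on(s) for s in ("T1", "T2", "T3", "A1"))
        and all(truncated.segment_on(s) for s in ("A2", "A8", "A9"))
    )

    # 5. A8 activity under cofactor loss requires the Abd-B monomer term
    results["a8_cofactorless_needs_abdb_monomer"] = full_hth.segment_on("A8") and not predict(
        sequences["vvl1+2"],
        models,
        registry,
        GenotypeSpec(cofactors_available=False, removed_factors=frozenset({"Abd-B"})),
        config=config,
    ).segment_on("A8")

    # 6. without STAT the weak-site construct is silent everywhere, while
    #    optimal-flank constructs retain activity
    stat_off = GenotypeSpec(stat_active=False)
    base_nostat = P("S1+55", stat_off)
    results["stat_loss_silences_weak_construct"] = not any(
        base_nostat.segment_on(s) for s in base_nostat.segments
    )
    results["stat_loss_spares_optimal_flanks"] = P(
        "S1+55cl2OF", stat_off
    ).segment_on("mx") and P("S1+55cl1OF", stat_off).segment_on("ic")

    return results
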