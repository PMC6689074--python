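"""Rational binding-site engineering: class conversion, optimal-flank design,
minimal-edit knockout, restoration, and overlap-aware side-effect auditing.

All operations return an :class:`EditPlan` of single-base substitutions;
applying then reverting a plan restores the original sequence exactly.
Conversion edits touch core positions only and flank optimisation touches
flank positions only — combined designs are explicit compositions, mirroring
separately testable construct variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .energy import EnergyModel, window_affinity
from .registry import MONOMER_ARCHITECTURE, Registry, SiteArchitecture
from .scan import BindingSite, CoreHit, best_affinity, find_cores, scan
from .seqs import ALPHABET, SequenceError, complement, hamming

_EDIT_BUDGET_EXHAUSTIVE_LEN = 60
_EDIT_BUDGET_EXHAUSTIVE_K = 3


class DesignError(ValueError):
    """Unsatisfiable or ill-posed design request."""


@dataclass(frozen=True)
class Substitution:
    position: int  # 0-based on the plus strand
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DesignError(f"substitution at {self.position} does not change the base")


@dataclass
class AuditReport:
    """Complete scan diff between two equal-length sequences.

    ``model_diffs`` maps model name to gained / lost / changed site lists
    (changed entries are (site_before, site_after) pairs).  ``core_gained``
    and ``core_lost`` record exact registered-core occurrences, which is the
    level at which conversion side effects such as the creation of a new
    class 3 core by a class 1 conversion are visible.
    """

    model_diffs: dict[str, dict[str, list]] = field(default_factory=dict)
    core_gained: list[CoreHit] = field(default_factory=list)
    core_lost: list[CoreHit] = field(default_factory=list)

    def is_empty(self) -> bool:
        if self.core_gained or self.core_lost:
            return False
        return all(
            not d["gained"] and not d["lost"] and not d["changed"]
            for d in self.model_diffs.values()
        )

    def gained_class_labels(self) -> list[str]:
        return [h.label for h in self.core_gained]


@dataclass
class EditPlan:
    substitutions: list[Substitution]
    provenance: dict = field(default_factory=dict)
    predicted_effects: AuditReport | None = None

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise DesignError("substitution positions must be unique")
        self.substitutions = sorted(self.substitutions, key=lambda s: s.position)

    def __len__(self) -> int:
        return len(self.substitutions)

    def apply(self, sequence: str) -> str:
        out = list(sequence)
        for sub in self.substitutions:
            if sub.position >= len(out):
                raise DesignError(f"substitution position {sub.position} out of bounds")
            if out[sub.position] != sub.ref:
                raise DesignError(
                    f"ref mismatch at {sub.position}: sequence has {out[sub.position]}, "
                    f"plan expects {sub.ref}"
                )
            out[sub.position] = sub.alt
        return "".join(out)

    def revert(self, sequence: str) -> str:
        out = list(sequence)
        for sub in self.substitutions:
            if out[sub.position] != sub.alt:
                raise DesignError(f"cannot revert: position {sub.position} is not {sub.alt}")
            out[sub.position] = sub.ref
        return "".join(out)

    def to_table(self, sequence_name: str = "seq") -> list[dict]:
        op = self.provenance.get("op", "manual")
        return [
            {"sequence": sequence_name, "position": s.position, "ref": s.ref,
             "alt": s.alt, "provenance": op}
            for s in self.substitutions
        ]


def _site_to_plus(site: BindingSite, window_index: int, alt_window_base: str) -> Substitution:
    """Map an edit expressed in scored-window coordinates onto the plus strand."""
    if site.strand == "+":
        pos = site.start + window_index
        ref = site.window[window_index]
        return Substitution(pos, ref, alt_window_base)
    pos = site.end - 1 - window_index
    ref = complement(site.window[window_index])
    return Substitution(pos, ref, complement(alt_window_base))


def convert_class(
    sequence: str,
    site: BindingSite,
    target_class: str,
    registry: Registry,
    *,
    models: list[EnergyModel] = (),
) -> EditPlan:
    """Minimal substitutions mapping the site's core to the target class core.

    Minimality is the Hamming distance between the two 8-bp cores; flanks are
    never touched.  For the registered cores any single conversion is a
    1-base edit (the cores differ only at core index 5).
    """
    arch = registry.architecture
    core = arch.core_of(site.window)
    source_label = registry.classify_window(core)
    if source_label is None:
        raise DesignError(f"site core {core} is not a registered class core")
    target_core = registry.class_core(target_class)
    subs = [
        _site_to_plus(site, arch.core_positions[i], target_core[i])
        for i in range(len(core))
        if core[i] != target_core[i]
    ]
    plan = EditPlan(
        subs,
        provenance={
            "op": "convert_class",
            "source_class": source_label,
            "target_class": target_class,
            "hamming": hamming(core, target_core),
        },
    )
    _attach_audit(plan, sequence, registry, models)
    return plan


def optimize_flanks(
    sequence: str,
    site: BindingSite,
    model: EnergyModel,
    registry: Registry,
    *,
    models: list[EnergyModel] = (),
) -> EditPlan:
    """Flank-only substitutions attaining the model's maximum affinity with
    the core fixed (exact per position because the energy model is additive).
    Ties between equally optimal bases break in A,C,G,T order."""
    if model.mode != "dimer":
        raise DesignError("optimize_flanks requires a dimer-mode model")
    arch = model.architecture or registry.architecture
    if model.footprint != arch.footprint or site.end - site.start != model.footprint:
        raise DesignError("site / model footprint mismatch")
    subs = []
    for tpos in arch.flank_positions:
        best = model.optimal_window()[tpos]
        if site.window[tpos] != best:
            subs.append(_site_to_plus(site, tpos, best))
    plan = EditPlan(
        subs,
        provenance={"op": "optimize_flanks", "model": model.name, "site_start": site.start},
    )
    _attach_audit(plan, sequence, registry, models)
    return plan


def restore(current_sequence: str, original_sequence: str, regions: list[tuple[int, int]]) -> str:
    """Return the original bases inside ``regions`` and current elsewhere."""
    if len(current_sequence) != len(original_sequence):
        raise SequenceError("restore requires equal-length sequences")
    out = list(current_sequence)
    for start, end in regions:
        if not (0 <= start <= end <= len(out)):
            raise SequenceError(f"region ({start}, {end}) out of bounds")
        out[start:end] = original_sequence[start:end]
    return "".join(out)


# -- knockout --------------------------------------------------------------

def _core_hits(sequence: str, registry: Registry, include_monomer: bool) -> list[CoreHit]:
    return find_cores(sequence, registry, include_monomer=include_monomer)


def _residual_core_count(sequence: str, registry: Registry, include_monomer: bool) -> int:
    return len(_core_hits(sequence, registry, include_monomer))


def _max_affinity(sequence: str, models: list[EnergyModel]) -> float:
    return max((best_affinity(sequence, m) for m in models), default=0.0)


def _candidate_substitutions(sequence: str, positions) -> list[Substitution]:
    cands = []
    for pos in sorted(positions):
        ref = sequence[pos]
        for alt in ALPHABET:
            if alt != ref:
                cands.append(Substitution(pos, ref, alt))
    return cands


def knockout(
    sequence: str,
    registry: Registry,
    *,
    mode: str = "core",
    models: list[EnergyModel] = (),
    ceiling: float = 0.05,
    max_edits: int = 3,
    include_monomer: bool = False,
    region: tuple[int, int] | None = None,
) -> EditPlan:
    """Fewest-substitution plan eliminating predicted Hox input.

    mode="core" (default) destroys every exact registered class core (and
    monomer cores when ``include_monomer``) on both strands without creating
    new ones — mirroring core-directed mutagenesis.  mode="affinity" instead
    drives every window of every supplied model below ``ceiling``.

    The search is exhaustive (certified minimal) while the search region is
    <= 60 bp and the plan needs <= 3 edits; otherwise an iterative greedy
    search is used and the provenance records ``certified: False``.
    """
    sequence = sequence.upper()
    lo, hi = region if region is not None else (0, len(sequence))

    if mode == "core":
        def satisfied(seq: str) -> bool:
            return _residual_core_count(seq, registry, include_monomer) == 0

        def badness(seq: str) -> float:
            return float(_residual_core_count(seq, registry, include_monomer))

    elif mode == "affinity":
        if not models:
            raise DesignError("affinity-mode knockout requires at least one model")
        if not 0.0 < ceiling < 1.0:
            raise DesignError("ceiling must lie in (0, 1)")

        def satisfied(seq: str) -> bool:
            return _max_affinity(seq, models) < ceiling

        def badness(seq: str) -> float:
            return _max_affinity(seq, models)

    else:
        raise DesignError(f"unknown knockout mode {mode!r}")

    if satisfied(sequence):
        return EditPlan([], provenance={"op": "knockout", "mode": mode, "certified": True,
                                        "minimal_edits": 0})

    def editable_positions(seq: str) -> set[int]:
        """Positions whose change can lower the objective."""
        pos: set[int] = set()
        if mode == "core":
            for hit in _core_hits(seq, registry, include_monomer):
                pos.update(range(hit.start, hit.end))
        else:
            for m in models:
                for s in scan(seq, m, threshold=ceiling):
                    pos.update(range(s.start, s.end))
        return {p for p in pos if lo <= p < hi}

    width = hi - lo
    exhaustive_ok = width <= _EDIT_BUDGET_EXHAUSTIVE_LEN
    if exhaustive_ok:
        cands = _candidate_substitutions(sequence, editable_positions(sequence))
        for k in range(1, min(max_edits, _EDIT_BUDGET_EXHAUSTIVE_K) + 1):
            # lexicographic (position, alt) order is inherited from cands
            for combo in itertools.combinations(cands, k):
                positions = {s.position for s in combo}
                if len(positions) != k:
                    continue
                trial = EditPlan(list(combo)).apply(sequence)
                if satisfied(trial):
                    plan = EditPlan(list(combo), provenance={
                        "op": "knockout", "mode": mode, "certified": True,
                        "minimal_edits": k})
                    _attach_audit(plan, sequence, registry, models)
                    return plan
        raise DesignError(
            f"no knockout plan within {max_edits} edits; residual badness "
            f"{badness(sequence):.4g}"
        )

    # greedy: one substitution at a time, maximally reducing the objective
    current = sequence
    chosen: list[Substitution] = []
    for _ in range(max_edits):
        best_sub, best_bad = None, badness(current)
        for sub in _candidate_substitutions(current, editable_positions(current)):
            trial = EditPlan([sub]).apply(current)
            b = badness(trial)
            if b < best_bad:
                best_sub, best_bad = sub, b
        if best_sub is None:
            break
        chosen.append(best_sub)
        current = EditPlan([best_sub]).apply(current)
        if satisfied(current):
            subs = [Substitution(s.position, sequence[s.position],
                                 current[s.position]) for s in chosen]
            plan = EditPlan(subs, provenance={
                "op": "knockout", "mode": mode, "certified": False,
                "minimal_edits": len(subs)})
            _attach_audit(plan, sequence, registry, models)
            return plan
    raise DesignError(
        f"no knockout plan within {max_edits} edits; residual badness "
        f"{badness(current):.4g}"
    )


# -- auditing ---------------------------------------------------------------

def side_effect_audit(
    sequence_before: str,
    sequence_after: str,
    models: list[EnergyModel],
    registry: Registry,
    *,
    threshold: float = 0.05,
    include_monomer_cores: bool = False,
) -> AuditReport:
    """Complete per-model scan diff plus exact-core gains and losses."""
    if len(sequence_before) != len(sequence_after):
        raise SequenceError("audit requires equal-length sequences")
    report = AuditReport()
    for model in models:
        before = {s.key(): s for s in scan(sequence_before, model, threshold, registry=registry)}
        after = {s.key(): s for s in scan(sequence_after, model, threshold, registry=registry)}
        gained = [after[k] for k in sorted(after.keys() - before.keys())]
        lost = [before[k] for k in sorted(before.keys() - after.keys())]
        changed = [
            (before[k], after[k])
            for k in sorted(before.keys() & after.keys())
            if abs(before[k].affinity - after[k].affinity) > 1e-12
            or before[k].window != after[k].window
        ]
        report.model_diffs[model.name] = {"gained": gained, "lost": lost, "changed": changed}
    cores_before = set(_core_hits(sequence_before, registry, include_monomer_cores))
    cores_after = set(_core_hits(sequence_after, registry, include_monomer_cores))
    report.core_gained = sorted(cores_after - cores_before, key=lambda h: (h.start, h.label))
    report.core_lost = sorted(cores_before - cores_after, key=lambda h: (h.start, h.label))
    return report


def _attach_audit(plan: EditPlan, sequence: str, registry: Registry,
                  models: list[EnergyModel]) -> None:
    plan.predicted_effects = side_effect_audit(
        sequence, plan.apply(sequence), list(models), registry
    )
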