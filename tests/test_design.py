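import itertools

import numpy as np
import pytest

from conftest import random_sequence
from hoxcrm.design import (
    DesignError,
    EditPlan,
    Substitution,
    convert_class,
    knockout,
    optimize_flanks,
    restore,
    side_effect_audit,
)
from hoxcrm.energy import window_affinity
from hoxcrm.scan import find_cores, scan
from hoxcrm.seqs import revcomp
from hoxcrm.synth import make_default_models
from hoxcrm.registry import default_registry

REG = default_registry()
MODELS = make_default_models(REG)
AUDITED = [MODELS.dimer[f] for f in ("Lab", "Dfd", "Ubx")]


def main_site(sequence, factor="Dfd", threshold=0.15):
    sites = scan(sequence, MODELS.dimer[factor], threshold, registry=REG)
    assert sites, "fixture must contain a scorable site"
    return sites[0]


@pytest.fixture()
def planted():
    # class 2 site with suboptimal flanks inside a neutral context
    return "GCGCGCGCC" + "C" + "TGATTAAT" + "GAT" + "GCCGCGGCC"


def test_edit_plan_apply_revert_roundtrip(planted):
    plan = EditPlan([Substitution(2, "G", "A"), Substitution(5, "C", "T")])
    edited = plan.apply(planted)
    assert edited != planted
    assert plan.revert(edited) == planted
    with pytest.raises(DesignError):
        EditPlan([Substitution(1, "A", "A")])
    with pytest.raises(DesignError):
        EditPlan([Substitution(1, "A", "C"), Substitution(1, "A", "G")])


@pytest.mark.parametrize(
    "target,core_index,alt",
    [("class3", 5, "T"), ("class1", 5, "G")],
)
def test_convert_class_single_base(planted, target, core_index, alt):
    site = main_site(planted)
    plan = convert_class(planted, site, target, REG, models=AUDITED)
    assert len(plan) == 1
    (sub,) = plan.substitutions
    core_start = site.start + 1  # Exd flank occupies window index 0
    assert sub.position == core_start + core_index
    assert (sub.ref, sub.alt) == ("A", alt)
    assert plan.provenance["hamming"] == 1
    edited = plan.apply(planted)
    assert REG.classify_window(edited[core_start : core_start + 8]) == target


def test_convert_class_identity_and_roundtrip(planted):
    site = main_site(planted)
    assert len(convert_class(planted, site, "class2", REG)) == 0
    to_cl1 = convert_class(planted, site, "class1", REG)
    seq1 = to_cl1.apply(planted)
    back = convert_class(seq1, main_site(seq1, "Lab"), "class2", REG)
    assert back.apply(seq1) == planted


def test_convert_class_requires_registered_core(planted):
    site = main_site(planted)
    broken = site.__class__(**{**vars(site), "window": "ACGTACGTACGT"})
    with pytest.raises(DesignError):
        convert_class(planted, broken, "class1", REG)


def test_convert_class_minus_strand():
    seq = "GCGC" + revcomp("CTGATTAATGAT") + "GCGCGCGC"
    site = main_site(seq)
    assert site.strand == "-"
    plan = convert_class(seq, site, "class3", REG)
    edited = plan.apply(seq)
    hits = find_cores(edited, REG)
    assert [(h.label, h.strand) for h in hits] == [("class3", "-")]


def test_optimize_flanks_exact_and_core_locked(planted):
    model = MODELS.dimer["Dfd"]
    site = main_site(planted)
    plan = optimize_flanks(planted, site, model, REG, models=AUDITED)
    edited = plan.apply(planted)
    new_window = edited[site.start : site.end]
    assert window_affinity(model, new_window) == pytest.approx(1.0)
    # core untouched
    assert new_window[1:9] == site.window[1:9]
    core_positions = {site.start + i for i in range(1, 9)}
    assert all(s.position not in core_positions for s in plan.substitutions)
    # exhaustive check: no flank assignment scores higher
    best = max(
        window_affinity(model, a + "TGATTAAT" + b + c + d)
        for a in "ACGT" for b in "ACGT" for c in "ACGT" for d in "ACGT"
    )
    assert window_affinity(model, new_window) == pytest.approx(best)
    # already-optimal flanks -> empty plan
    again = optimize_flanks(edited, main_site(edited), model, REG)
    assert len(again) == 0


def test_restore_roundtrip_and_regions(planted):
    site = main_site(planted)
    ko = knockout(planted, REG, mode="core", models=AUDITED)
    mutated = ko.apply(planted)
    restored = restore(mutated, planted, [(site.start, site.end)])
    assert restored == planted  # knockout edit fell inside the site window
    assert restore(mutated, planted, []) == mutated
    assert restore(mutated, planted, [(0, len(planted))]) == planted
    with pytest.raises(Exception):
        restore(mutated[:-1], planted, [])


def exhaustive_minimum_edits(sequence, max_edits=2):
    """Oracle: smallest k such that some k-substitution plan removes all
    registered class cores without creating new ones."""
    if not find_cores(sequence, REG):
        return 0
    candidates = [
        Substitution(pos, sequence[pos], alt)
        for pos in range(len(sequence))
        for alt in "ACGT"
        if alt != sequence[pos]
    ]
    for k in range(1, max_edits + 1):
        for combo in itertools.combinations(candidates, k):
            if len({c.position for c in combo}) != k:
                continue
            if not find_cores(EditPlan(list(combo)).apply(sequence), REG):
                return k
    return None


def test_knockout_single_planted_core(planted):
    plan = knockout(planted, REG, mode="core", models=AUDITED)
    assert len(plan) == 1
    assert plan.provenance["certified"] is True
    assert not find_cores(plan.apply(planted), REG)
    assert exhaustive_minimum_edits(planted) == 1


def test_knockout_dual_core_single_shared_edit():
    seq = "GCGCC" + "TGATTAATGATTTAT" + "CGGCC"
    plan = knockout(seq, REG, mode="core")
    assert len(plan) == 1
    (sub,) = plan.substitutions
    assert sub.position == 5 + 7  # the single base shared by both cores
    edited = plan.apply(seq)
    assert not find_cores(edited, REG)
    assert exhaustive_minimum_edits(seq) == 1


def test_knockout_clean_sequence_is_empty_plan():
    plan = knockout("GCGCGCGCGCGC", REG, mode="core")
    assert len(plan) == 0 and plan.provenance["minimal_edits"] == 0


def test_knockout_affinity_mode():
    seq = "GCGCGCGCC" + "C" + "TGATTAAT" + "GAT" + "GCCGCGGCC"
    plan = knockout(seq, REG, mode="affinity", models=[MODELS.dimer["Dfd"]], ceiling=0.05)
    edited = plan.apply(seq)
    assert scan(edited, MODELS.dimer["Dfd"], 0.05) == []
    with pytest.raises(DesignError):
        knockout(seq, REG, mode="affinity", models=[], ceiling=0.05)


@pytest.mark.parametrize("seed", range(8))
def test_knockout_matches_exhaustive_minimum_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 30)
    # plant up to two cores at random non-clashing offsets
    cores = ["TGATTAAT", "TGATTTAT"]
    offsets = [2, 16]
    for core, off in zip(cores[: rng.integers(1, 3)], offsets):
        seq = seq[:off] + core + seq[off + 8 :]
    oracle = exhaustive_minimum_edits(seq)
    if oracle is None:
        pytest.skip("no 2-edit solution exists for this instance")
    plan = knockout(seq, REG, mode="core", max_edits=3)
    assert len(plan) == oracle
    assert not find_cores(plan.apply(seq), REG)


def test_audit_identity_is_empty(planted):
    report = side_effect_audit(planted, planted, AUDITED, REG)
    assert report.is_empty()


def test_audit_reports_conversion_side_effect():
    # class 1 conversion of a class 2 site that simultaneously creates a
    # high-affinity class 3 core out of the downstream overlap
    before = "CCTGATTAATTTATCC"
    site = main_site(before, threshold=0.05)
    plan = convert_class(before, site, "class1", REG, models=AUDITED)
    assert [s.position for s in plan.substitutions] == [7]
    after = plan.apply(before)
    assert after == "CCTGATTGATTTATCC"
    report = plan.predicted_effects
    gained = {(h.label, h.start) for h in report.core_gained}
    lost = {(h.label, h.start) for h in report.core_lost}
    assert ("class1", 2) in gained
    assert ("class3", 6) in gained
    assert lost == {("class2", 2)}
    # plan-attached audit equals an independently recomputed audit
    fresh = side_effect_audit(before, after, AUDITED, REG)
    assert {(h.label, h.start) for h in fresh.core_gained} == gained


def test_audit_after_knockout_shows_no_residual_core(planted):
    plan = knockout(planted, REG, mode="core", models=AUDITED)
    report = side_effect_audit(planted, plan.apply(planted), AUDITED, REG)
    assert {h.label for h in report.core_lost} == {"class2"}
    assert not report.core_gained
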