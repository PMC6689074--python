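import numpy as np
import pytest

from hoxcrm.energy import window_affinity
from hoxcrm.scan import find_cores, find_overlaps, scan
from hoxcrm.seqs import revcomp
from hoxcrm.synth import (
    CASSETTE_LEN,
    GenerationError,
    VARIANT_NAMES,
    make_fixture_suite,
    noisy_measurements,
    plant,
    random_background,
    recover_penalties,
    variant_windows,
)


def test_background_determinism_and_gc():
    a = random_background(200, seed=42)
    b = random_background(200, seed=42)
    assert a == b
    assert set(random_background(100, gc_fraction=0.0, seed=1)) <= {"A", "T"}
    assert set(random_background(100, gc_fraction=1.0, seed=1)) <= {"C", "G"}


def test_background_forbids_class_cores(registry):
    seq = random_background(500, seed=3)
    for core in registry.core_motifs().values():
        assert core not in seq and revcomp(core) not in seq


def test_plant_and_overlapping_plant(registry):
    seq = random_background(30, seed=0)
    planted = plant(seq, "TGATTAAT", 4)
    assert registry.classify_window(planted[4:12]) == "class2"
    minus = plant(seq, "TGATTAAT", 4, strand="-")
    assert registry.classify_window(revcomp(minus[4:12])) == "class2"
    dual = plant(plant(seq, "TGATTAAT", 4), "TGATTTAT", 11)
    assert dual[4:19] == "TGATTAATGATTTAT"
    with pytest.raises(GenerationError):
        plant(seq, "TGATTAAT", 28)


def test_suite_regenerates_byte_identically():
    assert make_fixture_suite(1).sequences == make_fixture_suite(1).sequences


def test_cassette_invariants(suite, registry):
    cassette = suite.sequences["cassette"]
    assert len(cassette) == CASSETTE_LEN == 55
    hits = find_cores(cassette, registry)
    class2 = [h for h in hits if h.label == "class2"]
    class3 = [h for h in hits if h.label == "class3"]
    assert len(class2) == 1 and len(class3) == 1
    assert find_overlaps(class2, class3, min_shared_bp=1)


def test_s1_is_inert(suite, registry):
    assert find_cores(suite.sequences["S1"], registry, include_monomer=True) == []


def test_fragment_lengths_and_concatenation(suite):
    seqs = suite.sequences
    lengths = suite.manifest["fragment_lengths"]
    assert (len(seqs["S1"]), len(seqs["S2"]), len(seqs["S3"])) == (
        lengths["S1"], lengths["S2"], lengths["S3"],
    )
    # the reporter-tested fragments span the 200-680 bp range
    for name in ("S1", "S2", "S1+55", "S1+S2", "vvl1+2"):
        assert 200 <= len(seqs[name]) <= 680
    assert seqs["vvl1+2"] == seqs["S1"] + seqs["S2"] + seqs["S3"]
    assert len(seqs["vvl1+2"]) == 680
    assert seqs["S1+55"] == seqs["S1"] + seqs["cassette"]
    assert seqs["S2"].startswith(seqs["cassette"])


def test_manifest_agrees_with_scanner(suite, registry, models):
    full = suite.sequences["vvl1+2"]
    main = suite.manifest["sites"]["main"]
    (site,) = scan(full, models.dimer["Dfd"], 0.15, registry=registry)
    assert (site.start, site.end) == tuple(main["window"])
    assert site.class_label == "class2"
    over = suite.manifest["sites"]["overlapping"]
    (osite,) = scan(full, models.dimer["Ubx"], 0.05, registry=registry)
    assert (osite.start, osite.end) == tuple(over["window"])
    assert osite.class_label == "class3"
    monomer_hits = scan(full, models.monomer["Ubx"], 0.1, registry=registry)
    got = {(s.start, s.end) for s in monomer_hits}
    want = {
        tuple(suite.manifest["sites"][k]["window"]) for k in ("monomer_S2", "monomer_S3")
    }
    assert got == want


def test_variants_follow_design_contracts(suite, registry):
    base = suite.sequences["S1+55"]
    assert suite.sequences["S1+55cl2"] == base
    for name, edits in (("S1+55cl3", 1), ("S1+55cl1", 1), ("S1+55mut", 1)):
        diff = [i for i, (a, b) in enumerate(zip(base, suite.sequences[name])) if a != b]
        assert len(diff) == edits
    cassette_region = suite.sequences["S1+55mut"][len(suite.sequences["S1"]):]
    assert not find_cores(cassette_region, registry)
    assert set(VARIANT_NAMES) <= set(suite.sequences)


def test_variant_windows_span_large_affinity_range(suite, models):
    windows = variant_windows(suite)
    for factor in ("Lab", "Dfd", "Ubx"):
        values = [window_affinity(models.dimer[factor], w) for w in windows.values()]
        assert len(set(np.round(values, 10))) == len(values)  # pairwise distinct
        assert max(values) / min(values) > 10


def test_noisy_measurements_cv_zero_exact(models):
    windows = ["ATAATC", "GTAATA", "CTGATC"]
    exact = noisy_measurements(models.monomer["Ubx"], windows, cv=0.0)
    np.testing.assert_allclose(
        exact, [window_affinity(models.monomer["Ubx"], w) for w in windows]
    )


def test_noisy_measurements_rank_preserved_at_low_cv(suite, models):
    # across the engineered variant windows (>10-fold affinity spread) a 5%
    # measurement CV almost never reorders the ranking
    from scipy.stats import kendalltau

    windows = list(variant_windows(suite).values())
    model = models.dimer["Ubx"]
    truth = [window_affinity(model, w) for w in windows]
    perfect = 0
    for rep in range(200):
        noisy = noisy_measurements(model, windows, cv=0.05, seed=10_000 + rep)
        if kendalltau(truth, noisy).statistic == pytest.approx(1.0):
            perfect += 1
    assert perfect >= 190  # >= 95% of replicates


def test_large_cv_degrades_ranking(suite, models):
    from scipy.stats import kendalltau

    windows = list(variant_windows(suite).values())
    model = models.dimer["Ubx"]
    truth = [window_affinity(model, w) for w in windows]
    taus = [
        kendalltau(truth, noisy_measurements(model, windows, cv=2.5, seed=rep)).statistic
        for rep in range(100)
    ]
    assert np.mean(taus) < 1.0


def test_penalty_recovery_within_three_se(models):
    result = recover_penalties(models.monomer["Ubx"], n=500, cv=0.1, seed=2026)
    assert result.within(3.0) == 1.0
    # estimates are genuinely informative, not vacuously wide
    assert np.all(result.stderr < 0.1)
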