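"""Synthetic inputs with the structure the analysis assumes.

The study system is a segmentally active enhancer dissected into three
sub-fragments, with its Hox input concentrated in a 55-bp cassette carrying
two overlapping Hox–Exd sites — a class 2 "main" site and a class 3
"overlapping" site whose cores share one base pair — plus dispersed weak
Hox-monomer sites in the downstream fragments.  Because the real enhancer
sequence is not published, this module *emulates* that architecture:

* neutral backgrounds are built base-by-base so that no registered class or
  monomer core occurs on either strand (constructive rejection sampling);
* the dual-core cassette uses the 15-bp geometry TGATTAATGATTTAT (class 2
  core at offset 0, class 3 core at offset 7, sharing exactly 1 bp), which
  admits the observed single-base dual knockout;
* fragment lengths (S1-like 300 bp, S2-like 250 bp including the cassette,
  S3-like 130 bp; concatenation 680 bp) sit inside the 200–680 bp range of
  the dissected fragments;
* class-anchored synthetic energy models stand in for fitted
  protein-binding models.  Their calibration (below) reproduces the
  *orderings* reported in vitro — class 2 complexes bind non-cognate cores
  appreciably (promiscuity), class 1 complexes bind non-cognate cores
  weakly, core-destroying mutations abolish binding, and suboptimal flanks
  attenuate binding severalfold — with pairwise-distinct affinities across
  the seven engineered variant windows.

The generated seven variant constructs (cl1, cl2 = identity, cl3, mut,
cl1OF, cl2OF, cl3OF) are produced by the design operations themselves, so
fixture geometry and designer behaviour cannot drift apart.

Every fixture regenerates byte-identically from (suite version, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import EditPlan, convert_class, knockout, optimize_flanks
from .energy import BASE_INDEX, EnergyModel, model_from_core, window_affinity
from .expression import ModelSet
from .registry import MONOMER_ARCHITECTURE, Registry, default_registry
from .scan import find_cores, find_overlaps, scan
from .seqs import ALPHABET, revcomp

SUITE_VERSION = "1"

LN2, LN2_5, LN4 = math.log(2), math.log(2.5), math.log(4)
LN10, LN20, LN50 = math.log(10), math.log(20), math.log(50)

#: class 2 core (offset 0) and class 3 core (offset 7) sharing exactly 1 bp
DUAL_CORE = "TGATTAATGATTTAT"

# -- synthetic model calibration -------------------------------------------
# Flank penalties shared by all composite (Hox–Exd) models: optimal flank
# bases A|core|G,A,A; suboptimal bases cost a 2- to 4-fold factor.
DIMER_FLANK_PENALTIES = {
    0: {"C": LN2, "G": LN2, "T": LN2},
    9: {"A": LN2, "C": LN2, "T": LN2},
    10: {"C": LN2, "G": LN2, "T": LN2},
    11: {"C": LN2, "G": LN4, "T": LN2_5},
}

# Core mismatches are strongly penalised (50-fold) except at the
# class-discriminating core position (template index 6, core index 5) where
# cross-class binding is graded: class 2 complexes are promiscuous, class 1
# complexes bind non-cognate cores weakly.
CLASS_DISCRIMINATING_POSITION = 6
DIMER_CORE_PENALTY = LN50
CLASS_CROSS_PENALTIES = {
    "class1": {"A": LN50, "T": LN20, "C": LN50},
    "class2": {"T": LN4, "G": LN10, "C": LN50},
    "class3": {"A": LN10, "G": LN20, "C": LN50},
}

MONOMER_CORE_PENALTY = LN10
GENERIC_MONOMER_FLANKS = {
    0: {"C": LN4, "G": LN4, "T": LN4},
    5: {"C": LN4, "G": LN4, "T": LN4},
}
ABDB_MONOMER_FLANKS = {
    0: {"A": LN4, "C": LN4, "T": LN4},
    5: {"A": LN4, "C": LN4, "T": LN4},
}

#: planted monomer elements: a generic-core site with one suboptimal flank
#: (relative affinity 0.25) and an optimal-flank Abd-B site (affinity 1.0)
GENERIC_MONOMER_PLANT = "AATAATC"
ABDB_MONOMER_PLANT = "GTTATG"


class GenerationError(RuntimeError):
    """Sampling constraints could not be satisfied within the attempt cap."""


def make_default_models(registry: Registry | None = None) -> ModelSet:
    """Class-anchored composite and monomer models for every Hox factor."""
    registry = registry or default_registry()
    dimer: dict[str, EnergyModel] = {}
    monomer: dict[str, EnergyModel] = {}
    for factor in registry.hox_factor_names():
        label = registry.factors[factor].hox_class
        dimer[factor] = model_from_core(
            registry.class_core(label),
            registry.architecture,
            DIMER_CORE_PENALTY,
            DIMER_FLANK_PENALTIES,
            core_overrides={CLASS_DISCRIMINATING_POSITION: CLASS_CROSS_PENALTIES[label]},
            name=f"{factor}-Exd",
            factor=factor,
            mode="dimer",
        )
        if factor == "Abd-B":
            monomer[factor] = model_from_core(
                "TTAT",
                MONOMER_ARCHITECTURE,
                MONOMER_CORE_PENALTY,
                ABDB_MONOMER_FLANKS,
                core_overrides={4: {"G": 0.0, "A": LN10, "C": LN10}},
                name="Abd-B-monomer",
                factor=factor,
                mode="monomer",
            )
        else:
            monomer[factor] = model_from_core(
                "TAAT",
                MONOMER_ARCHITECTURE,
                MONOMER_CORE_PENALTY,
                GENERIC_MONOMER_FLANKS,
                name=f"{factor}-monomer",
                factor=factor,
                mode="monomer",
            )
    return ModelSet(dimer=dimer, monomer=monomer)


# -- background generation ---------------------------------------------------

def random_background(
    length: int,
    gc_fraction: float = 0.5,
    forbid_cores: bool = True,
    seed: int | None = None,
    *,
    extra_forbid: tuple[str, ...] = (),
    registry: Registry | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Reproducible random sequence avoiding forbidden motifs on both strands.

    With ``forbid_cores`` the registered class cores (and their reverse
    complements) never occur.  The sequence is grown base by base, excluding
    any base that would complete a forbidden motif; this is exact, unlike
    whole-sequence rejection, and stays fast for motif-dense forbid sets.
    """
    if length < 1:
        raise GenerationError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise GenerationError("gc_fraction must lie in [0, 1]")
    registry = registry or default_registry()
    forbidden: set[str] = set(extra_forbid)
    forbidden |= {revcomp(m) for m in extra_forbid}
    if forbid_cores:
        for core in registry.core_motifs().values():
            forbidden.add(core)
            forbidden.add(revcomp(core))
    rng = rng if rng is not None else np.random.default_rng(seed)
    weights = np.array([
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2,
    ])
    out: list[str] = []
    for _ in range(length):
        allowed = []
        for base in ALPHABET:
            tail = "".join(out) + base
            if any(tail.endswith(m) for m in forbidden):
                continue
            allowed.append(base)
        if not allowed:
            raise GenerationError("no admissible base under the forbid set")
        w = np.array([weights[BASE_INDEX[b]] for b in allowed])
        if w.sum() == 0:
            w = np.ones(len(allowed))
        out.append(str(rng.choice(allowed, p=w / w.sum())))
    return "".join(out)


def plant(sequence: str, insert: str, position: int, strand: str = "+") -> str:
    """Replace ``sequence[position:position+len(insert)]`` with the insert
    (reverse-complemented for the minus strand); length is preserved."""
    if position < 0 or position + len(insert) > len(sequence):
        raise GenerationError(
            f"insert of length {len(insert)} does not fit at position {position}"
        )
    if strand == "-":
        insert = revcomp(insert)
    return sequence[:position] + insert + sequence[position + len(insert):]


# -- fixture suite -----------------------------------------------------------

# cassette layout (55 bp): 19 bp filler | C | dual 15-mer | ACG | 17 bp filler
CASSETTE_LEN = 55
_DUAL_OFFSET = 20
#: cassette coordinates of the class 2 main core and class 3 overlapping core
MAIN_CORE_CASSETTE = (_DUAL_OFFSET, _DUAL_OFFSET + 8)
OVERLAP_CORE_CASSETTE = (_DUAL_OFFSET + 7, _DUAL_OFFSET + 15)
#: 12-bp site windows (Exd flank | core | 3 Hox flanks)
MAIN_WINDOW_CASSETTE = (_DUAL_OFFSET - 1, _DUAL_OFFSET + 11)
OVERLAP_WINDOW_CASSETTE = (_DUAL_OFFSET + 6, _DUAL_OFFSET + 18)

S1_LEN, S2_LEN, S3_LEN = 300, 250, 130

VARIANT_NAMES = (
    "S1+55cl1", "S1+55cl2", "S1+55cl3", "S1+55mut",
    "S1+55cl1OF", "S1+55cl2OF", "S1+55cl3OF",
)


@dataclass
class FixtureSuite:
    """Named sequences, engineered variants and a site-coordinate manifest."""

    sequences: dict[str, str]
    manifest: dict
    plans: dict[str, EditPlan]
    seed: int
    version: str = SUITE_VERSION


def _build_cassette(registry: Registry, rng: np.random.Generator) -> str:
    extra = tuple(registry.forbidden_background_motifs())
    filler_a = random_background(19, forbid_cores=False, extra_forbid=extra,
                                 registry=registry, rng=rng)
    filler_b = random_background(17, forbid_cores=False, extra_forbid=extra,
                                 registry=registry, rng=rng)
    cassette = filler_a + "C" + DUAL_CORE + "ACG" + filler_b
    assert len(cassette) == CASSETTE_LEN
    return cassette


def _build_fragment(length: int, plants: list[tuple[int, str]],
                    registry: Registry, rng: np.random.Generator) -> str:
    extra = tuple(registry.forbidden_background_motifs())
    frag = random_background(length, forbid_cores=False, extra_forbid=extra,
                             registry=registry, rng=rng)
    for position, insert in plants:
        frag = plant(frag, insert, position)
    return frag


def _validate_suite(suite: FixtureSuite, models: ModelSet, registry: Registry) -> None:
    seqs = suite.sequences
    cassette = seqs["cassette"]
    if len(cassette) != CASSETTE_LEN:
        raise GenerationError("cassette length drifted")
    hits = find_cores(cassette, registry)
    by_label = {}
    for h in hits:
        by_label.setdefault(h.label, []).append(h)
    if sorted(by_label) != ["class2", "class3"] or any(len(v) != 1 for v in by_label.values()):
        raise GenerationError(f"cassette core content wrong: {hits}")
    if not find_overlaps(by_label["class2"], by_label["class3"], min_shared_bp=1):
        raise GenerationError("cassette cores do not overlap")
    if find_cores(seqs["S1"], registry, include_monomer=True):
        raise GenerationError("S1 background contains a registered core")

    full = seqs["vvl1+2"]
    expect = suite.manifest["sites"]
    # The scan at a low threshold must contain exactly the engineered
    # windows (plus known cross-class echoes) and nothing else: this both
    # pins the manifest to scanner output and certifies that the random
    # background carries no near-site for any composite model.
    for factor, expected_names in (
        ("Dfd", {"main"}),
        ("Ubx", {"overlapping", "main"}),  # weak cross-class echo on the main site
        ("Lab", set()),
    ):
        model = models.dimer[factor]
        sites = scan(full, model, threshold=0.017, registry=registry)
        got = {(s.start, s.strand) for s in sites}
        want = {(expect[name]["window"][0], "+") for name in expected_names}
        if got != want:
            raise GenerationError(f"{factor} composite scan disagrees with manifest: {sites}")
    generic_sites = scan(full, models.monomer["Ubx"], threshold=0.1, registry=registry)
    want_generic = {
        (expect[name]["window"][0], "+") for name in ("monomer_S2", "monomer_S3")
    }
    if {(s.start, s.strand) for s in generic_sites} != want_generic:
        raise GenerationError(f"generic monomer scan disagrees: {generic_sites}")
    abdb_sites = scan(full, models.monomer["Abd-B"], threshold=0.1, registry=registry)
    want_abdb = {
        (expect[name]["window"][0], "+") for name in ("abdb_S2", "abdb_S3")
    }
    if {(s.start, s.strand) for s in abdb_sites} != want_abdb:
        raise GenerationError(f"Abd-B monomer scan disagrees: {abdb_sites}")

    mut_cassette = seqs["S1+55mut"][S1_LEN:]
    if any(h.label.startswith("class") for h in find_cores(mut_cassette, registry)):
        raise GenerationError("mut variant retains a class core")


def _design_variants(
    base: str, models: ModelSet, registry: Registry
) -> tuple[dict[str, str], dict[str, EditPlan]]:
    """Engineer the seven variant constructs from the base construct."""
    audited = [models.dimer[f] for f in ("Lab", "Dfd", "Ubx")]
    main_sites = scan(base, models.dimer["Dfd"], threshold=0.15, registry=registry)
    if len(main_sites) != 1:
        raise GenerationError(f"expected a unique main site, got {main_sites}")
    main = main_sites[0]

    sequences: dict[str, str] = {}
    plans: dict[str, EditPlan] = {}

    plans["S1+55cl2"] = EditPlan([], provenance={"op": "identity"})
    sequences["S1+55cl2"] = base

    for target, variant in (("class3", "S1+55cl3"), ("class1", "S1+55cl1")):
        plans[variant] = convert_class(base, main, target, registry, models=audited)
        sequences[variant] = plans[variant].apply(base)

    plans["S1+55mut"] = knockout(
        base, registry, mode="core", models=audited,
        region=(S1_LEN, S1_LEN + CASSETTE_LEN),
    )
    sequences["S1+55mut"] = plans["S1+55mut"].apply(base)

    plans["S1+55cl2OF"] = optimize_flanks(base, main, models.dimer["Dfd"], registry,
                                          models=audited)
    sequences["S1+55cl2OF"] = plans["S1+55cl2OF"].apply(base)

    for factor, converted, variant in (
        ("Ubx", "S1+55cl3", "S1+55cl3OF"),
        ("Lab", "S1+55cl1", "S1+55cl1OF"),
    ):
        seq = sequences[converted]
        sites = scan(seq, models.dimer[factor], threshold=0.15, registry=registry)
        if len(sites) != 1:
            raise GenerationError(f"expected unique converted site for {factor}")
        plan = optimize_flanks(seq, sites[0], models.dimer[factor], registry, models=audited)
        plans[variant] = plan
        sequences[variant] = plan.apply(seq)
    return sequences, plans


def make_fixture_suite(seed: int, *, registry: Registry | None = None,
                       models: ModelSet | None = None, max_attempts: int = 100) -> FixtureSuite:
    """Generate and validate the full fixture family for one seed."""
    registry = registry or default_registry()
    models = models or make_default_models(registry)
    rng = np.random.default_rng(seed)
    last_error: Exception | None = None
    for _ in range(max_attempts):
        try:
            cassette = _build_cassette(registry, rng)
            s1 = _build_fragment(S1_LEN, [], registry, rng)
            s2_rest = _build_fragment(
                S2_LEN - CASSETTE_LEN,
                [(100 - CASSETTE_LEN, GENERIC_MONOMER_PLANT),
                 (180 - CASSETTE_LEN, ABDB_MONOMER_PLANT)],
                registry, rng,
            )
            s2 = cassette + s2_rest
            s3 = _build_fragment(
                S3_LEN, [(40, GENERIC_MONOMER_PLANT), (90, ABDB_MONOMER_PLANT)],
                registry, rng,
            )
            base = s1 + cassette
            sequences = {
                "S1": s1, "cassette": cassette, "S2": s2, "S3": s3,
                "S1+55": base, "S1+S2": s1 + s2, "vvl1+2": s1 + s2 + s3,
            }
            variant_seqs, plans = _design_variants(base, models, registry)
            sequences.update(variant_seqs)

            main_w = (S1_LEN + MAIN_WINDOW_CASSETTE[0], S1_LEN + MAIN_WINDOW_CASSETTE[1])
            over_w = (S1_LEN + OVERLAP_WINDOW_CASSETTE[0], S1_LEN + OVERLAP_WINDOW_CASSETTE[1])
            manifest = {
                "version": SUITE_VERSION,
                "seed": seed,
                "fragment_lengths": {"S1": S1_LEN, "S2": S2_LEN, "S3": S3_LEN},
                "sites": {
                    "main": {
                        "class": "class2",
                        "core": (S1_LEN + MAIN_CORE_CASSETTE[0], S1_LEN + MAIN_CORE_CASSETTE[1]),
                        "window": main_w,
                    },
                    "overlapping": {
                        "class": "class3",
                        "core": (S1_LEN + OVERLAP_CORE_CASSETTE[0],
                                 S1_LEN + OVERLAP_CORE_CASSETTE[1]),
                        "window": over_w,
                    },
                    "monomer_S2": {"window": (S1_LEN + 100 + 1, S1_LEN + 100 + 7)},
                    "abdb_S2": {"window": (S1_LEN + 180, S1_LEN + 186)},
                    "monomer_S3": {"window": (S1_LEN + S2_LEN + 40 + 1, S1_LEN + S2_LEN + 40 + 7)},
                    "abdb_S3": {"window": (S1_LEN + S2_LEN + 90, S1_LEN + S2_LEN + 96)},
                },
                "variant_window": main_w,
            }
            suite = FixtureSuite(sequences=sequences, manifest=manifest,
                                 plans=plans, seed=seed)
            _validate_suite(suite, models, registry)
            return suite
        except GenerationError as exc:
            last_error = exc
            continue
    raise GenerationError(f"fixture generation failed after {max_attempts} attempts: {last_error}")


def variant_windows(suite: FixtureSuite) -> dict[str, str]:
    """The engineered 12-bp main-site window of each variant construct."""
    lo, hi = suite.manifest["variant_window"]
    return {name: suite.sequences[name][lo:hi] for name in VARIANT_NAMES}


# -- pseudo-measurements -----------------------------------------------------

def noisy_measurements(
    model: EnergyModel,
    windows: list[str],
    cv: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiplicative lognormal pseudo-measurements of window affinities.

    Emulates quantified relative band intensities with coefficient of
    variation ``cv``; the noise factor has mean 1.  cv=0 returns the exact
    affinities.
    """
    if cv < 0:
        raise GenerationError("cv must be >= 0")
    true = np.array([window_affinity(model, w) for w in windows])
    if cv == 0:
        return true
    rng = rng if rng is not None else np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(windows))
    return true * noise


@dataclass
class RecoveryResult:
    """Penalty-recovery regression summary (one coefficient per non-anchored
    position/base pair)."""

    estimates: np.ndarray
    truth: np.ndarray
    stderr: np.ndarray
    labels: list[tuple[int, str]]

    @property
    def z(self) -> np.ndarray:
        return (self.estimates - self.truth) / self.stderr

    def within(self, k: float = 3.0) -> float:
        """Fraction of penalties recovered within k standard errors."""
        return float(np.mean(np.abs(self.z) <= k))


def recover_penalties(
    model: EnergyModel, n: int = 500, cv: float = 0.1, seed: int | None = None
) -> RecoveryResult:
    """Re-estimate a model's penalties from noisy affinities of random windows.

    Fits -log(affinity) by ordinary least squares on per-position base
    indicators (anchored base as reference, intercept absorbing the small
    lognormal bias).  Valid because log affinity is additive across
    positions and the multiplicative noise is homoskedastic on the log
    scale.
    """
    rng = np.random.default_rng(seed)
    L = model.footprint
    codes = rng.integers(0, 4, size=(n, L))
    windows = ["".join(ALPHABET[c] for c in row) for row in codes]
    y = -np.log(noisy_measurements(model, windows, cv, rng=rng))

    refs = model.penalties.argmin(axis=1)
    labels = [
        (pos, base)
        for pos in range(L)
        for b_idx, base in enumerate(ALPHABET)
        if b_idx != refs[pos]
    ]
    X = np.zeros((n, len(labels) + 1))
    X[:, 0] = 1.0
    for j, (pos, base) in enumerate(labels, start=1):
        X[:, j] = codes[:, pos] == BASE_INDEX[base]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    stderr = np.sqrt(np.diag(cov))
    truth = np.array([model.penalties[pos, BASE_INDEX[base]] for pos, base in labels])
    return RecoveryResult(
        estimates=beta[1:], truth=truth, stderr=stderr[1:], labels=labels
    )
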