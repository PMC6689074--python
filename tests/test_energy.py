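import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_model, random_sequence
from hoxcrm.energy import (
    EnergyModel,
    ModelError,
    model_from_core,
    normalize_to_reference,
    read_model,
    window_affinity,
    write_model,
)
from hoxcrm.registry import SiteArchitecture
from hoxcrm.seqs import SequenceError

ARCH = SiteArchitecture()


def simple_model(penalty_at=None):
    """Anchored 4-bp model: optimal window AAAA; selected positions give
    base C a penalty."""
    pen = np.zeros((4, 4))
    for pos, value in (penalty_at or {}).items():
        pen[pos, 1] = value  # base C
    return EnergyModel(name="toy", factor="t", mode="monomer", penalties=pen)


def test_optimal_window_scores_one():
    assert window_affinity(simple_model(), "AAAA") == pytest.approx(1.0)


def test_single_and_double_penalty_factors():
    m = simple_model({0: math.log(2), 2: math.log(2)})
    assert window_affinity(m, "CAAA") == pytest.approx(0.5)
    assert window_affinity(m, "CACA") == pytest.approx(0.25)


def test_window_length_and_alphabet_handling():
    m = simple_model()
    with pytest.raises(SequenceError):
        window_affinity(m, "AAA")
    assert window_affinity(m, "ANAA") == 0.0  # flagged as unscorable


def test_unanchored_and_negative_penalties_rejected():
    pen = np.full((3, 4), 0.5)
    with pytest.raises(ModelError, match="not anchored"):
        EnergyModel("bad", "t", "monomer", pen)
    pen = np.zeros((3, 4))
    pen[1, 2] = -0.1
    with pytest.raises(ModelError, match="negative"):
        EnergyModel("bad", "t", "monomer", pen)


def test_normalize_to_reference():
    # penalise every non-A base so both strands of the reference are suboptimal
    pen = np.zeros((4, 4))
    pen[:, 1:] = math.log(2)
    m = EnergyModel(name="allA", factor="t", mode="monomer", penalties=pen)
    # reference containing the optimal window: norm unchanged
    normed = normalize_to_reference(m, ["TTAAAATT"])
    assert normed.norm_max == pytest.approx(1.0)
    # reference whose best raw affinity is 0.5: all scores doubled
    normed = normalize_to_reference(m, ["CAAA"])
    assert normed.norm_max == pytest.approx(0.5)
    assert window_affinity(normed, "CAAA") == pytest.approx(1.0)
    assert window_affinity(normed, "AAAA") == pytest.approx(2.0)
    with pytest.raises(ModelError):
        normalize_to_reference(m, [])
    with pytest.raises(ModelError):
        normalize_to_reference(m, ["AC"])  # shorter than footprint


def test_model_from_core_class_anchoring():
    m = model_from_core("TGATTAAT", ARCH, math.log(10), name="cl2", mode="dimer")
    optimal = m.optimal_window()
    assert ARCH.core_of(optimal) == "TGATTAAT"
    assert window_affinity(m, optimal) == pytest.approx(1.0)
    # single core mismatch costs the core factor
    cl3_window = optimal[:6] + "T" + optimal[7:]
    assert ARCH.core_of(cl3_window) == "TGATTTAT"
    assert window_affinity(m, cl3_window) == pytest.approx(0.1)
    # a class-3-anchored model prefers its own core under any core penalty
    m3 = model_from_core("TGATTTAT", ARCH, 0.7, mode="dimer")
    assert window_affinity(m3, m3.optimal_window()) > window_affinity(
        m3, m3.optimal_window()[:6] + "A" + m3.optimal_window()[7:]
    )


def test_model_from_core_width_mismatch():
    with pytest.raises(ModelError):
        model_from_core("TGAT", ARCH, 1.0)


def test_json_roundtrip_and_schema_errors(tmp_path):
    rng = np.random.default_rng(0)
    m = random_model(rng, 6)
    path = tmp_path / "model.json"
    write_model(m, path)
    loaded = read_model(path)
    assert loaded.name == m.name and loaded.mode == m.mode
    np.testing.assert_allclose(loaded.penalties, m.penalties)
    assert loaded.norm_max == m.norm_max

    import json

    payload = json.loads(path.read_text())
    payload["penalties"][2][0] = -1.0
    bad = tmp_path / "bad.json"
    bad.write_text(json.dumps(payload))
    with pytest.raises(ModelError, match="penalties"):
        read_model(bad)

    payload = json.loads(path.read_text())
    payload["penalties"][3] = [0.1, 0.2, 0.3, 0.4]  # unanchored position
    bad.write_text(json.dumps(payload))
    with pytest.raises(ModelError, match="position 3"):
        read_model(bad)

    payload = json.loads(path.read_text())
    del payload["norm_max"]
    bad.write_text(json.dumps(payload))
    with pytest.raises(ModelError, match="norm_max"):
        read_model(bad)


@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000), pos=st.integers(0, 5))
def test_mutation_to_higher_penalty_never_increases_affinity(seed, pos):
    rng = np.random.default_rng(seed)
    m = random_model(rng, 6)
    window = random_sequence(rng, 6)
    base_order = np.argsort(m.penalties[pos])
    worse = "ACGT"[base_order[-1]]
    better = "ACGT"[base_order[0]]
    w_better = window[:pos] + better + window[pos + 1 :]
    w_worse = window[:pos] + worse + window[pos + 1 :]
    assert window_affinity(m, w_worse) <= window_affinity(m, w_better) + 1e-15


@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_log_affinity_additivity(seed):
    rng = np.random.default_rng(seed)
    m = random_model(rng, 8)
    window = random_sequence(rng, 8)
    per_position = sum(
        m.penalties[i, "ACGT".index(b)] for i, b in enumerate(window)
    )
    assert math.log(window_affinity(m, window)) == pytest.approx(
        -per_position, abs=1e-12
    )
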