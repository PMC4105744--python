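import numpy as np
import pytest

from craclash import (
    ReferenceSet,
    SimulationConfig,
    default_model,
    generate_reference,
    plant_interaction,
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture()
def tiny_ref():
    """Two short RNAs with distinctive sequences for mapping tests."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGU"))
    return ReferenceSet(
        rnas={
            "r1": "".join(rng.choice(bases, size=200)),
            "r2": "".join(rng.choice(bases, size=150)),
        },
        classes={"r1": "rRNA", "r2": "snoRNA"},
    )


def make_planted_pair(seed: int, length: int = 500, site_len: int = 19):
    """Random 500-nt RNA pair with a GC-rich perfect-complement site planted.

    Returns (reference, planted duplex truth).  Used by window-scan tests
    and the acceptance checks.
    """
    rng = np.random.default_rng(seed)
    ref = generate_reference(seed, [("q", length, "other"), ("t", length, "other")])
    t_start = int(rng.integers(30, length - site_len - 30))
    q_start = int(rng.integers(30, length - site_len - 30))
    gc_rich = "".join(
        rng.choice(np.array(list("ACGU")), size=site_len, p=[0.1, 0.4, 0.4, 0.1])
    )
    rnas = dict(ref.rnas)
    rnas["t"] = rnas["t"][: t_start - 1] + gc_rich + rnas["t"][t_start - 1 + site_len :]
    ref = ReferenceSet(rnas=rnas, classes=dict(ref.classes))
    ref, truth = plant_interaction(
        ref, ("t", t_start), ("q", q_start), site_len, seed=seed
    )
    return ref, truth.duplexes[0]


@pytest.fixture()
def quiet_cfg():
    """Error-free simulation config for deterministic fixtures."""
    return SimulationConfig(
        seed=1, n_reads=200, crosslink_rate=0.0, background_error_rate=0.0
    )
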