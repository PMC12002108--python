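import pytest

from zndesign.fixtures import build_design_scene, build_ideal_helix

P1 = "HMENCERRFARSDELSRHAHKC"
P1C = "HNMECLFARSSEDRRERHHKAC"
P1_ANCHORS = (1, 5, 18, 22)
P2 = "HTICRQCLEKLLASSINGVRCTYCTKEFVFDTIQSHQYQC"
P2C = "HTISRQSLEKLLASSINGVRSTYCTKEFVFDTIQSHQYQC"


@pytest.fixture(scope="session")
def positive_scene():
    return build_design_scene("positive", seed=1)


@pytest.fixture(scope="session")
def negative_scenes():
    return {
        kind: build_design_scene(kind, seed=1)
        for kind in ("donor_far", "long_gap", "wrong_composition", "terminal_coil")
    }


@pytest.fixture(scope="session")
def p1_model():
    """Idealized helical model carrying the P1 sequence."""
    return build_ideal_helix(P1, source_id="p1-model")
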