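import pytest

import studyprov as sp


@pytest.fixture(scope="session")
def patterns():
    return sp.default_patterns()


def ingest_stream(events, patterns=None):
    state = sp.BuilderState(**({"patterns": patterns} if patterns else {}))
    for ev in events:
        sp.ingest_event(state, ev)
    return state


@pytest.fixture()
def fig2_state():
    return ingest_stream(sp.fig2_stream())


@pytest.fixture()
def ministudy():
    """Factory: build a full (conceptual+refine+adapt) study state."""

    def build(seed=0, refine=3, invalid_fraction=0.0):
        script = sp.StudyScript(
            phases=(sp.Phase("conceptual", 1), sp.Phase("refine", refine), sp.Phase("adapt", 1)),
            seed=seed,
            invalid_fraction=invalid_fraction,
        )
        bundle = sp.generate_stream(script)
        return ingest_stream(bundle.events), bundle

    return build
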