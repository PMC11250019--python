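import pytest

import fifplan as fp


@pytest.fixture(scope="session")
def head():
    """Default head phantom: (density, body, ptv) at 2.5-mm spacing."""
    return fp.make_head_phantom()


@pytest.fixture(scope="session")
def original_plan(head):
    _, body, ptv = head
    return fp.make_original_plan(body, ptv)


@pytest.fixture(scope="session")
def engine(head):
    """Shared dose engine (default config); variants reuse its ray trace."""
    density, _, _ = head
    return fp.DoseEngine(density, fp.EngineConfig())


@pytest.fixture(scope="session")
def dose_original(engine, original_plan):
    dose, _ = engine.plan_dose(original_plan)
    return dose


@pytest.fixture(scope="session")
def fif_result(head, original_plan, engine, dose_original):
    """Full two-step run on the default (mild-hotspot) conditions."""
    density, _, ptv = head
    return fp.autofif(
        original_plan, density, ptv, fp.FIFConfig(), engine=engine, dose_orig=dose_original
    )


@pytest.fixture(scope="session")
def severe_cfg():
    """Steeper falloff producing a deep anterior/posterior hotspot that
    costs Step 1 more than the 1-pp D95 criterion."""
    return fp.FIFConfig(engine=fp.EngineConfig(mu_eff=0.0022))


@pytest.fixture(scope="session")
def severe_result(head, original_plan, engine, severe_cfg):
    density, _, ptv = head
    eng = engine.variant(severe_cfg.engine)
    return fp.autofif(original_plan, density, ptv, severe_cfg, engine=eng)


@pytest.fixture(scope="session")
def small_head():
    """Coarse small phantom for fast engine/IO/CLI tests."""
    return fp.make_head_phantom(40.0, 55.0, 45.0, spacing=5.0)
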