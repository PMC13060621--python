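import numpy as np
import pytest

from sxalign.cell import CrystalState, UnitCell, random_orientation
from sxalign.config import SimConfig, default_beam, default_cell, four_panel_geometry


@pytest.fixture(scope="session")
def geometry4():
    """The stock four-quadrant detector (1024 px panels, 100 um, 100 mm)."""
    return four_panel_geometry()


@pytest.fixture(scope="session")
def beam():
    return default_beam()


@pytest.fixture(scope="session")
def cell_mono():
    return default_cell()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A cheaper world for unit tests: smaller cell, fewer reflections."""
    return SimConfig(cell=UnitCell("monoclinic", 60.0, 40.0, 50.0, 90.0, 100.0, 90.0))


def crystal(cell, seed):
    return CrystalState(cell=cell, orientation=random_orientation(np.random.default_rng(seed)))


@pytest.fixture(scope="session")
def crystal_mono(cell_mono):
    return crystal(cell_mono, 7)


@pytest.fixture(scope="session")
def fitted_records(small_config):
    """Real records from local fits in the small world, with the misaligned
    model geometry of a 50 um x shift of q0."""
    from sxalign.geometry import CorrectionSet, apply_corrections
    from sxalign.localfit import build_mille_record, local_fit, truth_pairing
    from sxalign.millepede import GlobalParamRegistry, hierarchy_constraints
    from sxalign.sketch import simulate_dataset

    cfg = small_config
    ds = simulate_dataset(12, 9, cfg)
    model = apply_corrections(cfg.geometry,
                              CorrectionSet.from_entries([("q0", "tx", 0.05)]))
    registry = GlobalParamRegistry.from_hierarchy(model, level=1)
    records = []
    for p in ds.patterns:
        res = local_fit(p.crystal, (p.panels, p.fs, p.ss), truth_pairing(p),
                        model, cfg.beam)
        assert res.converged
        records.append(build_mille_record(res, model, cfg.beam, registry, p.pattern_id))
    constraints = hierarchy_constraints(registry, model)
    return registry, constraints, records, model


@pytest.fixture(scope="session")
def triclinic_systems():
    """Whole-detector refinement incl. out-of-plane tilts, triclinic cells,
    with and without the excitation-error rows."""
    from sxalign.localfit import build_mille_record, local_fit, truth_pairing
    from sxalign.millepede import (
        GlobalParamRegistry,
        NormalSystem,
        accumulate,
        hierarchy_constraints,
    )
    from sxalign.sketch import simulate_dataset

    cfg = SimConfig(cell=UnitCell("triclinic", 40.0, 50.0, 60.0, 80.0, 95.0, 105.0))
    ds = simulate_dataset(10, 7, cfg)
    reg = GlobalParamRegistry.from_hierarchy(cfg.geometry, level=0)
    cons = hierarchy_constraints(reg, cfg.geometry)
    records = []
    for p in ds.patterns:
        res = local_fit(p.crystal, (p.panels, p.fs, p.ss), truth_pairing(p),
                        cfg.geometry, cfg.beam)
        if res.converged:
            records.append(build_mille_record(res, cfg.geometry, cfg.beam,
                                              reg, p.pattern_id))
    assert len(records) >= 8
    systems = {}
    for use_e in (True, False):
        system = NormalSystem.empty(reg)
        for r in records:
            accumulate(r, system, reg, use_excitation=use_e)
        systems[use_e] = system
    return reg, cons, systems
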