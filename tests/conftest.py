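import numpy as np
import pytest

from filasim.params import (SimConfig, MechParams, StericParams, EntityParams,
                            RunParams)
from filasim.world import World


def free_config(Lp=15.0, kBT=None, dt=None, seed=1, duration=5.0,
                steric=False):
    """Config with no pattern and no entities (free fibers only)."""
    mech = MechParams(Lp=Lp, dt=dt) if kBT is None else \
        MechParams(Lp=Lp, kBT=kBT, dt=dt)
    return SimConfig(
        geometry={"rects": []},
        mech=mech,
        steric=StericParams(enabled=steric),
        entities=EntityParams(nucleators_per_region=0, arp_per_region=0,
                              binder_density=0.0),
        run=RunParams(duration=duration, seed=seed, fiber_budget=10**9),
    )


def free_world(fibers, growing=False, **kw):
    w = World.from_fibers([np.asarray(f, float) for f in fibers],
                          config=free_config(**kw))
    w.growing[:] = growing
    return w


@pytest.fixture(scope="session")
def branched_world():
    """A bar simulation run long enough to accumulate >= 600 branching
    events (shared by the branching statistics tests)."""
    cfg = SimConfig(
        geometry={"preset": "bar", "length": 8.0, "width": 1.0},
        mech=MechParams(Lp=15.0),
        steric=StericParams(),
        entities=EntityParams(nucleators_per_region=40, arp_per_region=700),
        run=RunParams(duration=60.0, seed=11, fiber_budget=700),
    )
    w = World(cfg)
    w.run()
    assert len(w.branch_angles) >= 500
    return w
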