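import numpy as np
import pandas as pd
import pytest

from ssmi import ProbeCalibration, SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed 11)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(default_sim):
    """Calibration fitted on the training donor of the default simulation."""
    sim = default_sim
    model = ProbeCalibration(sim.array, sim.seq_tpm, sim.annotation, sim.metadata)
    return model.fit(train_donor="brain2")


@pytest.fixture(scope="session")
def deep_sim():
    """Deep-coverage simulation (depth 1e6) for shape analyses whose knee /
    plateau sits beyond the observable range at the scaled-down default
    depth."""
    return simulate(SimulationConfig(seed=11, depth=1e6))


@pytest.fixture(scope="session")
def noisefree_sim():
    """Zero-noise, no off-target, unbounded-range simulation (seed 7)."""
    return simulate(SimulationConfig(seed=7).noise_free())


@pytest.fixture(scope="session")
def noisefree_fitted(noisefree_sim):
    sim = noisefree_sim
    model = ProbeCalibration(
        sim.array, sim.seq_tpm, sim.annotation, sim.metadata, tbt=False, epsilon=0.0
    )
    return model.fit(train_donor="brain2")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tiny_metadata(n_regions=3, donors=("d1", "d2"), reps=2, region_class=None):
    """Small hand-made metadata grid for unit tests."""
    rows = []
    for d in donors:
        for i in range(n_regions):
            cls = (
                region_class[i]
                if region_class is not None
                else ("neocortex" if i % 2 == 0 else "non_neocortex")
            )
            for h in ("L",):
                for r in range(1, reps + 1):
                    rows.append(
                        {
                            "sample_id": f"{d}_r{i}_{h}{r}",
                            "donor": d,
                            "region": f"r{i}",
                            "region_class": cls,
                            "hemisphere": h,
                            "replicate": r,
                            "batch": d,
                        }
                    )
    from ssmi import SampleMetadata

    return SampleMetadata(pd.DataFrame(rows))
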