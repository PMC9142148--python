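import numpy as np
import pytest

import gripdecode as gd


@pytest.fixture(scope="session")
def coupled_session():
    """Short force-coupled session used by several unit tests: recording,
    referenced features, and target bundle (gamma coupling 1, seed 1)."""
    cfg = gd.SimulationConfig(duration_s=120.0, n_movements=13, seed=1)
    rec, force, truth = gd.generate_recording(cfg)
    fs = gd.extract_feature_series(gd.rereference(rec))
    tgt = gd.ForceTarget.from_raw(force, fs.t_end)
    return dict(cfg=cfg, rec=rec, force=force, truth=truth, features=fs, target=tgt)


@pytest.fixture(scope="session")
def hub_connectome():
    """Planted-hub connectome fixture at the reference size."""
    return gd.generate_connectome(n_sites=60, n_fibers=400, slope_a=1.0, noise_sd=0.1, seed=3)
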