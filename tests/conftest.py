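import pytest

import facesft as fs


@pytest.fixture(scope="session")
def design():
    return fs.default_design()


@pytest.fixture(scope="session")
def grt(design):
    return fs.default_grt(design)


@pytest.fixture(scope="session")
def lba():
    return fs.default_lba()


@pytest.fixture(scope="session")
def serial_spec(design, grt, lba):
    return fs.ModelSpec(architecture="serial_st", lba=lba, grt=grt, p_x=0.6)


@pytest.fixture(scope="session")
def parallel_spec(design, grt, lba):
    return fs.ModelSpec(architecture="parallel_st", lba=lba, grt=grt)


@pytest.fixture(scope="session")
def coactive_spec(design, grt, lba):
    return fs.ModelSpec(architecture="coactive", lba=lba, grt=grt)


@pytest.fixture(scope="session")
def mixed_spec(design, grt, lba):
    return fs.ModelSpec(architecture="mixed_serial_parallel", lba=lba, grt=grt,
                        p_x=0.4, p_serial=0.6, m=1.3, A_parallel=200.0)


@pytest.fixture(scope="session")
def serial_dataset(design, serial_spec):
    """One participant's double-factorial dataset from the serial truth."""
    truth = fs.GroundTruth(model_spec=serial_spec, design=design,
                           n_trials_per_item=400, seed=11)
    return fs.simulate_rt_dataset(truth)


@pytest.fixture()
def trials_csv(tmp_path, serial_dataset):
    path = tmp_path / "trials.csv"
    fs.write_trials(serial_dataset, path)
    return path


@pytest.fixture(scope="session")
def simulate_items():
    """Factory: correct target-item RT samples keyed LL/LH/HL/HH."""
    def _simulate(spec, n, seed):
        out = {}
        for role, (x, y) in {"HH": (2, 2), "HL": (2, 1),
                             "LH": (1, 2), "LL": (1, 1)}.items():
            resp, rts = fs.simulate_model(spec, x, y, n, seed=seed)
            out[role] = rts[resp == "target"]
        return out
    return _simulate
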