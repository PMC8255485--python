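import pytest

from usvscore.io_formats import build_zone_map
from usvscore.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def zone_map():
    return build_zone_map()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A written 2-animal cohort shared by I/O and pipeline tests."""
    root = tmp_path_factory.mktemp("cohort")
    config = SimConfig(n_animals=2, seed=11)
    dataset = generate_cohort(config, root)
    return config, dataset


def write_csv(path, text):
    path.write_text(text)
    return path


@pytest.fixture()
def label_fixture(tmp_path):
    return write_csv(
        tmp_path / "labels.csv",
        "start_s,end_s,subtype,amp_ch1,amp_ch2,amp_ch3,amp_ch4,channel\n"
        "0.50,0.54,Trill,-40,-35,-50,-60,\n"
        "1.00,2.20,22kHz,-42,-44,-46,-48,\n",
    )


@pytest.fixture()
def track_fixture(tmp_path):
    return write_csv(
        tmp_path / "tracks.csv",
        "t_s,x_cm,y_cm\n0.00,0.0,0.0\n0.04,0.5,70.0\n0.08,,\n",
    )
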