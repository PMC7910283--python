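import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid():
    from chromavice.vplot import build_window_grid

    return build_window_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def bed6_file(tmp_path):
    p = tmp_path / "features.bed"
    p.write_text(
        "chr1\t100\t110\tm1\t9.5\t+\n"
        "chr1\t5000\t5010\tm2\t3.0\t-\n"
        "chr2\t200\t212\tm3\t1.5\t+\n"
    )
    return p


@pytest.fixture()
def fragments_file(tmp_path):
    p = tmp_path / "fragments.bed"
    p.write_text(
        "chr1\t1000\t1180\n"
        "chr1\t1000\t1181\n"
        "chr2\t50\t120\n"
    )
    return p
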