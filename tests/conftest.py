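import numpy as np
import pytest

from escea.synthetic import demo_workbook, table1_fixture


@pytest.fixture(scope="session")
def demo_wb():
    return demo_workbook()


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def demo_results(demo_wb):
    from escea.pipeline import run_base_case

    return run_base_case(demo_wb)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
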