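import datetime as dt

import pytest

from faersig.records import DemoRecord
from faersig.stats import ContingencyTable
from faersig.synth import SyntheticConfig, generate_dataset


@pytest.fixture
def worked_table() -> ContingencyTable:
    """The module-wide worked example: a=10, b=20, c=30, d=240, N=300."""
    return ContingencyTable(10, 20, 30, 240)


def make_demo(primaryid="1", caseid="1", fda="20200301", **kw) -> DemoRecord:
    return DemoRecord(
        primaryid=primaryid,
        caseid=caseid,
        fda_dt=dt.datetime.strptime(fda, "%Y%m%d").date(),
        **kw,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset shared by I/O and CLI tests."""
    outdir = tmp_path_factory.mktemp("synthdata")
    cfg = SyntheticConfig(
        n_reports=2000,
        target_prevalence=0.05,
        signal_effects={("ISTRADEFYLLINE", "PT_RARE_1"): 8.0},
        seed=20240401,
    )
    truth = generate_dataset(cfg, outdir)
    return cfg, truth, outdir
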