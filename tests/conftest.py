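import numpy as np
import pandas as pd
import pytest

from aepymorph.scheme import Element
from aepymorph.synthetic import Missingness, default_config, generate


@pytest.fixture(scope="session")
def tmt_breakage():
    """Four-cluster tarsometatarsal draw at published midpoints with 15%
    breakage missingness - the standard recovery scenario."""
    cfg = default_config(
        Element.TARSOMETATARSUS,
        n_per_cluster=18,
        missingness=Missingness(mode="breakage", rate=0.15),
        seed=1,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def tmt_clean():
    """Same four clusters with no missingness."""
    cfg = default_config(
        Element.TARSOMETATARSUS,
        n_per_cluster=18,
        missingness=Missingness(mode="MCAR", rate=0.0),
        seed=2,
    )
    return generate(cfg)


@pytest.fixture()
def femur_csv(tmp_path):
    """Tiny hand-written femur table: 3 complete rows."""
    rows = []
    rng = np.random.default_rng(0)
    for i in range(3):
        row = {"specimen_id": f"F-{i}", "element": "femur", "collection": "TEST"}
        for j in range(1, 21):
            row[f"F{j}"] = round(float(100 + 10 * j + rng.random()), 2)
        rows.append(row)
    path = tmp_path / "femora.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
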