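import numpy as np
import pandas as pd
import pytest

from dndnet.datamodel import DirectedNet, OmicsMatrix, SampleTable


@pytest.fixture
def toy_matrix() -> OmicsMatrix:
    rng = np.random.default_rng(42)
    feats = [f"g{i}" for i in range(6)] + ["mir1", "mir2"]
    sids = [f"s{i}" for i in range(12)]
    data = pd.DataFrame(rng.normal(size=(8, 12)), index=feats, columns=sids)
    kind = pd.Series(["mRNA"] * 6 + ["miRNA"] * 2, index=feats)
    return OmicsMatrix(data, kind)


@pytest.fixture
def toy_samples() -> SampleTable:
    rows = []
    for i in range(6):
        for stage in ("ctrl", "peri", "lesion"):
            rows.append({"sample_id": f"s{len(rows)}", "subject_id": f"p{i}", "stage": stage})
    return SampleTable(pd.DataFrame(rows[:12]), ["ctrl", "peri", "lesion"], min_reference=3)


@pytest.fixture
def chain_net() -> DirectedNet:
    return DirectedNet.from_edges([("A", "B"), ("B", "C")])
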