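import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from persisterprot import RunDescriptor, SpectralCountMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_matrix(counts, conditions, lengths=None, n_tech=1, times=None):
    """Build a small annotated matrix.

    ``counts``: dict protein -> list of per-run counts, ordered as
    condition-major, then bio_rep, then tech_rep.  ``conditions``: list of
    (condition, n_bio_reps).
    """
    runs = []
    for cond, n_bio in conditions:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                runs.append(
                    RunDescriptor(
                        run_id=f"{cond}_b{b}_t{t}",
                        condition=cond,
                        bio_rep=b,
                        tech_rep=t,
                        time_h=(times or {}).get(cond),
                    )
                )
    proteins = list(counts)
    data = np.array([counts[p] for p in proteins], dtype=np.int64).reshape(
        len(proteins), len(runs)
    )
    df = pd.DataFrame(
        data,
        index=pd.Index(proteins, name="protein"),
        columns=[r.run_id for r in runs],
    )
    if lengths is None:
        lengths = {p: 100 for p in proteins}
    return SpectralCountMatrix(df, runs, pd.Series(lengths))


@pytest.fixture
def two_condition_matrix():
    """3 bio reps x 2 conditions, single tech rep, easy numbers."""
    return make_matrix(
        {
            "P1": [10, 12, 11, 30, 33, 28],
            "P2": [20, 18, 22, 21, 19, 20],
            "P3": [0, 0, 0, 4, 3, 2],
            "P4": [5, 0, 0, 1, 0, 0],
        },
        [("pre", 3), ("post", 3)],
        lengths={"P1": 100, "P2": 200, "P3": 150, "P4": 120},
    )
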