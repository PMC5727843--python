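import numpy as np
import pandas as pd
import pytest

from sasangdx.preprocess import Cohort
from sasangdx.synthetic import template_face


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def template():
    return template_face()


def make_cohort(n=60, seed=0, modalities=("face", "body", "questionnaire", "voice"),
                p=4, missing=None):
    """Small hand-rolled cohort for bookkeeping tests (not the synthetic
    generator; feature values are plain noise)."""
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    meta = pd.DataFrame({
        "sex": rng.choice(["M", "F"], n),
        "age": rng.integers(15, 80, n).astype(float),
        "sc_type": rng.choice(["TE", "SE", "SY"], n),
    }, index=ids)
    blocks = {}
    for m in modalities:
        keep = ids
        if missing and m in missing:
            keep = ids.difference(missing[m])
        blocks[m] = pd.DataFrame(rng.standard_normal((len(keep), p)),
                                 index=keep,
                                 columns=[f"{m}_{j}" for j in range(p)])
    return Cohort(meta=meta, blocks=blocks)
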