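import numpy as np
import pandas as pd
import pytest

from mamt.sumstats import StudyTable


def make_table(
    betas,
    ses,
    chrom="1",
    pos=None,
    ea="G",
    oa="A",
    n=10_000,
    eaf=0.5,
    ancestry="EUR",
    trait="SLE",
    study_id="study",
):
    """Build a StudyTable from effect/SE vectors with sensible defaults."""
    betas = np.atleast_1d(np.asarray(betas, float))
    ses = np.atleast_1d(np.asarray(ses, float))
    m = betas.size
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    z2 = (betas / ses) ** 2
    from scipy import stats

    df = pd.DataFrame(
        {
            "SNP": [f"rs{i+1}" for i in range(m)],
            "CHR": np.broadcast_to(np.asarray(chrom, object), m).copy(),
            "POS": pos,
            "EA": np.broadcast_to(np.asarray(ea, object), m).copy(),
            "OA": np.broadcast_to(np.asarray(oa, object), m).copy(),
            "BETA": betas,
            "SE": ses,
            "P": np.clip(stats.chi2.sf(z2, 1), np.finfo(float).tiny, 1.0),
            "N": n,
            "EAF": eaf,
        }
    )
    return StudyTable(df, ancestry=ancestry, trait=trait, study_id=study_id)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
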