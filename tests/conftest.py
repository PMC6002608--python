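import numpy as np
import pandas as pd
import pytest

from phagoscreen.library_index import LibraryIndex, SgRNARecord, default_library
from phagoscreen.read_counting import CassetteSpec, CountMatrix, sample_meta_from_ids


@pytest.fixture(scope="session")
def paper_index() -> LibraryIndex:
    """The full default screen design (391 SLC + 20 essential genes + NT)."""
    return default_library(seed=1)


@pytest.fixture()
def small_index() -> LibraryIndex:
    """A miniature library: 8 SLC genes x 6, 2 essential x 6, 12 NT."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seen: set[str] = set()

    def spacer() -> str:
        while True:
            sp = "".join(bases[rng.integers(0, 4, 20)])
            if sp not in seen:
                seen.add(sp)
                return sp

    records = []
    for g in range(1, 9):
        for k in range(1, 7):
            records.append(SgRNARecord(f"SLC{g:03d}_sg{k}", f"SLC{g:03d}", spacer(), "SLC"))
    for g in range(1, 3):
        for k in range(1, 7):
            records.append(
                SgRNARecord(f"ESS{g:02d}_sg{k}", f"ESS{g:02d}", spacer(), "EssentialControl")
            )
    for k in range(1, 13):
        records.append(SgRNARecord(f"NT_{k:03d}", "NonTargeting", spacer(), "NonTargeting"))
    return LibraryIndex(records)


@pytest.fixture()
def cassette() -> CassetteSpec:
    return CassetteSpec()


def make_count_matrix(arr, sgrna_ids=None, populations=("PhagoLate", "PhagoNeg")) -> CountMatrix:
    """Helper: wrap an array into a CountMatrix with rep{i}_{pop} columns."""
    arr = np.asarray(arr)
    n, m = arr.shape
    assert m % 2 == 0
    reps = m // 2
    cols = [f"rep{i}_{pop}" for pop in populations for i in range(1, reps + 1)]
    if sgrna_ids is None:
        sgrna_ids = [f"g{i:05d}" for i in range(n)]
    counts = pd.DataFrame(arr, index=pd.Index(sgrna_ids, name="sgrna_id"), columns=cols)
    return CountMatrix(counts=counts, sample_meta=sample_meta_from_ids(cols))
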