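import numpy as np
import pytest

from landgen.genotypes import GenotypeTable


def make_table(alleles, xy=None, ids=None, sex=None, group=None, locus_names=None):
    """Build a GenotypeTable from a nested list [(a1, a2) per locus] per row."""
    al = np.asarray(alleles, dtype=np.int32)
    n = al.shape[0]
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(al.shape[1])]
    return GenotypeTable(
        individual_id=np.array(ids, dtype=object),
        alleles=al,
        locus_names=locus_names,
        xy=xy,
        sex=sex,
        group=group,
    )


def random_table(rng, n=20, L=9, n_alleles=6, missing_rate=0.0, extent=1000.0):
    """Random genotypes at HWE-ish frequencies with uniform coordinates."""
    al = rng.integers(1, n_alleles + 1, size=(n, L, 2)).astype(np.int32)
    if missing_rate > 0:
        miss = rng.random((n, L)) < missing_rate
        al[miss] = 0
    xy = rng.uniform(0, extent, size=(n, 2))
    return make_table(al, xy=xy)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
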