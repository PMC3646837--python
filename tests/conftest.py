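import numpy as np
import pandas as pd
import pytest

from sgstools.io_tables import GenotypeDataset, Locus


def make_dataset(genotypes, x=None, y=None, meta=None, allele_codes=None):
    """Build a dataset from per-individual genotype strings.

    ``genotypes`` is a list of strings like ``"AB CD"`` (one token per locus,
    two letters per token; ``.`` = missing allele). Letters map to integer
    allele codes A=1, B=2, ...
    """
    tokens = [g.split() for g in genotypes]
    n, L = len(tokens), len(tokens[0])
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for i, row in enumerate(tokens):
        for l, tok in enumerate(row):
            for a, ch in enumerate(tok):
                calls[i, l, a] = 0 if ch == "." else ord(ch) - ord("A") + 1
    if allele_codes is None:
        loci = []
        for l in range(L):
            obs = sorted(set(calls[:, l, :].ravel()) - {0}) or [1]
            loci.append(Locus(f"L{l + 1}", tuple(obs)))
    else:
        loci = [Locus(f"L{l + 1}", tuple(allele_codes)) for l in range(L)]
    x = np.zeros(n) if x is None else np.asarray(x, dtype=float)
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    meta = pd.DataFrame(meta if meta is not None else {}, index=range(n))
    return GenotypeDataset(
        ids=[f"i{k}" for k in range(n)], loci=loci, calls=calls, x=x, y=y, meta=meta
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_dataset(rng, n=8, L=3, n_alleles=4, span=100.0):
    codes = tuple(range(1, n_alleles + 1))
    calls = rng.integers(1, n_alleles + 1, size=(n, L, 2))
    return GenotypeDataset(
        ids=[f"i{k}" for k in range(n)],
        loci=[Locus(f"L{l + 1}", codes) for l in range(L)],
        calls=calls,
        x=rng.uniform(0, span, n),
        y=rng.uniform(0, span, n),
        meta=pd.DataFrame(index=range(n)),
    )
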