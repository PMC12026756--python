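import numpy as np
import pytest

from rohdiv.io_formats import GenotypeDataset, MarkerMap


def random_dataset(rng, n_samples, n_markers, n_chrom=1, missing_rate=0.05,
                   spacing=10_000):
    """Small random dataset with strictly increasing positions per chromosome."""
    per = np.array_split(np.arange(n_markers), n_chrom)
    chrom, pos = [], []
    for c, idx in enumerate(per):
        chrom.extend([str(c + 1)] * len(idx))
        p = np.cumsum(rng.integers(1, spacing, size=len(idx)))
        pos.extend(p.tolist())
    bases = np.array(list("ACGT"))
    ref = rng.choice(4, size=n_markers)
    alt = (ref + rng.integers(1, 4, size=n_markers)) % 4
    mm = MarkerMap(chrom, pos, [f"snp{j}" for j in range(n_markers)],
                   bases[ref], bases[alt])
    calls = rng.choice([0, 1, 2], size=(n_samples, n_markers)).astype(np.uint8)
    calls[rng.random((n_samples, n_markers)) < missing_rate] = 3
    return GenotypeDataset(mm, [f"S{i}" for i in range(n_samples)], calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
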