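import numpy as np
import pytest

from mapdist import HistogramSpec, build_histogram, clean_fa_md
from mapdist.core_io import Modality


@pytest.fixture
def group_histograms():
    """Helper: clean FA/MD map pairs and bin the chosen modality."""

    def _build(pairs, modality="FA"):
        modality = Modality(modality)
        out = []
        for fa, md in pairs:
            fa_c, md_c, _ = clean_fa_md(fa, md)
            m = fa_c if modality is Modality.FA else md_c
            out.append(build_histogram(m, HistogramSpec.for_modality(modality)))
        return out

    return _build


@pytest.fixture
def random_prob_vectors():
    """Factory for probability vectors, including sparse ones with exact
    zeros, to exercise the 0/0 conventions of the distance formulas."""

    def _make(rng, n_bins=20, sparse=False):
        v = rng.dirichlet(np.full(n_bins, 0.5))
        if sparse:
            keep = rng.random(n_bins) < 0.5
            if not keep.any():
                keep[rng.integers(n_bins)] = True
            v = np.where(keep, v, 0.0)
            v = v / v.sum()
        return v

    return _make
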