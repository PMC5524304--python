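import numpy as np
import pytest

from ohnocne.io_formats import AlignmentBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_block(rng, n_columns=60, n_fish=3, n_tetrapod=2, p_conserve=0.5,
                 p_gap=0.05, ref_gap_prob=0.0):
    """Random small alignment block with mixed conservation, for oracle tests."""
    bases = np.array(list("ACGT"))
    ref_codes = rng.integers(0, 4, n_columns)
    ref = bases[ref_codes].copy()
    if ref_gap_prob > 0:
        gaps = rng.random(n_columns) < ref_gap_prob
        ref[gaps] = "-"
    rows = {"reference": "".join(ref)}
    classes = {"reference": "reference"}
    conserved_col = rng.random(n_columns) < p_conserve
    names = [f"fish_{i}" for i in range(n_fish)] + [f"tet_{i}" for i in range(n_tetrapod)]
    for name in names:
        match_p = np.where(conserved_col, 0.97, 0.3)
        mism = rng.random(n_columns) >= match_p
        seq = bases[(ref_codes + np.where(mism, rng.integers(1, 4, n_columns), 0)) % 4].copy()
        gaps = rng.random(n_columns) < p_gap
        seq[gaps] = "-"
        seq[ref == "-"] = bases[rng.integers(0, 4, n_columns)][ref == "-"]
        rows[name] = "".join(seq)
        classes[name] = "fish" if name.startswith("fish") else "tetrapod"
    return AlignmentBlock(
        reference_species="reference", rows=rows, ref_sequence_id="chrT",
        ref_start=0, species_class=classes,
    )
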