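import numpy as np
import pytest

from anchorforge.seqmodel import AlignedLocus, SeqRecord


def make_locus(locus_id, seqs, taxa=None, ids=None, **kw):
    """Build an AlignedLocus from plain strings (test helper)."""
    n = len(seqs)
    taxa = taxa or [f"t{i}" for i in range(n)]
    ids = ids or [f"{taxa[i]}_{i}" for i in range(n)]
    rows = [SeqRecord(id=ids[i], taxon=taxa[i], sequence=seqs[i])
            for i in range(n)]
    return AlignedLocus(locus_id, rows, **kw)


def random_locus(rng, n_rows, n_cols, locus_id="L", gap_frac=0.0):
    bases = np.frombuffer(b"ACGT", dtype="S1")
    mat = bases[rng.integers(0, 4, size=(n_rows, n_cols))]
    if gap_frac > 0:
        mat[rng.random((n_rows, n_cols)) < gap_frac] = b"-"
    seqs = ["".join(x.decode() for x in row) for row in mat]
    # avoid all-gap rows, which the model rejects downstream
    seqs = [s if set(s) != {"-"} else "A" + s[1:] for s in seqs]
    return make_locus(locus_id, seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture(scope="session")
def small_clade():
    from anchorforge.simulate import Duplication, SimSpec, simulate_clade

    spec = SimSpec(seed=42, n_species=8, n_loci=5,
                   duplications=(Duplication(1, ("sp01", "sp02", "sp03")),),
                   repeat_copies=3000, repeat_in_locus=0)
    return simulate_clade(spec)
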