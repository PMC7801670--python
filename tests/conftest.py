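import pytest

from gvannot.genome_io import CircularGenome
from gvannot.synthetic_data import GeneratorConfig, generate


def random_genome(rng, length, circular=True, gc=0.40):
    seq = "".join(rng.choice(list("ACGT"), size=length,
                             p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))
    return CircularGenome("random", seq, circular=circular)


@pytest.fixture(scope="session")
def small_truth():
    """A compact no-decoys genome: 10 ORFs, 3 major + 1 short hr, 1 dup."""
    cfg = GeneratorConfig(n_orfs=10, orf_len_range=(50, 250), n_major_hrs=3,
                          n_short_hrs=1, n_duplicates=1, no_decoys=True,
                          n_detected_proteins=6,
                          n_single_peptide_proteins=2)
    return generate(cfg, seed=101)


@pytest.fixture(scope="session")
def hr_truth():
    """The 8 major + 1 short hr architecture on a no-decoys genome."""
    cfg = GeneratorConfig(n_orfs=8, orf_len_range=(50, 200), n_major_hrs=8,
                          n_short_hrs=1, n_duplicates=0, no_decoys=True,
                          n_detected_proteins=0)
    return generate(cfg, seed=202)


@pytest.fixture(scope="session")
def messy_truth():
    """Decoys allowed: background ORFs may exist alongside the planted set."""
    cfg = GeneratorConfig(n_orfs=12, orf_len_range=(60, 300), n_major_hrs=2,
                          n_short_hrs=0, n_duplicates=1,
                          n_detected_proteins=0)
    return generate(cfg, seed=303)
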