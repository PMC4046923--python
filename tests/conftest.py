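import numpy as np
import pytest

from ccalign.matrices import blosum62
from ccalign.seq import AnnotatedProtein


def make_protein(pid: str, residues: str, cc_prob=None, register=None,
                 species: str = "sp") -> AnnotatedProtein:
    n = len(residues)
    if cc_prob is None:
        cc_prob = np.zeros(n)
    if register is None:
        register = np.full(n, "-", dtype="<U1")
    return AnnotatedProtein(id=pid, species=species, residues=residues,
                            cc_prob=np.asarray(cc_prob, dtype=float),
                            register=np.asarray(list(register), dtype="<U1"))


@pytest.fixture(scope="session")
def base_matrix():
    return blosum62()


@pytest.fixture(scope="session")
def small_families():
    """A small synthetic family set shared across tests."""
    from ccalign.simulate import FamilySpec, generate

    return generate(FamilySpec(n_families=8, decoys_per_family=2, seed=11))
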