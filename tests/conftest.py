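import pytest

from coassembler.coassemble import assemble_complex, scan_similarity
from coassembler.fixtures import (
    AB42_SEQUENCE,
    BinderSpec,
    DEFAULT_BINDER_START,
    FibrilSpec,
    build_binder,
    build_fibril,
)
from coassembler.structio import ONE_TO_THREE, Atom, Chain, Residue, Structure


@pytest.fixture(scope="session")
def small_fibril():
    """3-monomer parallel in-register fibril, short sequence, no hinge."""
    return build_fibril(FibrilSpec(n_monomers=3, sequence="KLVFFAE",
                                   disordered_nterm_len=0))


@pytest.fixture(scope="session")
def antiparallel_fibril():
    return build_fibril(FibrilSpec(n_monomers=4, sequence="KLVFFAE",
                                   disordered_nterm_len=0,
                                   arrangement="antiparallel"))


@pytest.fixture(scope="session")
def ab_fibril():
    """Default 5-monomer amyloid-beta fibril with hinged edge N-terminus."""
    return build_fibril(FibrilSpec())


@pytest.fixture(scope="session")
def binder():
    return build_binder(BinderSpec())


@pytest.fixture(scope="session")
def coassembly(ab_fibril, binder):
    """Assembled co-assembly-like complex (binder chain X + chains A-E)."""
    matches = scan_similarity(binder.sequence("X"),
                              ab_fibril.sequence("A")[:20], window=8,
                              min_identity=0.5,
                              binder_start=DEFAULT_BINDER_START)
    return assemble_complex(binder, ab_fibril, matches[0])


def random_structure(rng, n_chains=2, n_res=4, box=15.0, with_ion=False):
    """Random small structure for brute-force oracle comparisons."""
    resnames = list(ONE_TO_THREE.values())
    chains = []
    for ci in range(n_chains):
        ch = Chain(chain_id=chr(ord("A") + ci))
        for ri in range(n_res):
            rn = resnames[rng.integers(len(resnames))]
            res = Residue(chain_id=ch.chain_id, resseq=ri + 1, resname=rn)
            for ai in range(rng.integers(2, 5)):
                res.atoms.append(Atom(
                    name=["CA", "CB", "CG", "CD"][ai], element="C",
                    coord=rng.uniform(0, box, size=3)))
            ch.residues.append(res)
        chains.append(ch)
    if with_ion:
        ion = Chain(chain_id="_ions", is_ion_group=True)
        for k, el in enumerate(("NA", "CL")):
            r = Residue(chain_id="_ions", resseq=9000 + k, resname=el)
            r.atoms.append(Atom(name=el, element=el.capitalize(),
                                coord=rng.uniform(0, box, size=3)))
            ion.residues.append(r)
        chains.append(ion)
    return Structure(chains)
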