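"""Shared fixtures: small atom-mapped test networks and the shipped family.

The small networks stay within 8 total balanced carbons so the exhaustive
isotopomer oracle (tests/_oracles.py) can cross-check the EMU engine.
Each exercises a distinct structural feature: plain transfer and carbon
reordering, condensation plus cleavage, symmetric scrambling with a
recycle loop, and unlabeled-substrate dilution in a cycle.
"""

import numpy as np
import pytest

from fluxsel.emu_engine import TracerSpec
from fluxsel.example_models import get_tca_family
from fluxsel.network_model import parse_model_text

CHAIN_TEXT = """\
#substrate A.ext
#measured B C
reaction_id\tequation\treversible\tnotes
UPT\tA.ext(ab) -> B(ab)\t0\tuptake
ISO\tB(ab) -> C(ba)\t0\tcarbon reordering
EFF\tC ->\t0\tefflux
"""

COND_TEXT = """\
#substrate A.ext B.ext
#sink W
#measured Q R
reaction_id\tequation\treversible\tnotes
UPA\tA.ext(ab) -> M(ab)\t0\t
UPB\tB.ext(c) -> N(c)\t0\t
CND\tM(ab) + N(c) -> Q(abc)\t0\tcondensation
SPL\tQ(abc) -> R(bc) + W(a)\t0\tcleavage
EFQ\tQ ->\t0\t
EFR\tR ->\t0\t
"""

SYM_TEXT = """\
#substrate S.ext
#measured F M
reaction_id\tequation\treversible\tnotes
UPT\tS.ext(abcd) -> 1/2 F(abcd) + 1/2 F(dcba)\t0\tsymmetric scrambling
FH\tF(abcd) -> M(abcd)\t0\t
EX\tM(abcd) -> F(abcd)\t0\trecycle
EFM\tM ->\t0\t
"""

CYCLE_TEXT = """\
#substrate A.ext D.unl
#measured B C
reaction_id\tequation\treversible\tnotes
UPT\tA.ext(ab) -> B(ab)\t0\t
DIL\tD.unl(ab) -> B(ab)\t0\tunlabeled dilution
BC\tB(ab) -> C(ab)\t0\t
CB\tC(ab) -> B(ba)\t0\treordering recycle
EFC\tC ->\t0\t
"""


def _net(text, name):
    return parse_model_text(text, name=name)


# (model, steady-state flux vector, tracers) triples for oracle testing.
def small_networks():
    nets = []
    chain = _net(CHAIN_TEXT, "chain")
    nets.append((chain, np.array([1.0, 1.0, 1.0]),
                 [TracerSpec("t1", "A.ext", "10"),
                  TracerSpec("t2", "A.ext", "11")]))
    cond = _net(COND_TEXT, "cond")
    nets.append((cond, np.array([1.0, 1.0, 1.0, 0.4, 0.6, 0.4]),
                 [TracerSpec("ta", "A.ext", "01"),
                  TracerSpec("tb", "B.ext", "1")]))
    sym = _net(SYM_TEXT, "sym")
    nets.append((sym, np.array([1.0, 1.7, 0.7, 1.0]),
                 [TracerSpec("ts", "S.ext", "1100"),
                  TracerSpec("tu", "S.ext", "1000")]))
    cyc = _net(CYCLE_TEXT, "cycle")
    nets.append((cyc, np.array([0.6, 0.4, 1.8, 0.8, 1.0]),
                 [TracerSpec("tc", "A.ext", "11"),
                  TracerSpec("th", "A.ext", "01")]))
    return nets


@pytest.fixture(scope="session")
def chain_model():
    return _net(CHAIN_TEXT, "chain")


@pytest.fixture(scope="session")
def cond_model():
    return _net(COND_TEXT, "cond")


@pytest.fixture(scope="session")
def sym_model():
    return _net(SYM_TEXT, "sym")


@pytest.fixture(scope="session")
def cycle_model():
    return _net(CYCLE_TEXT, "cycle")


@pytest.fixture(scope="session")
def tca():
    return get_tca_family()


@pytest.fixture(scope="session")
def tca_true_mids(tca):
    from fluxsel.synthetic_data import true_mfa_mids

    return true_mfa_mids(tca)
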