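import numpy as np
import pytest

from operonevo.model import Gene, GeneOrder, Unit, OPERON, SINGLETON


def t(cls, ac, sign=1):
    return Gene(cls, ac, sign)


def r(cls, sign=1):
    return Gene(cls, None, sign)


def operon(*genes):
    return Unit(OPERON, list(genes))


def singleton(gene):
    return Unit(SINGLETON, [gene])


@pytest.fixture
def small_order():
    """<o> [16S 23S 5S tRNA-Ala(tgc)] tRNA-Ile(gat) <t> -[tRNA-Asn(gtt) tRNA-Glu(ttc)]"""
    return GeneOrder(
        "g1",
        [
            operon(r("16S"), r("23S"), r("5S"), t("Ala", "tgc")),
            singleton(t("Ile", "gat")),
            operon(t("Asn", "gtt", -1), t("Glu", "ttc", -1)),
        ],
        2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_root(seed, **kw):
    from operonevo.simulate import SimParams, generate_root

    return generate_root(SimParams(**kw), np.random.default_rng(seed))
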