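import pytest

from neoxy import CrossParameters, Hypothesis, Karyomorph
from neoxy.inference import CrossCounts, ProgenyCounts

XY_HYPOTHESES = [Hypothesis.MECH_A, Hypothesis.MECH_B, Hypothesis.MECH_C]
ALL_HYPOTHESES = [Hypothesis.STANDARD, *XY_HYPOTHESES]
DAMS = [Karyomorph.KII, Karyomorph.KIII, Karyomorph.KIV]


@pytest.fixture
def defaults():
    return CrossParameters()


@pytest.fixture
def observed_counts():
    """The published breeding-colony counts: sons/offspring per dam
    karyomorph plus the karyotyped-daughter subsample."""
    return ProgenyCounts(
        crosses={
            Karyomorph.KII: CrossCounts(
                n_dams=17,
                n_sons=54,
                n_daughters=95,
                karyotyped={
                    Karyomorph.KII: 9,
                    Karyomorph.KIII: 25,
                    Karyomorph.KIV: 3,
                },
            ),
            Karyomorph.KIII: CrossCounts(
                n_dams=18,
                n_sons=70,
                n_daughters=101,
                karyotyped={
                    Karyomorph.KII: 21,
                    Karyomorph.KIII: 6,
                    Karyomorph.KIV: 0,
                },
            ),
            Karyomorph.KIV: CrossCounts(n_dams=3, n_sons=7, n_daughters=0),
        }
    )
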