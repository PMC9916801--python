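import numpy as np
import pytest

from skimrepeats.simulate import GenomeSpec, RepeatFamilySpec, build_genome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_family(name="FamA", taxonomy=("ClassI", "LINE"), length=1000,
                copies=100, divergence=0.0, **kw) -> RepeatFamilySpec:
    return RepeatFamilySpec(name, taxonomy, length, copies, divergence, **kw)


@pytest.fixture(scope="session")
def small_genome():
    """1 Mb genome with two dispersed families and one satellite."""
    spec = GenomeSpec("test", 1_000_000, [
        make_family("FamA", ("ClassI", "LINE"), 500, 400, 0.01),
        make_family("FamB", ("ClassII", "TIR", "hAT"), 400, 250, 0.05),
        make_family("Sat", ("Satellite",), 170, 1200, 0.01, is_tandem=True),
    ], seed=7)
    return build_genome(spec)
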