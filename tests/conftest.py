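import pytest

from imprintcall import SampleSpec, Stage, Tissue, Wash, load_reference_study
from imprintcall.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def reference_study():
    return load_reference_study()


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=20240915)


@pytest.fixture
def cxl_sample():
    """Col-0 mother x Ler father, 2-4 cell embryo."""
    return SampleSpec(
        sample_id="CxL",
        maternal_accession="Col-0",
        paternal_accession="Ler",
    )


@pytest.fixture
def lxc_sample():
    """Ler mother x Col-0 father (reciprocal direction)."""
    return SampleSpec(
        sample_id="LxC",
        maternal_accession="Ler",
        paternal_accession="Col-0",
    )


@pytest.fixture
def seedling_samples():
    return {
        d: SampleSpec(
            sample_id=d,
            maternal_accession=m,
            paternal_accession=p,
            stage=Stage.SEEDLING,
            tissue=Tissue.SEEDLING,
            wash=Wash.NA,
        )
        for d, m, p in (
            ("CxL_sdl", "Col-0", "Ler"),
            ("LxC_sdl", "Ler", "Col-0"),
        )
    }
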