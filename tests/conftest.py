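import pytest
from hypothesis import HealthCheck, settings

from plectoneme.gelsim import GelConditions
from plectoneme.topology import CorrectionParameters, PlasmidSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ptptk2() -> PlasmidSpec:
    """The 5455 bp reporter plasmid used throughout."""
    return PlasmidSpec("pTPTK2", 5455)


@pytest.fixture
def params() -> CorrectionParameters:
    return CorrectionParameters()


@pytest.fixture
def counting_gel() -> GelConditions:
    """First-dimension chloroquine gel (1.5 ug/ml) at 24 C."""
    return GelConditions(chloroquine_dim1_ug_ml=1.5, chloroquine_dim2_ug_ml=7.5)


@pytest.fixture
def reference_gel() -> GelConditions:
    """No intercalator in the first dimension."""
    return GelConditions(chloroquine_dim1_ug_ml=0.0, chloroquine_dim2_ug_ml=7.5)
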