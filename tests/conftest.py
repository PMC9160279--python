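import io

import pytest

from biogaskit.feedstock import (
    UltimateAnalysis,
    load_proximate_analysis,
    load_ultimate_analysis,
    to_empirical_formula,
)

REFERENCE_ULTIMATE_CSV = """element,percent
C,45.19
N,3.579
H,7.299
S,0.94
O,42.992
"""

REFERENCE_PROXIMATE_CSV = """component,percent
moisture,6.3
volatile_solid,60.1
ash,27.0
fixed_carbon,6.7
sulfur,0.9
"""


@pytest.fixture
def sludge_ua() -> UltimateAnalysis:
    """Ultimate analysis of the reference beverage-sludge composition."""
    return load_ultimate_analysis(io.StringIO(REFERENCE_ULTIMATE_CSV))


@pytest.fixture
def sludge_pa():
    return load_proximate_analysis(io.StringIO(REFERENCE_PROXIMATE_CSV))


@pytest.fixture
def sludge_formula(sludge_ua):
    """Empirical formula of the reference sludge per 100 g dry mass."""
    return to_empirical_formula(sludge_ua, basis_mass=100.0)


@pytest.fixture
def ultimate_csv_path(tmp_path):
    p = tmp_path / "ultimate.csv"
    p.write_text(REFERENCE_ULTIMATE_CSV)
    return p


@pytest.fixture
def proximate_csv_path(tmp_path):
    p = tmp_path / "proximate.csv"
    p.write_text(REFERENCE_PROXIMATE_CSV)
    return p
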