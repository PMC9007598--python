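import numpy as np
import pytest

from isopop.models import analytic_surface


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def additive_unit():
    """f(x, y) = x + y on the unit dosing square (isobole at 1: anti-diagonal)."""
    return analytic_surface("additive", bounds=(1.0, 1.0), w1=1.0, w2=1.0)


@pytest.fixture(params=["additive", "bliss", "probit-additive"])
def monotone_fixture(request):
    """Each analytic family with a closed-form isobole, on the unit square."""
    return analytic_surface(request.param, bounds=(1.0, 1.0))
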