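import numpy as np
import pytest

from dlnmeta import BasisSpec, place_lag_knots


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def main_var_spec():
    """Quadratic B-spline for the predictor space, main-model settings."""
    return BasisSpec(
        "bspline",
        degree=2,
        internal_knots=(5.3, 15.1),
        boundary_knots=(-4.4, 24.9),
        intercept=False,
        center=17.0,
    )


@pytest.fixture
def main_lag_spec():
    """Natural cubic B-spline with intercept for lags 0..21."""
    return BasisSpec(
        "natural_cubic",
        internal_knots=tuple(place_lag_knots(21, 3)),
        boundary_knots=(0.0, 21.0),
        intercept=True,
    )


def basis_configs():
    """Assorted (var_spec, lag_spec, L) configurations used by property tests."""
    cfgs = []
    cfgs.append(
        (
            BasisSpec("bspline", degree=2, internal_knots=(5.3, 15.1),
                      boundary_knots=(-4.4, 24.9)),
            BasisSpec("natural_cubic", internal_knots=(1.0, 2.76, 7.61),
                      boundary_knots=(0.0, 21.0), intercept=True),
            21,
        )
    )
    cfgs.append(
        (
            BasisSpec("natural_cubic", internal_knots=(10.0,), boundary_knots=(0.0, 30.0)),
            BasisSpec("bspline", degree=3, internal_knots=(2.0,), boundary_knots=(0.0, 7.0),
                      intercept=True),
            7,
        )
    )
    cfgs.append(
        (
            BasisSpec("poly", degree=3),
            BasisSpec("constant"),
            3,
        )
    )
    cfgs.append(
        (
            BasisSpec("linear"),
            BasisSpec("natural_cubic", internal_knots=(1.0, 4.0),
                      boundary_knots=(0.0, 10.0), intercept=True),
            10,
        )
    )
    cfgs.append(
        (
            BasisSpec("threshold", internal_knots=(15.0,)),
            BasisSpec("strata", internal_knots=(3.0, 10.0), intercept=True),
            14,
        )
    )
    return cfgs
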