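"""Shared fixtures and independent numeric oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hydrafrap.frap_core import FitResult


def scaled_bessel_sum(x: float, terms: int = 600) -> float:
    """Independent series oracle for exp(-x) * (I0(x) + I1(x)).

    Term-recursive power series for both modified Bessel functions,
    scaled at the end; accurate well past x = 200 in double precision.
    """
    s0 = t0 = 1.0
    s1 = t1 = x / 2.0
    q = (x / 2.0) ** 2
    for k in range(1, terms):
        t0 *= q / (k * k)
        t1 *= q / (k * (k + 1))
        s0 += t0
        s1 += t1
        if t0 < 1e-18 * s0 and t1 < 1e-18 * s1:
            break
    return math.exp(-x) * (s0 + s1)


def make_fit(d: float, mobile: float = 0.9, w: float = 5.0) -> FitResult:
    """Minimal well-formed FitResult for aggregation-level tests."""
    tau = w ** 2 / (4.0 * d)
    b = 0.2
    a = mobile * (1.0 - b)
    return FitResult(
        a=a, b=b, tau_d=tau, covariance=np.zeros((3, 3)),
        confidence_level=0.95, ciw_a=0.0, ciw_b=0.0, ciw_tau=0.0,
        w=w, D=d, ciw_D=0.0, mobile_fraction=mobile,
        mobile_fraction_raw=mobile, mobile_clipped=False,
        residual_sd=0.0, converged=True, n_points=120,
    )


@pytest.fixture(scope="session")
def bessel_oracle():
    return scaled_bessel_sum


@pytest.fixture(scope="session")
def fit_factory():
    return make_fit
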