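"""Shared fixtures.

The reference parameter set (a = 0.5, m = 0.45, D = 0.01, s = 0) is the
regime in which the pulse reduction is valid and patterns are feasible;
critical-rainfall bisections are cached per session because several tests
interrogate the same feasibility boundaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from drypatch import NondimParams
from drypatch.stability import CriticalRainfall, critical_rainfall


@pytest.fixture(scope="session")
def p_ref() -> NondimParams:
    return NondimParams(a=0.5, m=0.45, D=0.01, s=0.0)


class _AcCache:
    """Lazy, session-wide cache of critical-rainfall bisections."""

    def __init__(self, p: NondimParams):
        self.p = p
        self._store: dict[tuple[int, float], CriticalRainfall] = {}

    def __call__(self, n: int, domain_length: float) -> CriticalRainfall:
        key = (n, round(domain_length, 6))
        if key not in self._store:
            hint = None
            for (n2, l2), crit in self._store.items():
                if abs(l2 / n2 - domain_length / n) < 0.3 and not crit.never_feasible:
                    hint = min(crit.a_c * 1.5, 1.0)
                    break
            self._store[key] = critical_rainfall(
                n, self.p, domain_length=domain_length, a_hi_start=hint
            )
        return self._store[key]


@pytest.fixture(scope="session")
def ac_cache(p_ref) -> _AcCache:
    return _AcCache(p_ref)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
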