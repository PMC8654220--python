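"""Stateless counter-based random numbers for scenario coupling.

Every stochastic decision in the simulation is a pure function of
``(master seed, process code, calendar year, person id)``.  Because draws are
keyed rather than sequenced, two scenario runs that share a master seed give
every person an identical stream of background randomness: a person whose
state is never touched by an intervention predicate follows a bit-identical
trajectory in every scenario (common random numbers).  Between-scenario
differences in outcomes are then driven by the interventions themselves, not
by Monte Carlo noise.

The generator is a splitmix64-style avalanche hash.  Each key component is
folded into 64-bit state with the golden-ratio increment and the standard
finalizer; the top 53 bits become a uniform on (0, 1).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_SEED0 = np.uint64(0x243F6A8885A308D3)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


class Process:
    """Stable process codes for the per-(individual, process) substreams."""

    INIT_SEX = 1
    INIT_AGE = 2
    INIT_EDU = 3
    INIT_INCOME = 4
    INIT_REGION = 5
    INIT_SMOKING = 6
    INIT_BMI = 7
    INIT_OA = 8
    INIT_HUI3 = 10  # +attribute index 0..7 -> 10..17
    INIT_COMORB = 20  # +flag index 0..5 -> 20..25
    INIT_JRS = 26
    INIT_JRS_YEAR = 27
    DEATH = 30
    EMIGRATION = 31
    BMI = 32
    OA_ONSET = 33
    MEDICATION = 40  # +drug index 0..3 -> 40..43
    GI = 50
    CVD = 51
    STROKE = 52
    DYSPEPSIA = 53
    OVERDOSE = 54
    GI_FATAL = 55
    CVD_FATAL = 56
    STROKE_FATAL = 57
    CVD_EXCESS = 58
    STROKE_EXCESS = 59
    JRS_PRIMARY = 60
    JRS_REVISION = 61
    JRS_PERIOP = 62
    JRS_PAIN_GAIN = 63
    JRS_MOBILITY_GAIN = 64
    HUI3 = 70  # +attribute index 0..7 -> 70..77
    PAIN_CHANGE = 80  # +drug index 0..3 -> 80..83


def _mix64(z: np.ndarray) -> np.ndarray:
    z = (z ^ (z >> np.uint64(30))) * _M1
    z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


def hash_u64(seed: int, process: int, year: int, ids) -> np.ndarray:
    """64-bit hash of the draw key, vectorised over person ids."""
    ids = np.atleast_1d(np.asarray(ids)).astype(np.uint64)
    z = np.full(ids.shape, _SEED0, dtype=np.uint64)
    for part in (np.uint64(int(seed)), np.uint64(int(process)), np.uint64(int(year))):
        z = _mix64((z + _GOLDEN) ^ part)
    return _mix64((z + _GOLDEN) ^ ids)


def uniforms(seed: int, process: int, year: int, ids) -> np.ndarray:
    """Uniforms on the open interval (0, 1), one per id, keyed not sequenced."""
    bits = hash_u64(seed, process, year, ids)
    return ((bits >> np.uint64(11)).astype(np.float64) + 0.5) * _INV53


def normals(seed: int, process: int, year: int, ids) -> np.ndarray:
    """Standard normals via the inverse CDF of the keyed uniforms."""
    return ndtri(uniforms(seed, process, year, ids))


def derive_seed(seed: int, salt: int) -> int:
    """A derived 31-bit seed for auxiliary generators (kept below 2**31)."""
    return int(hash_u64(seed, 999, salt, [0])[0] % np.uint64(2**31 - 1))
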