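"""Shared fixtures: session-scoped synthetic movies and their analyses.

Simulating and analyzing a movie dominates test runtime, so the handful of
movies the suite needs are built once per session. All generators are seeded;
everything here is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import epimap as em

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

FRAME_RATE = 490.2


@pytest.fixture(scope="session")
def protocol_2pcl():
    """Reduced dynamic pacing staircase: 250 and 150 ms PCL, 6 pulses each."""
    return em.build_protocol([250.0, 150.0], 6, FRAME_RATE)


@pytest.fixture(scope="session")
def identity_heart(protocol_2pcl):
    """Noise-free, fully captured 64×64 planar heart at 250/150 ms PCL, with
    ground truth and the full pipeline result."""
    movie, gt = em.simulate_movie(
        protocol_2pcl, em.APModel(), em.WavePattern(speed=50.0), grid=(64, 64)
    )
    result = em.analyze_movie(movie, protocol_2pcl, compute_cv=False)
    return movie, gt, result


@pytest.fixture(scope="session")
def block_heart(protocol_2pcl):
    """Same heart but with a planted 25×25 region (15.26 % of pixels) in 2:1
    conduction block at the 150 ms PCL only."""
    block = np.zeros((64, 64), dtype=bool)
    block[19:44, 19:44] = True
    wave = em.WavePattern(speed=50.0, block_mask=block, block_pcls=(150.0,))
    movie, gt = em.simulate_movie(protocol_2pcl, em.APModel(), wave, grid=(64, 64))
    result = em.analyze_movie(movie, protocol_2pcl, compute_cv=False)
    return movie, gt, result, block


@pytest.fixture(scope="session")
def hetero_heart(protocol_2pcl):
    """48×48 heart with a two-region steady-state APD field (54 | 62 ms):
    regional repolarization heterogeneity under full capture."""
    apd_ss = np.full((48, 48), 54.0)
    apd_ss[:, 24:] = 62.0
    movie, gt = em.simulate_movie(
        protocol_2pcl,
        em.APModel(apd_ss_true=apd_ss),
        em.WavePattern(speed=50.0),
        grid=(48, 48),
    )
    result = em.analyze_movie(movie, protocol_2pcl, compute_cv=False)
    return movie, gt, result, apd_ss


@pytest.fixture(scope="session")
def planar_heart_32():
    """32×32 single-PCL (200 ms × 8) noise-free planar heart at 50 cm/s with
    CV analysis, for parameter-recovery checks."""
    protocol = em.build_protocol([200.0], 8, FRAME_RATE)
    movie, gt = em.simulate_movie(
        protocol, em.APModel(), em.WavePattern(speed=50.0), grid=(32, 32)
    )
    result = em.analyze_movie(
        movie, protocol, compute_cv=True, dispersion_pcls=(), loss_pcls=(0.0, 0.0)
    )
    return protocol, movie, gt, result
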