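"""Shared fixtures: small synthetic traces, peaks and digests."""

from __future__ import annotations

import numpy as np
import pytest

from ccscore import (
    DigestConfig,
    Peak,
    TETRAD_INTERVAL,
    TimeTrace,
    TraceConfig,
    simulate_mixture,
    synthetic_trif_like_protein,
)


@pytest.fixture(scope="session")
def trif_like_protein():
    return synthetic_trif_like_protein()


@pytest.fixture(scope="session")
def trif_digest_config(trif_like_protein):
    """Default digest emulating the protection experiment on the construct."""
    return DigestConfig(
        protein=trif_like_protein,
        core_start=654,
        core_end=709,
        anchor=TETRAD_INTERVAL,
        seed=11,
    )


@pytest.fixture(scope="session")
def hetero_trace():
    """A short mixture trace with a high dual fraction and ground truth."""
    return simulate_mixture(0.9, 300.0, TraceConfig(duration_s=60.0, seed=42))


def make_peaks(spans, channel="green"):
    """Peak list from inclusive (start, end) spans; apex at span start."""
    return [
        Peak(
            channel=channel,
            start_bin=s,
            end_bin=e,
            apex_bin=s,
            max_intensity=50.0,
            integrated_photons=100.0,
        )
        for s, e in spans
    ]


def random_disjoint_spans(rng: np.random.Generator, n_max=30, record=2000):
    """Sorted, non-overlapping random spans inside a record."""
    n = int(rng.integers(0, n_max + 1))
    cuts = np.sort(rng.choice(record, size=min(2 * n, record), replace=False))
    spans = []
    for k in range(0, len(cuts) - 1, 2):
        spans.append((int(cuts[k]), int(cuts[k + 1] - 1)))
    return [(s, e) for s, e in spans if e >= s]
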