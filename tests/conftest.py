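"""Shared fixtures.

Heavy Monte Carlo ledgers (1e7 photons) are built once per session through a
lazy bank keyed by medium configuration, so every test that needs the same
geometry reuses one simulation.  Fast tests use small dedicated ledgers.
"""

from __future__ import annotations

import zlib

import pytest

from layerlight import (
    make_ds_array,
    make_homogeneous,
    make_three_layer,
    make_two_layer,
    run_white_mc,
)

HEAVY_PHOTONS = 10_000_000
#: Total-path cutoff for the heavy runs: at the fitted baseline absorptions
#: (>= 0.0139 mm^-1) a 700 mm path carries relative weight e^-9.7, so the
#: truncation bias is far below the Monte Carlo noise at 1e7 photons.
HEAVY_MAX_PATH = 700.0


def _seed_for(key) -> int:
    """Deterministic per-configuration seed below 2**31."""
    return zlib.crc32(repr(key).encode()) % (2**31)


def build_medium(model: str, L1: float, musp1: float, mua1: float = 0.017):
    if model == "2L":
        return make_two_layer(L1, mua1=mua1, mua2=0.021, musp1=musp1, musp2=1.1)
    if model == "3L":
        return make_three_layer(L1, mua1=mua1, mua3=0.021, musp1=musp1, musp3=1.1)
    raise ValueError(model)


class LedgerBank:
    """Lazy cache of white-MC ledgers keyed by (model, L1, musp1)."""

    def __init__(self, optodes):
        self.optodes = optodes
        self._cache = {}

    def get(self, model: str, L1: float, musp1: float):
        key = (model, float(L1), float(musp1))
        if key not in self._cache:
            medium = build_medium(model, L1, musp1)
            self._cache[key] = run_white_mc(
                medium,
                self.optodes,
                HEAVY_PHOTONS,
                seed=_seed_for(key),
                tally_mode="annular",
                max_path=HEAVY_MAX_PATH,
            )
        return self._cache[key]


@pytest.fixture(scope="session")
def optodes():
    return make_ds_array()


@pytest.fixture(scope="session")
def ledger_bank(optodes):
    return LedgerBank(optodes)


@pytest.fixture(scope="session")
def small_three_layer_ledger(optodes):
    """Modest three-layer run for fast structural tests (~1 s)."""
    medium = make_three_layer(10.0, mua1=0.017, mua3=0.021, musp1=0.75, musp3=1.1)
    return run_white_mc(medium, optodes, 200_000, seed=_seed_for("small-3L"),
                        tally_mode="annular", max_path=1500.0)


@pytest.fixture(scope="session")
def small_homogeneous_ledger(optodes):
    medium = make_homogeneous(0.01, 1.0)
    return run_white_mc(medium, optodes, 200_000, seed=_seed_for("small-hom"),
                        tally_mode="annular", max_path=1500.0)
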