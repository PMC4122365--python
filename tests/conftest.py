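"""Shared fixtures: deterministic RNGs and compact pool-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from poolsweep.pool_io import BASES, POOLS, TABLE_COLUMNS, PoolSiteTable

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def make_site(arm: str, pos: int, ref: str, c1: dict, h1: dict, h2: dict,
              baseq: int = 30, bestq: int = 50) -> dict:
    """One pool-table row from per-pool count dicts.

    Pool dicts map base symbols to counts and may carry ``del``/``ins``
    support as ``("del", fwd, rev)`` style keys: ``del_fwd``, ``del_rev``,
    ``ins_fwd``, ``ins_rev``; ``depth`` defaults to the sum of base counts
    plus deletion support, and ``baseq``/``bestq`` may be overridden per
    pool.
    """
    row: dict = {"arm": arm, "pos": pos, "ref": ref}
    for pool, spec in zip(POOLS, (c1, h1, h2)):
        spec = dict(spec)
        for b in BASES:
            row[f"{pool}_{b}"] = spec.pop(b, 0)
        for f in ("del_fwd", "del_rev", "ins_fwd", "ins_rev"):
            row[f"{pool}_{f}"] = spec.pop(f, 0)
        row[f"{pool}_del"] = row[f"{pool}_del_fwd"] + row[f"{pool}_del_rev"]
        row[f"{pool}_ins"] = row[f"{pool}_ins_fwd"] + row[f"{pool}_ins_rev"]
        base_sum = sum(row[f"{pool}_{b}"] for b in BASES)
        row[f"{pool}_depth"] = spec.pop(
            "depth", base_sum + row[f"{pool}_del"])
        row[f"{pool}_baseq"] = spec.pop("baseq", baseq)
        row[f"{pool}_bestq"] = spec.pop("bestq", bestq)
        assert not spec, f"unknown keys {list(spec)}"
    return row


def make_table(rows: list[dict]) -> PoolSiteTable:
    return PoolSiteTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))
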