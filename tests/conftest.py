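"""Shared fixtures: one fully staged default simulation reused across tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pytest

import chronostage as cs


@dataclass
class StagedRun:
    """A generated data set carried through presence filtering and staging."""

    config: cs.SimConfig
    matrix: pd.DataFrame
    metadata: pd.DataFrame
    calls: pd.DataFrame
    truth: cs.SyntheticTruth
    present: pd.DataFrame
    pa_table: pd.DataFrame
    panels: dict
    excluded: list


def _run(config: cs.SimConfig) -> StagedRun:
    matrix, metadata, calls, truth = cs.generate(config)
    present = cs.presence_filter(matrix, calls, metadata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pa_table, panels, excluded = cs.stage_with_purge(present, metadata)
    return StagedRun(
        config=config,
        matrix=matrix,
        metadata=metadata,
        calls=calls,
        truth=truth,
        present=present,
        pa_table=pa_table,
        panels=panels,
        excluded=excluded,
    )


@pytest.fixture(scope="session")
def default_run() -> StagedRun:
    """Default study conditions (delay 6 h, toxicant effects on), seed 1."""
    return _run(cs.SimConfig(seed=1))


@pytest.fixture(scope="session")
def delay_only_run() -> StagedRun:
    """Developmental delay without any direct toxicant effect (seed 11)."""
    return _run(cs.SimConfig(effect_scale=0.0, seed=11))
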