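"""Shared fixtures: parameter factories and scripted (hand-built) persons."""

from __future__ import annotations

import copy

import numpy as np
import pytest
import yaml
from hypothesis import settings

from crcscreen.natural_history import Adenoma, Individual, PreclinicalCancer
from crcscreen.params import NaturalHistoryParams, default_params, params_from_dict, _data_path

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> NaturalHistoryParams:
    return default_params()


@pytest.fixture(scope="session")
def default_param_dict() -> dict:
    with open(_data_path("default_params.yaml")) as fh:
        d = yaml.safe_load(fh)
    d.pop("life_table_csv", None)
    return d


@pytest.fixture(scope="session")
def params_factory(default_param_dict):
    """Build NaturalHistoryParams from the default file with nested overrides,
    e.g. factory({'transition_coeffs.size_power': 0.0, 'frailty_sd': 0})."""

    def factory(overrides: dict | None = None) -> NaturalHistoryParams:
        d = copy.deepcopy(default_param_dict)
        for dotted, value in (overrides or {}).items():
            node = d
            *parents, leaf = dotted.split(".")
            for key in parents:
                node = node[key]
            node[leaf] = value
        return params_from_dict(d)

    return factory


def make_cancer(onset: float, sojourn: float, dwells=(1.0, 0.85, 0.75),
                u_cure: float = 0.99, u_time: float = 0.5) -> PreclinicalCancer:
    entries = (onset, onset + dwells[0], onset + dwells[0] + dwells[1],
               onset + dwells[0] + dwells[1] + dwells[2])
    return PreclinicalCancer(onset_age=onset, sojourn_years=sojourn,
                             stage_entry_ages=entries, u_cure=u_cure, u_time=u_time)


def make_individual(pid: int, death_age: float, sex: str = "female",
                    adenomas: list[Adenoma] | None = None) -> Individual:
    return Individual(id=pid, sex=sex, frailty=0.0, other_cause_death_age=death_age,
                      adenomas=adenomas or [], master_seed=0, attempt=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
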