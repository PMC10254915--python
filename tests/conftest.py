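import json

import pytest

from omicsflux.model_io import MetabolicModel, Reaction, model_from_dict


@pytest.fixture
def toy_model_dict():
    """3-metabolite, 4-reaction linear chain in the JSON dialect."""
    return {
        "metabolites": ["A", "B", "C"],
        "reactions": [
            {"id": "EX_A", "stoich": {"A": 1}, "lb": 0, "ub": 10,
             "gpr": None, "exchange": True},
            {"id": "R1", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 1000,
             "gpr": "g1", "exchange": False},
            {"id": "R2", "stoich": {"B": -1, "C": 1}, "lb": 0, "ub": 1000,
             "gpr": "g2a or g2b", "exchange": False},
            {"id": "biomass", "stoich": {"C": -1}, "lb": 0, "ub": 1000,
             "gpr": None, "exchange": True},
        ],
        "objective": "biomass",
    }


@pytest.fixture
def toy_model(toy_model_dict):
    return model_from_dict(toy_model_dict)


@pytest.fixture
def toy_model_file(tmp_path, toy_model_dict):
    path = tmp_path / "toy.json"
    path.write_text(json.dumps(toy_model_dict))
    return path


@pytest.fixture
def chain_model():
    """EX -> A -> B -> biomass with one enzymatic cap of 5 on A -> B."""
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 100.0, None, exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 5.0),
            Reaction("biomass", {"B": -1.0}, 0.0, 1000.0, None, exchange=True),
        ],
        objective_reaction="biomass",
    )


@pytest.fixture
def diamond_model():
    """Two parallel routes A -> B, each capped at 3, total demand 4."""
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 4.0, None, exchange=True),
            Reaction("Ra", {"A": -1.0, "B": 1.0}, 0.0, 3.0),
            Reaction("Rb", {"A": -1.0, "B": 1.0}, 0.0, 3.0),
            Reaction("biomass", {"B": -1.0}, 0.0, 1000.0, None, exchange=True),
        ],
        objective_reaction="biomass",
    )
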