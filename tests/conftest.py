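import numpy as np
import pandas as pd
import pytest

from personakit import (DistanceSpec, SurveyDataset, SurveySchema, VariableSpec,
                        default_schema)
from personakit.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def tiny_schema():
    """Three categorical variables across the three roles."""
    return SurveySchema((
        VariableSpec("a", categories=("x", "y", "z"), role="demographic"),
        VariableSpec("b", categories=("u", "v"), role="technological"),
        VariableSpec("c", categories=("p", "q", "r"), role="outcome"),
    ))


@pytest.fixture
def make_tiny_dataset(tiny_schema):
    def _make(n=8, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "a": rng.choice(["x", "y", "z"], n),
            "b": rng.choice(["u", "v"], n),
            "c": rng.choice(["p", "q", "r"], n),
        }, index=[f"r{i}" for i in range(n)])
        return SurveyDataset(tiny_schema, df)
    return _make


@pytest.fixture(scope="session")
def survey_dataset():
    """One shared synthetic survey at the default study conditions."""
    dataset, truth = generate(GeneratorConfig(seed=20260926 % 2**31))
    return dataset, truth


@pytest.fixture(scope="session")
def main_sample(survey_dataset):
    """The female/male respondents entering the main clustering."""
    dataset, truth = survey_dataset
    main = dataset.filter(dataset.data["sex"].isin(["Female", "Male"]))
    return main, truth


def weighted_gower_reference(x: dict, y: dict, schema: SurveySchema,
                             ranges: dict | None = None) -> float:
    """Independent textbook implementation of the weighted Gower distance.

    Plain double loop over variables; kept deliberately separate from the
    package's vectorized kernel so the two can disagree.
    """
    num = den = 0.0
    for v in schema.variables:
        xv, yv = x.get(v.name), y.get(v.name)
        if xv is None or yv is None or xv != xv or yv != yv:
            continue
        if v.kind == "categorical":
            delta = 0.0 if xv == yv else 1.0
        else:
            rng = (ranges or {}).get(v.name, 0.0)
            delta = abs(float(xv) - float(yv)) / rng if rng > 0 else 0.0
        num += v.weight * delta
        den += v.weight
    if den == 0:
        raise ZeroDivisionError("no jointly observed variable")
    return num / den
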