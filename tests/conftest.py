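import logging

import pytest

from phsolv.activity_ph import ActivityModel
from phsolv.model_registry import MediumRecipe, build_default_model

logging.getLogger("phsolv").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def model_no_agg(model):
    return model.without_aggregates()


@pytest.fixture(scope="session")
def act_off():
    return ActivityModel.off()


@pytest.fixture(scope="session")
def davies():
    return ActivityModel()


@pytest.fixture(scope="session")
def recipe_set3():
    # 52 mg hydrochloride per mL of 0.15 M NaCl
    return MediumRecipe.from_weighed_solid(0.052, 1.0, "salt_BHCl",
                                           background_NaCl=0.15)


@pytest.fixture(scope="session")
def recipe_set5():
    # 71 mg free base per mL of 1.70 M NaCl
    return MediumRecipe.from_weighed_solid(0.071, 1.0, "free_base",
                                           background_NaCl=1.70)
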