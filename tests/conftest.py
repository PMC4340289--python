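import pytest

from pathforge.fixtures import breast_carcinoma_bundle
from pathforge.ontology import build_instance_model, merge_reasoning_model


@pytest.fixture(scope="session")
def bundle():
    return breast_carcinoma_bundle()


@pytest.fixture(scope="session")
def toy_model(bundle):
    inst = build_instance_model(bundle.toy_pathway, bundle.repository)
    return merge_reasoning_model(inst, bundle.profile, bundle.mapping)


@pytest.fixture(scope="session")
def full_model(bundle):
    inst = build_instance_model(bundle.full_pathway, bundle.repository)
    return merge_reasoning_model(inst, bundle.profile, bundle.mapping)
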