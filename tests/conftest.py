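import numpy as np
import pytest

from focusforge.fixtures import (FixtureRecipe, fixture_constraints,
                                 make_toy_ligand, make_toy_scaffold)
from focusforge.ligand import ConformerEnsemble, template_conformer
from focusforge.scaffold import anchor_superpose


@pytest.fixture(scope="session")
def template():
    return make_toy_ligand()


@pytest.fixture(scope="session")
def reference_conformer(template):
    return template_conformer(template)


@pytest.fixture(scope="session")
def recipe():
    return FixtureRecipe(seed=1)


@pytest.fixture(scope="session")
def scaffold_manifest(recipe):
    return make_toy_scaffold(recipe)


@pytest.fixture(scope="session")
def scaffold(scaffold_manifest):
    return scaffold_manifest[0]


@pytest.fixture(scope="session")
def manifest(scaffold_manifest):
    return scaffold_manifest[1]


@pytest.fixture(scope="session")
def pose(reference_conformer, scaffold):
    return anchor_superpose(reference_conformer, scaffold)


@pytest.fixture(scope="session")
def constraints(recipe, scaffold, pose):
    """Native carboxylate constraint + full-policy planted-group constraints."""
    return fixture_constraints(recipe, scaffold, pose)


@pytest.fixture(scope="session")
def full_constraints(constraints):
    return [c for c in constraints if c.rotamer_policy == "full"]


@pytest.fixture(scope="session")
def single_ensemble(reference_conformer):
    return ConformerEnsemble([reference_conformer])


@pytest.fixture(scope="session")
def reference_matches(scaffold, single_ensemble, constraints):
    from focusforge.matcher import find_matches

    return find_matches(scaffold, single_ensemble, constraints)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
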