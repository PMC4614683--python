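"""Shared fixtures: toy ontologies and the (expensive) default synthetic study."""

from __future__ import annotations

import warnings

import pytest

from cyanonet import (LRModel, build_gold_standard, generate_world)
from cyanonet.core_io import Ontology
from cyanonet.pipeline import RunConfig, compute_features


def make_ontology(parents: dict[str, set[str]], namespace: dict[str, str],
                  ) -> Ontology:
    return Ontology(parents={t: frozenset(ps) for t, ps in parents.items()},
                    namespace=dict(namespace))


@pytest.fixture()
def chain_ontology():
    """BP chain root -> t1 -> ... -> t7 plus a CC root."""
    parents = {"root": set()}
    namespace = {"root": "biological_process"}
    prev = "root"
    for i in range(1, 8):
        t = f"t{i}"
        parents[t] = {prev}
        namespace[t] = "biological_process"
        prev = t
    parents["cc_root"] = set()
    namespace["cc_root"] = "cellular_component"
    return make_ontology(parents, namespace)


@pytest.fixture(scope="session")
def default_world():
    """The standard benchmark world (300 proteins, 8 modules, seed 17)."""
    return generate_world(seed=17)


@pytest.fixture(scope="session")
def default_study(default_world):
    """Gold standard, features, fitted model and scored pairs on the default world."""
    gs = build_gold_standard(default_world.gsp, default_world.catalog,
                             default_world.ontology)
    cfg = RunConfig(seed=17)
    features, retained = compute_features(default_world, cfg, gs)
    model = LRModel().fit(features, gs)
    scored = model.score_all(features, exclude=gs.gsp)
    return {"gs": gs, "config": cfg, "features": features,
            "retained": retained, "model": model, "scored": scored}


@pytest.fixture(scope="session")
def null_study():
    """The null world (every signal strength zero) scored by the same pipeline."""
    from cyanonet import WorldConfig
    world = generate_world(WorldConfig().null(), seed=17)
    gs = build_gold_standard(world.gsp, world.catalog, world.ontology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features, retained = compute_features(world, RunConfig(seed=17), gs)
        model = LRModel().fit(features, gs)
    scored = model.score_all(features, exclude=gs.gsp)
    return {"world": world, "gs": gs, "features": features,
            "retained": retained, "model": model, "scored": scored}
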