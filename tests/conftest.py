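"""Shared fixtures: small reference trees/models and one session-scoped
end-to-end run of the default synthetic scenario (simulate -> filter ->
fit-neutral -> score) reused by the feature-comparison and acceptance
tests."""

import numpy as np
import pytest

from norfevo import conacc_scoring, genome_tracks_io as gio, neutral_fit, \
    synthetic_data as sd
from norfevo.phylo_likelihood import PhyloTree
from norfevo.subst_models import build_model, jukes_cantor

SCENARIO_SEED = 42  # the study-condition seed for the shared scenario


@pytest.fixture(scope="session")
def jc():
    return jukes_cantor()


@pytest.fixture(scope="session")
def hky():
    return build_model("HKY", [0.3, 0.2, 0.2, 0.3], kappa=2.5)


@pytest.fixture(scope="session")
def three_taxon_tree():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def scenario():
    """Full synthetic-scenario pipeline state shared across tests."""
    plan = sd.default_cichlid_scenario(SCENARIO_SEED)
    blocks, features, truth = sd.simulate_alignment(plan)
    blocks = gio.sort_maf(gio.filter_maf(blocks, 5))
    columns = neutral_fit.extract_4d_columns(blocks, features["CDS"])
    neutral = neutral_fit.fit_neutral_model(columns, plan.tree, seed=1)
    track = conacc_scoring.score_alignment(neutral, blocks)
    return {
        "plan": plan,
        "blocks": blocks,
        "features": features,
        "truth": truth,
        "neutral": neutral,
        "track": track,
    }


def simulate_columns(tree, model, n, rho, seed):
    """n alignment columns evolved at rate multiplier rho (helper)."""
    plan = sd.RegionPlan(
        regions=[sd.Region("sim", n, rho)], taxa=tree.leaf_labels,
        tree=tree, model=model, seed=seed)
    blocks, _, _ = sd.simulate_alignment(plan)
    cols = []
    for b in blocks:
        for j in range(b.width):
            cols.append({r.species: r.text[j] for r in b.rows})
    return cols
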