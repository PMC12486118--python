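"""Shared fixtures: one synthetic reference bundle plus biased bulk
samples, reused session-wide so expensive simulation and training run once."""

import pytest

from tn5shadow import model as mdl
from tn5shadow import synthetic as syn
from tn5shadow import tracks as tr
from tn5shadow.features import FeatureRecipe, build_training_matrix

from helpers import GenomeLayoutFactory

BETA_BIASED = 0.5


@pytest.fixture(scope="session")
def bundle():
    return syn.simulate_reference(syn.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def layout(bundle):
    return bundle.layout


@pytest.fixture(scope="session")
def toy_layout():
    return GenomeLayoutFactory()


@pytest.fixture(scope="session")
def biased_bulk(bundle):
    """Two biased CUT&Tag replicates + shared ATAC at beta = 0.5."""
    layout = bundle.layout
    cut_frags = [
        syn.simulate_bulk(bundle, "cuttag_repressive", beta=BETA_BIASED, seed=300 + i)[0]
        for i in range(2)
    ]
    peaks = syn.simulate_bulk(bundle, "cuttag_repressive", beta=BETA_BIASED, seed=300)[1]
    atac_frags, _ = syn.simulate_bulk(bundle, "atac", seed=400)
    return {
        "cut_frags": cut_frags,
        "cut_tracks": [tr.build_signal_track(f, layout) for f in cut_frags],
        "atac_track": tr.build_signal_track(atac_frags, layout),
        "peaks": peaks,
        "beta": BETA_BIASED,
    }


@pytest.fixture(scope="session")
def training_features(bundle, biased_bulk):
    labeled = bundle.labeled_bins()
    return build_training_matrix(
        labeled,
        biased_bulk["cut_tracks"],
        {"atac": biased_bulk["atac_track"]},
        FeatureRecipe(("cuttag", "atac")),
    )


@pytest.fixture(scope="session")
def trained_model(training_features):
    return mdl.train(training_features, seed=7, mark_name="synthetic-repressive")


@pytest.fixture(scope="session")
def genome_scores(trained_model, biased_bulk, layout):
    return mdl.predict_genome(
        trained_model,
        {"cuttag": biased_bulk["cut_tracks"][0], "atac": biased_bulk["atac_track"]},
        layout,
    )
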