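import pytest

from t4apscan import (
    assign_families,
    classify_all,
    detect_clusters,
    dk1622_fixture,
    generate_panel,
    saurantiaca_fixture,
)

PANEL_SEED = 20


@pytest.fixture(scope="session")
def panel_anc():
    """One reference panel + ancestor registry shared by the whole suite."""
    return generate_panel(PANEL_SEED)


@pytest.fixture(scope="session")
def panel(panel_anc):
    return panel_anc[0]


@pytest.fixture(scope="session")
def ancestors(panel_anc):
    return panel_anc[1]


def scan_and_cluster(genome, panel):
    assignments = assign_families(genome, panel)
    clusters = classify_all(detect_clusters(genome, assignments, 5, panel), panel)
    return assignments, clusters


@pytest.fixture(scope="session")
def dk(panel_anc):
    """Myxococcus-like clustered fixture: genome, truth, assignments,
    classified clusters."""
    panel, ancestors = panel_anc
    genome, truth = dk1622_fixture(ancestors, seed=1)
    assignments, clusters = scan_and_cluster(genome, panel)
    return genome, truth, assignments, clusters


@pytest.fixture(scope="session")
def saur(panel_anc):
    """Stigmatella-like fixture with tandem pilA in the main locus."""
    panel, ancestors = panel_anc
    genome, truth = saurantiaca_fixture(ancestors, seed=2)
    assignments, clusters = scan_and_cluster(genome, panel)
    return genome, truth, assignments, clusters
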