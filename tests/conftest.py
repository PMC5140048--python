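import numpy as np
import pytest

from rbpreg import motifs, panels, synthdata

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_config():
    return synthdata.SimConfig(
        n_samples=20, n_genes=80, n_rbps=10, seed=FIXTURE_SEED
    )


@pytest.fixture(scope="session")
def fixture_data(fixture_config):
    """In-memory synthetic dataset shared across module tests."""
    panel, truth = synthdata.generate_panel(fixture_config)
    pwms = synthdata.generate_motifs(fixture_config)
    annotations, ledger = synthdata.generate_sequences(fixture_config, truth, pwms)
    return {
        "config": fixture_config,
        "panel": panel,
        "truth": truth,
        "pwms": pwms,
        "annotations": annotations,
        "ledger": ledger,
    }


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_config):
    """Fixture suite written to disk in the external-interface formats."""
    out = tmp_path_factory.mktemp("fixture")
    paths = synthdata.make_fixture_suite(out, seed=FIXTURE_SEED, config=fixture_config)
    return paths


@pytest.fixture(scope="session")
def centered_fixture(fixture_data):
    """Filtered + centred fixture panel with the measured-restricted map."""
    panel, _, _ = panels.filter_detected(fixture_data["panel"])
    panel = panels.mean_center(panel)
    seqs = [
        (tid, region, seq)
        for tid, ann in sorted(fixture_data["annotations"].items())
        for region, seq in (("5UTR", ann.utr5), ("3UTR", ann.utr3))
    ]
    imap, hits = motifs.scan_and_filter(seqs, fixture_data["pwms"], fdr=0.20)
    imap = motifs.restrict_to_measured(imap, panel)
    return panel, imap, hits


def rng(seed=0):
    return np.random.default_rng(seed)
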