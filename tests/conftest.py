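import pytest

import nuwtscan as ns


@pytest.fixture(scope="session")
def genome_pair():
    """Small dual reference with a mitochondrial homology decoy."""
    return ns.simulate_genome_pair(60_000, 20_000, 3_000, 200, seed=11)


@pytest.fixture(scope="session")
def hawaii_arch():
    return ns.build_nuwt_architecture("hawaii_like", 20_000)


@pytest.fixture(scope="session")
def hawaii_sim(genome_pair, hawaii_arch):
    cfg = ns.ReadoutConfig(duplicate_rate=0.05, contaminant_rate=0.01, seed=11)
    return ns.simulate_alignments(genome_pair, hawaii_arch, cfg)


@pytest.fixture(scope="session")
def class_arch():
    """One segment per predicted copy class {1, 2, 4, 8, 12}."""
    return ns.build_nuwt_architecture(
        "custom",
        10_000,
        segments=[(0, 2000, 1), (2000, 4000, 2), (4000, 6000, 4),
                  (6000, 8000, 8), (8000, 10_000, 12)],
    )


@pytest.fixture(scope="session")
def class_panel(class_arch):
    """~25 amplicons (5 per copy class), 6 reference genes, dsx-like control."""
    return ns.panel_for_architecture(
        class_arch, amplicons_per_segment=5, heterochromatic_controls=("dsx",)
    )


@pytest.fixture(scope="session")
def class_truth(class_panel):
    return {a.name: a.copy_class for a in class_panel.nuwt_amplicons}
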