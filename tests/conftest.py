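import dataclasses

import pytest

from chipde import synthetic_data as syn


@pytest.fixture(scope="session")
def demo_cfg():
    return syn.demo_config(seed=11)


@pytest.fixture(scope="session")
def demo_annotation(demo_cfg):
    return syn.generate_annotation(demo_cfg)


@pytest.fixture(scope="session")
def demo_peaks(demo_cfg, demo_annotation):
    return syn.generate_peaks(demo_cfg, demo_annotation)


@pytest.fixture(scope="session")
def demo_de(demo_cfg, demo_annotation, demo_peaks):
    return syn.generate_de_table(demo_cfg, demo_annotation, demo_peaks)


@pytest.fixture(scope="session")
def wt_mark_track(demo_cfg, demo_peaks):
    return syn.generate_coverage(demo_cfg, demo_peaks, "WT", "histone_mark")


def small_config(seed=0, **overrides):
    """Tiny genome for fast unit tests; overridable per test."""
    base = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=200_000,
        n_genes=50,
        n_peaks=40,
        cluster_sizes={"V": 5},
        association_prob={"V": 0.6},
    )
    base.update(overrides)
    return syn.SyntheticConfig(**base)
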