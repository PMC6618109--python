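"""Shared fixtures: registries, tiny synthetic studies, QC products.

The expensive end-to-end fixtures are session-scoped so the simulated
study is generated and QC'd once and reused across test modules.
"""

from __future__ import annotations

import pytest

from its2div.core import Config, SequenceRegistry, load_clade_references
from its2div.io import read_fastq_pairs
from its2div.qc import run_sample_qc
from its2div.simulate import generate_study


@pytest.fixture()
def registry():
    return SequenceRegistry.with_bundled_catalogue()


@pytest.fixture(scope="session")
def clade_refs():
    return load_clade_references()


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 9-sample, 3-genotype clade-C study at modest depth."""
    out = tmp_path_factory.mktemp("study")
    truth = generate_study(out, k=3, n_per_genotype=3, depth=500,
                           error_rate=0.001, seed=11)
    return out, truth


@pytest.fixture(scope="session")
def small_study_qc(small_study):
    """The small study after QC: (collections, reports, registry, truth)."""
    out, truth = small_study
    config = Config()
    refs = load_clade_references()
    registry = SequenceRegistry.with_bundled_catalogue()
    collections, reports = [], []
    for sample_id, pairs in read_fastq_pairs(out / "samples.tsv"):
        ccs, report = run_sample_qc(sample_id, pairs, config, refs, registry)
        collections.extend(ccs)
        reports.append(report)
    return collections, reports, registry, truth
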