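"""Convenience drivers: sample sheet -> collections -> analysis."""

from __future__ import annotations

from pathlib import Path

from .core import Config, SequenceRegistry, load_clade_references
from .io import read_fastq_pairs
from .profiles import AnalysisResult, run_analysis
from .qc import QCReport, run_sample_qc


def qc_study(study_dir: str | Path, config: Config | None = None,
             registry: SequenceRegistry | None = None):
    """QC every sample of a study directory (``samples.tsv`` + FASTQ).

    Returns (collections, reports, registry).
    """
    config = config or Config()
    registry = registry or SequenceRegistry.with_bundled_catalogue()
    refs = load_clade_references()
    collections, reports = [], []
    for sample_id, pairs in read_fastq_pairs(Path(study_dir) / "samples.tsv"):
        ccs, report = run_sample_qc(sample_id, pairs, config, refs, registry)
        collections.extend(ccs)
        reports.append(report)
    return collections, reports, registry


def analyse_study(study_dir: str | Path, config: Config | None = None
                  ) -> tuple[list, list[QCReport], SequenceRegistry,
                             AnalysisResult]:
    """QC a study directory and run the profile analysis on it."""
    config = config or Config()
    collections, reports, registry = qc_study(study_dir, config)
    result = run_analysis(collections, registry, config)
    return collections, reports, registry, result
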