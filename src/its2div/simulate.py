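"""Synthetic Symbiodiniaceae communities with known ground truth.

Each synthetic genotype carries a fixed proportion vector over a small set
of intragenomic ITS2 variants (a base sequence plus variants within a few
edits), emulating the multicopy rRNA array of a single symbiont genome.
Samples mix one or more genotypes at fixed weights; reads are drawn
multinomially from the variant pool, carry per-base substitution errors,
keep their amplification primers and overlap as paired reads, so every QC
stage is exercised.  The generator records which genotypes (and hence which
DIV sets) each sample contains, enabling parameter-recovery tests of the
profile engine.

Default genotype rosters are built from the bundled (synthetic) variant
catalogue, mirroring the structure of host-associated profile sets: three
clade-C genotypes sharing a C3 backbone with distinct accessory variants, a
disjoint C15-radiation genotype, and a clade-D genotype (D1/D4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import catalogue_by_name, load_clade_references
from .qc import FWD_PRIMER, IUPAC, REV_PRIMER, ReadPair, revcomp

__all__ = [
    "SyntheticGenotype",
    "GroundTruth",
    "make_genotype",
    "genotype_from_catalogue",
    "default_genotypes",
    "simulate_sample_reads",
    "generate_study",
    "generate_benchmark_study",
]

HIGH_Q = "I"   # Phred 40
ERR_Q = "#"    # Phred 2 at simulated error positions


def _concrete(primer: str, rng_free: bool = True) -> str:
    """Resolve IUPAC degeneracies to the first base of each code's set."""
    return "".join(IUPAC[c][0] for c in primer)


@dataclass(frozen=True)
class SyntheticGenotype:
    """A genome's ITS2 copy pool: variant sequences and fixed proportions."""

    name: str
    clade: str
    variants: tuple[str, ...]
    proportions: tuple[float, ...]
    variant_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.proportions):
            raise ValueError("one proportion per variant required")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variants must be unique")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


@dataclass
class GroundTruth:
    """Simulator-side truth: genotype mixtures and expected DIVs per sample."""

    genotypes: dict[str, SyntheticGenotype] = field(default_factory=dict)
    mixtures: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def expected_divs(self, sample_id: str) -> set[str]:
        out: set[str] = set()
        for gname, _ in self.mixtures[sample_id]:
            out |= set(self.genotypes[gname].variants)
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tgenotype\tweight\n")
            for sample_id in sorted(self.mixtures):
                for gname, w in self.mixtures[sample_id]:
                    fh.write(f"{sample_id}\t{gname}\t{w:.6g}\n")


def _default_proportions(k: int) -> tuple[float, ...]:
    """Geometric-decay copy proportions, realistic skew for an rDNA array."""
    raw = np.array([0.55 ** i for i in range(k)])
    return tuple(raw / raw.sum())


def make_genotype(clade: str, n_variants: int,
                  proportion_spec: Sequence[float] | None = None,
                  divergence: int = 3, seed: int = 0,
                  base: str | None = None,
                  name: str | None = None) -> SyntheticGenotype:
    """Construct a genotype from a base sequence and derived variants.

    The base defaults to the bundled clade anchor; each further variant
    carries between 1 and ``divergence`` substitutions relative to the
    base.  Deterministic for a fixed seed.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if divergence < 1 and n_variants > 1:
        raise ValueError("cannot derive distinct variants with 0 edits")
    if base is None:
        base = load_clade_references()[clade]
    rng = np.random.default_rng(seed)
    variants = [base]
    attempts = 0
    while len(variants) < n_variants:
        n_edits = int(rng.integers(1, divergence + 1))
        seq = list(base)
        for pos in rng.choice(len(base), size=n_edits, replace=False):
            alts = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alts[rng.integers(3)]
        cand = "".join(seq)
        attempts += 1
        if cand not in variants:
            variants.append(cand)
        elif attempts > 100 * n_variants:
            raise RuntimeError("could not generate enough distinct variants")
    props = (tuple(proportion_spec) if proportion_spec is not None
             else _default_proportions(n_variants))
    if len(props) != n_variants:
        raise ValueError("proportion_spec length must equal n_variants")
    return SyntheticGenotype(name=name or f"{clade}_geno{seed}", clade=clade,
                             variants=tuple(variants), proportions=props)


def genotype_from_catalogue(name: str, variant_names: Sequence[str],
                            proportions: Sequence[float]) -> SyntheticGenotype:
    """A genotype whose variants are named catalogue sequences."""
    cat = catalogue_by_name()
    clades = {cat[v][0] for v in variant_names}
    if len(clades) != 1:
        raise ValueError("catalogue variants must share one clade")
    return SyntheticGenotype(name=name, clade=clades.pop(),
                             variants=tuple(cat[v][1] for v in variant_names),
                             proportions=tuple(proportions),
                             variant_names=tuple(variant_names))


#: genotype rosters used by :func:`generate_study`; structured after the
#: kinds of host-associated profile sets seen in clade-C communities.
_ROSTER = [
    ("acro", ["C3", "C3gulf", "C3c", "C3aq"], (0.50, 0.25, 0.15, 0.10)),
    ("cyph", ["C3", "C3gulf", "C3c", "C3am"], (0.45, 0.30, 0.15, 0.10)),
    ("plat", ["C3", "C3gulf", "C3d", "C3i", "C115c", "C115b"],
     (0.35, 0.25, 0.15, 0.12, 0.08, 0.05)),
    ("c15", ["C15", "C15x", "C15a"], (0.60, 0.25, 0.15)),
]
_CROSS_CLADE = ("dur", ["D1", "D4"], (0.70, 0.30))


def default_genotypes(k: int = 3) -> list[SyntheticGenotype]:
    """The first ``k`` clade-C roster genotypes (k <= 4)."""
    if not 1 <= k <= len(_ROSTER):
        raise ValueError(f"k must be in 1..{len(_ROSTER)}")
    return [genotype_from_catalogue(n, v, p) for n, v, p in _ROSTER[:k]]


def simulate_sample_reads(sample_id: str,
                          genotype_weights: Sequence[tuple[SyntheticGenotype, float]],
                          depth: int = 2000, error_rate: float = 0.001,
                          read_length: int = 250, seed: int = 0,
                          fwd_primer: str = FWD_PRIMER,
                          rev_primer: str = REV_PRIMER) -> list[ReadPair]:
    """Draw one sample's paired reads from a genotype mixture.

    Reads are sampled multinomially from the flattened (weight x
    proportion) variant pool; each read of the pair receives independent
    per-base substitution errors at ``error_rate``, marked by a low
    quality score so overlap merging can resolve them.  Primers are
    attached so trimming is exercised; byte-identical output for a fixed
    seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    weights = np.array([w for _, w in genotype_weights], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("genotype weights must sum to 1")
    rng = np.random.default_rng(seed)
    fwd_p = _concrete(fwd_primer)
    rev_p = _concrete(rev_primer)
    amplicons = []
    probs = []
    for (geno, w) in genotype_weights:
        for variant, p in zip(geno.variants, geno.proportions):
            amplicons.append(fwd_p + variant + revcomp(rev_p))
            probs.append(w * p)
    probs = np.array(probs)
    counts = rng.multinomial(depth, probs / probs.sum())

    def with_errors(seq: str) -> tuple[str, str]:
        arr = list(seq)
        qual = [HIGH_Q] * len(arr)
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for pos in hits:
            alts = [b for b in "ACGT" if b != arr[pos]]
            arr[pos] = alts[rng.integers(3)]
            qual[pos] = ERR_Q
        return "".join(arr), "".join(qual)

    pairs = []
    i = 0
    for amp, n in zip(amplicons, counts):
        for _ in range(n):
            fwd, fq = with_errors(amp[:read_length])
            rev, rq = with_errors(revcomp(amp)[:read_length])
            pairs.append(ReadPair(read_id=f"{sample_id}_r{i:06d}",
                                  fwd=fwd, fwd_qual=fq, rev=rev, rev_qual=rq))
            i += 1
    return pairs


def generate_study(out_dir: str | Path, k: int = 3, n_per_genotype: int = 10,
                   mixed_fraction: float = 0.0,
                   cross_clade_fraction: float = 0.0,
                   depth: int = 2000, error_rate: float = 0.001,
                   read_length: int = 250, seed: int = 0,
                   genotypes: Sequence[SyntheticGenotype] | None = None
                   ) -> GroundTruth:
    """Emit a ready-to-run study: sample sheet, paired FASTQ, ground truth.

    ``k`` genotypes each appear standalone in ``n_per_genotype`` samples.
    ``mixed_fraction`` / ``cross_clade_fraction`` of the final sample count
    additionally mix two same-clade genotypes (preferring a pair with
    disjoint variant sets, as when two distinct taxa co-colonize a host)
    or a clade-C genotype with the clade-D genotype, at weights 0.6/0.4.
    Every mixture constituent is therefore also represented standalone.
    """
    from .io import write_fastq_pair, write_sample_sheet

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genotypes is None:
        genotypes = default_genotypes(k)
    genos = list(genotypes)
    rng = np.random.default_rng(seed)

    n_standalone = len(genos) * n_per_genotype
    resident = 1.0 - mixed_fraction - cross_clade_fraction
    if resident <= 0:
        raise ValueError("mixture fractions must leave room for standalone samples")
    total = n_standalone / resident
    n_mixed = int(round(total * mixed_fraction))
    n_cross = int(round(total * cross_clade_fraction))

    truth = GroundTruth(genotypes={g.name: g for g in genos})
    plan: list[list[tuple[str, float]]] = []
    for g in genos:
        plan.extend([[(g.name, 1.0)]] * n_per_genotype)
    if n_mixed:
        pairs = [(a, b) for i, a in enumerate(genos) for b in genos[i + 1:]
                 if not set(a.variants) & set(b.variants)]
        if not pairs:
            pairs = [(genos[i], genos[(i + 1) % len(genos)])
                     for i in range(len(genos))]
        for i in range(n_mixed):
            a, b = pairs[i % len(pairs)]
            plan.append([(a.name, 0.6), (b.name, 0.4)])
    if n_cross:
        dgeno = genotype_from_catalogue(*_CROSS_CLADE)
        truth.genotypes[dgeno.name] = dgeno
        for i in range(n_cross):
            a = genos[i % len(genos)]
            plan.append([(a.name, 0.6), (dgeno.name, 0.4)])

    sheet_rows = []
    for idx, mixture in enumerate(plan):
        sample_id = f"s{idx:03d}_" + "_".join(g for g, _ in mixture)
        truth.mixtures[sample_id] = mixture
        pairs = simulate_sample_reads(
            sample_id,
            [(truth.genotypes[g], w) for g, w in mixture],
            depth=depth, error_rate=error_rate, read_length=read_length,
            seed=int(rng.integers(2 ** 31)))
        fwd = out_dir / f"{sample_id}_R1.fastq"
        rev = out_dir / f"{sample_id}_R2.fastq"
        write_fastq_pair(pairs, fwd, rev)
        sheet_rows.append((sample_id, fwd.name, rev.name))
    write_sample_sheet(sheet_rows, out_dir / "samples.tsv")
    truth.write_tsv(out_dir / "ground_truth.tsv")
    return truth

def generate_benchmark_study(out_dir: str | Path, depth: int = 2000,
                             error_rate: float = 0.001,
                             read_length: int = 250, seed: int = 0
                             ) -> GroundTruth:
    """A 42-sample emulation of a three-host-species coral survey.

    Thirteen samples carry the ``acro`` genotype, fifteen ``cyph`` and
    fourteen ``plat``, mirroring a survey in which each host species
    associates with its own clade-C subtaxon.  One ``acro``-host sample
    (A08) instead carries an aberrant genotype whose rarest variant (C3aq)
    sits far below the footprint cutoff, so the profile engine cannot
    match the full acro profile there and must fall back to the sample's
    most abundant sequence - the conservative single-DIV outcome.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_fastq_pair, write_sample_sheet

    acro, cyph, plat = default_genotypes(3)
    aberrant = genotype_from_catalogue(
        "acro_aberrant", ["C3", "C3gulf", "C3c", "C3aq"],
        (0.55, 0.28, 0.166, 0.004))
    truth = GroundTruth(genotypes={g.name: g
                                   for g in (acro, cyph, plat, aberrant)})
    plan: list[tuple[str, SyntheticGenotype]] = []
    for i in range(1, 14):
        geno = aberrant if i == 8 else acro
        plan.append((f"A{i:02d}", geno))
    plan.extend((f"C{i:02d}", cyph) for i in range(1, 16))
    plan.extend((f"P{i:02d}", plat) for i in range(1, 15))

    rng = np.random.default_rng(seed)
    sheet_rows = []
    for sample_id, geno in plan:
        truth.mixtures[sample_id] = [(geno.name, 1.0)]
        pairs = simulate_sample_reads(
            sample_id, [(geno, 1.0)], depth=depth, error_rate=error_rate,
            read_length=read_length, seed=int(rng.integers(2 ** 31)))
        fwd = out_dir / f"{sample_id}_R1.fastq"
        rev = out_dir / f"{sample_id}_R2.fastq"
        write_fastq_pair(pairs, fwd, rev)
        sheet_rows.append((sample_id, fwd.name, rev.name))
    write_sample_sheet(sheet_rows, out_dir / "samples.tsv")
    truth.write_tsv(out_dir / "ground_truth.tsv")
    return truth
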