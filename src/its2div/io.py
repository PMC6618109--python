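"""Readers and writers for the pipeline's standard formats.

Inputs are paired FASTQ(.gz) files listed in a tab-separated sample sheet.
Core outputs follow the five-file convention of the framework: absolute and
relative sequence count tables plus a FASTA of every reported sequence,
absolute and relative type-profile count tables, and per-clade distance
matrices with PCoA coordinates; trees are written as newick.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .core import SequenceRegistry, SpeciesRule, TypeProfile, associate_species
from .qc import QC_STAGES, QCReport, ReadPair


# ---------------------------------------------------------------------------
# FASTQ and sample sheets
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality) triples of a plain or gzipped FASTQ file."""
    records = []
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual or not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record near {header!r}")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise ValueError(f"{path}: sequence/quality length mismatch "
                                 f"for {header.strip()}")
            records.append((header[1:].strip().split()[0], seq.upper(), qual))
    return records


def read_fastq_pair_files(fwd_path: str | Path, rev_path: str | Path
                          ) -> list[ReadPair]:
    """Paired reads from a forward/reverse FASTQ file pair.

    Read ids must pair up positionally (ignoring a trailing /1 or /2);
    mismatched pairing raises with the offending ids listed.
    """
    fwd = _read_fastq(fwd_path)
    rev = _read_fastq(rev_path)
    if len(fwd) != len(rev):
        raise ValueError(f"unequal read counts: {fwd_path} has {len(fwd)}, "
                         f"{rev_path} has {len(rev)}")
    pairs = []
    bad = []
    for (fid, fseq, fq), (rid, rseq, rq) in zip(fwd, rev):
        fbase = fid.removesuffix("/1")
        rbase = rid.removesuffix("/2")
        if fbase != rbase:
            bad.append((fid, rid))
            continue
        pairs.append(ReadPair(read_id=fbase, fwd=fseq, fwd_qual=fq,
                              rev=rseq, rev_qual=rq))
    if bad:
        raise ValueError(f"mismatched read ids between {fwd_path} and "
                         f"{rev_path}: {bad[:5]}")
    return pairs


def write_fastq_pair(pairs: Sequence[ReadPair], fwd_path: str | Path,
                     rev_path: str | Path) -> None:
    with _open_text(fwd_path, "wt") as ffh, _open_text(rev_path, "wt") as rfh:
        for p in pairs:
            ffh.write(f"@{p.read_id}/1\n{p.fwd}\n+\n{p.fwd_qual}\n")
            rfh.write(f"@{p.read_id}/2\n{p.rev}\n+\n{p.rev_qual}\n")


def write_sample_sheet(rows: Iterable[tuple[str, str, str]],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tfwd\trev\n")
        for sample_id, fwd, rev in rows:
            fh.write(f"{sample_id}\t{fwd}\t{rev}\n")


def read_fastq_pairs(sample_sheet: str | Path):
    """Yield (sample_id, read pairs) for each row of a sample sheet.

    FASTQ paths in the sheet are resolved relative to the sheet's
    directory; duplicate sample ids are an error.
    """
    sheet = Path(sample_sheet)
    base = sheet.parent
    seen = set()
    with open(sheet) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "fwd", "rev"]:
            raise ValueError(f"{sheet}: expected columns sample_id/fwd/rev")
        for line in fh:
            if not line.strip():
                continue
            sample_id, fwd, rev = line.rstrip("\n").split("\t")[:3]
            if sample_id in seen:
                raise ValueError(f"duplicate sample id {sample_id!r}")
            seen.add(sample_id)
            yield sample_id, read_fastq_pair_files(base / fwd, base / rev)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def write_sequence_count_table(registry: SequenceRegistry, collections,
                               reports: Sequence[QCReport],
                               out_dir: str | Path,
                               prefix: str = "sequences") -> dict[str, Path]:
    """Absolute and relative sequence count tables plus the FASTA.

    Rows are sequence UIDs ordered by total abundance across all samples
    (descending, ties to lower UID); columns follow the sample order of the
    QC reports.  Per-sample QC retention counts are appended as extra rows
    labelled ``qc_<stage>`` in the absolute table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = [r.sample_id for r in reports]
    counts: dict[int, dict[str, int]] = {}
    for cc in collections:
        for uid, n in cc.abundances.items():
            counts.setdefault(uid, {})[cc.sample_id] = \
                counts.get(uid, {}).get(cc.sample_id, 0) + n
    order = sorted(counts, key=lambda u: (-sum(counts[u].values()), u))
    rows = []
    for uid in order:
        rec = registry.get(uid)
        row = {"uid": uid, "name": rec.name or "", "clade": rec.clade}
        for s in samples:
            row[s] = counts[uid].get(s, 0)
        rows.append(row)
    absolute = pd.DataFrame(rows).set_index("uid")
    abs_path = out_dir / f"{prefix}.absolute.tsv"
    rel_path = out_dir / f"{prefix}.relative.tsv"
    fasta_path = out_dir / f"{prefix}.fasta"

    with open(abs_path, "w") as fh:
        absolute.to_csv(fh, sep="\t")
        for stage in QC_STAGES:
            vals = "\t".join(str(r.counts.get(stage, 0)) for r in reports)
            fh.write(f"qc_{stage}\t\t\t{vals}\n")

    rel = absolute.copy()
    totals = {s: absolute[s].sum() for s in samples}
    for s in samples:
        rel[s] = absolute[s] / totals[s] if totals[s] else 0.0
    rel.to_csv(rel_path, sep="\t")

    with open(fasta_path, "w") as fh:
        for uid in order:
            fh.write(f">{uid}\n{registry.get(uid).sequence}\n")
    return {"absolute": abs_path, "relative": rel_path, "fasta": fasta_path}


def write_profile_count_table(profiles: Sequence[TypeProfile],
                              per_collection: Mapping[str, list[tuple[int, float]]],
                              assignments, collections,
                              registry: SequenceRegistry,
                              rules: Sequence[SpeciesRule],
                              out_dir: str | Path, analysis_uid: int,
                              db_sample_counts: Mapping[int, int] | None = None,
                              prefix: str = "profiles") -> dict[str, Path]:
    """Absolute and relative ITS2 type-profile count tables.

    One row per profile with the standard feature columns - UID, clade,
    majority sequence(s), associated species, local and database sample
    counts, name, DIV UID list - followed by per-sample values: summed DIV
    read counts (absolute table) or the merged whole-sample relative
    abundance (relative table).  Rows are ordered by the number of output
    samples the profile was found in, descending; the analysis UID is
    recorded in a header line.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_uid = {p.uid: p for p in profiles}
    cc_by_id = {cc.id: cc for cc in collections}
    samples = sorted({cc.sample_id for cc in collections})

    abs_counts: dict[int, dict[str, int]] = {}
    for cc_id, pairs in per_collection.items():
        cc = cc_by_id[cc_id]
        for uid, _ in pairs:
            p = by_uid[uid]
            tot = sum(cc.abundances.get(d, 0) for d in p.divs)
            abs_counts.setdefault(uid, {}).setdefault(cc.sample_id, 0)
            abs_counts[uid][cc.sample_id] += tot
    rel_counts: dict[int, dict[str, float]] = {}
    for a in assignments:
        rel_counts.setdefault(a.profile_uid, {})[a.sample_id] = \
            rel_counts.get(a.profile_uid, {}).get(a.sample_id, 0.0) \
            + a.rel_abundance

    local = {uid: len(m) for uid, m in abs_counts.items()}
    order = sorted(local, key=lambda u: (-local[u], u))

    def feature_row(uid: int) -> dict:
        p = by_uid[uid]
        majority = "/".join(registry.label(u) for u in p.divs
                            if u in p.majority_set)
        species = ", ".join(associate_species(p, rules, registry))
        db = (db_sample_counts or {}).get(uid, local.get(uid, 0))
        return {
            "profile_uid": uid, "clade": p.clade,
            "majority_its2_sequences": majority,
            "associated_species": species,
            "abundance_local": local.get(uid, 0),
            "abundance_db": db,
            "profile_name": p.name,
            "div_uids": "-".join(str(u) for u in p.divs),
        }

    paths = {}
    for kind, table in (("absolute", abs_counts), ("relative", rel_counts)):
        rows = []
        for uid in order:
            row = feature_row(uid)
            for s in samples:
                row[s] = table.get(uid, {}).get(s, 0)
            rows.append(row)
        df = pd.DataFrame(rows)
        path = out_dir / f"{prefix}.{kind}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# analysis_uid\t{analysis_uid}\n")
            df.to_csv(fh, sep="\t", index=False)
        paths[kind] = path
    return paths


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Re-read a count table written by this module."""
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Distance matrices, PCoA coordinates, trees
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.ids) + "\n")
        for i, lab in enumerate(dm.ids):
            vals = "\t".join(f"{v:.10g}" for v in dm.data[i])
            fh.write(f"{lab}\t{vals}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])


def write_pcoa(result, path: str | Path) -> None:
    """PCoA coordinates with eigenvalue and variance-explained footer rows."""
    k = result.coordinates.shape[1]
    axes = [f"PC{i + 1}" for i in range(k)]
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(axes) + "\n")
        for lab, coords in zip(result.labels, result.coordinates):
            fh.write(lab + "\t" + "\t".join(f"{c:.10g}" for c in coords) + "\n")
        fh.write("eigenvalue\t" +
                 "\t".join(f"{e:.10g}" for e in result.eigenvalues[:k]) + "\n")
        fh.write("proportion_explained\t" +
                 "\t".join(f"{p:.10g}" for p in result.proportion_explained) +
                 "\n")


def write_distance_outputs(matrices: Mapping[tuple[str, str, str], DistanceMatrix],
                           out_dir: str | Path) -> list[Path]:
    """One matrix file + one PCoA file per (level, metric, clade) key."""
    from .distance import pcoa

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (level, metric, clade), dm in sorted(matrices.items()):
        stem = f"{level}_{metric}_{clade}"
        mpath = out_dir / f"{stem}.dist.tsv"
        write_distance_matrix(dm, mpath)
        written.append(mpath)
        if len(dm.ids) >= 2:
            ppath = out_dir / f"{stem}.pcoa.tsv"
            write_pcoa(pcoa(dm), ppath)
            written.append(ppath)
    return written


def write_tree(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")
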