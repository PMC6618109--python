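"""Domain types, the reference-sequence registry, and local persistence.

The registry assigns a stable integer UID to every unique post-QC nucleotide
sequence, independent of any one sample; the bundled variant catalogue maps
canonical names (``C3``, ``D1``, ...) to sequences by exact full-length
identity.  A local single-file JSON store stands in for a hosted database:
it persists loaded samples, clade collections, discovered type profiles and
profile assignments losslessly across runs, so later analyses can re-use and
re-support profiles discovered earlier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CLADES = tuple("ABCDEFGHI")

STORE_FORMAT_VERSION = 1

_VALID_BASES = frozenset("ACGT")


class RegistryConflictError(ValueError):
    """A sequence was re-registered under a different clade."""


class StoreError(RuntimeError):
    """The persisted store is unreadable, corrupt or version-mismatched."""


@dataclass(frozen=True)
class ReferenceSequence:
    """One unique post-QC nucleotide sequence, independent of any sample."""

    uid: int
    sequence: str
    clade: str
    name: str | None = None
    accession: str | None = None

    @property
    def label(self) -> str:
        """Canonical name if assigned, otherwise the UID as a string."""
        return self.name if self.name else str(self.uid)


@dataclass
class SampleRecord:
    """A loaded sample with per-stage QC survivor counts."""

    sample_id: str
    dataset_id: str
    qc_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CladeCollection:
    """All of one sample's post-QC sequences belonging to one clade.

    The searchable analysis unit: collections totalling more than
    ``min_collection_size`` reads (default 200) take part in the
    profile search; smaller ones are reported but never searched, to
    avoid sequencing-depth artefacts.
    """

    sample_id: str
    clade: str
    abundances: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}")

    @property
    def total(self) -> int:
        return sum(self.abundances.values())

    @property
    def id(self) -> str:
        return f"{self.sample_id}|{self.clade}"

    def searchable(self, min_collection_size: int = 200) -> bool:
        return self.total > min_collection_size

    def relative_abundances(self) -> dict[int, float]:
        tot = self.total
        return {uid: n / tot for uid, n in self.abundances.items()}


@dataclass
class TypeProfile:
    """An ITS2 type profile: an ordered DIV set with abundance ranges.

    ``divs`` are ordered by decreasing mean relative abundance across the
    supporting collections; ``ranges`` holds each DIV's observed [min, max]
    relative abundance (fractions of the clade collection); ``majority_set``
    contains every DIV observed as the most abundant sequence in at least
    one supporter.  ``fallback`` marks single-DIV profiles created for
    samples in which no re-occurring set could be matched.
    """

    uid: int
    clade: str
    divs: list[int] = field(default_factory=list)
    ranges: dict[int, tuple[float, float]] = field(default_factory=dict)
    majority_set: set[int] = field(default_factory=set)
    support: list[str] = field(default_factory=list)
    name: str = ""
    fallback: bool = False

    def validate(self) -> None:
        if not self.majority_set <= set(self.divs):
            raise ValueError("majority_set must be a subset of divs")
        for uid, (lo, hi) in self.ranges.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid range for DIV {uid}: [{lo}, {hi}]")


@dataclass(frozen=True)
class ProfileAssignment:
    """(sample, profile, relative abundance) after genus re-merging.

    ``rel_abundance`` is a fraction of the whole sample, i.e. the
    within-clade profile abundance scaled by the clade's share of the
    sample's post-QC reads.
    """

    sample_id: str
    profile_uid: int
    rel_abundance: float


@dataclass(frozen=True)
class SpeciesRule:
    """A species description: the canonical variant names it requires."""

    species_name: str
    required_names: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_names:
            raise ValueError("required_names must be non-empty")


@dataclass
class Config:
    """All numeric thresholds of the pipeline, with their defaults.

    maxambig / maxhomop
        quality screen: maximum ambiguous bases (0) and longest allowed
        homopolymer run (5) in a merged contig.
    abund_cutoff
        per-sample abundance screen; a unique sequence survives only at
        abundance strictly greater than this (default 2).
    pdiffs / rdiffs
        mismatches tolerated when locating the forward / reverse primer (2).
    minlength / maxlength
        post-trim length window in bp, inclusive (184..310).
    min_collection_size
        a per-sample per-clade collection is searched for profiles only if
        it holds strictly more than this many reads (200).
    footprint_rel_cutoff
        minimum within-collection relative abundance for a sequence to
        enter the collection's footprint (0.01).
    min_support
        minimum number of collections that must share a sequence set for it
        to seed a type profile (3).
    range_tolerance
        fractional widening applied to each DIV's observed abundance range
        when matching profiles to samples (0 = strict observed min/max).
    otu_cutoff
        dissimilarity threshold of the OTU clustering baseline (0.03).
    entropy_threshold
        minimum Shannon column entropy at which the entropy-based
        decomposition keeps splitting (0.10).
    """

    maxambig: int = 0
    maxhomop: int = 5
    abund_cutoff: int = 2
    pdiffs: int = 2
    rdiffs: int = 2
    minlength: int = 184
    maxlength: int = 310
    min_collection_size: int = 200
    footprint_rel_cutoff: float = 0.01
    min_support: int = 3
    range_tolerance: float = 0.0
    otu_cutoff: float = 0.03
    entropy_threshold: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("footprint_rel_cutoff", "range_tolerance", "otu_cutoff",
                     "entropy_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.minlength > self.maxlength:
            raise ValueError("minlength must not exceed maxlength")


class SequenceRegistry:
    """Bijective map between unique nucleotide sequences and integer UIDs.

    UIDs are monotonically increasing and assigned at first registration;
    re-registration of a known sequence is idempotent and never mutates the
    existing record.  Registering a known sequence under a different clade
    raises :class:`RegistryConflictError`.  Sequences present in the named
    variant catalogue receive their canonical name on registration.
    """

    def __init__(self, catalogue: Mapping[str, tuple[str, str]] | None = None):
        # catalogue: sequence -> (name, clade)
        self._by_seq: dict[str, ReferenceSequence] = {}
        self._by_uid: dict[int, ReferenceSequence] = {}
        self._next_uid = 1
        self._catalogue = dict(catalogue) if catalogue else {}

    @classmethod
    def with_bundled_catalogue(cls) -> "SequenceRegistry":
        return cls(catalogue=load_variant_catalogue())

    def __len__(self) -> int:
        return len(self._by_uid)

    def __iter__(self):
        return iter(self._by_uid.values())

    def register(self, sequence: str, clade: str) -> int:
        if not sequence:
            raise ValueError("sequence must be non-empty")
        if not set(sequence) <= _VALID_BASES:
            bad = sorted(set(sequence) - _VALID_BASES)
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        if clade not in CLADES:
            raise ValueError(f"unknown clade {clade!r}")
        existing = self._by_seq.get(sequence)
        if existing is not None:
            if existing.clade != clade:
                raise RegistryConflictError(
                    f"sequence already registered as clade {existing.clade}, "
                    f"cannot re-register as clade {clade}"
                )
            return existing.uid
        name = None
        cat = self._catalogue.get(sequence)
        if cat is not None and cat[1] == clade:
            name = cat[0]
        rec = ReferenceSequence(uid=self._next_uid, sequence=sequence,
                                clade=clade, name=name)
        self._next_uid += 1
        self._by_seq[sequence] = rec
        self._by_uid[rec.uid] = rec
        return rec.uid

    def get(self, uid: int) -> ReferenceSequence:
        return self._by_uid[uid]

    def lookup(self, sequence: str) -> ReferenceSequence | None:
        return self._by_seq.get(sequence)

    def label(self, uid: int) -> str:
        return self._by_uid[uid].label

    # -- persistence hooks -------------------------------------------------
    def to_records(self) -> list[dict]:
        return [asdict(r) for r in sorted(self._by_uid.values(),
                                          key=lambda r: r.uid)]

    @classmethod
    def from_records(cls, records: Iterable[Mapping],
                     catalogue: Mapping[str, tuple[str, str]] | None = None
                     ) -> "SequenceRegistry":
        reg = cls(catalogue=catalogue)
        for rec in records:
            r = ReferenceSequence(**rec)
            reg._by_seq[r.sequence] = r
            reg._by_uid[r.uid] = r
            reg._next_uid = max(reg._next_uid, r.uid + 1)
        return reg


def associate_species(profile: TypeProfile, rules: Sequence[SpeciesRule],
                      registry: SequenceRegistry) -> list[str]:
    """Species descriptions compatible with a profile's named DIVs.

    A rule matches when every variant name it requires is among the
    profile's named DIVs; unnamed DIVs never match anything.  Output order
    follows rule order, so the result is stable.
    """
    names = {registry.get(uid).name for uid in profile.divs
             if registry.get(uid).name}
    return [r.species_name for r in rules if r.required_names <= names]


# ---------------------------------------------------------------------------
# Bundled data
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("its2div.data").joinpath(filename)

def load_clade_references() -> dict[str, str]:
    """The nine clade anchor sequences (A-I) as a clade -> sequence map.

    Synthetic stand-ins: deterministic sequences bundled with the package,
    one per clade, mutually divergent; see ``data/clade_refs.synthetic.fasta``.
    """
    refs: dict[str, str] = {}
    label = None
    for line in _data_path("clade_refs.synthetic.fasta").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith(">"):
            label = line[1:].split()[0]
        else:
            refs[label] = refs.get(label, "") + line.upper()
    return refs


def load_variant_catalogue() -> dict[str, tuple[str, str]]:
    """The named-variant catalogue as sequence -> (name, clade).

    Synthetic stand-ins for the canonical variants; exact full-length
    identity is the only match criterion.
    """
    cat: dict[str, tuple[str, str]] = {}
    text = _data_path("variant_catalogue.synthetic.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, clade, seq = line.split("\t")
        cat[seq.upper()] = (name, clade)
    return cat


def catalogue_by_name() -> dict[str, tuple[str, str]]:
    """The variant catalogue keyed by name: name -> (clade, sequence)."""
    return {name: (clade, seq)
            for seq, (name, clade) in load_variant_catalogue().items()}


def load_species_rules() -> list[SpeciesRule]:
    """Bundled species-association rules (species -> required DIV names)."""
    rules = []
    text = _data_path("species_rules.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("species\t"):
            continue
        species, req = line.split("\t")
        rules.append(SpeciesRule(species_name=species,
                                 required_names=frozenset(req.split(","))))
    return rules


# ---------------------------------------------------------------------------
# Persistence: single-file JSON store
# ---------------------------------------------------------------------------

@dataclass
class RunState:
    """Everything a run needs to persist: loads plus analyses."""

    registry: SequenceRegistry = field(default_factory=SequenceRegistry)
    samples: list[SampleRecord] = field(default_factory=list)
    collections: list[CladeCollection] = field(default_factory=list)
    profiles: list[TypeProfile] = field(default_factory=list)
    assignments: list[ProfileAssignment] = field(default_factory=list)
    per_collection: dict[str, list[tuple[int, float]]] = field(
        default_factory=dict)
    analysis_uid: int = 0


def persist_run(state: RunState, store_path: str | Path) -> None:
    """Write the full run state to a single JSON store file."""
    doc = {
        "format_version": STORE_FORMAT_VERSION,
        "analysis_uid": state.analysis_uid,
        "registry": state.registry.to_records(),
        "samples": [asdict(s) for s in state.samples],
        "collections": [
            {"sample_id": c.sample_id, "clade": c.clade,
             "abundances": {str(k): v for k, v in c.abundances.items()}}
            for c in state.collections
        ],
        "profiles": [
            {"uid": p.uid, "clade": p.clade, "divs": p.divs,
             "ranges": {str(k): list(v) for k, v in p.ranges.items()},
             "majority_set": sorted(p.majority_set), "support": p.support,
             "name": p.name, "fallback": p.fallback}
            for p in state.profiles
        ],
        "assignments": [asdict(a) for a in state.assignments],
        "per_collection": {k: [[uid, x] for uid, x in v]
                           for k, v in state.per_collection.items()},
    }
    Path(store_path).write_text(json.dumps(doc, indent=1))


def load_run(store_path: str | Path) -> RunState:
    """Load a run state; raises :class:`StoreError` on any defect."""
    path = Path(store_path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StoreError(f"cannot read store {path}: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise StoreError(f"{path} is not a run store")
    if doc["format_version"] != STORE_FORMAT_VERSION:
        raise StoreError(
            f"store format version {doc['format_version']} unsupported "
            f"(expected {STORE_FORMAT_VERSION})"
        )
    try:
        registry = SequenceRegistry.from_records(
            doc["registry"], catalogue=load_variant_catalogue())
        samples = [SampleRecord(**s) for s in doc["samples"]]
        collections = [
            CladeCollection(sample_id=c["sample_id"], clade=c["clade"],
                            abundances={int(k): v
                                        for k, v in c["abundances"].items()})
            for c in doc["collections"]
        ]
        profiles = [
            TypeProfile(uid=p["uid"], clade=p["clade"], divs=list(p["divs"]),
                        ranges={int(k): (v[0], v[1])
                                for k, v in p["ranges"].items()},
                        majority_set=set(p["majority_set"]),
                        support=list(p["support"]), name=p["name"],
                        fallback=p["fallback"])
            for p in doc["profiles"]
        ]
        assignments = [ProfileAssignment(**a) for a in doc["assignments"]]
        per_collection = {k: [(int(uid), float(x)) for uid, x in v]
                          for k, v in doc.get("per_collection", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise StoreError(f"corrupt store {path}: {exc}") from exc
    return RunState(registry=registry, samples=samples,
                    collections=collections, profiles=profiles,
                    assignments=assignments, per_collection=per_collection,
                    analysis_uid=doc.get("analysis_uid", 0))
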