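"""Generate the bundled synthetic reference data shipped with the package.

Run once from the repository root; the outputs are committed under
``src/its2div/data/``.  All sequences here are synthetic stand-ins for the
canonical clade anchors and named ITS2 variants: one random 260-bp anchor
per clade A-I (mutually divergent by construction), and named variants
derived from the anchors by a handful of substitutions, so that exact-match
catalogue lookup, clade screening, profile naming and species association
are all exercised end to end.  Variant names follow the field's
nomenclature (C3, C3gulf, D1, ...); the sequences do not reproduce the real
GenBank entries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "its2div" / "data"
BASES = np.array(list("ACGT"))
SEED = 988_321_117
INSERT_LEN = 260


def longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def random_insert(rng: np.random.Generator) -> str:
    """Random 260-mer with no homopolymer run longer than 4."""
    while True:
        seq = "".join(rng.choice(BASES, size=INSERT_LEN))
        if longest_run(seq) <= 4:
            return seq


def mutate(base: str, n_edits: int, rng: np.random.Generator,
           taken: set[str]) -> str:
    """Substitute ``n_edits`` distinct positions; keep runs <= 5, unique."""
    while True:
        seq = list(base)
        for pos in rng.choice(len(base), size=n_edits, replace=False):
            alts = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alts[rng.integers(len(alts))]
        out = "".join(seq)
        if longest_run(out) <= 5 and out not in taken:
            return out


def main() -> None:
    rng = np.random.default_rng(SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    anchors = {clade: random_insert(rng) for clade in "ABCDEFGHI"}
    with open(OUT / "clade_refs.synthetic.fasta", "w") as fh:
        fh.write("; synthetic clade anchor sequences, one per clade A-I\n")
        for clade, seq in anchors.items():
            fh.write(f">{clade} synthetic_anchor_clade_{clade}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    # (name, clade, edits from the clade anchor or from a named parent)
    plan = [
        ("C3", "C", 0, None), ("C3gulf", "C", 1, "C3"), ("C3c", "C", 1, "C3"),
        ("C3aq", "C", 2, "C3"), ("C3am", "C", 2, "C3"), ("C3d", "C", 1, "C3"),
        ("C3i", "C", 2, "C3"), ("C115c", "C", 3, "C3"), ("C115b", "C", 3, "C3"),
        ("C3a", "C", 1, "C3"), ("C3ab", "C", 2, "C3"),
        ("C1", "C", 3, "C3"), ("C21", "C", 3, "C3"),
        ("C15", "C", 12, "C3"), ("C15x", "C", 1, "C15"), ("C15a", "C", 2, "C15"),
        ("D1", "D", 0, None), ("D4", "D", 2, "D1"), ("D4c", "D", 3, "D1"),
        ("D1a", "D", 1, "D1"),
        ("A1", "A", 0, None), ("A1a", "A", 1, "A1"),
        ("B1", "B", 0, None),
    ]
    seqs: dict[str, str] = {}
    taken: set[str] = set(anchors.values())
    for name, clade, edits, parent in plan:
        base = anchors[clade] if parent is None else seqs[parent]
        seq = base if edits == 0 else mutate(base, edits, rng, taken)
        seqs[name] = seq
        taken.add(seq)

    with open(OUT / "variant_catalogue.synthetic.tsv", "w") as fh:
        fh.write("# synthetic named-variant catalogue: exact-match lookup\n")
        fh.write("name\tclade\tsequence\n")
        for name, clade, _, _ in plan:
            fh.write(f"{name}\t{clade}\t{seqs[name]}\n")

    with open(OUT / "species_rules.tsv", "w") as fh:
        fh.write("species\trequired_names\n")
        fh.write("Durusdinium trenchii\tD1,D4\n")
        fh.write("Cladocopium thermophilum\tC3,C3gulf\n")
        fh.write("Cladocopium goreaui\tC1\n")
        fh.write("Symbiodinium microadriaticum\tA1\n")

    print("wrote", sorted(p.name for p in OUT.iterdir()))


if __name__ == "__main__":
    main()
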