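"""Generate the synthetic study corpus and write it to results/corpus.

Emits a two-chromosome annotated genome with 50 planted duplication events
of each of the six modes, syntenic anchor lists (within-species WGD anchors
plus cross-species ortholog anchors carrying ancestral-locus evidence), a
protein homology table, and the ground-truth JSON."""

from collections import Counter

from common import CONFIG, CORPUS
from dupmodes.synthetic_data import simulate_genome


def main() -> None:
    sim = simulate_genome(CONFIG)
    paths = sim.write(CORPUS)
    counts = Counter(p.mode.value for p in sim.truth.pairs)
    print(f"wrote corpus to {CORPUS}")
    print(f"  genes: {len(sim.annotation)}  anchor pairs: {len(sim.anchors)}")
    print(f"  planted pairs by mode: {dict(counts)}")
    print(f"  singletons: {len(sim.truth.singletons)}")
    for name, path in paths.items():
        print(f"  {name}: {path.name}")


if __name__ == "__main__":
    main()
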