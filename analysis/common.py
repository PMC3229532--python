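"""Shared plumbing for the numbered analysis drivers.

All drivers work on the default synthetic study corpus (seed 0).  The first
driver writes the corpus files under ``results/corpus``; later drivers read
them back through the package's file readers when present, and regenerate
them in memory otherwise, so each driver can also run stand-alone.
"""

from pathlib import Path

from dupmodes.genome_io import read_anchors, read_blast_tab, read_gff
from dupmodes.synthetic_data import SimulationConfig, simulate_genome

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
CORPUS = RESULTS / "corpus"

CONFIG = SimulationConfig(seed=0)


def load_corpus():
    """(annotation, anchors, hits, truth) -- from disk if 01 has run."""
    sim = simulate_genome(CONFIG)
    gff = CORPUS / "genome.gff3"
    if gff.exists():
        annotation = read_gff(gff)
        anchors = read_anchors(
            CORPUS / "anchors.tsv", ortholog_path=CORPUS / "ortholog_anchors.tsv"
        )
        hits = read_blast_tab(CORPUS / "blast.tsv")
        return annotation, anchors, hits, sim.truth
    return sim.annotation, sim.anchors, sim.hits, sim.truth
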