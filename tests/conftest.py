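import numpy as np
import pytest
from hypothesis import settings

from flanklift.synth import SimulationConfig, make_genome_pair, plant_heterozygotes

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_pair():
    """A 60 kb diverged genome pair with 100 planted hets (default rates)."""
    cfg = SimulationConfig(ancestor_length=60_000, n_het_sites=100, seed=5)
    genome_a, genome_b, truth = make_genome_pair(cfg)
    recs_a, table, recs_b = plant_heterozygotes(genome_a, genome_b, truth, cfg)
    return {
        "cfg": cfg,
        "genome_a": genome_a,
        "genome_b": genome_b,
        "truth": truth,
        "hets_a": recs_a,
        "het_table": table,
        "genotypes_b": recs_b,
    }


def write_fasta(path, contigs, width=70):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def mutate_sequence(rng, seq, sub_rate=0.02, indel_rate=0.0):
    """Point-mutate (and optionally indel) a sequence; plain-Python reference."""
    bases = "ACGT"
    out = []
    for ch in seq:
        r = rng.random()
        if indel_rate and r < indel_rate / 2:
            continue  # deletion
        if indel_rate and r < indel_rate:
            out.append(bases[rng.integers(0, 4)])  # insertion before ch
        if rng.random() < sub_rate:
            out.append(bases[(bases.index(ch) + rng.integers(1, 4)) % 4])
        else:
            out.append(ch)
    return "".join(out)
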