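"""Synthetic diverged-genome pairs with ground-truth orthology.

Emulates the study design the liftover pipeline targets: two genomes
descended from a common ancestor down independent branches, accumulating
point substitutions, small indels, inserted repeat copies, optional
block inversions, and (on the target branch) optional paralogous
segmental duplications. The generator returns an exact base-level
orthology map between the two genomes, so every pipeline stage can be
scored against truth without any external data.

Heterozygous variant sites are then planted at eligible orthologous
positions of genome A, together with the matching (strand-adjusted)
genotype calls against genome B, emulating the same animal's calls
against a diverged reference and against its own reference.

Default rates give ~1.5% pairwise divergence at orthologous columns,
representative of conserved regions between mammalian species diverged
on the order of tens of millions of years -- the regime where
cross-species read mapping works at all.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, Interval
from .variant_io import GenotypeCall, VariantRecord, write_vcf

__all__ = [
    "SimulationConfig",
    "EvolvedGenome",
    "SyntheticTruth",
    "simulate_ancestor",
    "evolve",
    "make_genome_pair",
    "plant_heterozygotes",
    "write_bundle",
]

_BYTES = np.frombuffer(b"ACGTN?", dtype=np.uint8)
_COMP4 = np.array([3, 2, 1, 0], dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BYTES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-branch divergence simulation.

    ``substitution_rate`` and ``indel_rate`` are per-base, per-branch
    event probabilities; pairwise divergence at orthologous columns is
    approximately ``1 - (1 - substitution_rate)**2``. Indel lengths are
    geometric with the stated mean. ``repeat_fraction`` is the fraction
    of each derived genome covered by inserted repeat copies;
    ``paralog_events`` segmental duplications (applied to the target
    branch only) are appended to the end of the target contig so the
    orthology map is unaffected. ``het_guard_bp`` keeps planted het
    sites at least that many bases away from any alignment gap
    (0 disables the guard, for stress tests of projection through gaps).
    """

    ancestor_length: int = 200_000
    gc_content: float = 0.42
    substitution_rate: float = 0.0075
    indel_rate: float = 0.0005
    indel_mean_length: float = 2.0
    repeat_fraction: float = 0.05
    repeat_unit_length: int = 300
    repeat_copy_divergence: float = 0.02
    paralog_events: int = 0
    paralog_length: int = 2_000
    paralog_divergence: float = 0.02
    inversion_fraction: float = 0.0
    inversion_block_length: int = 2_000
    n_het_sites: int = 500
    genotype_error_rate: float = 0.0
    het_guard_bp: int = 100
    seed: int = 0
    contig_name: str = "chr1"

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "indel_rate",
            "repeat_fraction",
            "repeat_copy_divergence",
            "paralog_divergence",
            "inversion_fraction",
            "genotype_error_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        if self.ancestor_length < 10 * 201:
            raise ValueError("ancestor_length must be >= 2010 bp")
        if self.n_het_sites < 0 or self.het_guard_bp < 0:
            raise ValueError("n_het_sites and het_guard_bp must be >= 0")


@dataclass
class EvolvedGenome:
    """One branch's derived genome plus its map back to the ancestor.

    ``der2anc[i]`` is the ancestor index of derived base ``i`` (-1 for
    inserted material); ``der_strand[i]`` is +1, or -1 inside inverted
    blocks. ``repeats`` are the spans of inserted repeat copies in
    derived coordinates; ``paralogs`` the appended duplicate spans.
    """

    codes: np.ndarray
    der2anc: np.ndarray
    der_strand: np.ndarray
    repeats: List[Tuple[int, int]]
    paralogs: List[Tuple[int, int]]

    @property
    def sequence(self) -> str:
        return _decode(self.codes)


def simulate_ancestor(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> str:
    """I.i.d. ancestral sequence of the configured length and GC content."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=config.ancestor_length, p=p).astype(np.uint8)
    return _decode(codes)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(len(out)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return out


def _evolve_codes(
    anc: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    paralog_events: int,
) -> EvolvedGenome:
    L = len(anc)
    base = _mutate(anc, cfg.substitution_rate, rng)
    idx = np.arange(L, dtype=np.int64)
    strand = np.ones(L, dtype=np.int8)

    if cfg.inversion_fraction > 0:
        bl = min(cfg.inversion_block_length, L // 4)
        nblocks = int(round(cfg.inversion_fraction * L / bl))
        if nblocks:
            starts = np.sort(rng.choice(L - bl, size=nblocks, replace=False))
            last_end = -1
            for s in starts:
                s = int(s)
                if s <= last_end:
                    continue
                e = s + bl
                base[s:e] = _COMP4[base[s:e]][::-1]
                idx[s:e] = idx[s:e][::-1]
                strand[s:e] = -1
                last_end = e

    n_indels = rng.binomial(L, cfg.indel_rate)
    if n_indels:
        positions = np.sort(rng.choice(L, size=n_indels, replace=False))
        is_ins = rng.random(n_indels) < 0.5
        lengths = rng.geometric(1.0 / cfg.indel_mean_length, n_indels)
        parts_b: List[np.ndarray] = []
        parts_i: List[np.ndarray] = []
        parts_s: List[np.ndarray] = []
        cur = 0
        for p, ins, le in zip(positions, is_ins, lengths):
            p, le = int(p), int(le)
            if p < cur:  # event swallowed by a previous deletion
                continue
            parts_b.append(base[cur:p])
            parts_i.append(idx[cur:p])
            parts_s.append(strand[cur:p])
            if ins:
                parts_b.append(rng.integers(0, 4, le).astype(np.uint8))
                parts_i.append(np.full(le, -1, dtype=np.int64))
                parts_s.append(np.ones(le, dtype=np.int8))
                cur = p
            else:
                cur = min(L, p + le)
        parts_b.append(base[cur:])
        parts_i.append(idx[cur:])
        parts_s.append(strand[cur:])
        base = np.concatenate(parts_b)
        idx = np.concatenate(parts_i)
        strand = np.concatenate(parts_s)

    repeats: List[Tuple[int, int]] = []
    if cfg.repeat_fraction > 0:
        unit = cfg.repeat_unit_length
        cur_len = len(base)
        total = cfg.repeat_fraction * cur_len / (1 - cfg.repeat_fraction)
        n_copies = max(1, int(round(total / unit)))
        motifs = rng.integers(0, 4, size=(3, unit)).astype(np.uint8)
        points = np.sort(rng.choice(cur_len + 1, size=n_copies, replace=True))
        parts_b, parts_i, parts_s = [], [], []
        cur = 0
        inserted = 0
        for p in points:
            p = int(p)
            parts_b.append(base[cur:p])
            parts_i.append(idx[cur:p])
            parts_s.append(strand[cur:p])
            motif = motifs[int(rng.integers(0, len(motifs)))]
            copy = _mutate(motif, cfg.repeat_copy_divergence, rng)
            parts_b.append(copy)
            parts_i.append(np.full(unit, -1, dtype=np.int64))
            parts_s.append(np.ones(unit, dtype=np.int8))
            repeats.append((p + inserted, p + inserted + unit))
            inserted += unit
            cur = p
        parts_b.append(base[cur:])
        parts_i.append(idx[cur:])
        parts_s.append(strand[cur:])
        base = np.concatenate(parts_b)
        idx = np.concatenate(parts_i)
        strand = np.concatenate(parts_s)

    # Paralog draws are last so a run with paralog_events=0 is otherwise
    # byte-identical to one with paralogs (site-for-site comparisons).
    paralogs: List[Tuple[int, int]] = []
    for _ in range(paralog_events):
        plen = min(cfg.paralog_length, len(base) // 2)
        s = int(rng.integers(0, len(base) - plen + 1))
        copy = _mutate(base[s : s + plen], cfg.paralog_divergence, rng)
        start = len(base)
        base = np.concatenate([base, copy])
        idx = np.concatenate([idx, np.full(plen, -1, dtype=np.int64)])
        strand = np.concatenate([strand, np.ones(plen, dtype=np.int8)])
        paralogs.append((start, start + plen))

    return EvolvedGenome(
        codes=base, der2anc=idx, der_strand=strand, repeats=repeats, paralogs=paralogs
    )


def evolve(
    ancestor: str,
    config: SimulationConfig,
    branch_seed: Union[int, np.random.SeedSequence],
    paralog_events: Optional[int] = None,
) -> EvolvedGenome:
    """Evolve the ancestor down one branch; returns the derived genome
    with its exact ancestor coordinate map."""
    rng = np.random.default_rng(branch_seed)
    n_par = config.paralog_events if paralog_events is None else paralog_events
    return _evolve_codes(_encode(ancestor), config, rng, n_par)


@dataclass
class SyntheticTruth:
    """Base-level orthology between genomes A and B plus planted hets.

    ``a2b[i]`` is the 0-based B position orthologous to A position ``i``
    (-1 when unaligned); ``a2b_strand`` is the relative strand (+1/-1)
    at mapped columns. ``het_table`` (filled by
    :func:`plant_heterozygotes`) has one row per planted site with
    1-based source and true target positions.
    """

    contig_a: str
    contig_b: str
    a2b: np.ndarray
    a2b_strand: np.ndarray
    repeats_a: List[Interval]
    repeats_b: List[Interval]
    het_table: Optional[pd.DataFrame] = None

    def mapped_columns(self) -> np.ndarray:
        return np.nonzero(self.a2b >= 0)[0]

    def mismatch_fraction(self, genome_a: GenomeSequence, genome_b: GenomeSequence) -> float:
        """Observed divergence at mapped columns (strand-adjusted);
        self-consistency oracle for the orthology map."""
        a_codes = _encode(genome_a.contigs[self.contig_a])
        b_codes = _encode(genome_b.contigs[self.contig_b])
        cols = self.mapped_columns()
        if len(cols) == 0:
            raise ValueError("orthology map has no aligned columns")
        ba = b_codes[self.a2b[cols]]
        minus = self.a2b_strand[cols] == -1
        ba = ba.copy()
        ba[minus] = _COMP4[ba[minus]]
        return float(np.mean(a_codes[cols] != ba))


def _anc_to_der(ev: EvolvedGenome, anc_len: int) -> Tuple[np.ndarray, np.ndarray]:
    pos = np.full(anc_len, -1, dtype=np.int64)
    st = np.zeros(anc_len, dtype=np.int8)
    valid = ev.der2anc >= 0
    pos[ev.der2anc[valid]] = np.nonzero(valid)[0]
    st[ev.der2anc[valid]] = ev.der_strand[valid]
    return pos, st


def make_genome_pair(
    config: SimulationConfig,
) -> Tuple[GenomeSequence, GenomeSequence, SyntheticTruth]:
    """Evolve one ancestor down two independent branches.

    Branch A never receives paralog duplications; branch B receives
    ``config.paralog_events`` of them. The two ancestor coordinate maps
    are composed into a direct A<->B orthology map.
    """
    ss = np.random.SeedSequence(config.seed)
    s_anc, s_a, s_b, _ = ss.spawn(4)
    anc = _encode(simulate_ancestor(config, np.random.default_rng(s_anc)))
    ev_a = _evolve_codes(anc, config, np.random.default_rng(s_a), 0)
    ev_b = _evolve_codes(anc, config, np.random.default_rng(s_b), config.paralog_events)

    anc2a, anc2a_st = _anc_to_der(ev_a, len(anc))
    anc2b, anc2b_st = _anc_to_der(ev_b, len(anc))
    both = (anc2a >= 0) & (anc2b >= 0)
    a2b = np.full(len(ev_a.codes), -1, dtype=np.int64)
    a2b_strand = np.zeros(len(ev_a.codes), dtype=np.int8)
    a2b[anc2a[both]] = anc2b[both]
    a2b_strand[anc2a[both]] = anc2a_st[both] * anc2b_st[both]

    name = config.contig_name
    genome_a = GenomeSequence({name: ev_a.sequence})
    genome_b = GenomeSequence({name: ev_b.sequence})
    truth = SyntheticTruth(
        contig_a=name,
        contig_b=name,
        a2b=a2b,
        a2b_strand=a2b_strand,
        repeats_a=[Interval(name, s, e) for s, e in ev_a.repeats],
        repeats_b=[Interval(name, s, e) for s, e in ev_b.repeats],
    )
    return genome_a, genome_b, truth


def _eligible_positions(truth: SyntheticTruth, guard: int) -> np.ndarray:
    """Mapped positions whose +-guard window is gap-free and collinear."""
    a2b = truth.a2b
    L = len(a2b)
    mapped = a2b >= 0
    if guard == 0:
        return np.nonzero(mapped)[0]
    csum = np.concatenate([[0], np.cumsum(mapped.astype(np.int64))])
    centers = np.arange(guard, L - guard)
    full = (csum[centers + guard + 1] - csum[centers - guard]) == 2 * guard + 1
    cand = centers[full]
    d = a2b[cand + guard] - a2b[cand - guard]
    s = truth.a2b_strand[cand]
    ok = (
        (np.abs(d) == 2 * guard)
        & (np.sign(d).astype(np.int8) == s)
        & (truth.a2b_strand[cand - guard] == s)
        & (truth.a2b_strand[cand + guard] == s)
    )
    return cand[ok]


def plant_heterozygotes(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[VariantRecord], pd.DataFrame, List[VariantRecord]]:
    """Plant heterozygous SNVs on genome A with matching calls on genome B.

    Sites are sampled without replacement from mapped, non-repeat
    positions (inserted repeats are unmapped by construction) whose
    guard window contains no alignment gap. Each site's genotype is
    {A-reference base, one random other base}; the genome-B genotype
    reports the strand-adjusted same pair at the true target position.
    With ``genotype_error_rate`` > 0 that fraction of B-side calls is
    corrupted to a homozygote or a no-call (half each in expectation).

    Returns (het VCF records vs A, truth table, genotype records vs B)
    and stores the truth table on ``truth.het_table``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    eligible = _eligible_positions(truth, config.het_guard_bp)
    n = config.n_het_sites
    if n > len(eligible):
        raise ValueError(
            f"requested {n} het sites but only {len(eligible)} eligible positions"
        )
    chosen = np.sort(rng.choice(eligible, size=n, replace=False)) if n else np.array([], dtype=int)
    seq_a = genome_a.contigs[truth.contig_a]
    seq_b = genome_b.contigs[truth.contig_b]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bases = "ACGT"
    recs_a: List[VariantRecord] = []
    recs_b: List[VariantRecord] = []
    rows = []
    for a0 in chosen:
        a0 = int(a0)
        ref_a = seq_a[a0]
        alt = bases[(bases.index(ref_a) + int(rng.integers(1, 4))) % 4]
        b0 = int(truth.a2b[a0])
        rel = int(truth.a2b_strand[a0])
        pair_a = (ref_a, alt)
        pair_b = tuple(sorted(comp[x] for x in pair_a)) if rel == -1 else tuple(sorted(pair_a))
        ref_b = seq_b[b0]
        alts_b = tuple(sorted(set(pair_b) - {ref_b}))
        call_b = GenotypeCall.of(*pair_b)
        if config.genotype_error_rate > 0 and rng.random() < config.genotype_error_rate:
            if rng.random() < 0.5:
                call_b = GenotypeCall.no_call()
            else:
                hom = pair_b[int(rng.integers(0, 2))]
                call_b = GenotypeCall.of(hom, hom)
        recs_a.append(
            VariantRecord(
                contig=truth.contig_a,
                pos=a0 + 1,
                ref=ref_a,
                alts=(alt,),
                genotype=GenotypeCall.of(ref_a, alt),
            )
        )
        if not alts_b:
            # Both alleles match B's reference base -- cannot happen for a
            # het pair (two distinct alleles, at most one equals REF).
            raise AssertionError("het allele pair collapsed on target side")
        recs_b.append(
            VariantRecord(
                contig=truth.contig_b,
                pos=b0 + 1,
                ref=ref_b,
                alts=alts_b,
                genotype=call_b,
            )
        )
        rows.append(
            {
                "src_contig": truth.contig_a,
                "src_pos": a0 + 1,
                "allele1": min(pair_a),
                "allele2": max(pair_a),
                "tgt_contig": truth.contig_b,
                "tgt_pos": b0 + 1,
                "strand": "+" if rel == 1 else "-",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "src_contig", "src_pos", "allele1", "allele2",
            "tgt_contig", "tgt_pos", "strand",
        ],
    )
    recs_b.sort(key=lambda r: (r.contig, r.pos))
    truth.het_table = table
    return recs_a, table, recs_b


def _write_fasta(path: Path, genome: GenomeSequence, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_bed(path: Path, intervals: List[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def _truth_blocks(truth: SyntheticTruth) -> pd.DataFrame:
    """Collinear-run view of the per-base orthology map (compact TSV form)."""
    pos = np.nonzero(truth.a2b >= 0)[0]
    if len(pos) == 0:
        return pd.DataFrame(columns=["a_start", "a_end", "b_at_a_start", "strand"])
    b = truth.a2b[pos]
    s = truth.a2b_strand[pos]
    new = np.ones(len(pos), dtype=bool)
    new[1:] = (
        (np.diff(pos) != 1) | (np.diff(b) != s[:-1]) | (s[1:] != s[:-1])
    )
    starts = np.nonzero(new)[0]
    ends = np.append(starts[1:], len(pos))
    return pd.DataFrame(
        {
            "a_start": pos[starts],
            "a_end": pos[ends - 1] + 1,
            "b_at_a_start": b[starts],
            "strand": np.where(s[starts] == 1, "+", "-"),
        }
    )


def write_bundle(config: SimulationConfig, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Run the full generator and write its outputs to ``outdir``.

    Writes both genomes as FASTA, the planted het VCF against A, the
    genotype VCF against B, per-genome repeat BEDs, the orthology map as
    collinear blocks, the het truth table, and the echoed configuration.
    Byte-identical across reruns with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_a, genome_b, truth = make_genome_pair(config)
    recs_a, het_table, recs_b = plant_heterozygotes(genome_a, genome_b, truth, config)
    paths = {
        "genome_a": outdir / "genome_a.fa",
        "genome_b": outdir / "genome_b.fa",
        "hets_a": outdir / "hets_a.vcf",
        "genotypes_b": outdir / "genotypes_b.vcf",
        "repeats_a": outdir / "repeats_a.bed",
        "repeats_b": outdir / "repeats_b.bed",
        "truth_blocks": outdir / "truth_blocks.tsv",
        "het_table": outdir / "het_table.tsv",
        "config": outdir / "config.json",
    }
    _write_fasta(paths["genome_a"], genome_a)
    _write_fasta(paths["genome_b"], genome_b)
    write_vcf(recs_a, paths["hets_a"], genome_a.lengths)
    write_vcf(recs_b, paths["genotypes_b"], genome_b.lengths)
    _write_bed(paths["repeats_a"], truth.repeats_a)
    _write_bed(paths["repeats_b"], truth.repeats_b)
    _truth_blocks(truth).to_csv(paths["truth_blocks"], sep="\t", index=False)
    het_table.to_csv(paths["het_table"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
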