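"""Project variant positions through accepted HSPs into target coordinates.

One source variant yields one :class:`TranslationRecord`: either a
translated target position (with strand and strand-adjusted alleles), or
a terminal status explaining why no trustworthy orthologous position
exists (no HSP, multiple HSPs, variant column inside an alignment gap,
unique HSP on an excluded contig, or no usable flank).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pysam

from .flank_align import (
    AlignParams,
    HSP,
    TargetSeedIndex,
    filter_hsps,
    find_hsps,
)
from .genome_io import GenomeIOError, GenomeSequence, extract_flank
from .variant_io import (
    DEFAULT_EXCLUDED_CONTIGS,
    GenotypeCall,
    VariantRecord,
)

__all__ = [
    "TranslationStatus",
    "TranslationRecord",
    "project_position",
    "translate_alleles",
    "liftover_variant",
    "lift_variants",
    "write_translation_table",
    "read_translation_table",
    "write_translation_vcf",
    "status_counts",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TranslationStatus(Enum):
    TRANSLATED = "translated"
    NO_HSP = "no_hsp"
    MULTIPLE_HSP = "multiple_hsp"
    GAP_AT_VARIANT = "gap_at_variant"
    TARGET_EXCLUDED_CONTIG = "target_excluded_contig"
    FLANK_UNAVAILABLE = "flank_unavailable"


@dataclass(frozen=True)
class TranslationRecord:
    """The liftover outcome for one source variant.

    Target fields are present iff ``status`` is ``TRANSLATED``;
    ``target_pos`` is 1-based. ``translated_alleles`` are the source
    genotype alleles, reverse-complemented when the unique HSP is on the
    minus strand of the target.
    """

    source: VariantRecord
    status: TranslationStatus
    target_contig: Optional[str] = None
    target_pos: Optional[int] = None
    strand: Optional[str] = None
    target_ref_base: Optional[str] = None
    translated_alleles: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        translated = self.status is TranslationStatus.TRANSLATED
        have_all = all(
            x is not None
            for x in (
                self.target_contig,
                self.target_pos,
                self.strand,
                self.target_ref_base,
                self.translated_alleles,
            )
        )
        if translated != have_all:
            raise ValueError(
                "target fields must be present exactly when status is translated"
            )


def project_position(h: HSP, query_pos: int) -> Optional[int]:
    """Map a 0-based query offset through an HSP to a 0-based target position.

    Returns ``None`` when the query position falls between aligned blocks
    (the variant column sits in a target-side gap). Within a block the
    mapping increases with query position on the plus strand and
    decreases on the minus strand.
    """
    if not h.query_start <= query_pos < h.query_end:
        raise ValueError(
            f"query position {query_pos} outside HSP query span "
            f"[{h.query_start}, {h.query_end})"
        )
    for q_off, t_off, length in h.blocks:
        if q_off <= query_pos < q_off + length:
            if h.strand == "+":
                return t_off + (query_pos - q_off)
            return t_off + (length - 1) - (query_pos - q_off)
    return None


def translate_alleles(alleles: Tuple[str, str], strand: str) -> Tuple[str, str]:
    """Carry a single-base allele pair across to the target strand.

    Identity on "+"; base-wise complement on "-" (the pair stays
    unordered, so no reversal is involved).
    """
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "+":
        out = alleles
    else:
        try:
            out = tuple(_COMPLEMENT[a] for a in alleles)
        except KeyError as exc:
            raise ValueError(f"non-ACGT allele {exc}") from None
    return tuple(sorted(out))  # type: ignore[return-value]


def liftover_variant(
    v: VariantRecord,
    source_genome: GenomeSequence,
    target_genome: GenomeSequence,
    params: AlignParams,
    excluded_target_contigs: Set[str] = DEFAULT_EXCLUDED_CONTIGS,
    index: Optional[TargetSeedIndex] = None,
) -> TranslationRecord:
    """Lift one heterozygous SNV to the target assembly.

    Composes flank extraction -> seeded HSP search -> acceptance filters
    -> uniqueness -> position projection -> strand-adjusted allele
    translation. All failure modes are statuses, never exceptions.
    """
    try:
        flank = extract_flank(source_genome, v.contig, v.pos, params.flank)
    except GenomeIOError:
        return TranslationRecord(v, TranslationStatus.FLANK_UNAVAILABLE)
    if len(v.ref) == 1 and flank.sequence[flank.variant_offset] != v.ref:
        # Source genome disagrees with the VCF REF allele at this site.
        return TranslationRecord(v, TranslationStatus.FLANK_UNAVAILABLE)
    hsps = filter_hsps(find_hsps(flank, target_genome, params, index), flank, params)
    picked = unique = None
    if not hsps:
        return TranslationRecord(v, TranslationStatus.NO_HSP)
    if len(hsps) > 1:
        return TranslationRecord(v, TranslationStatus.MULTIPLE_HSP)
    picked = hsps[0]
    if picked.target_contig in excluded_target_contigs:
        return TranslationRecord(v, TranslationStatus.TARGET_EXCLUDED_CONTIG)
    t0 = project_position(picked, flank.variant_offset)
    if t0 is None:
        return TranslationRecord(v, TranslationStatus.GAP_AT_VARIANT)
    if not v.genotype.is_call:
        return TranslationRecord(v, TranslationStatus.FLANK_UNAVAILABLE)
    alleles = translate_alleles(v.genotype.alleles, picked.strand)  # type: ignore[arg-type]
    return TranslationRecord(
        source=v,
        status=TranslationStatus.TRANSLATED,
        target_contig=picked.target_contig,
        target_pos=t0 + 1,
        strand=picked.strand,
        target_ref_base=target_genome.base(picked.target_contig, t0 + 1),
        translated_alleles=alleles,
    )


def lift_variants(
    variants: Iterable[VariantRecord],
    source_genome: GenomeSequence,
    target_genome: GenomeSequence,
    params: Optional[AlignParams] = None,
    excluded_target_contigs: Set[str] = DEFAULT_EXCLUDED_CONTIGS,
    het_only: bool = True,
    snv_only: bool = True,
) -> Iterator[TranslationRecord]:
    """Lift a stream of variants, reusing one seed index for the whole run.

    By default only heterozygous SNVs are lifted (the corroboration
    procedure centres a single variant base in the flank query); set
    ``het_only=False`` to also lift homozygous sites, e.g. for building
    an interspecies variant catalogue. Non-SNV records and records
    outside the selection are skipped silently.
    """
    if params is None:
        params = AlignParams()
    index = TargetSeedIndex(target_genome, params.seed_k)
    for v in variants:
        if snv_only and not v.is_snv:
            continue
        if het_only and not v.genotype.is_het:
            continue
        if not v.genotype.is_call:
            continue
        yield liftover_variant(
            v, source_genome, target_genome, params, excluded_target_contigs, index
        )


def status_counts(records: Iterable[TranslationRecord]) -> Dict[str, int]:
    counts = {s.value: 0 for s in TranslationStatus}
    for r in records:
        counts[r.status.value] += 1
    return counts


_TABLE_COLUMNS = [
    "src_contig",
    "src_pos",
    "src_ref",
    "allele1",
    "allele2",
    "status",
    "tgt_contig",
    "tgt_pos",
    "strand",
    "tgt_ref",
]


def write_translation_table(
    records: Iterable[TranslationRecord], path: Union[str, Path]
) -> None:
    """Write all translation outcomes (every status) as a TSV table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TABLE_COLUMNS)
        for r in records:
            src = r.source
            a1, a2 = (src.genotype.alleles or (".", "."))
            w.writerow(
                [
                    src.contig,
                    src.pos,
                    src.ref,
                    a1,
                    a2,
                    r.status.value,
                    r.target_contig or ".",
                    r.target_pos if r.target_pos is not None else ".",
                    r.strand or ".",
                    r.target_ref_base or ".",
                ]
            )


def read_translation_table(path: Union[str, Path]) -> List[TranslationRecord]:
    """Read a TSV written by :func:`write_translation_table`."""
    out: List[TranslationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            gt = (
                GenotypeCall.of(row["allele1"], row["allele2"])
                if row["allele1"] != "."
                else GenotypeCall.no_call()
            )
            ref = row["src_ref"]
            alts = tuple(
                sorted(a for a in (gt.alleles or ()) if a != ref)
            )
            src = VariantRecord(
                contig=row["src_contig"],
                pos=int(row["src_pos"]),
                ref=ref,
                alts=alts or ("N",),
                genotype=gt,
            )
            status = TranslationStatus(row["status"])
            if status is TranslationStatus.TRANSLATED:
                out.append(
                    TranslationRecord(
                        source=src,
                        status=status,
                        target_contig=row["tgt_contig"],
                        target_pos=int(row["tgt_pos"]),
                        strand=row["strand"],
                        target_ref_base=row["tgt_ref"],
                        translated_alleles=translate_alleles(
                            gt.alleles, row["strand"]  # type: ignore[arg-type]
                        ),
                    )
                )
            else:
                out.append(TranslationRecord(source=src, status=status))
    return out


def write_translation_vcf(
    records: Iterable[TranslationRecord],
    path: Union[str, Path],
    contig_lengths: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write translated sites as a VCF against the target assembly.

    REF is the target reference base; ALT carries every translated allele
    that differs from it (for a non-ref het on the target side both
    alleles appear as ALT). INFO records the source coordinate and the
    mapping strand; when two source variants land on the same target
    position both are emitted and flagged ``COLLIDE``.
    """
    translated = [r for r in records if r.status is TranslationStatus.TRANSLATED]
    translated.sort(key=lambda r: (r.target_contig, r.target_pos))
    seen: Dict[Tuple[str, int], int] = {}
    for r in translated:
        key = (r.target_contig, r.target_pos)  # type: ignore[arg-type]
        seen[key] = seen.get(key, 0) + 1
    collisions = {k for k, n in seen.items() if n > 1}
    if collisions:
        warnings.warn(
            f"{len(collisions)} target positions receive multiple source variants"
        )
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("SRC", 1, "String", "Source assembly coordinate contig:pos")
    header.info.add("STRAND", 1, "String", "Mapping strand of the unique HSP")
    header.info.add("COLLIDE", 0, "Flag", "Another source variant maps here")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in translated:
            ref = r.target_ref_base
            alts = tuple(sorted(set(r.translated_alleles) - {ref}))  # type: ignore[arg-type]
            alleles = (ref,) + alts
            rec = out.new_record(
                contig=r.target_contig,
                start=r.target_pos - 1,  # type: ignore[operator]
                alleles=alleles,
            )
            rec.info["SRC"] = f"{r.source.contig}:{r.source.pos}"
            rec.info["STRAND"] = r.strand
            if (r.target_contig, r.target_pos) in collisions:
                rec.info["COLLIDE"] = True
            idx = {a: i for i, a in enumerate(alleles)}
            rec.samples[sample]["GT"] = tuple(
                idx[a] for a in r.translated_alleles  # type: ignore[union-attr]
            )
            out.write(rec)
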