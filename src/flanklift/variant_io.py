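"""VCF input/output, genotype classification, and variant filtering.

The pipeline consumes single-animal genotype calls as VCF 4.x (fields
CHROM, POS, ID, REF, ALT, FORMAT:GT), classifies each site by zygosity
relative to the reference allele, and applies the two source-side
filters used before liftover: removal of calls inside annotated repeat
intervals, and removal of calls on excluded (sex) chromosomes.

A "non-ref het" is a heterozygous call where *neither* detected allele
matches the reference base at the site -- a class that is common in
cross-species mappings, where the reference species carries a third
allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence, Set, Tuple, Union

import pysam

from .genome_io import Interval, RepeatIndex

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "VariantClass",
    "VariantSummary",
    "VariantIOError",
    "DEFAULT_EXCLUDED_CONTIGS",
    "MAX_ALT_ALLELES",
    "read_vcf",
    "write_vcf",
    "classify_variant",
    "filter_variants",
    "summarize_variants",
]

MAX_ALT_ALLELES = 3
DEFAULT_EXCLUDED_CONTIGS = frozenset({"chrX", "X"})

_ACGT = frozenset("ACGT")


class VariantIOError(ValueError):
    """Raised for malformed or out-of-contract VCF/PED input."""


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair at one site, or a no-call.

    ``alleles`` is a sorted 2-tuple of allele strings when called, or
    ``None`` for a missing genotype.
    """

    alleles: Optional[Tuple[str, str]]

    @classmethod
    def of(cls, a: str, b: str) -> "GenotypeCall":
        return cls(tuple(sorted((a, b))))  # type: ignore[arg-type]

    @classmethod
    def no_call(cls) -> "GenotypeCall":
        return cls(None)

    @property
    def is_call(self) -> bool:
        return self.alleles is not None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def allele_set(self) -> frozenset:
        if self.alleles is None:
            return frozenset()
        return frozenset(self.alleles)

    def __str__(self) -> str:
        if self.alleles is None:
            return "./."
        return "/".join(self.alleles)


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site with a single-sample genotype. ``pos`` is 1-based."""

    contig: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotype: GenotypeCall
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ref:
            raise VariantIOError(f"{self.contig}:{self.pos}: empty REF allele")
        if any(not a for a in self.alts):
            raise VariantIOError(f"{self.contig}:{self.pos}: empty ALT allele")
        if self.ref in self.alts:
            raise VariantIOError(f"{self.contig}:{self.pos}: ALT equals REF")
        if len(self.alts) > MAX_ALT_ALLELES:
            raise VariantIOError(
                f"{self.contig}:{self.pos}: more than {MAX_ALT_ALLELES} ALT alleles"
            )

    @property
    def is_snv(self) -> bool:
        return (
            self.ref in _ACGT
            and len(self.alts) > 0
            and all(len(a) == 1 and a in _ACGT for a in self.alts)
        )


class VariantClass(Enum):
    HOM_REF = "hom_ref"
    HOM_ALT = "hom_alt"
    HET_REF_ALT = "het_ref_alt"
    HET_NONREF = "het_nonref"
    NO_CALL = "no_call"


def classify_variant(v: VariantRecord) -> VariantClass:
    """Classify a genotype by zygosity relative to the reference allele.

    A het whose two alleles both differ from REF is ``HET_NONREF``.
    """
    g = v.genotype
    if not g.is_call:
        return VariantClass.NO_CALL
    a, b = g.alleles  # type: ignore[misc]
    if a == b:
        return VariantClass.HOM_REF if a == v.ref else VariantClass.HOM_ALT
    if v.ref in (a, b):
        return VariantClass.HET_REF_ALT
    return VariantClass.HET_NONREF


def read_vcf(path: Union[str, Path]) -> Iterator[VariantRecord]:
    """Stream a single-sample VCF as :class:`VariantRecord` objects.

    Sites with more than three ALT alleles are skipped with a warning
    (outside the genotyper's configured allele cap); a missing GT becomes
    a no-call. Multi-sample files are rejected -- the contract is one
    animal per file.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise VariantIOError(
                f"{path}: expected exactly 1 sample, found {len(samples)}"
            )
        sample = samples[0]
        for rec in vf:
            alts = tuple(rec.alts) if rec.alts else ()
            if len(alts) > MAX_ALT_ALLELES:
                warnings.warn(
                    f"{path}: {rec.chrom}:{rec.pos}: skipped, "
                    f"{len(alts)} ALT alleles exceeds cap of {MAX_ALT_ALLELES}"
                )
                continue
            gt = rec.samples[sample].get("GT")
            if gt is None or all(i is None for i in gt):
                call = GenotypeCall.no_call()
            else:
                if len(gt) != 2 or any(i is None for i in gt):
                    raise VariantIOError(
                        f"{path}: {rec.chrom}:{rec.pos}: malformed diploid GT {gt!r}"
                    )
                alleles = (rec.ref,) + alts
                try:
                    call = GenotypeCall.of(alleles[gt[0]], alleles[gt[1]])
                except IndexError:
                    raise VariantIOError(
                        f"{path}: {rec.chrom}:{rec.pos}: GT index out of range"
                    ) from None
            yield VariantRecord(
                contig=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=alts,
                genotype=call,
                id=rec.id,
            )


def write_vcf(
    records: Iterable[VariantRecord],
    path: Union[str, Path],
    contig_lengths: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write records as a single-sample VCF 4.2 with ##contig headers.

    Records must be sorted by (contig, pos); genotypes round-trip through
    :func:`read_vcf` losslessly for the in-scope fields.
    """
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    last: Optional[Tuple[str, int]] = None
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in records:
            key = (v.contig, v.pos)
            if last is not None and v.contig == last[0] and v.pos < last[1]:
                raise VariantIOError(
                    f"unsorted input at {v.contig}:{v.pos} (after {last[0]}:{last[1]})"
                )
            last = key
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref,) + v.alts,
                id=v.id,
            )
            if v.genotype.is_call:
                allele_index = {a: i for i, a in enumerate((v.ref,) + v.alts)}
                try:
                    gt = tuple(allele_index[a] for a in v.genotype.alleles)  # type: ignore[union-attr]
                except KeyError as exc:
                    raise VariantIOError(
                        f"{v.contig}:{v.pos}: genotype allele {exc} not in REF/ALT"
                    ) from None
                rec.samples[sample]["GT"] = gt
            else:
                rec.samples[sample]["GT"] = (None, None)
            out.write(rec)


def filter_variants(
    variants: Iterable[VariantRecord],
    repeats: Union[Sequence[Interval], RepeatIndex],
    excluded_contigs: Set[str] = DEFAULT_EXCLUDED_CONTIGS,
) -> Iterator[VariantRecord]:
    """Drop variants inside repeat intervals or on excluded contigs.

    Repeat membership is tested at the variant's anchor position (POS)
    only. Input order is preserved.
    """
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    for v in variants:
        if v.contig in excluded_contigs:
            continue
        if index.contains(v.contig, v.pos):
            continue
        yield v


@dataclass
class VariantSummary:
    """Zygosity tallies overall and restricted to non-repeat positions."""

    total: int = 0
    homozygous: int = 0
    heterozygous: int = 0
    het_nonref: int = 0
    het_not_in_repeats: int = 0
    het_refalt_not_in_repeats: int = 0
    het_nonref_not_in_repeats: int = 0
    no_call: int = 0

    @property
    def het_refalt(self) -> int:
        return self.heterozygous - self.het_nonref

    def as_dict(self) -> Dict[str, int]:
        return {
            "total": self.total,
            "homozygous": self.homozygous,
            "heterozygous": self.heterozygous,
            "het_refalt": self.het_refalt,
            "het_nonref": self.het_nonref,
            "het_not_in_repeats": self.het_not_in_repeats,
            "het_refalt_not_in_repeats": self.het_refalt_not_in_repeats,
            "het_nonref_not_in_repeats": self.het_nonref_not_in_repeats,
            "no_call": self.no_call,
        }


def summarize_variants(
    variants: Iterable[VariantRecord],
    repeats: Union[Sequence[Interval], RepeatIndex] = (),
) -> VariantSummary:
    """Tally genotype classes, overall and outside repeat intervals.

    ``total`` counts called genotypes only (homozygous + heterozygous);
    no-calls are tallied separately.
    """
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    s = VariantSummary()
    for v in variants:
        cls = classify_variant(v)
        if cls is VariantClass.NO_CALL:
            s.no_call += 1
            continue
        s.total += 1
        in_rep = index.contains(v.contig, v.pos)
        if cls in (VariantClass.HOM_REF, VariantClass.HOM_ALT):
            s.homozygous += 1
        else:
            s.heterozygous += 1
            if not in_rep:
                s.het_not_in_repeats += 1
            if cls is VariantClass.HET_NONREF:
                s.het_nonref += 1
                if not in_rep:
                    s.het_nonref_not_in_repeats += 1
            elif not in_rep:
                s.het_refalt_not_in_repeats += 1
    return s
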