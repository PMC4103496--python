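"""Genotype corroboration and array-concordance statistics.

After liftover, each translated heterozygous site is compared with the
genotype called at its orthologous position on the target assembly: the
site is *corroborated* when the target call is heterozygous with the
same (strand-adjusted) allele pair. Independent validation against SNP
array genotypes requires Illumina top-strand normalisation first, since
array genotypes are reported on a canonical strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from .liftover import TranslationRecord, TranslationStatus
from .variant_io import GenotypeCall, VariantIOError, VariantRecord

__all__ = [
    "Outcome",
    "TOP_AMBIGUOUS",
    "CorroborationResult",
    "ConcordanceSummary",
    "corroborate_site",
    "corroborate_all",
    "corroboration_summary",
    "to_top_strand",
    "concordance",
    "read_site_genotypes",
    "calls_from_variants",
    "het_capture_estimate",
    "intraspecies_lower_bound",
]


class Outcome(Enum):
    CORROBORATED = "corroborated"
    NOT_CORROBORATED = "not_corroborated"
    NO_CALL = "no_call"


class _TopAmbiguous:
    """Sentinel: allele set is complement-invariant (A/T or C/G) and
    cannot be oriented to the top strand without flank context."""

    def __repr__(self) -> str:  # pragma: no cover
        return "TOP_AMBIGUOUS"


TOP_AMBIGUOUS = _TopAmbiguous()


def corroborate_site(
    t: TranslationRecord,
    target_call: Optional[GenotypeCall],
    het_only: bool = False,
) -> Outcome:
    """Compare one translated site with the target-assembly genotype.

    Default (strict) mode corroborates only when the target genotype is
    heterozygous with exactly the translated allele pair; ``het_only``
    reproduces the looser reading where any heterozygous call at the
    site corroborates.
    """
    if t.status is not TranslationStatus.TRANSLATED:
        raise ValueError("can only corroborate translated records")
    if target_call is None or not target_call.is_call:
        return Outcome.NO_CALL
    if not target_call.is_het:
        return Outcome.NOT_CORROBORATED
    if het_only:
        return Outcome.CORROBORATED
    if target_call.allele_set() == frozenset(t.translated_alleles):  # type: ignore[arg-type]
        return Outcome.CORROBORATED
    return Outcome.NOT_CORROBORATED


def corroborate_all(
    translations: Iterable[TranslationRecord],
    target_calls: Mapping[Tuple[str, int], GenotypeCall],
    het_only: bool = False,
) -> List[Tuple[TranslationRecord, Outcome]]:
    """Corroborate every translated record against a target call table.

    ``target_calls`` is keyed by (contig, 1-based position); positions
    without a call in the table are counted as no-call.
    """
    out = []
    for t in translations:
        if t.status is not TranslationStatus.TRANSLATED:
            continue
        call = target_calls.get((t.target_contig, t.target_pos))  # type: ignore[arg-type]
        out.append((t, corroborate_site(t, call, het_only=het_only)))
    return out


@dataclass(frozen=True)
class CorroborationResult:
    """Corroboration tallies plus the rate over translatable sites."""

    input_hets: int
    translated: int
    corroborated: int
    not_corroborated: int = 0
    no_call: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.corroborated <= self.translated <= self.input_hets:
            raise ValueError(
                "need corroborated <= translated <= input het count "
                f"(got {self.corroborated}/{self.translated}/{self.input_hets})"
            )

    @property
    def rate(self) -> Optional[float]:
        """Fraction of translated sites corroborated (None when undefined)."""
        if self.translated == 0:
            return None
        return self.corroborated / self.translated

    @property
    def rate_pct(self) -> Optional[float]:
        """Corroboration rate as a percentage, one decimal place."""
        if self.rate is None:
            return None
        return round(100.0 * self.rate, 1)

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "input_hets": self.input_hets,
            "translated": self.translated,
            "corroborated": self.corroborated,
            "not_corroborated": self.not_corroborated,
            "no_call": self.no_call,
            "rate_pct": self.rate_pct,
        }


def corroboration_summary(
    outcomes: Iterable[Outcome], input_het_count: int, translated_count: int
) -> CorroborationResult:
    """Tally per-site outcomes into a :class:`CorroborationResult`."""
    outcomes = list(outcomes)
    corroborated = sum(1 for o in outcomes if o is Outcome.CORROBORATED)
    not_corr = sum(1 for o in outcomes if o is Outcome.NOT_CORROBORATED)
    no_call = sum(1 for o in outcomes if o is Outcome.NO_CALL)
    return CorroborationResult(
        input_hets=input_het_count,
        translated=translated_count,
        corroborated=corroborated,
        not_corroborated=not_corr,
        no_call=no_call,
    )


# Het allele sets with a defined top-strand image.
_TOP_MAP = {
    frozenset("CT"): ("A", "G"),
    frozenset("GT"): ("A", "C"),
}
_AMBIGUOUS_SETS = (frozenset("AT"), frozenset("CG"))


def to_top_strand(g: GenotypeCall):
    """Normalise a genotype to the Illumina top-strand convention.

    C/T and G/T heterozygotes are complemented to A/G and A/C; A/C and
    A/G are already top-strand; the complement-invariant sets A/T and
    C/G cannot be oriented from the genotype alone and return
    :data:`TOP_AMBIGUOUS`. Homozygous calls and no-calls are returned
    unchanged (a hom call compared against a het is discordant under
    either orientation).
    """
    if not g.is_call or g.is_hom:
        return g
    a, b = g.alleles  # type: ignore[misc]
    if not set((a, b)) <= set("ACGT"):
        raise VariantIOError(f"non-ACGT alleles in genotype {g}")
    s = frozenset((a, b))
    if s in _AMBIGUOUS_SETS:
        return TOP_AMBIGUOUS
    if s in _TOP_MAP:
        return GenotypeCall.of(*_TOP_MAP[s])
    return g


@dataclass(frozen=True)
class ConcordanceSummary:
    """Genotype agreement between two call tables over shared sites."""

    overlapping_sites: int
    no_call_sites: int
    concordant_sites: int

    @property
    def compared_sites(self) -> int:
        return self.overlapping_sites - self.no_call_sites

    @property
    def percent_concordant(self) -> Optional[float]:
        if self.compared_sites == 0:
            return None
        return round(100.0 * self.concordant_sites / self.compared_sites, 2)

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "overlapping_sites": self.overlapping_sites,
            "no_call_sites": self.no_call_sites,
            "compared_sites": self.compared_sites,
            "concordant_sites": self.concordant_sites,
            "percent_concordant": self.percent_concordant,
        }


def concordance(
    calls_a: Mapping[Tuple[str, int], GenotypeCall],
    calls_b: Mapping[Tuple[str, int], GenotypeCall],
) -> ConcordanceSummary:
    """Allele-set concordance over sites shared by two call tables.

    Both tables are keyed by (contig, 1-based position) and are
    top-strand normalised internally; a site where either side is a
    no-call or top-strand ambiguous (A/T, C/G) is excluded from the
    comparison. The percentage is reported to two decimals.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    no_call = 0
    concordant = 0
    for key in shared:
        a = to_top_strand(calls_a[key])
        b = to_top_strand(calls_b[key])
        if a is TOP_AMBIGUOUS or b is TOP_AMBIGUOUS or not a.is_call or not b.is_call:
            no_call += 1
            continue
        if a.allele_set() == b.allele_set():
            concordant += 1
    return ConcordanceSummary(
        overlapping_sites=len(shared),
        no_call_sites=no_call,
        concordant_sites=concordant,
    )


def read_site_genotypes(
    ped_path: Union[str, Path], map_path: Union[str, Path]
) -> Dict[Tuple[str, int], GenotypeCall]:
    """Read one individual's array genotypes from a minimal PED/MAP pair.

    MAP rows give (contig, marker, [cM,] 1-based position); the PED row
    carries six leading pedigree columns followed by one allele pair per
    marker, in marker order, with "0" marking a missing allele. Exactly
    one individual is expected.
    """
    sites: List[Tuple[str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise VariantIOError(
                    f"{map_path}: line {lineno}: expected 3 or 4 MAP columns"
                )
            contig = fields[0]
            try:
                pos = int(fields[-1])
            except ValueError:
                raise VariantIOError(
                    f"{map_path}: line {lineno}: non-integer position"
                ) from None
            sites.append((contig, pos))
    rows = []
    with open(ped_path) as fh:
        for line in fh:
            if line.strip():
                rows.append(line.split())
    if len(rows) != 1:
        raise VariantIOError(
            f"{ped_path}: expected exactly one individual, found {len(rows)}"
        )
    fields = rows[0]
    alleles = fields[6:]
    if len(alleles) != 2 * len(sites):
        raise VariantIOError(
            f"{ped_path}: {len(alleles)} genotype alleles for {len(sites)} "
            "MAP markers (expected 2 per marker after 6 pedigree columns)"
        )
    table: Dict[Tuple[str, int], GenotypeCall] = {}
    for i, key in enumerate(sites):
        a, b = alleles[2 * i], alleles[2 * i + 1]
        if a == "0" or b == "0":
            table[key] = GenotypeCall.no_call()
        else:
            table[key] = GenotypeCall.of(a, b)
    return table


def calls_from_variants(
    variants: Iterable[VariantRecord],
) -> Dict[Tuple[str, int], GenotypeCall]:
    """Index a variant stream as a (contig, pos) -> genotype table."""
    return {(v.contig, v.pos): v.genotype for v in variants}


def het_capture_estimate(het_cross_species: float, het_same_species: float) -> float:
    """Share of within-species heterozygosity recoverable by cross-species
    mapping: het calls against the diverged reference over het calls
    against the species' own reference, as a percentage (one decimal)."""
    if het_same_species <= 0:
        raise ValueError("same-species het count must be positive")
    return round(100.0 * het_cross_species / het_same_species, 1)


def intraspecies_lower_bound(total_hets: float, corroboration_rate: float) -> float:
    """Lower bound on legitimate within-species het sites: the het count
    scaled by the corroboration rate (a fraction in [0, 1])."""
    if not 0 <= corroboration_rate <= 1:
        raise ValueError("corroboration_rate must be a fraction in [0, 1]")
    return total_hets * corroboration_rate
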