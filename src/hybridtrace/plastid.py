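"""Plastid haplotype assignment and crossing-direction inference.

Chloroplasts are maternally inherited in these water-crowfoots, so the
plastid haplotype of a hybrid identifies its seed (maternal) parent: of the
two species contributing the nuclear ITS copies, the one whose reference
haplotype the sample carries donated the chloroplast, and the other acted
as the pollen (paternal) donor.  Two intergenic spacers are used as markers
(rpl32-trnL, with reference clades A/C/D/I, and petL-psbE, with clades
A/C/F); when both are available their orientations must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .additivity import ParentageCall, Verdict, hamming_distance
from .errors import AlignmentGeometryError, UndefinedStatisticError, ValidationError
from .seq_io import read_alignment


@dataclass
class HaplotypeRefSet:
    """Named reference haplotypes for one plastid marker plus species map.

    ``species_map`` maps species name -> set of haplotype labels that
    species carries for this marker (a species may carry several regional
    haplotypes; a haplotype may be shared by several species).
    """

    marker: str
    refs: dict[str, str]  # haplotype_label -> aligned sequence
    species_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.refs:
            raise ValidationError(f"empty haplotype reference set for {self.marker}")
        lengths = {len(s) for s in self.refs.values()}
        if len(lengths) != 1:
            raise AlignmentGeometryError(f"{self.marker} references are not aligned to one length")
        for sp, labels in self.species_map.items():
            unknown = labels - set(self.refs)
            if unknown:
                raise ValidationError(
                    f"species_map for {sp!r} names unknown haplotype(s) {sorted(unknown)}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.refs.values())))

    def species_for(self, label: str) -> set[str]:
        """Species mapped to a haplotype label (may be empty)."""
        return {sp for sp, labels in self.species_map.items() if label in labels}

    @classmethod
    def from_files(
        cls, marker: str, fasta_path: str | Path, species_map_path: str | Path
    ) -> "HaplotypeRefSet":
        """Load references from FASTA ("marker|label" headers) and a
        species-map TSV with columns marker, haplotype_label, species."""
        mat = read_alignment(fasta_path)
        refs: dict[str, str] = {}
        for name, row in mat.items():
            mk, label = name.split("|", 1) if "|" in name else (marker, name)
            if mk == marker:
                refs[label] = row
        smap = read_species_map(species_map_path).get(marker, {})
        return cls(marker=marker, refs=refs, species_map=smap)


def read_species_map(path: str | Path) -> dict[str, dict[str, set[str]]]:
    """Parse a species-map TSV into {marker: {species: {labels}}}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "haplotype_label", "species"}
    if not required <= set(df.columns):
        raise ValidationError(f"species map must have columns {sorted(required)}")
    out: dict[str, dict[str, set[str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["marker"], {}).setdefault(row["species"], set()).add(
            row["haplotype_label"]
        )
    return out


def default_species_map() -> dict[str, dict[str, set[str]]]:
    """The packaged species->haplotype map for the two survey markers."""
    with resources.as_file(
        resources.files("hybridtrace.data").joinpath("species_map.tsv")
    ) as p:
        return read_species_map(p)


@dataclass(frozen=True)
class HaplotypeAssignment:
    sample_id: str
    marker: str
    haplotype_label: str | None  # None when no reference is within delta_max
    distance: int
    deviant: bool  # nearest reference matched, but not exactly
    tie: bool = False


class Confidence(Enum):
    ORIENTED = "ORIENTED"
    UNORIENTED = "UNORIENTED"
    CONFLICT = "CONFLICT"


@dataclass(frozen=True)
class OrientedCross:
    sample_id: str
    maternal_species: str | None
    paternal_species: str | None
    orientation_basis: tuple[str, ...]
    confidence: Confidence


def assign_haplotype(
    sample_id: str,
    seq: str,
    refs: HaplotypeRefSet,
    delta_max: int = 2,
) -> HaplotypeAssignment:
    """Assign the nearest reference haplotype by mismatch count.

    Distance counts mismatching columns where both sequences carry a base.
    Ties break lexicographically on the label and are flagged.  A sample
    farther than ``delta_max`` from every reference stays unassigned.
    """
    if len(seq) != refs.length:
        raise AlignmentGeometryError(
            f"sequence length {len(seq)} != {refs.marker} reference length {refs.length}"
        )
    dists = sorted(
        (hamming_distance(seq, ref_seq), label) for label, ref_seq in refs.refs.items()
    )
    best_dist, best_label = dists[0]
    tie = len(dists) > 1 and dists[1][0] == best_dist
    if best_dist > delta_max:
        return HaplotypeAssignment(sample_id, refs.marker, None, best_dist, False, tie)
    return HaplotypeAssignment(
        sample_id, refs.marker, best_label, best_dist, best_dist > 0, tie
    )


def orient_cross(
    call: ParentageCall,
    assignments: dict[str, HaplotypeAssignment],
    refsets: dict[str, HaplotypeRefSet],
) -> OrientedCross:
    """Orient a hybrid's cross from its plastid haplotype(s).

    For each marker with an assigned haplotype, the species mapped to that
    haplotype are intersected with the two ITS parents: exactly one parent
    -> that parent is the maternal candidate; both parents -> the haplotype
    is shared and cannot orient; neither -> no information.  Markers that
    nominate different maternal parents yield CONFLICT.
    """
    if call.verdict not in (Verdict.F1_HYBRID, Verdict.COMPLEX_HYBRID):
        raise ValidationError(
            f"orient_cross requires a hybrid call, got {call.verdict.value}"
        )
    if call.best_pair is None:
        raise ValidationError("hybrid call lacks a parent pair")
    parents = {call.best_pair.species_a, call.best_pair.species_b}

    maternal_by_marker: dict[str, str] = {}
    basis: list[str] = []
    for marker, assignment in sorted(assignments.items()):
        if assignment is None or assignment.haplotype_label is None:
            continue
        refset = refsets[marker]
        mapped = refset.species_for(assignment.haplotype_label) & parents
        if len(mapped) == 1:
            maternal_by_marker[marker] = next(iter(mapped))
            basis.append(marker)

    maternal_set = set(maternal_by_marker.values())
    if len(maternal_set) > 1:
        return OrientedCross(call.sample_id, None, None, tuple(basis), Confidence.CONFLICT)
    if not maternal_set:
        return OrientedCross(call.sample_id, None, None, (), Confidence.UNORIENTED)
    maternal = maternal_set.pop()
    paternal = next(iter(parents - {maternal}))
    return OrientedCross(call.sample_id, maternal, paternal, tuple(basis), Confidence.ORIENTED)


@dataclass(frozen=True)
class DirectionalityResult:
    """Fraction of oriented crosses with the focal species as pollen donor."""

    fraction_paternal_focal: float
    n_oriented: int
    n_paternal_focal: int
    n_unoriented: int
    n_conflict: int


def directionality(crosses: list[OrientedCross], focal_species: str) -> DirectionalityResult:
    """Crossing-direction statistic: how consistently the focal species is
    the paternal (pollen) parent among oriented crosses.

    UNORIENTED and CONFLICT crosses are excluded from the denominator and
    reported as separate counts.
    """
    oriented = [c for c in crosses if c.confidence is Confidence.ORIENTED]
    n_unoriented = sum(1 for c in crosses if c.confidence is Confidence.UNORIENTED)
    n_conflict = sum(1 for c in crosses if c.confidence is Confidence.CONFLICT)
    if not oriented:
        raise UndefinedStatisticError("directionality undefined: zero oriented crosses")
    n_focal = sum(1 for c in oriented if c.paternal_species == focal_species)
    return DirectionalityResult(
        fraction_paternal_focal=n_focal / len(oriented),
        n_oriented=len(oriented),
        n_paternal_focal=n_focal,
        n_unoriented=n_unoriented,
        n_conflict=n_conflict,
    )


def crosses_to_frame(crosses: list[OrientedCross]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "maternal": c.maternal_species or "",
                "paternal": c.paternal_species or "",
                "basis": ",".join(c.orientation_basis),
                "confidence": c.confidence.value,
            }
            for c in crosses
        ],
        columns=["sample_id", "maternal", "paternal", "basis", "confidence"],
    )
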