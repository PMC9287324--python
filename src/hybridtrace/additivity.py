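"""Additive-polymorphism site classification and hybrid parentage calling.

The biological model: nuclear ribosomal ITS is biparentally inherited, so a
first-generation hybrid carries both parental ribotype copies.  Direct Sanger
sequencing of such an individual yields, at every column where the parents
differ, a double peak that base callers record as the IUPAC code equal to the
*union* of the two parental bases.  Classifying each alignment column of a
query against a candidate parent pair therefore separates:

* INVARIANT — all three sequences agree;
* PARENT_A / PARENT_B — parents differ, query shows exactly one parent's
  symbol (either a true species site or an additive site where one copy's
  peak dropped out of the trace);
* ADDITIVE — parents differ and the query equals their union (the hybrid
  signature);
* RESIDUAL — the query symbol is explained by neither parent nor their
  union (pointing at ribotype variation or a third parental lineage);
* GAPPED — a gap (or an uninformative 'N') is involved; excluded from
  scoring.

A single-base indel between the parents produces a distinct signature: the
two co-amplified templates fall out of register downstream of the indel, so
the trace shows the superposition of the longer parent at column *i* with
the shorter parent's base belonging to column *i+1*.  ``shifted_superposition``
tests a query for that one-base-offset pattern.

Parentage calling evaluates every cross-species ribotype pair, ranks pairs
by how cleanly they explain the query (few residuals, many additive sites),
and issues a SPECIES / F1_HYBRID / COMPLEX_HYBRID / UNRESOLVED verdict; for
complex hybrids it ranks third-parent candidates by how many residual
columns each explains as a three-way superposition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from . import iupac
from .errors import AlignmentGeometryError, ValidationError
from .iupac import GAP
from .seq_io import AlignedMatrix, read_alignment


class SiteLabel(Enum):
    INVARIANT = "INVARIANT"
    PARENT_A = "PARENT_A"
    PARENT_B = "PARENT_B"
    ADDITIVE = "ADDITIVE"
    RESIDUAL = "RESIDUAL"
    GAPPED = "GAPPED"


class Verdict(Enum):
    SPECIES = "SPECIES"
    F1_HYBRID = "F1_HYBRID"
    COMPLEX_HYBRID = "COMPLEX_HYBRID"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class SiteClassification:
    position: int  # 1-based alignment column
    label: SiteLabel
    observed: str
    parent_a: str
    parent_b: str


@dataclass(frozen=True)
class IndelSuperpositionResult:
    """Outcome of the one-base-offset superposition test around a 1-column indel."""

    indel_position: int
    shift_consistent: bool
    n_shift_explained: int
    n_testable: int


@dataclass
class PairScore:
    parent_a: str  # ribotype name "species|ribotype"
    parent_b: str
    species_a: str
    species_b: str
    n_additive: int
    n_residual: int
    n_parent_only: int
    n_invariant: int
    n_gapped: int
    residual_positions: list[int] = field(default_factory=list)
    additive_positions: list[int] = field(default_factory=list)
    indel_shift: IndelSuperpositionResult | None = None

    @property
    def species_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.species_a, self.species_b)))


@dataclass
class ParentageCall:
    sample_id: str
    verdict: Verdict
    best_pair: PairScore | None = None
    species_match: tuple[str, int] | None = None  # (ribotype name, distance)
    residual_positions: list[int] = field(default_factory=list)
    third_parent_candidates: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class ParentageConfig:
    """Calling thresholds.

    tau_species: maximum mismatches to a single panel ribotype for a SPECIES
        call; default 2, accommodating within-species ribotype variants that
        differ by one or two substitutions.
    tau_residual: maximum residual (unexplained polymorphic) sites tolerated
        in an F1 call before the sample is escalated to COMPLEX_HYBRID.
    tau_noise: fraction of downstream columns allowed to contradict the
        shifted-superposition model while still calling it consistent.
    """

    tau_species: int = 2
    tau_residual: int = 2
    tau_noise: float = 0.05


def _check_same_length(*rows: str) -> int:
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentGeometryError(f"rows of unequal length: {sorted(lengths)}")
    return lengths.pop()


def classify_sites(query: str, parent_a: str, parent_b: str) -> list[SiteClassification]:
    """Classify every alignment column of ``query`` against a parent pair.

    When the parents differ and the observed symbol equals both the parental
    union and one parent (possible when one parent's code subsumes the
    other's), ADDITIVE takes precedence.
    """
    length = _check_same_length(query, parent_a, parent_b)
    out: list[SiteClassification] = []
    for i in range(length):
        q, a, b = query[i], parent_a[i], parent_b[i]
        if q == GAP or a == GAP or b == GAP or q == "N":
            label = SiteLabel.GAPPED
        elif a == b:
            label = SiteLabel.INVARIANT if q == a else SiteLabel.RESIDUAL
        elif q == iupac.union(a, b):
            label = SiteLabel.ADDITIVE
        elif q == a:
            label = SiteLabel.PARENT_A
        elif q == b:
            label = SiteLabel.PARENT_B
        else:
            label = SiteLabel.RESIDUAL
        out.append(SiteClassification(i + 1, label, q, a, b))
    return out


def _single_gap_column(parent_short: str, parent_long: str) -> int | None:
    """1-based column of the unique 1-column gap in parent_short vs parent_long.

    Returns None unless parent_short has exactly one gap column, parent_long
    has a base there, and parent_long is gap-free.
    """
    if GAP in parent_long:
        return None
    gaps = [i + 1 for i, s in enumerate(parent_short) if s == GAP]
    if len(gaps) != 1:
        return None
    return gaps[0]


def shifted_superposition(
    query: str,
    parent_short: str,
    parent_long: str,
    tau_noise: float = 0.05,
) -> IndelSuperpositionResult | None:
    """Test the one-base-offset superposition downstream of a 1-column indel.

    In a direct trace of a hybrid whose parents differ by a single-base
    indel, both templates emit one base per trace position.  Downstream of
    the indel (gap column g in the shorter parent) the templates are out of
    register by one: at aligned column i >= g the longer parent contributes
    its own base while the shorter parent contributes the base aligned at
    column i+1.  Each testable query column must subsume that offset union.

    Returns None when the pair does not carry exactly one 1-column gap
    (caller falls back to plain column-wise classification).  Raises
    AlignmentGeometryError if the query has a gap at the indel column.
    """
    _check_same_length(query, parent_short, parent_long)
    g = _single_gap_column(parent_short, parent_long)
    if g is None:
        return None
    if query[g - 1] == GAP:
        raise AlignmentGeometryError(f"query has a gap at indel column {g}")
    length = len(query)
    n_testable = 0
    n_explained = 0
    for i in range(g, length):  # aligned columns g..L-1, 0-based index i = col-1 .. wait below
        # i is the 0-based index of aligned column i+1; we test columns g..L-1 (1-based),
        # pairing long[col] with short[col+1].
        col = i  # 1-based column being tested is `col` where col runs g..length-1
        long_sym = parent_long[col - 1]
        short_sym = parent_short[col]  # aligned column col+1 (0-based index col)
        q = query[col - 1]
        if long_sym == GAP or short_sym == GAP or q == GAP or q == "N":
            continue
        n_testable += 1
        if iupac.subsumes(q, iupac.union(long_sym, short_sym)):
            n_explained += 1
    consistent = n_testable > 0 and n_explained >= (1.0 - tau_noise) * n_testable
    return IndelSuperpositionResult(
        indel_position=g,
        shift_consistent=consistent,
        n_shift_explained=n_explained,
        n_testable=n_testable,
    )


def score_pair(
    query: str,
    parent_a: str,
    parent_b: str,
    name_a: str = "A",
    name_b: str = "B",
    species_a: str | None = None,
    species_b: str | None = None,
    tau_noise: float = 0.05,
) -> PairScore:
    """Count site classes of ``query`` against one candidate parent pair.

    If the parents differ by exactly one 1-column gap and the query has a
    base there, the shifted-superposition test is run and attached.  When
    the shift is consistent, columns downstream of the indel are judged
    against the one-base-offset superposition instead of the plain column
    union: a downstream column explained by the offset model counts as
    ADDITIVE where the aligned parents differ and INVARIANT where they
    agree, and as RESIDUAL only where the offset model fails too.  (In a
    real trace every downstream column is double-peaked; the aligned
    parental difference is still what distinguishes an additive site from
    mere register offset.)
    """
    sites = classify_sites(query, parent_a, parent_b)

    indel_shift = None
    short = long_ = None
    for cand_short, cand_long in ((parent_a, parent_b), (parent_b, parent_a)):
        g = _single_gap_column(cand_short, cand_long)
        if g is not None and query[g - 1] != GAP:
            indel_shift = shifted_superposition(query, cand_short, cand_long, tau_noise=tau_noise)
            short, long_ = cand_short, cand_long
            break

    if indel_shift is not None and indel_shift.shift_consistent:
        g = indel_shift.indel_position
        length = len(query)
        relabelled: list[SiteClassification] = []
        for s in sites:
            col = s.position
            if col < g or col >= length:  # upstream of the indel / final column
                relabelled.append(s)
                continue
            q, ls, ss = query[col - 1], long_[col - 1], short[col]
            if q == GAP or q == "N" or ls == GAP or ss == GAP:
                relabelled.append(SiteClassification(col, SiteLabel.GAPPED, q, s.parent_a, s.parent_b))
                continue
            # each parent's offset contribution at this trace position
            contrib_a = parent_a[col - 1] if parent_a is long_ else parent_a[col]
            contrib_b = parent_b[col - 1] if parent_b is long_ else parent_b[col]
            offset_union = iupac.base_set(ls) | iupac.base_set(ss)
            q_set = iupac.base_set(q)
            a, b = parent_a[col - 1], parent_b[col - 1]
            parents_differ = a != b and a != GAP and b != GAP
            if q_set == offset_union:
                label = SiteLabel.ADDITIVE if parents_differ else SiteLabel.INVARIANT
            elif q_set < offset_union:
                # register-offset dropout: only one template's peak was read
                label = SiteLabel.PARENT_A if q_set <= iupac.base_set(contrib_a) else SiteLabel.PARENT_B
            else:
                label = SiteLabel.RESIDUAL
            relabelled.append(SiteClassification(col, label, q, s.parent_a, s.parent_b))
        sites = relabelled

    counts = {label: 0 for label in SiteLabel}
    residual_positions: list[int] = []
    additive_positions: list[int] = []
    for s in sites:
        counts[s.label] += 1
        if s.label is SiteLabel.RESIDUAL:
            residual_positions.append(s.position)
        elif s.label is SiteLabel.ADDITIVE:
            additive_positions.append(s.position)

    return PairScore(
        parent_a=name_a,
        parent_b=name_b,
        species_a=species_a if species_a is not None else name_a,
        species_b=species_b if species_b is not None else name_b,
        n_additive=counts[SiteLabel.ADDITIVE],
        n_residual=counts[SiteLabel.RESIDUAL],
        n_parent_only=counts[SiteLabel.PARENT_A] + counts[SiteLabel.PARENT_B],
        n_invariant=counts[SiteLabel.INVARIANT],
        n_gapped=counts[SiteLabel.GAPPED],
        residual_positions=residual_positions,
        additive_positions=additive_positions,
        indel_shift=indel_shift,
    )


@dataclass
class RibotypePanel:
    """Named parental reference ribotypes: (species, ribotype_id, aligned seq).

    FASTA headers use "species_name|ribotype_id".
    """

    entries: list[tuple[str, str, str]]  # (species, ribotype_id, sequence)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("empty ribotype panel")
        names = [f"{sp}|{rid}" for sp, rid, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species|ribotype identifiers in panel")
        lengths = {len(seq) for _, _, seq in self.entries}
        if len(lengths) != 1:
            raise AlignmentGeometryError("panel ribotypes are not aligned to one length")

    @property
    def length(self) -> int:
        return len(self.entries[0][2])

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for sp, _, _ in self.entries:
            if sp not in seen:
                seen.append(sp)
        return seen

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RibotypePanel":
        mat = read_alignment(path)
        entries = []
        for name, row in mat.items():
            if "|" not in name:
                raise ValidationError(f"panel header {name!r} is not 'species|ribotype'")
            sp, rid = name.split("|", 1)
            entries.append((sp, rid, row))
        return cls(entries)


def hamming_distance(a: str, b: str) -> int:
    """Mismatch count over columns where both sequences carry a base (non-gap)."""
    _check_same_length(a, b)
    return sum(1 for x, y in zip(a, b) if x != y and x != GAP and y != GAP)


def _explained_residuals(
    query: str,
    parent_a: str,
    parent_b: str,
    third: str,
    residual_positions: list[int],
    shift_active: bool = False,
) -> int:
    """Residual columns where the query is exactly the three-way parental union.

    The third parent must contribute a base outside the pair union, so a
    candidate scores only where it is genuinely required.  When the pair
    differs by a single 1-column gap, the pair's contribution downstream of
    it is the one-base-offset superposition rather than the plain column
    union.
    """
    shift_g = None
    short = long_ = None
    if shift_active:
        for cand_short, cand_long in ((parent_a, parent_b), (parent_b, parent_a)):
            g = _single_gap_column(cand_short, cand_long)
            if g is not None:
                shift_g, short, long_ = g, cand_short, cand_long
                break

    n = 0
    length = len(query)
    for pos in residual_positions:
        i = pos - 1
        q, a, b, c = query[i], parent_a[i], parent_b[i], third[i]
        if GAP in (q, c) or q == "N":
            continue
        if shift_g is not None and shift_g <= pos < length:
            ls, ss = long_[i], short[i + 1]
            if GAP in (ls, ss):
                continue
            pair_union = iupac.base_set(ls) | iupac.base_set(ss)
        else:
            if GAP in (a, b):
                continue
            pair_union = iupac.base_set(a) | iupac.base_set(b)
        three_union = pair_union | iupac.base_set(c)
        if three_union == iupac.base_set(q) and not iupac.base_set(c) <= pair_union:
            n += 1
    return n


def infer_parentage(
    sample_id: str,
    query: str,
    panel: RibotypePanel,
    config: ParentageConfig | None = None,
) -> ParentageCall:
    """Call a sample as SPECIES / F1_HYBRID / COMPLEX_HYBRID / UNRESOLVED.

    Procedure: (i) nearest single ribotype by mismatch count — within
    ``tau_species`` means the sample is that species; (ii) otherwise every
    cross-species ribotype pair is scored and ranked by (n_residual
    ascending, n_additive descending, n_parent_only ascending, lexicographic
    species pair, lexicographic ribotype pair); the best pair with
    n_residual <= tau_residual gives an F1 call, more residuals escalate to
    COMPLEX_HYBRID with ranked third-parent candidates.  Deterministic.
    """
    cfg = config or ParentageConfig()
    if len(query) != panel.length:
        raise AlignmentGeometryError(
            f"query length {len(query)} != panel alignment length {panel.length}"
        )

    # (i) species check against each single ribotype
    distances = [
        (hamming_distance(query, seq), f"{sp}|{rid}") for sp, rid, seq in panel
    ]
    best_dist, best_name = min(distances, key=lambda t: (t[0], t[1]))
    if best_dist <= cfg.tau_species:
        return ParentageCall(
            sample_id=sample_id,
            verdict=Verdict.SPECIES,
            species_match=(best_name, best_dist),
        )

    # (ii) all unordered cross-species ribotype pairs
    scored: list[PairScore] = []
    for (sp1, r1, s1), (sp2, r2, s2) in itertools.combinations(panel, 2):
        if sp1 == sp2:
            continue
        (sa, na, qa), (sb, nb, qb) = sorted(
            [(sp1, f"{sp1}|{r1}", s1), (sp2, f"{sp2}|{r2}", s2)], key=lambda t: t[1]
        )
        scored.append(
            score_pair(
                query, qa, qb,
                name_a=na, name_b=nb, species_a=sa, species_b=sb,
                tau_noise=cfg.tau_noise,
            )
        )
    if not scored:
        return ParentageCall(sample_id=sample_id, verdict=Verdict.UNRESOLVED,
                             species_match=(best_name, best_dist))

    scored.sort(
        key=lambda p: (
            p.n_residual,
            -p.n_additive,
            p.n_parent_only,
            p.species_pair,
            (p.parent_a, p.parent_b),
        )
    )
    best = scored[0]
    if best.n_additive < 1:
        return ParentageCall(sample_id=sample_id, verdict=Verdict.UNRESOLVED,
                             species_match=(best_name, best_dist))
    if best.n_residual <= cfg.tau_residual:
        return ParentageCall(
            sample_id=sample_id,
            verdict=Verdict.F1_HYBRID,
            best_pair=best,
            species_match=(best_name, best_dist),
            residual_positions=best.residual_positions,
        )

    # complex hybrid: rank third-parent candidates over the residual columns
    seq_a = next(s for sp, r, s in panel if f"{sp}|{r}" == best.parent_a)
    seq_b = next(s for sp, r, s in panel if f"{sp}|{r}" == best.parent_b)
    candidates: list[tuple[str, int]] = []
    for sp, rid, seq in panel:
        if sp in (best.species_a, best.species_b):
            continue
        n_exp = _explained_residuals(
            query, seq_a, seq_b, seq, best.residual_positions,
            shift_active=best.indel_shift is not None and best.indel_shift.shift_consistent,
        )
        candidates.append((f"{sp}|{rid}", n_exp))
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return ParentageCall(
        sample_id=sample_id,
        verdict=Verdict.COMPLEX_HYBRID,
        best_pair=best,
        species_match=(best_name, best_dist),
        residual_positions=best.residual_positions,
        third_parent_candidates=candidates,
    )


def constant_additive_positions(
    rows: list[str], parent_a: str, parent_b: str
) -> list[int]:
    """Columns classified ADDITIVE in *every* query of a hybrid group.

    Distinguishes the constant additive core shared by all individuals of a
    hybrid group from additive sites private to some samples.
    """
    if not rows:
        raise ValidationError("constant_additive_positions requires at least one query row")
    shared: set[int] | None = None
    for row in rows:
        additive = {
            s.position
            for s in classify_sites(row, parent_a, parent_b)
            if s.label is SiteLabel.ADDITIVE
        }
        shared = additive if shared is None else shared & additive
    return sorted(shared)


def calls_to_frame(calls: list[ParentageCall]) -> pd.DataFrame:
    """Flatten ParentageCalls to the tabular output schema."""
    rows = []
    for c in calls:
        bp = c.best_pair
        rows.append(
            {
                "sample_id": c.sample_id,
                "verdict": c.verdict.value,
                "parent_a": bp.parent_a if bp else "",
                "parent_b": bp.parent_b if bp else "",
                "species_a": bp.species_a if bp else "",
                "species_b": bp.species_b if bp else "",
                "n_additive": bp.n_additive if bp else 0,
                "n_residual": bp.n_residual if bp else 0,
                "species_match": c.species_match[0] if c.species_match else "",
                "species_match_distance": c.species_match[1] if c.species_match else "",
                "residual_positions": ",".join(map(str, c.residual_positions)),
                "third_parent_candidates": ";".join(
                    f"{name}:{n}" for name, n in c.third_parent_candidates
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "verdict", "parent_a", "parent_b", "species_a", "species_b",
            "n_additive", "n_residual", "species_match", "species_match_distance",
            "residual_positions", "third_parent_candidates",
        ],
    )
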