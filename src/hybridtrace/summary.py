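"""Regional hybridization-frequency statistics.

Aggregates per-sample verdicts into per-locality tallies and per-region
summaries: what fraction of individuals are hybrids, what fraction of the
studied river sites harbour hybrids, and in how many sites hybrids occur
without either parental species.  Percentages are reported as half-up
rounded integers (raw ratios are kept alongside); the locality denominator
is the number of river sites *studied* in the region, not only the sites
that yielded classifiable sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import UndefinedStatisticError, ValidationError

HYBRID_VERDICTS = ("F1_HYBRID", "COMPLEX_HYBRID")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (0.5 -> 1)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LocalityTally:
    region: str
    locality: str
    n_species_individuals: int
    n_hybrid_individuals: int

    def __post_init__(self) -> None:
        if self.n_species_individuals < 0 or self.n_hybrid_individuals < 0:
            raise ValidationError("negative individual count")
        if self.n_species_individuals == 0 and self.n_hybrid_individuals == 0:
            raise ValidationError(f"empty tally for {self.region}/{self.locality}")


@dataclass(frozen=True)
class RegionSummary:
    region: str
    n_individuals: int
    n_hybrid_individuals: int
    n_localities: int                # distinct localities with classified individuals
    n_localities_studied: int        # denominator for locality percentages
    n_localities_with_hybrids: int
    n_localities_hybrid_only: int
    n_localities_cooccur: int
    frac_hybrid_individuals: float
    frac_localities_with_hybrids: float
    frac_localities_hybrid_only: float
    pct_hybrid_individuals: int
    pct_localities_with_hybrids: int
    pct_localities_hybrid_only: int


def tally(classified: pd.DataFrame) -> tuple[list[LocalityTally], int]:
    """Aggregate classified samples into per-(region, locality) tallies.

    ``classified`` needs columns region, locality, verdict.  SPECIES counts
    toward species individuals, F1_HYBRID/COMPLEX_HYBRID toward hybrids;
    UNRESOLVED samples are excluded and their count returned separately.
    """
    for col in ("region", "locality", "verdict"):
        if col not in classified.columns:
            raise ValidationError(f"classified table lacks column {col!r}")
    if classified.empty:
        return [], 0
    if (classified["verdict"].astype(str).str.strip() == "").any():
        raise ValidationError("record without verdict")
    n_unresolved = int((classified["verdict"] == "UNRESOLVED").sum())
    usable = classified[classified["verdict"] != "UNRESOLVED"]
    tallies: list[LocalityTally] = []
    for (region, locality), grp in usable.groupby(["region", "locality"], sort=True):
        n_hyb = int(grp["verdict"].isin(HYBRID_VERDICTS).sum())
        n_sp = int((grp["verdict"] == "SPECIES").sum())
        tallies.append(LocalityTally(region, locality, n_sp, n_hyb))
    return tallies, n_unresolved


def summarize_region(
    tallies: list[LocalityTally], region: str, total_localities_studied: int
) -> RegionSummary:
    """Regional hybrid-frequency arithmetic.

    Individual percentages use all classified individuals of the region as
    denominator; locality percentages use ``total_localities_studied``.
    """
    regional = [t for t in tallies if t.region == region]
    n_localities = len({t.locality for t in regional})
    if total_localities_studied < n_localities:
        raise ValidationError(
            f"total_localities_studied={total_localities_studied} < "
            f"{n_localities} tallied localities"
        )
    n_ind = sum(t.n_species_individuals + t.n_hybrid_individuals for t in regional)
    if n_ind == 0:
        raise UndefinedStatisticError(f"no classified individuals in region {region!r}")
    n_hyb = sum(t.n_hybrid_individuals for t in regional)
    with_hyb = [t for t in regional if t.n_hybrid_individuals > 0]
    hybrid_only = [t for t in with_hyb if t.n_species_individuals == 0]
    cooccur = [t for t in with_hyb if t.n_species_individuals > 0]

    frac_ind = n_hyb / n_ind
    frac_with = len(with_hyb) / total_localities_studied
    frac_only = len(hybrid_only) / total_localities_studied
    return RegionSummary(
        region=region,
        n_individuals=n_ind,
        n_hybrid_individuals=n_hyb,
        n_localities=n_localities,
        n_localities_studied=total_localities_studied,
        n_localities_with_hybrids=len(with_hyb),
        n_localities_hybrid_only=len(hybrid_only),
        n_localities_cooccur=len(cooccur),
        frac_hybrid_individuals=frac_ind,
        frac_localities_with_hybrids=frac_with,
        frac_localities_hybrid_only=frac_only,
        pct_hybrid_individuals=round_half_up(100 * frac_ind),
        pct_localities_with_hybrids=round_half_up(100 * frac_with),
        pct_localities_hybrid_only=round_half_up(100 * frac_only),
    )


def load_survey_fixture() -> tuple[list[LocalityTally], dict[str, int]]:
    """Packaged synthetic reconstruction of the two-region river survey.

    Per-locality counts are an even split consistent with the published
    aggregate counts (individuals, localities with species/hybrids,
    co-occurrence sites, and total sites studied per region); they are not
    a transcript of the original locality table.
    """
    data = resources.files("hybridtrace.data")
    with resources.as_file(data.joinpath("survey_counts.tsv")) as p:
        counts = pd.read_csv(p, sep="\t")
    with resources.as_file(data.joinpath("survey_regions.tsv")) as p:
        regions = pd.read_csv(p, sep="\t")
    tallies = [
        LocalityTally(
            r["region"], r["locality"],
            int(r["n_species_individuals"]), int(r["n_hybrid_individuals"]),
        )
        for _, r in counts.iterrows()
    ]
    totals = dict(zip(regions["region"], regions["total_localities_studied"].astype(int)))
    return tallies, totals


def summaries_to_frame(summaries: list[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": s.region,
                "n_individuals": s.n_individuals,
                "n_hybrid_individuals": s.n_hybrid_individuals,
                "n_localities_studied": s.n_localities_studied,
                "n_localities_with_hybrids": s.n_localities_with_hybrids,
                "n_localities_hybrid_only": s.n_localities_hybrid_only,
                "n_localities_cooccur": s.n_localities_cooccur,
                "pct_hybrid_individuals": s.pct_hybrid_individuals,
                "pct_localities_with_hybrids": s.pct_localities_with_hybrids,
                "pct_localities_hybrid_only": s.pct_localities_hybrid_only,
            }
            for s in summaries
        ]
    )


def report_text(summaries: list[RegionSummary]) -> str:
    """Human-readable regional report."""
    lines = []
    for s in summaries:
        lines.append(
            f"{s.region}: {s.n_individuals} classified individuals, "
            f"{s.n_hybrid_individuals} hybrids ({s.pct_hybrid_individuals}%); "
            f"hybrids in {s.n_localities_with_hybrids}/{s.n_localities_studied} "
            f"studied localities ({s.pct_localities_with_hybrids}%), "
            f"only hybrids in {s.n_localities_hybrid_only} "
            f"({s.pct_localities_hybrid_only}%), "
            f"co-occurring with species in {s.n_localities_cooccur}."
        )
    return "\n".join(lines)
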