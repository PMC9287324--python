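"""Synthetic panels, hybrids and plastid haplotypes for end-to-end testing.

The generator reproduces the statistical structure the analysis assumes:

* a panel of 2-6 parental species ribotypes descended from one ancestral
  ITS sequence with a stated pairwise per-column divergence, plus optional
  within-species ribotype variants a substitution or two away;
* optionally a single-base indel distinguishing one species from the rest
  (one parent carries an extra base at a fixed column, emulating a
  diagnostic 1-bp insertion near the 5' end of ITS);
* F1 hybrids whose ITS consensus is the column-wise IUPAC union of the two
  parental ribotypes — with the one-base-offset superposition applied
  downstream when the parents differ by the 1-bp indel;
* three-way hybrids that add a third parent's base at a fixed number of
  extra columns;
* ambiguity-dropout noise: each additive column independently collapses to
  a single parental base with a stated probability, emulating uneven peak
  heights in real traces;
* maternally inherited plastid haplotypes, one distinct haplotype per
  species and two markers per sample; under the FIXED_NON_FOCAL rule the
  focal species is always the pollen (paternal) donor, so every hybrid
  carries the other parent's plastid.

All randomness flows from a single integer seed through numpy's
``default_rng`` (PCG64); identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import iupac
from .additivity import RibotypePanel
from .errors import ValidationError
from .iupac import GAP
from .plastid import HaplotypeRefSet
from .seq_io import AlignedMatrix, SampleRecord, write_alignment, write_samples

SPECIES_NAMES = ("circinatus", "fluitans", "kauffmannii", "aquatilis", "trichophyllus", "peltatus")
HAPLOTYPE_LABELS = ("I", "A", "C", "D", "E", "G")
BASES = ("A", "C", "G", "T")

MATERNAL_RULES = ("RANDOM", "FIXED_NON_FOCAL")


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the survey setting: ITS amplicons ~650 columns with
    roughly 3% between-species column divergence (about 20 differing
    columns per pair, the scale of the published additive-site counts),
    within-species variants 1-2 substitutions apart, six extra additive
    columns for three-way hybrids, and a unidirectional crossing rule with
    *circinatus* as pollen donor.
    """

    seed: int
    n_species: int = 4
    ribotypes_per_species: int = 1
    seq_length: int = 650
    pairwise_divergence: float = 0.03
    within_species_divergence: float = 0.003
    indel_between: tuple[str, str] | None = None  # (carrier species, partner species)
    indel_position: int = 30
    n_f1: int = 0
    n_threeway: int = 0
    extra_additive_sites: int = 6
    dropout_noise: float = 0.0
    plastid_length: int = 300
    plastid_divergence: float = 0.02
    maternal_rule: str = "FIXED_NON_FOCAL"
    focal_species: str = "circinatus"
    region: str = "SimRegion"

    def __post_init__(self) -> None:
        if not (2 <= self.n_species <= 6):
            raise ValidationError("n_species must be in 2..6")
        for name, p in (
            ("pairwise_divergence", self.pairwise_divergence),
            ("within_species_divergence", self.within_species_divergence),
            ("dropout_noise", self.dropout_noise),
            ("plastid_divergence", self.plastid_divergence),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {p}")
        if self.n_f1 < 0 or self.n_threeway < 0 or self.ribotypes_per_species < 1:
            raise ValidationError("counts must be non-negative")
        if self.maternal_rule not in MATERNAL_RULES:
            raise ValidationError(f"maternal_rule must be one of {MATERNAL_RULES}")
        if self.n_threeway > 0 and self.n_species < 3:
            raise ValidationError("three-way hybrids need at least 3 species")

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES_NAMES[: self.n_species]


def _per_lineage_rate(pairwise: float) -> float:
    """Per-lineage substitution probability q giving the requested pairwise
    column divergence p between two lineages mutated independently from a
    common ancestor: p = 2q(1-q) + (2/3)q^2 (uniform choice among the three
    alternative bases, so two changed lineages still agree w.p. 1/3)."""
    if pairwise == 0.0:
        return 0.0
    # solve (4/3)q^2 - 2q + p = 0 for the small root
    return (1.0 - math.sqrt(1.0 - (4.0 / 3.0) * pairwise)) / (4.0 / 3.0)


def _mutate(seq: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    if rate <= 0.0:
        return out
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if out[i] == GAP:
            continue
        alternatives = [b for b in BASES if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return out


def _random_seq(length: int, rng: np.random.Generator) -> list[str]:
    return [BASES[k] for k in rng.integers(0, 4, size=length)]


@dataclass
class PanelTruth:
    """Ground truth recorded by generate_panel."""

    species: tuple[str, ...]
    ribotype_names: list[str]
    haplotype_by_species: dict[str, str]
    indel_column: int | None


def generate_panel(
    config: SimConfig,
) -> tuple[RibotypePanel, dict[str, HaplotypeRefSet], PanelTruth]:
    """Generate the reference panel: species ribotypes, ribotype variants,
    and one distinct plastid haplotype per species for each of two markers."""
    rng = np.random.default_rng(config.seed)
    species = config.species
    q = _per_lineage_rate(config.pairwise_divergence)

    ancestor = _random_seq(config.seq_length, rng)
    base_ribotypes: dict[str, list[str]] = {sp: _mutate(ancestor, q, rng) for sp in species}

    if config.indel_between is not None:
        carrier, partner = config.indel_between
        for sp in (carrier, partner):
            if sp not in species:
                raise ValidationError(f"indel_between names unknown species {sp!r}")
        col = config.indel_position - 1
        if not 0 <= col < config.seq_length:
            raise ValidationError("indel_position outside the alignment")
        # carrier keeps a base at the indel column; everyone else gets a gap
        for sp in species:
            if sp != carrier:
                base_ribotypes[sp][col] = GAP

    entries: list[tuple[str, str, str]] = []
    for sp in species:
        entries.append((sp, "r1", "".join(base_ribotypes[sp])))
        for k in range(2, config.ribotypes_per_species + 1):
            variant = _mutate(base_ribotypes[sp], config.within_species_divergence, rng)
            entries.append((sp, f"r{k}", "".join(variant)))
    panel = RibotypePanel(entries)

    refsets: dict[str, HaplotypeRefSet] = {}
    haplotype_by_species = {sp: HAPLOTYPE_LABELS[i] for i, sp in enumerate(species)}
    for marker in ("rpl32-trnL", "petL-psbE"):
        qh = _per_lineage_rate(config.plastid_divergence)
        haps = {}
        for _ in range(50):
            anc = _random_seq(config.plastid_length, rng)
            haps = {
                haplotype_by_species[sp]: "".join(_mutate(anc, qh, rng)) for sp in species
            }
            if len(set(haps.values())) == len(haps):  # haplotypes must be distinct
                break
        else:
            # degenerate divergence: force one diagnostic column per species
            anc = _random_seq(config.plastid_length, rng)
            haps = {}
            for i, sp in enumerate(species):
                j = i % config.plastid_length
                row = list(anc)
                row[j] = BASES[(BASES.index(row[j]) + 1) % 4]
                if i > 0:  # also make it differ from the other forced variants
                    row[(j + 1) % config.plastid_length] = BASES[i % 4]
                haps[haplotype_by_species[sp]] = "".join(row)
        refsets[marker] = HaplotypeRefSet(
            marker=marker,
            refs=dict(sorted(haps.items())),
            species_map={sp: {haplotype_by_species[sp]} for sp in species},
        )

    truth = PanelTruth(
        species=species,
        ribotype_names=[f"{sp}|{rid}" for sp, rid, _ in panel],
        haplotype_by_species=haplotype_by_species,
        indel_column=config.indel_position if config.indel_between else None,
    )
    return panel, refsets, truth


def _f1_consensus(pa: str, pb: str) -> list[str]:
    """Column-wise union consensus, with the one-base-offset superposition
    applied downstream when the pair differs by exactly one 1-column gap."""
    length = len(pa)
    gap_cols_a = [i for i in range(length) if pa[i] == GAP and pb[i] != GAP]
    gap_cols_b = [i for i in range(length) if pb[i] == GAP and pa[i] != GAP]
    short = long_ = None
    if len(gap_cols_a) == 1 and not gap_cols_b:
        short, long_, g = pa, pb, gap_cols_a[0]
    elif len(gap_cols_b) == 1 and not gap_cols_a:
        short, long_, g = pb, pa, gap_cols_b[0]

    out: list[str] = []
    for i in range(length):
        a, b = pa[i], pb[i]
        if a == GAP and b == GAP:
            out.append(GAP)
        elif a == GAP:
            out.append(b)
        elif b == GAP:
            out.append(a)
        else:
            out.append(iupac.union(a, b))
    if short is not None:
        # downstream of the indel the reads overlap out of register:
        # column i shows long[i] superposed with the short parent's base at i+1
        for col in range(g, length - 1):  # 0-based col g..L-2 => 1-based g+1..L-1
            ls, ss = long_[col], short[col + 1]
            if ls != GAP and ss != GAP:
                out[col] = iupac.union(ls, ss)
        out[length - 1] = long_[length - 1]
    return out


def _apply_dropout(
    consensus: list[str], pa: str, pb: str, noise: float, rng: np.random.Generator
) -> tuple[list[str], list[int]]:
    """Collapse each additive column to one parent's base w.p. ``noise``."""
    out = list(consensus)
    noised: list[int] = []
    if noise <= 0.0:
        return out, noised
    for i, sym in enumerate(out):
        if sym == GAP or not iupac.is_ambiguous(sym):
            continue
        if rng.random() < noise:
            choices = [p[i] for p in (pa, pb) if p[i] != GAP and p[i] in iupac.base_set(sym)]
            if not choices:
                choices = sorted(iupac.base_set(sym))
            out[i] = choices[rng.integers(0, len(choices))]
            noised.append(i + 1)
    return out, noised


def generate_hybrids(
    panel: RibotypePanel,
    refsets: dict[str, HaplotypeRefSet],
    truth: PanelTruth,
    config: SimConfig,
) -> tuple[AlignedMatrix, dict[str, AlignedMatrix], list[SampleRecord], pd.DataFrame]:
    """Generate hybrid samples: ITS consensus rows, per-marker plastid rows,
    metadata, and a truth table (sample_id, kind, parents, maternal parent,
    noised columns)."""
    rng = np.random.default_rng(config.seed + 1)
    species = list(truth.species)
    if config.n_f1 > 0 and len(species) < 2:
        raise ValidationError("F1 hybrids need at least 2 species")
    first_ribotype = {sp: seq for sp, rid, seq in panel if rid == "r1"}

    names: list[str] = []
    its_rows: list[str] = []
    plastid_rows: dict[str, list[str]] = {m: [] for m in refsets}
    records: list[SampleRecord] = []
    truth_rows: list[dict] = []

    def _choose_pair() -> tuple[str, str]:
        others = [sp for sp in species if sp != config.focal_species]
        if config.maternal_rule == "FIXED_NON_FOCAL":
            if config.focal_species not in species:
                raise ValidationError("focal_species absent from the panel")
            other = others[rng.integers(0, len(others))]
            return other, config.focal_species  # (maternal, paternal)
        a, b = rng.choice(len(species), size=2, replace=False)
        return species[a], species[b]

    def _emit(kind: str, idx: int, maternal: str, paternal: str, third: str | None) -> None:
        pa, pb = first_ribotype[maternal], first_ribotype[paternal]
        consensus = _f1_consensus(pa, pb)
        extra_cols: list[int] = []
        if third is not None:
            pc = first_ribotype[third]
            eligible = [
                i for i in range(len(pc))
                if pc[i] != GAP and consensus[i] != GAP
                and iupac.base_set(pc[i]) - iupac.base_set(consensus[i])
            ]
            k = min(config.extra_additive_sites, len(eligible))
            chosen = sorted(rng.choice(eligible, size=k, replace=False)) if k else []
            for i in chosen:
                consensus[i] = iupac.union(consensus[i], pc[i])
                extra_cols.append(i + 1)
        consensus, noised = _apply_dropout(consensus, pa, pb, config.dropout_noise, rng)

        sid = f"{kind}{idx:03d}"
        names.append(sid)
        its_rows.append("".join(consensus))
        for marker, refset in refsets.items():
            label = truth.haplotype_by_species[maternal]
            plastid_rows[marker].append(refset.refs[label])
        records.append(
            SampleRecord(sample_id=sid, region=config.region, locality=f"river_{idx:02d}")
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "kind": kind,
                "parent_a": min(maternal, paternal),
                "parent_b": max(maternal, paternal),
                "parent_c": third or "",
                "maternal": maternal,
                "paternal": paternal,
                "extra_additive_columns": ",".join(map(str, extra_cols)),
                "noised_columns": ",".join(map(str, noised)),
            }
        )

    for idx in range(1, config.n_f1 + 1):
        maternal, paternal = _choose_pair()
        _emit("F1_", idx, maternal, paternal, None)
    for idx in range(1, config.n_threeway + 1):
        maternal, paternal = _choose_pair()
        pool = [sp for sp in species if sp not in (maternal, paternal)]
        third = pool[rng.integers(0, len(pool))]
        _emit("TW_", idx, maternal, paternal, third)

    if not names:
        raise ValidationError("config generates no hybrid samples (n_f1 + n_threeway == 0)")
    its = AlignedMatrix(names=list(names), rows=its_rows, marker="ITS")
    plastid = {
        m: AlignedMatrix(names=list(names), rows=rows, marker=m)
        for m, rows in plastid_rows.items()
    }
    truth_df = pd.DataFrame(truth_rows)
    return its, plastid, records, truth_df


def write_simulation(
    out_dir: str | Path,
    panel: RibotypePanel,
    refsets: dict[str, HaplotypeRefSet],
    truth: PanelTruth,
    its: AlignedMatrix,
    plastid: dict[str, AlignedMatrix],
    records: list[SampleRecord],
    truth_df: pd.DataFrame,
) -> dict[str, Path]:
    """Write the simulated bundle as FASTA/TSV files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    panel_mat = AlignedMatrix(
        names=[f"{sp}|{rid}" for sp, rid, _ in panel],
        rows=[seq for _, _, seq in panel],
    )
    paths["panel"] = out / "panel.fasta"
    write_alignment(panel_mat, paths["panel"])

    paths["its"] = out / "its.fasta"
    write_alignment(its, paths["its"])

    marker_files = {"rpl32-trnL": "rpl32.fasta", "petL-psbE": "petl.fasta"}
    smap_rows = []
    for marker, refset in refsets.items():
        ref_mat = AlignedMatrix(
            names=[f"{marker}|{label}" for label in refset.refs],
            rows=list(refset.refs.values()),
        )
        paths[f"refs_{marker}"] = out / f"refs_{marker_files[marker]}"
        write_alignment(ref_mat, paths[f"refs_{marker}"])
        paths[marker] = out / marker_files[marker]
        write_alignment(plastid[marker], paths[marker])
        for sp, labels in sorted(refset.species_map.items()):
            for label in sorted(labels):
                smap_rows.append({"marker": marker, "haplotype_label": label, "species": sp})

    paths["species_map"] = out / "species_map.tsv"
    pd.DataFrame(smap_rows).to_csv(paths["species_map"], sep="\t", index=False)

    paths["samples"] = out / "samples.tsv"
    write_samples(records, paths["samples"])
    paths["truth"] = out / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
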