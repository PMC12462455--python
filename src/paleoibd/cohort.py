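"""Synthetic cohorts with group-structured IBD sharing.

Generates the three standard inputs — individual metadata, an IBD segment
table, and a pseudo-haploid genotype matrix — with the statistical
structure the analyses assume: per-pair retained-segment counts are
Poisson with a group-pair intensity, segment lengths follow a shifted
exponential above the retention floor, and optional planted relative
pairs get their segments from the pedigree simulator instead, with
matching elevated genotype sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from paleoibd.kinship import MISSING
from paleoibd.pedsim import (
    EXPECTED_IBD_FRACTION,
    EXPECTED_PMR_COEFFICIENT,
    GeneticMap,
    simulate_pair_ibd,
)
from paleoibd.segments import (
    IBDSegment,
    Individual,
    filter_segments,
    merge_adjacent_states,
    write_metadata,
    write_segments,
)

PRESETS = ("coexistence", "replacement", "continuity")


@dataclass(frozen=True)
class GroupSpec:
    label: str
    region: str
    size: int
    lat: float
    lon: float


@dataclass
class CohortScenario:
    """Generator parameters for one synthetic cohort.

    ``lam`` maps unordered group-label pairs to the expected number of
    retained segments per individual pair; lengths are
    ``min_len_cM + Exponential(mean_excess_cM)``.
    """

    groups: list[GroupSpec]
    lam: dict[tuple[str, str], float]
    min_len_cM: float = 12.0
    mean_excess_cM: float = 8.0
    snp_density_per_cM: float = 300.0
    allele_freq_beta: tuple[float, float] = (1.0, 1.0)
    n_sites: int = 2_000
    missing_rate: float = 0.0
    relatedness_plants: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if any(g.size < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        if self.mean_excess_cM <= 0:
            raise ValueError("mean_excess_cM must be > 0")
        known = set(labels)
        normalized = {}
        for (a, b), rate in self.lam.items():
            if a not in known or b not in known:
                raise ValueError(f"lambda references unknown group pair ({a}, {b})")
            if rate < 0:
                raise ValueError("lambda entries must be >= 0")
            normalized[tuple(sorted((a, b)))] = float(rate)
        self.lam = normalized

    def rate(self, group_a: str, group_b: str) -> float:
        return self.lam.get(tuple(sorted((group_a, group_b))), 0.0)


@dataclass
class Cohort:
    individuals: list[Individual]
    segments: list[IBDSegment]
    genotypes: np.ndarray
    ids: list[str]

    def write(self, out_dir: str | Path) -> None:
        """Write meta.tsv, segments.tsv, and genotypes.tsv (0/1/9-coded)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metadata(self.individuals, out / "meta.tsv")
        write_segments(self.segments, out / "segments.tsv")
        with open(out / "genotypes.tsv", "w") as fh:
            fh.write("iid\t" + "\t".join(f"site{j}" for j in range(self.genotypes.shape[1])) + "\n")
            for iid, row in zip(self.ids, self.genotypes):
                fh.write(iid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _draw_segment(
    rng: np.random.Generator,
    scenario: CohortScenario,
    gmap: GeneticMap,
    id_a: str,
    id_b: str,
) -> IBDSegment:
    max_len = float(gmap.lengths.max())
    while True:
        length = scenario.min_len_cM + rng.exponential(scenario.mean_excess_cM)
        if length < max_len:
            break
    eligible = gmap.lengths >= length
    weights = np.where(eligible, gmap.lengths, 0.0)
    chrom = int(rng.choice(gmap.n_chrom, p=weights / weights.sum()))
    start = float(rng.uniform(0.0, gmap.lengths[chrom] - length))
    return IBDSegment(
        id_a=id_a,
        id_b=id_b,
        chrom=chrom + 1,
        start_cM=start,
        end_cM=start + length,
        length_cM=length,
        n_snps=int(round(length * scenario.snp_density_per_cM)),
        state="IBD1",
    )


def generate_cohort(scenario: CohortScenario, gmap: GeneticMap | None = None) -> Cohort:
    """Generate metadata, segments, and pseudo-haploid genotypes, fully seeded.

    Per-pair segment counts are Poisson with the group-pair intensity;
    chromosome assignment is proportional to map length and positions are
    uniform. Planted relative pairs instead receive merged and filtered
    pedigree-simulated segments, and copy each other's genotype over the
    expected IBD fraction of sites.
    """
    gmap = gmap or GeneticMap.default()
    rng = np.random.default_rng(scenario.seed)
    individuals: list[Individual] = []
    for group in scenario.groups:
        for k in range(1, group.size + 1):
            individuals.append(
                Individual(
                    id=f"{group.label}{k:03d}",
                    mortuary_group=group.label,
                    region=group.region,
                    lat=group.lat,
                    lon=group.lon,
                    sex="F" if rng.random() < 0.5 else "M",
                )
            )
    ids = [p.id for p in individuals]
    group_of = {p.id: p.mortuary_group for p in individuals}
    planted = {tuple(sorted(pair)): rel for pair, rel in scenario.relatedness_plants}
    for pair, rel in planted.items():
        for iid in pair:
            if iid not in group_of:
                raise ValueError(f"planted pair references unknown individual {iid!r}")
        if rel not in EXPECTED_IBD_FRACTION:
            raise ValueError(f"unknown planted relationship {rel!r}")

    segments: list[IBDSegment] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            key = tuple(sorted((a, b)))
            if key in planted:
                raw = simulate_pair_ibd(planted[key], gmap, rng=rng, id_a=a, id_b=b)
                raw = [
                    IBDSegment(
                        id_a=s.id_a,
                        id_b=s.id_b,
                        chrom=s.chrom,
                        start_cM=s.start_cM,
                        end_cM=s.end_cM,
                        length_cM=s.length_cM,
                        n_snps=int(round(s.length_cM * scenario.snp_density_per_cM)),
                        state=s.state,
                    )
                    for s in raw
                ]
                segments.extend(
                    filter_segments(
                        merge_adjacent_states(raw), min_len_cM=scenario.min_len_cM
                    )
                )
                continue
            rate = scenario.rate(group_of[a], group_of[b])
            if rate <= 0:
                continue
            for _ in range(rng.poisson(rate)):
                segments.append(_draw_segment(rng, scenario, gmap, a, b))

    freqs = rng.beta(*scenario.allele_freq_beta, size=scenario.n_sites)
    genotypes = (rng.random((len(ids), scenario.n_sites)) < freqs).astype(np.int8)
    index = {iid: k for k, iid in enumerate(ids)}
    for (a, b), rel in planted.items():
        # pseudo-haploid calls match because of the relationship only when
        # both individuals happen to sample the shared haplotype, so the
        # copy fraction is the expected pmr coefficient, not the IBD fraction
        share = rng.random(scenario.n_sites) < EXPECTED_PMR_COEFFICIENT[rel]
        genotypes[index[b], share] = genotypes[index[a], share]
    if scenario.missing_rate > 0:
        miss = rng.random(genotypes.shape) < scenario.missing_rate
        genotypes[miss] = MISSING

    segments.sort(key=lambda s: (s.id_a, s.id_b, s.chrom, s.start_cM))
    return Cohort(individuals=individuals, segments=segments, genotypes=genotypes, ids=ids)


def preset(name: str, seed: int = 0) -> CohortScenario:
    """Named scenarios exercising the three hypotheses the tests target.

    ``coexistence``: two sympatric groups with within-group sharing four
    times the between-group level (the label-shuffle test should reject).
    ``replacement``: four groups whose successor-tradition sharing is
    independent of the focal region (the continuity test should not
    reject). ``continuity``: focal-region successive-group sharing raised
    threefold (the continuity test should reject).
    """
    if name == "coexistence":
        groups = [
            GroupSpec("A", "central", 11, 47.0, 102.0),
            GroupSpec("B", "central", 15, 47.2, 102.3),
        ]
        lam = {("A", "A"): 1.6, ("B", "B"): 1.6, ("A", "B"): 0.4}
        return CohortScenario(groups=groups, lam=lam, seed=seed)
    if name in ("replacement", "continuity"):
        groups = [
            GroupSpec("Fc", "central", 3, 47.0, 102.0),
            GroupSpec("Fe", "eastern", 8, 46.5, 111.0),
            GroupSpec("Sc", "central", 6, 47.1, 102.2),
            GroupSpec("So", "eastern", 9, 48.5, 110.0),
        ]
        base = 0.5
        lam = {
            ("Fc", "Fc"): 1.0,
            ("Fe", "Fe"): 1.0,
            ("Fc", "Fe"): 1.0,
            ("Sc", "Sc"): 1.0,
            ("So", "So"): 1.0,
            ("Sc", "So"): 1.0,
            ("Fc", "Sc"): 3.0 * base if name == "continuity" else base,
            ("Fc", "So"): base,
            ("Fe", "Sc"): base,
            ("Fe", "So"): base,
        }
        return CohortScenario(groups=groups, lam=lam, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


def figure_slab_layout(
    scenario: CohortScenario,
) -> tuple[list[str], list[str], list[int], list[int]]:
    """Row/column layout for the continuity and contribution tests.

    Returns (figure ids, slab ids, focal row indices, focal column
    indices) for a four-group Fc/Fe/Sc/So scenario.
    """
    by_label: Mapping[str, list[str]] = {}
    out: dict[str, list[str]] = {}
    for g in scenario.groups:
        out[g.label] = [f"{g.label}{k:03d}" for k in range(1, g.size + 1)]
    by_label = out
    for needed in ("Fc", "Fe", "Sc", "So"):
        if needed not in by_label:
            raise ValueError(f"scenario lacks group {needed!r}")
    fig_ids = by_label["Fc"] + by_label["Fe"]
    slab_ids = by_label["Sc"] + by_label["So"]
    fc_rows = list(range(len(by_label["Fc"])))
    sc_cols = list(range(len(by_label["Sc"])))
    return fig_ids, slab_ids, fc_rows, sc_cols
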