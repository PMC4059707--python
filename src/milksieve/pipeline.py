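"""The screening cascade: from cleaned tags to a plant-miRNA profile.

Stage order (fixed; each stage only removes tags):

1. plant-match      — keep tags with a gap-free, mismatch-free containment
                      match (|Δlen| <= 1) to a mature plant miRNA
2. host-ncrna       — drop tags with a significant local hit (E <= 0.01)
                      against host tRNA/rRNA/snoRNA/snRNA/miRNA sequences
3. host-mrna-repeat — likewise against host mRNA / repeat-associated RNA
4. genome-map       — drop tags mapping end-to-end to the host genome with
                      <= 1 mismatch
5. genome-editing   — drop tags mapping with <= 2 mismatches of which at
                      least one is an A-to-I-editing-compatible change
6. microbiome       — drop tags with an exact full-length occurrence in
                      any microbiome genome (E <= 0.01)
7. min-count        — keep miRNA species supported by >= min_count reads

Surviving counts feed a per-sample profile with MIR-family roll-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ParseError, SequenceRecord, parse_mirna_id
from .match import (
    KarlinParams,
    MiRNAIndex,
    ReferenceIndex,
    ScoringScheme,
    SubjectSet,
    containment_match,
    editing_aware_map,
    hamming_map,
    local_search,
    solve_karlin,
)
from .preprocess import Tag

__all__ = [
    "ReferenceBundle",
    "ScreenConfig",
    "StageReport",
    "PlantMiRNAProfile",
    "run_screen",
    "microbiome_filter",
    "aggregate_families",
]


@dataclass
class ReferenceBundle:
    """All reference sets the cascade consults."""

    plant_mirnas: list[SequenceRecord]
    host_ncrna: list[SequenceRecord]
    host_mrna_repeats: list[SequenceRecord]
    host_genome: list[SequenceRecord]
    microbiome: list[SequenceRecord]

    def validate(self) -> None:
        for name in (
            "plant_mirnas",
            "host_ncrna",
            "host_mrna_repeats",
            "host_genome",
            "microbiome",
        ):
            if getattr(self, name) is None:
                raise ValueError(f"reference bundle is missing {name}")


@dataclass(frozen=True)
class ScreenConfig:
    min_count: int = 5
    evalue_max: float = 0.01
    genome_mismatches: int = 1
    editing_pass: bool = True
    both_strands: bool = True
    scheme: ScoringScheme = ScoringScheme()


@dataclass
class StageReport:
    """Tag/read survivor counts at every cascade boundary."""

    sample_id: str
    stages: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    # (stage_name, tags_in, tags_out, reads_in, reads_out)

    def record(self, name: str, tags_in, tags_out) -> None:
        self.stages.append(
            (
                name,
                len(tags_in),
                len(tags_out),
                sum(t.count for t in tags_in),
                sum(t.count for t in tags_out),
            )
        )

    def as_dicts(self) -> list[dict]:
        return [
            dict(
                stage=s, tags_in=ti, tags_out=to, reads_in=ri, reads_out=ro
            )
            for s, ti, to, ri, ro in self.stages
        ]


@dataclass
class PlantMiRNAProfile:
    """Per-sample miRNA-species read counts with MIR-family roll-up."""

    sample_id: str
    entries: dict[str, int] = field(default_factory=dict)
    families: dict[str, int] = field(default_factory=dict)
    star_species: frozenset[str] = frozenset()

    @property
    def n_species(self) -> int:
        return len(self.entries)

    @property
    def n_families(self) -> int:
        return len(self.families)


def microbiome_filter(
    tags: list[Tag],
    microbiome: list[SequenceRecord],
    params: KarlinParams,
    evalue_max: float = 0.01,
    scheme: ScoringScheme = ScoringScheme(),
) -> list[Tag]:
    """Drop tags with an exact, gap-free full-length microbiome occurrence.

    Mismatches and gaps are disallowed at this stage, so the criterion is
    plain substring containment (both strands) — with the perfect-match
    score still required to clear the E-value bar, which any >= 17 nt exact
    match against a realistic database does.
    """
    if not microbiome:
        return list(tags)
    total_n = sum(len(r) for r in microbiome)
    genomes = [r.seq for r in microbiome]

    def hits(tag: Tag) -> bool:
        from .io import reverse_complement
        from .match import evalue as _evalue

        for q in (tag.seq, reverse_complement(tag.seq)):
            for g in genomes:
                if q in g:
                    score = len(tag.seq) * scheme.match
                    if _evalue(score, len(tag.seq), total_n, params) <= evalue_max:
                        return True
        return False

    return [t for t in tags if not hits(t)]


def _profile_from_tags(
    tags: list[Tag],
    index: MiRNAIndex,
    sample_id: str,
    min_count: int,
) -> tuple[PlantMiRNAProfile, list[Tag]]:
    """Species counts (a tag counts toward every miRNA it matches), then
    the min-count threshold on species-level counts."""
    species: dict[str, int] = {}
    species_tags: dict[str, list[Tag]] = {}
    for tag in tags:
        for hit in index.lookup(tag.seq):
            species[hit.mirna_id] = species.get(hit.mirna_id, 0) + tag.count
            species_tags.setdefault(hit.mirna_id, []).append(tag)
    kept = {m: c for m, c in species.items() if c >= min_count}
    profile = PlantMiRNAProfile(sample_id=sample_id, entries=dict(sorted(kept.items())))
    # family roll-up, deduplicating shared tags within a family
    families: dict[str, int] = {}
    fam_tags: dict[str, dict[str, int]] = {}
    stars = set()
    for mid in kept:
        try:
            ident = parse_mirna_id(mid)
            fam = ident.family
            if ident.is_star:
                stars.add(mid)
        except ParseError:
            fam = "UNKNOWN"
        for tag in species_tags[mid]:
            fam_tags.setdefault(fam, {})[tag.seq] = tag.count
    for fam, seqs in fam_tags.items():
        families[fam] = sum(seqs.values())
    profile.families = dict(sorted(families.items()))
    profile.star_species = frozenset(stars)
    surviving = sorted(
        {t.seq: t for m in kept for t in species_tags[m]}.values(),
        key=lambda t: (-t.count, t.seq),
    )
    return profile, surviving


def run_screen(
    tags: list[Tag],
    refs: ReferenceBundle,
    config: ScreenConfig = ScreenConfig(),
    sample_id: str = "",
) -> tuple[PlantMiRNAProfile, StageReport, list[Tag]]:
    """Run the full cascade; returns (profile, stage report, surviving tags).

    The returned tag list contains the pre-threshold survivors of stage 6,
    so sub-threshold species remain auditable.
    """
    refs.validate()
    params = solve_karlin(config.scheme)
    index = MiRNAIndex(refs.plant_mirnas)
    report = StageReport(sample_id=sample_id)

    current = sorted(tags, key=lambda t: (-t.count, t.seq))

    # 1: plant containment match
    matched = [t for t in current if containment_match(t, index)]
    report.record("plant-match", current, matched)
    current = matched

    # 2/3: local similarity vs host ncRNA then mRNA/repeats
    for stage_name, records in (
        ("host-ncrna", refs.host_ncrna),
        ("host-mrna-repeat", refs.host_mrna_repeats),
    ):
        if records:
            subjects = SubjectSet(records)
            survivors = [
                t
                for t in current
                if not local_search(
                    t,
                    subjects,
                    params,
                    evalue_max=config.evalue_max,
                    scheme=config.scheme,
                    both_strands=config.both_strands,
                )
            ]
        else:
            survivors = current
        report.record(stage_name, current, survivors)
        current = survivors

    # 4: genome mapping, k mismatches
    genome = ReferenceIndex(refs.host_genome)
    survivors = [
        t for t in current if not hamming_map(t, genome, k=config.genome_mismatches)
    ]
    report.record("genome-map", current, survivors)
    current = survivors

    # 5: editing-aware second pass
    if config.editing_pass:
        survivors = [t for t in current if not editing_aware_map(t, genome)]
    else:
        survivors = current
    report.record("genome-editing", current, survivors)
    current = survivors

    # 6: microbiome exact-match exclusion
    survivors = microbiome_filter(
        current, refs.microbiome, params, config.evalue_max, config.scheme
    )
    report.record("microbiome", current, survivors)
    current = survivors

    # 7: abundance threshold at the species level
    profile, above = _profile_from_tags(current, index, sample_id, config.min_count)
    report.record("min-count", current, above)
    return profile, report, current


def aggregate_families(profile: PlantMiRNAProfile) -> dict:
    """Summary table: per-family counts plus species/family totals."""
    return {
        "families": dict(profile.families),
        "n_species": profile.n_species,
        "n_families": profile.n_families,
        "star_species": sorted(profile.star_species),
    }
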