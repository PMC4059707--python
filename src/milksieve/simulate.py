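"""Synthetic reference bundles and FASTQ samples with known composition.

The generator emulates the statistical shape of a 2011-era 36 bp
single-end small-RNA milk-exosome run: each read is a 17–25 nt insert
followed by the 3' adapter, truncated/padded to 36 nt, with Phred
qualities from a clipped normal model.  Inserts come from four origins:

* **plant** — planted mature plant miRNAs (the true positives), 20–24 nt,
  rejection-sampled so the cascade's own matchers find no similarity to
  any host or microbiome reference (class disjointness at the 17-mer
  level and below the screening E-value);
* **host** — background substrings of host ncRNA/mRNA/genome (removed at
  the plant-match stage) plus *decoy* reads whose sequences are planted in
  the plant-miRNA reference but genuinely originate from host ncRNA,
  mRNA, genome, or genome-with-editing-signature loci, so that every
  exclusion stage has dedicated casualties;
* **microbe** — microbiome-genome substrings, including decoys present in
  the plant reference that stage 6 must remove;
* **adapter-dimer** — reads with no insert.

A :class:`GroundTruthManifest` records every read's origin and the
planted per-miRNA counts; since all origin classes are sequence-disjoint,
a tag's sequence identifies its origin exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import QualityRead, SequenceRecord, reverse_complement, write_fasta, write_fastq
from .match import (
    MiRNAIndex,
    ReferenceIndex,
    SubjectSet,
    editing_aware_map,
    hamming_map,
    local_search,
    solve_karlin,
    ScoringScheme,
)
from .pipeline import ReferenceBundle
from .preprocess import Tag

__all__ = [
    "SimulationConfig",
    "GroundTruthManifest",
    "generate_references",
    "generate_sample",
    "make_target_fixture",
]

_BASES = np.array(list("ACGT"))
_SPECIES = ("ath", "osa", "zma", "bdi", "ptc", "aly", "pab", "ctr")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    host_genome_len: int = 6000  # split over two chromosomes
    n_host_ncrna: int = 8
    n_host_mrna: int = 6
    n_microbe_genomes: int = 3
    microbe_genome_len: int = 1500
    n_plant_mirnas: int = 10
    mirna_len_range: tuple[int, int] = (20, 24)
    # read counts per planted miRNA index; default plants two species below
    # the count-5 threshold and one exactly at it
    planted_counts: tuple[int, ...] = (40, 31, 25, 18, 14, 11, 8, 5, 4, 3)
    decoys_per_stage: int = 3
    decoy_read_count: int = 5
    host_read_count: int = 60
    microbe_read_count: int = 20
    adapter_dimer_count: int = 5
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    error_rate: float = 0.0
    qual_mean: float = 38.0
    qual_sd: float = 2.0
    read_len: int = 36
    max_retries: int = 200

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if len(self.planted_counts) != self.n_plant_mirnas:
            raise ValueError("planted_counts must list one count per miRNA")
        if any(c < 0 for c in self.planted_counts):
            raise ValueError("planted counts must be >= 0")


@dataclass
class GroundTruthManifest:
    """Per-read origins and planted composition — the acceptance oracle."""

    read_labels: list[tuple[str, str]] = field(default_factory=list)
    planted_counts: dict[str, int] = field(default_factory=dict)
    origin_by_insert: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, label in self.read_labels:
            top = label.split(":")[0]
            out[top] = out.get(top, 0) + 1
        return out

    def origin_of(self, insert_seq: str) -> str:
        return self.origin_by_insert.get(insert_seq, "unknown")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "read_labels": self.read_labels,
                    "planted_counts": self.planted_counts,
                    "origin_by_insert": self.origin_by_insert,
                    "provenance": self.provenance,
                },
                indent=1,
                sort_keys=True,
            )
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its retry budget."""


def generate_references(
    config: SimulationConfig,
) -> tuple[ReferenceBundle, GroundTruthManifest]:
    """Build a reference bundle with guaranteed class structure.

    Host ncRNA and mRNA are genuine substrings of the host genome (so they
    map back); plant miRNAs are rejection-sampled against the pipeline's
    own matchers until none shows any host/microbiome signal; decoy
    plant-reference entries are copies of host/microbiome subsequences so
    every cascade stage sees dedicated casualties.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    half = config.host_genome_len // 2
    chrom1 = _random_seq(rng, half)
    chrom2 = _random_seq(rng, config.host_genome_len - half)
    genome = [
        SequenceRecord("chr1", chrom1, "synthetic host chromosome"),
        SequenceRecord("chr2", chrom2, "synthetic host chromosome"),
    ]

    def substring(src: str, length: int) -> tuple[str, int]:
        start = int(rng.integers(0, len(src) - length + 1))
        return src[start : start + length], start

    ncrna = []
    for i in range(config.n_host_ncrna):
        length = int(rng.integers(80, 151))
        seq, start = substring(chrom1, length)
        ncrna.append(SequenceRecord(f"ncRNA_{i}", seq, f"chr1:{start}"))
    mrna = []
    for i in range(config.n_host_mrna):
        length = int(rng.integers(200, 401))
        seq, start = substring(chrom2, length)
        mrna.append(SequenceRecord(f"mRNA_{i}", seq, f"chr2:{start}"))

    host_17mers = _kmers(chrom1, 17) | _kmers(chrom2, 17)
    microbes = []
    for i in range(config.n_microbe_genomes):
        for _ in range(config.max_retries):
            seq = _random_seq(rng, config.microbe_genome_len)
            if not (_kmers(seq, 17) & host_17mers):
                microbes.append(SequenceRecord(f"microbe_{i}", seq))
                break
        else:
            raise GenerationError("could not draw a host-disjoint microbe genome")
    microbe_17mers = set()
    for rec in microbes:
        microbe_17mers |= _kmers(rec.seq, 17)

    # matcher-backed screens used during rejection sampling
    genome_index = ReferenceIndex(genome)
    params = solve_karlin(ScoringScheme())
    nc_subjects = SubjectSet(ncrna)
    m_subjects = SubjectSet(mrna)

    def host_signal(seq: str) -> bool:
        tag = Tag(seq=seq, count=1)
        if hamming_map(tag, genome_index, k=2):
            return True
        if local_search(tag, nc_subjects, params) or local_search(
            tag, m_subjects, params
        ):
            return True
        forbidden = host_17mers | microbe_17mers
        if _kmers(seq, 17) & forbidden:
            return True
        return any(
            seq in rec.seq or reverse_complement(seq) in rec.seq for rec in microbes
        )

    lengths = rng.integers(
        config.mirna_len_range[0], config.mirna_len_range[1] + 1,
        size=config.n_plant_mirnas,
    )
    plant: list[SequenceRecord] = []
    plant_seqs: set[str] = set()
    for i in range(config.n_plant_mirnas):
        for _ in range(config.max_retries):
            seq = _random_seq(rng, int(lengths[i]))
            # keep species mutually non-contained so counts stay exact
            near = any(
                s == seq or s in seq or seq in s for s in plant_seqs
            )
            if not near and not host_signal(seq):
                break
        else:
            raise GenerationError("could not draw a host-disjoint plant miRNA")
        prefix = _SPECIES[i % len(_SPECIES)]
        fam = 901 if i < 2 else 901 + i  # first two share a MIR family
        variant = chr(ord("a") + i) if i < 2 else "a"
        plant.append(SequenceRecord(f"{prefix}-miR{fam}{variant}", seq))
        plant_seqs.add(seq)

    # decoy plant-reference entries: host/microbe sequences that will pass
    # the plant-match stage and must be eliminated by stages 2-6
    decoys: dict[str, list[SequenceRecord]] = {}
    sources = {
        "host:ncrna-decoy": lambda: substring(
            ncrna[int(rng.integers(len(ncrna)))].seq, 21
        )[0],
        "host:mrna-decoy": lambda: substring(
            mrna[int(rng.integers(len(mrna)))].seq, 21
        )[0],
        "host:genome-decoy": lambda: substring(chrom2, 21)[0],
        "host:editing-decoy": lambda: _editing_variant(rng, chrom1),
        "microbe:decoy": lambda: substring(
            microbes[int(rng.integers(len(microbes)))].seq, 21
        )[0],
    }
    n_decoy = 0
    for label, draw in sources.items():
        decoys[label] = []
        for _ in range(config.decoys_per_stage):
            for _ in range(config.max_retries):
                seq = draw()
                if seq is None or seq in plant_seqs:
                    continue
                if any(s in seq or seq in s for s in plant_seqs):
                    continue
                if _decoy_ok(label, seq, genome_index, nc_subjects, m_subjects,
                             params, microbes):
                    break
            else:
                raise GenerationError(f"could not draw a clean {label}")
            prefix = _SPECIES[n_decoy % len(_SPECIES)]
            decoys[label].append(
                SequenceRecord(f"{prefix}-miR{950 + n_decoy}", seq)
            )
            plant_seqs.add(seq)
            n_decoy += 1

    plant_ref = plant + [d for ds in decoys.values() for d in ds]
    bundle = ReferenceBundle(
        plant_mirnas=plant_ref,
        host_ncrna=ncrna,
        host_mrna_repeats=mrna,
        host_genome=genome,
        microbiome=microbes,
    )
    manifest = GroundTruthManifest(
        provenance={
            "true_mirnas": {r.id: r.seq for r in plant},
            "decoys": {
                label: {r.id: r.seq for r in ds} for label, ds in decoys.items()
            },
        }
    )
    return bundle, manifest


def _editing_variant(rng: np.random.Generator, chrom: str) -> str | None:
    """A 21-mer genome substring with exactly two mismatches to its locus,
    one A-to-I-compatible (reference A read as G) and one not."""
    start = int(rng.integers(0, len(chrom) - 21 + 1))
    seq = list(chrom[start : start + 21])
    a_positions = [i for i in range(4, 17) if seq[i] == "A"]
    c_positions = [i for i in range(4, 17) if seq[i] == "C" and seq[i] != "A"]
    if not a_positions or not c_positions:
        return None
    ai = int(rng.choice(a_positions))
    ci = int(rng.choice([c for c in c_positions if c != ai]))
    seq[ai] = "G"  # ref A -> read G (the editing signature)
    seq[ci] = "A"  # ref C -> read A (plain sequencing-era mismatch)
    return "".join(seq)


def _decoy_ok(label, seq, genome_index, nc_subjects, m_subjects, params, microbes):
    """Check a decoy is removed at its intended stage and no earlier."""
    tag = Tag(seq=seq, count=1)
    nc_hit = bool(local_search(tag, nc_subjects, params))
    m_hit = bool(local_search(tag, m_subjects, params))
    g1 = bool(hamming_map(tag, genome_index, k=1))
    ge = bool(editing_aware_map(tag, genome_index))
    mic = any(
        seq in rec.seq or reverse_complement(seq) in rec.seq for rec in microbes
    )
    if label == "host:ncrna-decoy":
        return nc_hit
    if label == "host:mrna-decoy":
        return m_hit and not nc_hit
    if label == "host:genome-decoy":
        return g1 and not nc_hit and not m_hit
    if label == "host:editing-decoy":
        return ge and not g1 and not nc_hit and not m_hit
    if label == "microbe:decoy":
        return mic and not nc_hit and not m_hit and not g1 and not ge
    raise ValueError(label)


def generate_sample(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    manifest: GroundTruthManifest,
    sample_id: str = "S1",
) -> tuple[list[QualityRead], GroundTruthManifest]:
    """Draw the FASTQ reads for one sample and complete the manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    true_ids = list(manifest.provenance["true_mirnas"])
    inserts: list[tuple[str, str]] = []  # (insert, label)

    for idx, mid in enumerate(true_ids):
        seq = manifest.provenance["true_mirnas"][mid]
        count = config.planted_counts[idx]
        manifest.planted_counts[mid] = count
        manifest.origin_by_insert[seq] = f"plant:{mid}"
        inserts += [(seq, f"plant:{mid}")] * count

    for label, entries in manifest.provenance["decoys"].items():
        for seq in entries.values():
            manifest.origin_by_insert[seq] = label
            inserts += [(seq, label)] * config.decoy_read_count

    host_pool = (
        [r.seq for r in bundle.host_ncrna]
        + [r.seq for r in bundle.host_mrna_repeats]
        + [r.seq for r in bundle.host_genome]
    )
    for _ in range(config.host_read_count):
        src = host_pool[int(rng.integers(len(host_pool)))]
        length = int(rng.integers(17, 26))
        start = int(rng.integers(0, len(src) - length + 1))
        seq = src[start : start + length]
        inserts.append((seq, "host:background"))
        manifest.origin_by_insert.setdefault(seq, "host:background")
    for _ in range(config.microbe_read_count):
        src = bundle.microbiome[int(rng.integers(len(bundle.microbiome)))].seq
        length = int(rng.integers(17, 26))
        start = int(rng.integers(0, len(src) - length + 1))
        seq = src[start : start + length]
        inserts.append((seq, "microbe:background"))
        manifest.origin_by_insert.setdefault(seq, "microbe:background")
    inserts += [("", "adapter-dimer")] * config.adapter_dimer_count

    reads: list[QualityRead] = []
    for n, (insert, label) in enumerate(inserts):
        if config.error_rate > 0 and insert:
            bases = list(insert)
            for i in range(len(bases)):
                if rng.random() < config.error_rate:
                    bases[i] = str(
                        rng.choice([b for b in "ACGT" if b != bases[i]])
                    )
            insert = "".join(bases)
        raw = insert + config.adapter3
        if len(raw) < config.read_len:
            raw += _random_seq(rng, config.read_len - len(raw))
        raw = raw[: config.read_len]
        qual = np.clip(
            np.rint(rng.normal(config.qual_mean, config.qual_sd, len(raw))), 2, 40
        ).astype(int)
        read_id = f"{sample_id}_r{n}"
        reads.append(QualityRead(id=read_id, seq=raw, qual=tuple(qual)))
        manifest.read_labels.append((read_id, label))
    return reads, manifest


def write_bundle(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all reference FASTAs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, records in (
        ("plant_mirnas", bundle.plant_mirnas),
        ("host_ncrna", bundle.host_ncrna),
        ("host_mrna", bundle.host_mrna_repeats),
        ("host_genome", bundle.host_genome),
        ("microbiome", bundle.microbiome),
    ):
        path = outdir / f"{name}.fa"
        write_fasta(records, path)
        paths[name] = path
    return paths


def make_target_fixture(
    mirna: str, context: str = "unstructured", flank: int = 20
) -> tuple[SequenceRecord, tuple[int, int]]:
    """A transcript embedding the perfect-complement site of a miRNA.

    ``unstructured`` places the site in poly-A flanks (no secondary
    structure, ΔG_open = 0); ``hairpin`` pairs the site against its own
    reverse complement across a short loop, so the site sits in a strong
    stem and carries a positive opening cost.
    """
    site = reverse_complement(mirna)
    if context == "unstructured":
        seq = "A" * flank + site + "A" * flank
        span = (flank, flank + len(site))
        rec = SequenceRecord("fixture_unstructured", seq, "synthetic target fixture")
    elif context == "hairpin":
        seq = "A" * flank + site + "AAAA" + reverse_complement(site) + "A" * flank
        span = (flank, flank + len(site))
        rec = SequenceRecord("fixture_hairpin", seq, "synthetic target fixture")
    else:
        raise ValueError("context must be 'unstructured' or 'hairpin'")
    return rec, span
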