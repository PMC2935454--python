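"""Seed-deterministic synthetic inputs for the analysis modules.

The generators state a simple world matching the project the package was
written for: a heterozygous diploid genome sequenced by a ~5x long-read
platform (366 b reads, homopolymer indel errors) and a ~25x short-read
platform (74 b reads, substitution errors); marker maps laid out over
chromosomes with optional planted scaffold misjoins; per-gene dN/dS tables
with a planted fraction of lineage-accelerated genes; and gene-family
copy-number matrices with planted expansions/contractions.

Every generator takes one integer seed; sub-streams are derived
deterministically, so identical seeds give byte-identical serialized
outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .snv import (
    GAP,
    LONG_READ_PLATFORM,
    SHORT_READ_PLATFORM,
    PileupColumn,
    ReadObservation,
    homopolymer_run_length,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# diploid truth + pileup columns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    position: int
    kind: str  # substitution | insertion | deletion
    alleles: tuple[str, str]
    homopolymer_flag: bool


@dataclass
class DiploidTruth:
    reference: str
    variants: list[Variant]


@dataclass(frozen=True)
class PlatformProfile:
    """Sequencing platform error/coverage model.

    ``homopolymer_indel_error`` is the per-base probability of a spurious
    single-base deletion inside a homopolymer run (pyrosequencing's
    signature failure mode); ``sub_error`` the per-base substitution error.
    """

    name: str
    read_length: int
    depth: float
    sub_error: float
    homopolymer_indel_error: float
    quality_range: tuple[int, int] = (20, 40)

    def __post_init__(self) -> None:
        if not (0 <= self.sub_error <= 1 and 0 <= self.homopolymer_indel_error <= 1):
            raise ValueError("error probabilities must be in [0,1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.quality_range[0] > self.quality_range[1]:
            raise ValueError("quality bounds out of order")


#: defaults emulating the two-platform mix of the assembly this package models
LONG_READ_PROFILE = PlatformProfile(LONG_READ_PLATFORM, 366, 5.0, 0.001, 0.01)
SHORT_READ_PROFILE = PlatformProfile(SHORT_READ_PLATFORM, 74, 25.0, 0.003, 0.0)
DEFAULT_PROFILES = (LONG_READ_PROFILE, SHORT_READ_PROFILE)


def gen_diploid_truth(
    length: int,
    snp_rate: float = 0.001,
    indel_rate: float = 0.0003,
    homopolymer_bias: float = 1.0,
    seed: int = 0,
    min_run: int = 2,
) -> DiploidTruth:
    """Random reference with planted heterozygous substitutions and
    single-base indels.

    Indels are placed per-base with probability ``indel_rate``, multiplied
    by ``homopolymer_bias`` inside homopolymer runs (of length >=
    ``min_run``), mirroring the long-read platform's error context.  The
    ``homopolymer_flag`` of each variant records whether the site satisfies
    the homopolymer predicate used by the SNV classifier.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 <= snp_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    ref = rng.choice(_BASES, size=length)
    reference = "".join(ref)

    in_run = np.zeros(length, dtype=bool)
    if min_run >= 2:
        same_left = np.zeros(length, dtype=bool)
        same_left[1:] = ref[1:] == ref[:-1]
        same_right = np.zeros(length, dtype=bool)
        same_right[:-1] = ref[:-1] == ref[1:]
        # a site is "in a run" when it has at least one identical neighbour;
        # longer min_run thresholds are resolved exactly below
        in_run = same_left | same_right

    snp_hits = rng.random(length) < snp_rate
    indel_p = np.full(length, indel_rate)
    indel_p[in_run] = np.minimum(indel_rate * homopolymer_bias, 1.0)
    indel_hits = rng.random(length) < indel_p
    indel_hits &= ~snp_hits  # SNP wins on collision

    variants: list[Variant] = []
    for p in np.flatnonzero(snp_hits):
        p = int(p)
        alt = rng.choice([b for b in "ACGT" if b != reference[p]])
        variants.append(Variant(p, "substitution", (reference[p], str(alt)), False))
    for p in np.flatnonzero(indel_hits):
        p = int(p)
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        run = homopolymer_run_length(
            reference[p], reference[max(0, p - 6) : p], reference[p + 1 : p + 7]
        )
        variants.append(Variant(p, kind, (reference[p], GAP), run >= min_run))
    variants.sort(key=lambda v: v.position)
    return DiploidTruth(reference=reference, variants=variants)


def gen_columns(
    truth: DiploidTruth,
    profiles: Sequence[PlatformProfile] = DEFAULT_PROFILES,
    seed: int = 0,
    context: int = 5,
    balanced_het: bool = False,
) -> tuple[list[PileupColumn], dict[str, np.ndarray]]:
    """Truth-aligned pileup columns plus a per-platform coverage track.

    Per position and platform the read count is Poisson(profile.depth); each
    read samples one of the two haplotypes (fair coin, or a deterministic
    even split when ``balanced_het`` — useful for exercising the classifier
    without binomial sampling noise at low depth).  Substitution errors
    replace the base, homopolymer deletion errors emit a gap observation.
    Qualities are uniform over the profile's Phred bounds; gap observations
    carry flanking qualities so gap-quality assignment is exercised.
    """
    if not profiles:
        raise ValueError("need at least one platform profile")
    rng = np.random.default_rng(seed)
    ref = truth.reference
    L = len(ref)
    var_at = {v.position: v for v in truth.variants}
    coverage = {p.name: np.zeros(L, dtype=np.int64) for p in profiles}

    columns: list[PileupColumn] = []
    for pos in range(L):
        obs: list[ReadObservation] = []
        variant = var_at.get(pos)
        in_run = (
            homopolymer_run_length(
                ref[pos], ref[max(0, pos - 6) : pos], ref[pos + 1 : pos + 7]
            )
            >= 2
        )
        for prof in profiles:
            depth = int(rng.poisson(prof.depth))
            coverage[prof.name][pos] = depth
            qlo, qhi = prof.quality_range
            for i in range(depth):
                if variant is not None:
                    hap = i % 2 if balanced_het else int(rng.integers(2))
                    symbol = variant.alleles[hap]
                else:
                    symbol = ref[pos]
                if symbol != GAP and prof.sub_error > 0 and rng.random() < prof.sub_error:
                    symbol = str(rng.choice([b for b in "ACGT" if b != symbol]))
                if (
                    symbol != GAP
                    and in_run
                    and prof.homopolymer_indel_error > 0
                    and rng.random() < prof.homopolymer_indel_error
                ):
                    symbol = GAP
                if symbol == GAP:
                    flanks = (int(rng.integers(qlo, qhi + 1)), int(rng.integers(qlo, qhi + 1)))
                    q = min(flanks)
                    obs.append(
                        ReadObservation(GAP, q, prof.name, f"{prof.name}.{pos}.{i}", flanks)
                    )
                else:
                    q = int(rng.integers(qlo, qhi + 1))
                    obs.append(ReadObservation(symbol, q, prof.name, f"{prof.name}.{pos}.{i}"))
        columns.append(
            PileupColumn(
                contig="contig1",
                position=pos,
                consensus=ref[pos],
                observations=obs,
                left_context=ref[max(0, pos - context) : pos],
                right_context=ref[pos + 1 : pos + 1 + context],
            )
        )
    return columns, coverage


# ---------------------------------------------------------------------------
# marker scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldTruth:
    scaffold_id: str
    chromosome: str | None  # None for misjoined scaffolds
    length: int
    reversed_: bool


@dataclass(frozen=True)
class Misjoin:
    scaffold_id: str
    breakpoint: int
    left_flank: int  # scaffold_pos of the last marker before the join
    right_flank: int  # scaffold_pos of the first marker after the join
    left_chromosome: str
    right_chromosome: str


@dataclass
class MarkerScenario:
    chromosomes: dict[str, list[str]]  # chromosome -> ordered marker ids
    scaffolds: list[ScaffoldTruth]
    observations: pd.DataFrame
    misjoins: list[Misjoin]


_SOURCES = ("microsatellite-linkage", "snp-linkage", "bes-physical")
_MARKER_SPACING = 10_000


def gen_marker_scenario(
    n_chrom: int,
    scaffolds_per_chrom: int,
    markers_per_scaffold: int,
    reversal_fraction: float = 0.3,
    misjoin_fraction: float = 0.0,
    seed: int = 0,
) -> MarkerScenario:
    """Chromosome layouts, scaffolds carrying marker blocks, and an
    observation table; optionally with planted cross-chromosome misjoins.

    A misjoined scaffold is the fusion of two half-scaffolds from different
    chromosomes; the recorded breakpoint is the midpoint between its
    flanking marker hits.  All other scaffolds carry a single-chromosome
    monotone marker block.
    """
    if min(n_chrom, scaffolds_per_chrom, markers_per_scaffold) < 1:
        raise ValueError("counts must be >= 1")
    if not (0 <= reversal_fraction <= 1 and 0 <= misjoin_fraction <= 1):
        raise ValueError("fractions must be in [0,1]")
    rng = np.random.default_rng(seed)

    chromosomes: dict[str, list[str]] = {}
    rows: list[dict] = []
    scaffolds: list[ScaffoldTruth] = []
    sid = itertools.count(1)
    scaffold_obs: dict[str, list[dict]] = {}

    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        order: list[str] = []
        for s in range(scaffolds_per_chrom):
            scaffold = f"scaffold{next(sid)}"
            rev = bool(rng.random() < reversal_fraction)
            length = (markers_per_scaffold + 1) * _MARKER_SPACING
            markers = [f"m{chrom}_{s}_{k}" for k in range(markers_per_scaffold)]
            order.extend(markers)
            positions = [(k + 1) * _MARKER_SPACING for k in range(markers_per_scaffold)]
            if rev:
                positions = positions[::-1]
            obs_rows = []
            for marker, pos in zip(markers, positions):
                obs_rows.append(
                    {
                        "marker_id": marker,
                        "source": str(rng.choice(_SOURCES)),
                        "chromosome": chrom,
                        "scaffold_id": scaffold,
                        "scaffold_pos": pos,
                    }
                )
            scaffold_obs[scaffold] = obs_rows
            scaffolds.append(ScaffoldTruth(scaffold, chrom, length, rev))
        chromosomes[chrom] = order

    # global chromosome ranks
    rank = {
        m: i for chrom, order in chromosomes.items() for i, m in enumerate(order)
    }
    for obs_rows in scaffold_obs.values():
        for r in obs_rows:
            r["chrom_order"] = rank[r["marker_id"]]

    misjoins: list[Misjoin] = []
    if misjoin_fraction > 0 and n_chrom >= 2:
        n_mis = int(round(misjoin_fraction * len(scaffolds)))
        # fuse pairs of scaffolds from different chromosomes
        candidates = list(range(len(scaffolds)))
        rng.shuffle(candidates)
        used: set[int] = set()
        made = 0
        for i in candidates:
            if made >= n_mis:
                break
            if i in used:
                continue
            a = scaffolds[i]
            partner = next(
                (
                    j
                    for j in candidates
                    if j not in used and j != i and scaffolds[j].chromosome != a.chromosome
                ),
                None,
            )
            if partner is None:
                continue
            b = scaffolds[partner]
            used.update((i, partner))
            rows_a = scaffold_obs[a.scaffold_id]
            rows_b = scaffold_obs[b.scaffold_id]
            offset = a.length
            fused_rows = [dict(r) for r in rows_a]
            for r in rows_b:
                r2 = dict(r)
                r2["scaffold_id"] = a.scaffold_id
                r2["scaffold_pos"] = r["scaffold_pos"] + offset
                fused_rows.append(r2)
            left_flank = max(r["scaffold_pos"] for r in rows_a)
            right_flank = min(r["scaffold_pos"] + offset for r in rows_b)
            scaffold_obs[a.scaffold_id] = fused_rows
            del scaffold_obs[b.scaffold_id]
            misjoins.append(
                Misjoin(
                    scaffold_id=a.scaffold_id,
                    breakpoint=(left_flank + right_flank) // 2,
                    left_flank=left_flank,
                    right_flank=right_flank,
                    left_chromosome=a.chromosome,
                    right_chromosome=b.chromosome,
                )
            )
            made += 1
        if misjoins:
            mis_ids = {m.scaffold_id for m in misjoins}
            fused_partner = used - {
                i for i in used if scaffolds[i].scaffold_id in mis_ids
            }
            keep = []
            for i, sc in enumerate(scaffolds):
                if i in fused_partner:
                    continue  # absorbed into the fused scaffold
                if sc.scaffold_id in mis_ids:
                    keep.append(
                        ScaffoldTruth(sc.scaffold_id, None, 2 * sc.length, sc.reversed_)
                    )
                else:
                    keep.append(sc)
            scaffolds = keep

    for obs_rows in scaffold_obs.values():
        rows.extend(obs_rows)
    observations = pd.DataFrame(
        rows,
        columns=["marker_id", "source", "chromosome", "chrom_order", "scaffold_id", "scaffold_pos"],
    ).sort_values(["scaffold_id", "scaffold_pos"], kind="stable").reset_index(drop=True)
    return MarkerScenario(chromosomes, scaffolds, observations, misjoins)


# ---------------------------------------------------------------------------
# omega tables
# ---------------------------------------------------------------------------

MAMMALS = ("human", "mouse", "dog", "opossum")
AVIAN_PAIR = "turkey:chicken"


def default_species_pairs() -> dict[str, list[str]]:
    """Pair labels by role: the avian pair, the six mammal-mammal pairs, and
    the eight avian-mammal pairs used by the lineage test."""
    mammal_pairs = [f"{a}:{b}" for a, b in itertools.combinations(MAMMALS, 2)]
    avian_mammal = [f"{bird}:{m}" for bird in ("turkey", "chicken") for m in MAMMALS]
    return {"avian": [AVIAN_PAIR], "mammal": mammal_pairs, "avian_mammal": avian_mammal}


def gen_omega_table(
    n_genes: int,
    species_pairs: dict[str, list[str]] | None = None,
    accel_fraction: float = 0.05,
    effect: float = 2.0,
    seed: int = 0,
    pair_sd: float = 0.25,
    gene_mean: float = -1.4,
    gene_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-pair (dN, dS, omega) long table plus truth labels.

    Each gene has a baseline log-omega drawn from N(gene_mean, gene_sd^2).
    The avian pair reports that baseline exactly — it is the gene's shared
    rate between the two closely related birds — while every other pair
    scatters around it with sd ``pair_sd``.  Accelerated genes (fraction
    ``accel_fraction``, lineage turkey or chicken with equal probability)
    add log(effect) to the avian pair and to that lineage's avian-mammal
    pairs.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    if not 0 <= accel_fraction <= 1:
        raise ValueError("accel_fraction must be in [0,1]")
    pairs = species_pairs or default_species_pairs()
    if len(pairs.get("avian", [])) != 1 or len(pairs.get("mammal", [])) < 2:
        raise ValueError("need one avian pair and at least two mammalian pairs")
    rng = np.random.default_rng(seed)

    accel = rng.random(n_genes) < accel_fraction
    lineages = np.where(rng.random(n_genes) < 0.5, "turkey", "chicken")
    shift = math.log(effect)

    rows = []
    truth_rows = []
    for g in range(n_genes):
        gene = f"gene{g:05d}"
        base = rng.normal(gene_mean, gene_sd)
        lineage = lineages[g] if accel[g] else "none"
        truth_rows.append(
            {"gene_id": gene, "accelerated": bool(accel[g]), "lineage": lineage}
        )
        for role, labels in pairs.items():
            for label in labels:
                log_omega = base if role == "avian" else base + rng.normal(0.0, pair_sd)
                if accel[g]:
                    if role == "avian":
                        log_omega += shift
                    elif role == "avian_mammal" and label.startswith(lineage + ":"):
                        log_omega += shift
                omega = math.exp(log_omega)
                dS = math.exp(rng.normal(math.log(0.3), 0.2))
                rows.append(
                    {
                        "gene_id": gene,
                        "pair": label,
                        "role": role,
                        "dN": omega * dS,
                        "dS": dS,
                        "omega": omega,
                    }
                )
    table = pd.DataFrame(rows, columns=["gene_id", "pair", "role", "dN", "dS", "omega"])
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "accelerated", "lineage"])
    return table, truth


# ---------------------------------------------------------------------------
# gene-family matrices
# ---------------------------------------------------------------------------

#: divergence times from the reference species (human), million years
DEFAULT_DIVERGENCE_TIMES = {
    "human": 0.0,
    "chimpanzee": 6.0,
    "macaque": 29.0,
    "mouse": 90.0,
    "rat": 90.0,
    "dog": 97.0,
    "pig": 94.0,
    "cow": 94.0,
    "opossum": 163.0,
    "platypus": 177.0,
    "lizard": 276.0,
    "chicken": 312.0,
    "turkey": 312.0,
    "zebra_finch": 312.0,
    "zebrafish": 429.0,
    "fugu": 435.0,
    "fruitfly": 782.0,
}


def gen_family_matrix(
    n_families: int,
    species: dict[str, float] | None = None,
    event_rate: float = 0.2,
    reference: str = "human",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-family x species copy-number matrix with planted gain/loss
    events, plus a truth table of the per-species change sign.

    ``species`` maps species name to divergence time (My) from the
    reference; the reference must have time 0.  Returns (matrix, truth):
    the matrix has family rows and species columns (integer copy counts,
    ``divergence_time`` stored in ``matrix.attrs``); truth has one row per
    (family, species) event with sign "expanded"/"contracted".
    """
    sp = dict(species) if species is not None else dict(DEFAULT_DIVERGENCE_TIMES)
    if reference not in sp or sp[reference] != 0.0:
        raise ValueError("reference species must be present with divergence time 0")
    if any(t < 0 for t in sp.values()):
        raise ValueError("negative divergence time")
    if not 0 <= event_rate <= 1:
        raise ValueError("event_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    names = list(sp)
    counts = np.zeros((n_families, len(names)), dtype=np.int64)
    truth_rows = []
    for i in range(n_families):
        base = 1 + int(rng.poisson(2.0))
        counts[i, :] = base
        for j, name in enumerate(names):
            if name == reference:
                continue
            if rng.random() < event_rate:
                delta = (1 + int(rng.poisson(1.0))) * (1 if rng.random() < 0.5 else -1)
                counts[i, j] = max(0, base + delta)
                if counts[i, j] != base:
                    truth_rows.append(
                        {
                            "family_id": f"fam{i:04d}",
                            "species": name,
                            "sign": "expanded" if counts[i, j] > base else "contracted",
                        }
                    )
    matrix = pd.DataFrame(
        counts, index=[f"fam{i:04d}" for i in range(n_families)], columns=names
    )
    matrix.index.name = "family_id"
    matrix.attrs["divergence_times"] = sp
    matrix.attrs["reference"] = reference
    truth = pd.DataFrame(truth_rows, columns=["family_id", "species", "sign"])
    return matrix, truth


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], handle: IO[str], width: int = 70) -> None:
    """Write sequences as FASTA (wrapped at ``width`` columns)."""
    for name, seq in sequences.items():
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def truth_frame(truth: DiploidTruth) -> pd.DataFrame:
    """Tabular view of a planted variant set."""
    return pd.DataFrame(
        [
            {
                "position": v.position,
                "kind": v.kind,
                "allele_a": v.alleles[0],
                "allele_b": v.alleles[1],
                "homopolymer": v.homopolymer_flag,
            }
            for v in truth.variants
        ],
        columns=["position", "kind", "allele_a", "allele_b", "homopolymer"],
    )
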