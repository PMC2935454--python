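"""Tiered SNV classification from read pileup columns.

A heterozygous site in a diploid assembly shows up as a pileup column where
the underlying reads disagree with the consensus.  Sites are classified into
two tiers by evidence strength:

* **strong** — at least ``min_support`` (default 3) reads support each of at
  least two alleles, the sum of each allele's top ``top_k`` (3) base
  qualities is at least ``quality_sum`` (60), and total column depth is at
  most ``max_depth`` (30; deeper columns are suspect collapsed repeats);
* **weak** — a more inclusive tier: at least 2 supporting reads per allele
  and a top-2 quality sum of at least 45, with no depth cap.

Single-base indels inside homopolymer runs are the dominant error mode of
pyrosequencing, so an indel variant in a homopolymer additionally requires
at least one short-read-platform observation per allele in either tier.

Gap observations have no base quality of their own and are assigned the
minimum quality of the flanking bases of the same read.

Coordinates are 0-based half-open internally; only the VCF writer shifts to
1-based.
"""

from __future__ import annotations

import math
import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

GAP = "-"
NUCLEOTIDES = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: platform tags used throughout the package
LONG_READ_PLATFORM = "long-read"
SHORT_READ_PLATFORM = "short-read"


class PileupError(ValueError):
    """Malformed pileup input or configuration."""


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at a column.

    ``flank_qualities`` holds the qualities of the same read's bases
    flanking this column (``None`` where the read ends); it is only
    consulted for gap observations, whose ``quality`` is derived from it.
    """

    symbol: str
    quality: int
    platform: str
    read_id: str
    flank_qualities: tuple[int | None, int | None] = (None, None)

    def __post_init__(self) -> None:
        if self.symbol not in NUCLEOTIDES and self.symbol not in (GAP, "N"):
            raise PileupError(f"invalid observation symbol {self.symbol!r}")
        if self.quality < 0:
            raise PileupError("negative Phred quality")


@dataclass
class PileupColumn:
    """All read observations aligned over one consensus position."""

    contig: str
    position: int
    consensus: str
    observations: list[ReadObservation]
    left_context: str = ""
    right_context: str = ""

    @property
    def depth(self) -> int:
        """Number of callable (non-N) observations."""
        return sum(1 for o in self.observations if o.symbol != "N")


@dataclass
class VariantEvidence:
    """Aggregated support for one allele at a column."""

    allele: str
    support: int
    qualities: list[int]  # sorted descending
    platforms: frozenset[str]

    def top_quality_sum(self, k: int) -> int:
        return sum(self.qualities[:k])


@dataclass
class SNVCall:
    contig: str
    position: int
    consensus: str
    alleles: list[VariantEvidence]
    tier: str  # "strong" | "weak"
    kind: str  # "substitution" | "indel"
    depth: int
    multiallelic: bool = False


@dataclass
class SNVSummary:
    n_strong: int
    n_total: int
    transitions: int
    transversions: int
    indels: int
    multiallelic: int
    depth_mean: float | None
    depth_sd: float | None
    ts_tv: float | None  # rounded to one decimal; None when undefined

    @property
    def ratio_defined(self) -> bool:
        return self.ts_tv is not None


@dataclass
class DiversityEstimate:
    theta: float
    S: int
    L: int
    n: int
    a: float


@dataclass(frozen=True)
class SNVThresholds:
    """Evidence thresholds for the two SNV tiers."""

    strong_min_support: int = 3
    strong_top_k: int = 3
    strong_quality_sum: int = 60
    strong_max_depth: int = 30
    weak_min_support: int = 2
    weak_top_k: int = 2
    weak_quality_sum: int = 45
    homopolymer_min_run: int = 2
    short_read_platform: str = SHORT_READ_PLATFORM

    def __post_init__(self) -> None:
        for name in (
            "strong_min_support",
            "strong_top_k",
            "strong_quality_sum",
            "strong_max_depth",
            "weak_min_support",
            "weak_top_k",
            "weak_quality_sum",
            "homopolymer_min_run",
        ):
            if getattr(self, name) <= 0:
                raise PileupError(f"threshold {name} must be positive")


DEFAULT_THRESHOLDS = SNVThresholds()


def assign_gap_quality(column: PileupColumn, observation: ReadObservation) -> int:
    """Quality for a gap observation: minimum of the same read's flanking
    base qualities.  At a read end only the single available flank is used.
    """
    if observation.symbol != GAP:
        raise PileupError("assign_gap_quality called on a non-gap observation")
    flanks = [q for q in observation.flank_qualities if q is not None]
    if not flanks:
        raise PileupError(
            f"gap observation {observation.read_id} at {column.contig}:"
            f"{column.position} has no flanking bases"
        )
    return min(flanks)


def homopolymer_run_length(base: str, left_context: str, right_context: str) -> int:
    """Length of the mononucleotide run of ``base`` spanning the column."""
    run = 1
    for ch in reversed(left_context):
        if ch != base:
            break
        run += 1
    for ch in right_context:
        if ch != base:
            break
        run += 1
    return run


def is_homopolymer_indel(column: PileupColumn, min_run: int = 2) -> bool:
    """True iff the column's indel base sits in a homopolymer run of length
    at least ``min_run`` spanning the column.

    The indel base is the consensus base when the consensus is a nucleotide
    (deletion-style column); for a gap consensus it is the best-supported
    non-gap observed symbol.
    """
    if column.consensus in NUCLEOTIDES:
        base = column.consensus
    else:
        counts: dict[str, int] = defaultdict(int)
        for o in column.observations:
            if o.symbol in NUCLEOTIDES:
                counts[o.symbol] += 1
        if not counts:
            return False
        base = min(counts, key=lambda s: (-counts[s], s))
    return homopolymer_run_length(base, column.left_context, column.right_context) >= min_run


def variant_evidence(column: PileupColumn) -> list[VariantEvidence]:
    """Tally per-allele support at a column.

    N observations are excluded.  Gap observations use the assigned gap
    quality where flank information is available, otherwise the quality
    stored on the observation (e.g. read from a pileup TSV).  Entries are
    sorted by support descending, allele ascending on ties.
    """
    tally: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for obs in column.observations:
        if obs.symbol == "N":
            continue
        if obs.symbol == GAP and any(q is not None for q in obs.flank_qualities):
            q = assign_gap_quality(column, obs)
        else:
            q = obs.quality
        tally[obs.symbol].append((q, obs.platform))
    out = []
    for allele, entries in tally.items():
        quals = sorted((q for q, _ in entries), reverse=True)
        out.append(
            VariantEvidence(
                allele=allele,
                support=len(entries),
                qualities=quals,
                platforms=frozenset(p for _, p in entries),
            )
        )
    out.sort(key=lambda e: (-e.support, e.allele))
    return out


def _qualifying(
    evidence: Sequence[VariantEvidence], min_support: int, top_k: int, quality_sum: int
) -> list[VariantEvidence]:
    return [
        e
        for e in evidence
        if e.support >= min_support and e.top_quality_sum(top_k) >= quality_sum
    ]


def _homopolymer_ok(
    column: PileupColumn, variants: Sequence[VariantEvidence], cfg: SNVThresholds
) -> bool:
    if not any(v.allele == GAP for v in variants):
        return True
    if not is_homopolymer_indel(column, cfg.homopolymer_min_run):
        return True
    return all(cfg.short_read_platform in v.platforms for v in variants)


def classify_column(
    column: PileupColumn, cfg: SNVThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Classify a column as ``"strong"``, ``"weak"`` or ``"none"``.

    Strong requires at least two alleles each passing the strong per-allele
    thresholds, total depth at most the strong cap, and — for homopolymer
    indels — a short-read observation behind every qualifying allele.  The
    weak tier is evaluated independently with its own thresholds and no
    depth cap.  A strong column is never reported weak.
    """
    evidence = variant_evidence(column)
    if len(evidence) >= 2:
        strong = _qualifying(
            evidence, cfg.strong_min_support, cfg.strong_top_k, cfg.strong_quality_sum
        )
        if (
            len(strong) >= 2
            and column.depth <= cfg.strong_max_depth
            and _homopolymer_ok(column, strong, cfg)
        ):
            return "strong"
        weak = _qualifying(
            evidence, cfg.weak_min_support, cfg.weak_top_k, cfg.weak_quality_sum
        )
        if len(weak) >= 2 and _homopolymer_ok(column, weak, cfg):
            return "weak"
    return "none"


def call_snvs(
    columns: Iterable[PileupColumn], cfg: SNVThresholds = DEFAULT_THRESHOLDS
) -> list[SNVCall]:
    """Classify a (contig, position)-sorted column stream into SNV calls."""
    calls: list[SNVCall] = []
    prev: tuple[str, int] | None = None
    for col in columns:
        key = (col.contig, col.position)
        if prev is not None and key < prev:
            raise PileupError(f"columns not sorted at {col.contig}:{col.position}")
        prev = key
        tier = classify_column(col, cfg)
        if tier == "none":
            continue
        evidence = variant_evidence(col)
        if tier == "strong":
            alleles = _qualifying(
                evidence, cfg.strong_min_support, cfg.strong_top_k, cfg.strong_quality_sum
            )
        else:
            alleles = _qualifying(
                evidence, cfg.weak_min_support, cfg.weak_top_k, cfg.weak_quality_sum
            )
        kind = "indel" if any(a.allele == GAP for a in alleles) else "substitution"
        calls.append(
            SNVCall(
                contig=col.contig,
                position=col.position,
                consensus=col.consensus,
                alleles=alleles,
                tier=tier,
                kind=kind,
                depth=col.depth,
                multiallelic=len(alleles) > 2,
            )
        )
    return calls


def substitution_class(a: str, b: str) -> str:
    """``"transition"`` for purine<->purine / pyrimidine<->pyrimidine pairs,
    ``"transversion"`` otherwise."""
    if a not in NUCLEOTIDES or b not in NUCLEOTIDES:
        raise PileupError(f"substitution_class needs two nucleotides, got {a!r},{b!r}")
    if a == b:
        raise PileupError("substitution_class needs two distinct alleles")
    pair = {a, b}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def ts_tv_ratio(transitions: int, transversions: int) -> float | None:
    """Transition/transversion ratio rounded to one decimal; ``None`` when
    there are no transversions."""
    if transversions == 0:
        return None
    return round(transitions / transversions, 1)


def summarize_calls(calls: Sequence[SNVCall], tier: str = "all") -> SNVSummary:
    """Summary statistics over calls of the selected tier.

    ``tier`` selects which calls enter the ts/tv tally and the depth
    moments: ``"strong"``, ``"weak"`` or ``"all"``.  Ts/tv is computed over
    biallelic substitution calls only.
    """
    if tier == "all":
        selected = list(calls)
    else:
        selected = [c for c in calls if c.tier == tier]
    ts = tv = 0
    for c in selected:
        if c.kind == "substitution" and not c.multiallelic and len(c.alleles) == 2:
            if substitution_class(c.alleles[0].allele, c.alleles[1].allele) == "transition":
                ts += 1
            else:
                tv += 1
    depths = [c.depth for c in selected]
    return SNVSummary(
        n_strong=sum(1 for c in calls if c.tier == "strong"),
        n_total=len(calls),
        transitions=ts,
        transversions=tv,
        indels=sum(1 for c in selected if c.kind == "indel"),
        multiallelic=sum(1 for c in selected if c.multiallelic),
        depth_mean=statistics.mean(depths) if depths else None,
        depth_sd=statistics.stdev(depths) if len(depths) > 1 else None,
        ts_tv=ts_tv_ratio(ts, tv),
    )


def watterson_theta(S: int, L: int, n: int) -> DiversityEstimate:
    """Watterson's diversity estimator θ = S / (a·L) with a = Σ_{i<n} 1/i.

    ``S`` segregating sites over ``L`` covered bases across ``n`` sampled
    sequences.
    """
    if L <= 0:
        raise ValueError("covered length L must be positive")
    if n < 2:
        raise ValueError("need at least two sequences")
    if S < 0:
        raise ValueError("negative segregating-site count")
    a = sum(1.0 / i for i in range(1, n))
    return DiversityEstimate(theta=S / (a * L), S=S, L=L, n=n, a=a)


# ---------------------------------------------------------------------------
# pileup TSV dialect
# ---------------------------------------------------------------------------

PILEUP_HEADER = ["contig", "position", "consensus", "left_context", "right_context"]


def write_pileup_tsv(columns: Iterable[PileupColumn], handle: IO[str]) -> None:
    """Write columns in the package's pileup TSV dialect.

    Fixed headered columns (contig, 0-based position, consensus, flanking
    consensus contexts) followed by one ``symbol:quality:platform:read_id``
    field per observation.  Gap observations are written with their assigned
    gap quality, so the dialect is self-contained.
    """
    handle.write("\t".join(PILEUP_HEADER) + "\tobservations...\n")
    for col in columns:
        fields = [
            col.contig,
            str(col.position),
            col.consensus,
            col.left_context or ".",
            col.right_context or ".",
        ]
        for obs in col.observations:
            if obs.symbol == GAP and any(q is not None for q in obs.flank_qualities):
                q = assign_gap_quality(col, obs)
            else:
                q = obs.quality
            fields.append(f"{obs.symbol}:{q}:{obs.platform}:{obs.read_id}")
        handle.write("\t".join(fields) + "\n")


def read_pileup_tsv(handle: IO[str]) -> list[PileupColumn]:
    header = handle.readline()
    if not header.startswith("contig\t"):
        raise PileupError("not a pileup TSV (missing header)")
    columns = []
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        contig, pos, consensus, left, right = parts[:5]
        obs = []
        for f in parts[5:]:
            symbol, quality, platform, read_id = f.split(":", 3)
            obs.append(ReadObservation(symbol, int(quality), platform, read_id))
        columns.append(
            PileupColumn(
                contig=contig,
                position=int(pos),
                consensus=consensus,
                observations=obs,
                left_context="" if left == "." else left,
                right_context="" if right == "." else right,
            )
        )
    return columns


def columns_from_alignment(
    path: str,
    reference: Mapping[str, str],
    platform_tag: str = "PL",
    default_platform: str = SHORT_READ_PLATFORM,
    context: int = 5,
) -> list[PileupColumn]:
    """Adapter building pileup columns from a SAM/BAM alignment.

    Reads are walked via their CIGAR alignments (no pileup engine, so plain
    unindexed SAM works).  The platform tag is taken from each read's read
    group ``PL`` field when present, else ``default_platform``.  Deletions
    produce gap observations carrying the flanking base qualities of the
    read, insertions relative to the reference are ignored (the column model
    is reference-anchored).
    """
    import pysam  # deferred: only needed for the SAM adapter

    by_pos: dict[tuple[str, int], list[ReadObservation]] = defaultdict(list)
    with pysam.AlignmentFile(path, check_sq=False) as af:
        rg_platform = {}
        for rg in af.header.to_dict().get("RG", []):
            rg_platform[rg["ID"]] = rg.get(platform_tag, default_platform)
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            platform = default_platform
            if read.has_tag("RG"):
                platform = rg_platform.get(read.get_tag("RG"), default_platform)
            seq = read.query_sequence or ""
            quals = read.query_qualities
            pairs = read.get_aligned_pairs()
            for i, (qpos, rpos) in enumerate(pairs):
                if rpos is None:
                    continue  # insertion / soft clip
                if qpos is not None:
                    q = int(quals[qpos]) if quals is not None else 0
                    by_pos[(read.reference_name, rpos)].append(
                        ReadObservation(seq[qpos].upper(), q, platform, read.query_name)
                    )
                else:  # deletion in the read
                    left = right = None
                    for qj, _ in reversed(pairs[:i]):
                        if qj is not None:
                            left = int(quals[qj]) if quals is not None else 0
                            break
                    for qj, _ in pairs[i + 1 :]:
                        if qj is not None:
                            right = int(quals[qj]) if quals is not None else 0
                            break
                    flanks = (left, right)
                    q = min(f for f in flanks if f is not None) if any(
                        f is not None for f in flanks
                    ) else 0
                    by_pos[(read.reference_name, rpos)].append(
                        ReadObservation(GAP, q, platform, read.query_name, flanks)
                    )
    columns = []
    for (contig, pos), obs in sorted(by_pos.items()):
        ref = reference[contig]
        columns.append(
            PileupColumn(
                contig=contig,
                position=pos,
                consensus=ref[pos],
                observations=obs,
                left_context=ref[max(0, pos - context) : pos],
                right_context=ref[pos + 1 : pos + 1 + context],
            )
        )
    return columns


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=aviangen
##INFO=<ID=TIER,Number=1,Type=String,Description="SNV evidence tier (strong or weak)">
##INFO=<ID=KIND,Number=1,Type=String,Description="substitution or indel">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Column depth of coverage">
##INFO=<ID=SUP,Number=.,Type=Integer,Description="Per-allele supporting read counts (consensus-first order)">
##INFO=<ID=MULTI,Number=0,Type=Flag,Description="More than two well-supported alleles">
##FILTER=<ID=weak,Description="Weak-tier SNV">
"""


def _left_normalize_deletion(reference: str, pos: int) -> int:
    """Leftmost equivalent position for deleting ``reference[pos]``: the
    start of the maximal homopolymer run containing it."""
    base = reference[pos]
    while pos > 0 and reference[pos - 1] == base:
        pos -= 1
    return pos


def write_vcf(calls: Sequence[SNVCall], reference: Mapping[str, str]) -> str:
    """Render calls as a VCF 4.2 document (1-based positions).

    Substitutions: REF is the reference base, ALT the other qualifying
    alleles.  Base-vs-gap (indel) calls are emitted as deletions
    left-normalized against the reference, anchored on the preceding base
    (or the following base when the run starts at position 0).
    """
    lines = [_VCF_HEADER + "\t".join(
        ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    )]
    prev: tuple[str, int] | None = None
    for call in calls:
        if prev is not None and (call.contig, call.position) < prev:
            raise PileupError("calls must be sorted for VCF output")
        prev = (call.contig, call.position)
        ref_seq = reference[call.contig]
        if call.position >= len(ref_seq):
            raise PileupError(
                f"call at {call.contig}:{call.position} outside reference"
            )
        filt = "PASS" if call.tier == "strong" else "weak"
        info = (
            f"TIER={call.tier};KIND={call.kind};DP={call.depth};"
            f"SUP={','.join(str(a.support) for a in call.alleles)}"
        )
        if call.multiallelic:
            info += ";MULTI"
        if call.kind == "substitution":
            ref_allele = ref_seq[call.position]
            alts = [a.allele for a in call.alleles if a.allele != ref_allele]
            pos1 = call.position + 1
            ref_field, alt_field = ref_allele, ",".join(alts)
        else:
            p = _left_normalize_deletion(ref_seq, call.position)
            if p > 0:
                pos1 = p  # 1-based coordinate of the anchor base p-1
                ref_field = ref_seq[p - 1 : p + 1]
                alt_field = ref_seq[p - 1]
            else:  # run starts the contig: anchor on the following base
                pos1 = 1
                ref_field = ref_seq[0:2]
                alt_field = ref_seq[1]
        lines.append(
            "\t".join(
                [call.contig, str(pos1), ".", ref_field, alt_field, ".", filt, info]
            )
        )
    return "\n".join(lines) + "\n"


def read_vcf(text: str) -> list[dict]:
    """Parse a VCF produced by :func:`write_vcf` back into call records
    (dicts with contig, pos0, tier, kind, depth, supports, multiallelic,
    ref, alt)."""
    records = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _id, ref, alt, _qual, filt, info = line.split("\t")
        fields = dict(
            kv.split("=", 1) if "=" in kv else (kv, True)
            for kv in info.split(";")
        )
        records.append(
            {
                "contig": chrom,
                "pos0": int(pos) - 1,
                "ref": ref,
                "alt": alt.split(","),
                "tier": fields["TIER"],
                "kind": fields["KIND"],
                "depth": int(fields["DP"]),
                "supports": [int(s) for s in str(fields["SUP"]).split(",")],
                "multiallelic": bool(fields.get("MULTI", False)),
            }
        )
    return records
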