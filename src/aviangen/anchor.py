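"""Combined-map construction and scaffold anchoring onto chromosomes.

Markers from several map sources (microsatellite linkage, SNP linkage,
BAC-end physical) are merged into one ranked order per chromosome (the
combined map).  Each scaffold's marker hits are then segmented into maximal
single-chromosome, strictly monotone blocks; a scaffold whose hits need
more than one block is split at the midpoints between the conflicting
flanking hits.  Blocks with enough markers become placed pieces — ordered
by the median combined-map rank of their markers and oriented by the sign
of the rank correlation between scaffold position and map rank — and
everything else is pooled into the unassigned bin (ChrUn).

Chromosome conflicts between sources are resolved by precedence
(linkage > physical): chromosome assignment rests on the genetic maps, the
physical map refines placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

CHRUN = "ChrUn"

#: lower value = higher precedence when sources disagree on the chromosome
SOURCE_PRECEDENCE = {
    "microsatellite-linkage": 0,
    "snp-linkage": 0,
    "bes-physical": 1,
}

OBSERVATION_COLUMNS = [
    "marker_id",
    "source",
    "chromosome",
    "chrom_order",
    "scaffold_id",
    "scaffold_pos",
]


@dataclass
class CombinedMap:
    """Ranked marker order per chromosome with provenance and conflict log."""

    order: dict[str, list[str]]  # chromosome -> marker ids in rank order
    rank: dict[str, tuple[str, int]]  # marker -> (chromosome, rank)
    sources: dict[str, set[str]]  # marker -> contributing sources
    conflicts: list[dict] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.rank)


@dataclass(frozen=True)
class Placement:
    piece_id: str
    chromosome: str  # chromosome id or CHRUN
    order_index: float | None  # undefined for ChrUn pieces
    orientation: str  # forward | reverse
    orientation_known: bool
    supporting_markers: int
    split_from: str | None = None  # original scaffold when this piece is a split product


@dataclass(frozen=True)
class SplitEvent:
    scaffold_id: str
    breakpoint: int
    left_piece: str
    right_piece: str


def build_cmap(observations: pd.DataFrame) -> CombinedMap:
    """Merge marker observations from all sources into a combined map.

    A marker claimed on different chromosomes by different sources is placed
    according to the highest-precedence source and the conflict is logged.
    Within a chromosome markers are ranked by their mean claimed position,
    ties broken by marker id.
    """
    if len(observations) == 0:
        raise ValueError("no marker observations")
    obs = observations[OBSERVATION_COLUMNS].copy()
    conflicts: list[dict] = []
    chosen: dict[str, tuple[str, float]] = {}
    sources: dict[str, set[str]] = {}
    for marker, grp in obs.groupby("marker_id", sort=True):
        sources[marker] = set(grp["source"])
        claims = grp.groupby("chromosome")["chrom_order"].mean()
        if len(claims) == 1:
            chrom = claims.index[0]
        else:
            prec = grp.assign(prec=grp["source"].map(SOURCE_PRECEDENCE))
            best = prec.sort_values(["prec", "chromosome"], kind="stable").iloc[0]
            chrom = best["chromosome"]
            conflicts.append(
                {
                    "marker_id": marker,
                    "chosen": chrom,
                    "claims": dict(
                        grp.groupby("chromosome")["source"].agg(lambda s: sorted(set(s)))
                    ),
                }
            )
        winners = grp[grp["chromosome"] == chrom]
        chosen[marker] = (chrom, float(winners["chrom_order"].mean()))

    order: dict[str, list[str]] = {}
    rank: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list[tuple[float, str]]] = {}
    for marker, (chrom, pos) in chosen.items():
        by_chrom.setdefault(chrom, []).append((pos, marker))
    for chrom in sorted(by_chrom):
        ordered = [m for _, m in sorted(by_chrom[chrom])]
        order[chrom] = ordered
        for i, m in enumerate(ordered):
            rank[m] = (chrom, i)
    return CombinedMap(order=order, rank=rank, sources=sources, conflicts=conflicts)


def segment_blocks(
    hits: Sequence[tuple[int, str, int]], cmap: CombinedMap | None = None
) -> list[list[tuple[int, str, int]]]:
    """Greedy left-to-right maximal segmentation of a scaffold's marker hits.

    ``hits`` are (scaffold_pos, chromosome, rank) sorted by scaffold_pos.
    Each block is single-chromosome with strictly monotone (ascending or
    descending) rank; a consistent scaffold yields exactly one block.
    """
    blocks: list[list[tuple[int, str, int]]] = []
    current: list[tuple[int, str, int]] = []
    direction = 0  # 0 undetermined, +1 ascending, -1 descending
    for hit in hits:
        if not current:
            current = [hit]
            direction = 0
            continue
        _, chrom, rank = hit
        _, pchrom, prank = current[-1]
        step = 0 if rank == prank else (1 if rank > prank else -1)
        ok = chrom == pchrom and step != 0 and (direction == 0 or step == direction)
        if ok:
            if direction == 0:
                direction = step
            current.append(hit)
        else:
            blocks.append(current)
            current = [hit]
            direction = 0
    if current:
        blocks.append(current)
    return blocks


def _orientation(block: Sequence[tuple[int, str, int]]) -> tuple[str, bool]:
    """Orientation from the Kendall rank correlation between scaffold
    position and map rank; single markers and ties report forward/unknown."""
    if len(block) < 2:
        return "forward", False
    pos = [h[0] for h in block]
    ranks = [h[2] for h in block]
    tau = stats.kendalltau(pos, ranks).statistic
    if tau > 0:
        return "forward", True
    if tau < 0:
        return "reverse", True
    return "forward", False


def place_scaffolds(
    observations: pd.DataFrame,
    cmap: CombinedMap,
    scaffold_ids: Iterable[str] | None = None,
    min_markers: int = 1,
) -> tuple[list[Placement], list[SplitEvent], list[Placement]]:
    """Assign scaffolds to chromosomes via the combined map.

    Returns ``(placements, split_events, chrun)``.  Scaffolds in
    ``scaffold_ids`` without any usable marker hit land in ChrUn, as do
    split pieces with fewer than ``min_markers`` supporting markers.  Every
    input scaffold is accounted for exactly once across the three outputs.
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    obs = observations[observations["marker_id"].isin(cmap.rank)]
    placements: list[Placement] = []
    splits: list[SplitEvent] = []
    chrun: list[Placement] = []
    seen: set[str] = set()
    for scaffold, grp in obs.groupby("scaffold_id", sort=True):
        seen.add(scaffold)
        grp = grp.sort_values(["scaffold_pos", "marker_id"], kind="stable")
        hits = [
            (int(r.scaffold_pos), cmap.rank[r.marker_id][0], cmap.rank[r.marker_id][1])
            for r in grp.itertuples()
        ]
        blocks = segment_blocks(hits, cmap)
        split = len(blocks) > 1
        piece_ids = (
            [f"{scaffold}.{i + 1}" for i in range(len(blocks))] if split else [scaffold]
        )
        for i, (block, piece) in enumerate(zip(blocks, piece_ids)):
            if i > 0:
                left = blocks[i - 1][-1][0]
                right = block[0][0]
                splits.append(
                    SplitEvent(
                        scaffold_id=scaffold,
                        breakpoint=(left + right) // 2,
                        left_piece=piece_ids[i - 1],
                        right_piece=piece,
                    )
                )
            orientation, known = _orientation(block)
            if len(block) >= min_markers:
                placements.append(
                    Placement(
                        piece_id=piece,
                        chromosome=block[0][1],
                        order_index=float(median(h[2] for h in block)),
                        orientation=orientation,
                        orientation_known=known,
                        supporting_markers=len(block),
                        split_from=scaffold if split else None,
                    )
                )
            else:
                chrun.append(
                    Placement(
                        piece_id=piece,
                        chromosome=CHRUN,
                        order_index=None,
                        orientation="forward",
                        orientation_known=False,
                        supporting_markers=len(block),
                        split_from=scaffold if split else None,
                    )
                )
    if scaffold_ids is not None:
        for scaffold in scaffold_ids:
            if scaffold not in seen:
                chrun.append(
                    Placement(
                        piece_id=scaffold,
                        chromosome=CHRUN,
                        order_index=None,
                        orientation="forward",
                        orientation_known=False,
                        supporting_markers=0,
                    )
                )
    placements.sort(key=lambda p: (p.chromosome, p.order_index, p.piece_id))
    return placements, splits, chrun


def place_by_liftover(liftover: pd.DataFrame) -> list[Placement]:
    """Fallback placement from reference-genome coordinates.

    For chromosomes with no usable marker map (in practice the sex
    chromosomes), scaffolds aligned only to the corresponding reference
    chromosome are ordered and oriented by their reference coordinates.
    ``liftover`` columns: scaffold_id, chromosome, ref_start, strand (+/-).
    """
    placements = []
    for r in liftover.sort_values(["chromosome", "ref_start", "scaffold_id"]).itertuples():
        placements.append(
            Placement(
                piece_id=r.scaffold_id,
                chromosome=r.chromosome,
                order_index=float(r.ref_start),
                orientation="reverse" if r.strand == "-" else "forward",
                orientation_known=True,
                supporting_markers=0,
            )
        )
    return placements


def chromosome_table(
    placements: Sequence[Placement], sizes: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromosome contig and non-gap base totals, with a Total row.

    ``sizes`` is indexed by piece id with columns ``contigs`` and ``bases``;
    a record is required for every placed piece (ChrUn members included when
    passed in ``placements``).
    """
    rows = []
    for p in placements:
        if p.piece_id not in sizes.index:
            raise KeyError(f"no size record for piece {p.piece_id}")
        rec = sizes.loc[p.piece_id]
        rows.append(
            {
                "chromosome": p.chromosome,
                "contigs": int(rec["contigs"]),
                "bases": int(rec["bases"]),
            }
        )
    df = pd.DataFrame(rows, columns=["chromosome", "contigs", "bases"])
    table = df.groupby("chromosome", sort=True).sum()
    total = pd.DataFrame(
        {"contigs": [table["contigs"].sum()], "bases": [table["bases"].sum()]},
        index=pd.Index(["Total"], name="chromosome"),
    )
    return pd.concat([table, total])


def assigned_genome_fraction(assigned_bases: int, genome_size_estimate: float) -> float:
    """Fraction of the estimated genome captured by chromosome-assigned
    sequence (ChrUn included)."""
    if genome_size_estimate <= 0:
        raise ValueError("genome size estimate must be positive")
    return assigned_bases / genome_size_estimate


# ---------------------------------------------------------------------------
# AGP 2.0
# ---------------------------------------------------------------------------


def emit_agp(
    placements: Sequence[Placement],
    lengths: Mapping[str, int],
    gap_length: int = 100,
) -> str:
    """Render chromosome-placed pieces as an AGP 2.0 document.

    Pieces alternate with fixed-size scaffold gaps (type U, linkage yes,
    evidence map).  ChrUn placements are skipped — AGP describes assembled
    objects.  ``lengths`` maps piece id to component length in bases.
    """
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        if p.chromosome == CHRUN:
            continue
        by_chrom.setdefault(p.chromosome, []).append(p)
    lines = ["##agp-version 2.0"]
    for chrom in sorted(by_chrom):
        pieces = sorted(by_chrom[chrom], key=lambda p: (p.order_index, p.piece_id))
        indices = [p.order_index for p in pieces]
        if len(set(indices)) != len(indices):
            raise ValueError(f"overlapping order indices on {chrom}")
        pos = 1
        part = 1
        for i, p in enumerate(pieces):
            if i > 0:
                lines.append(
                    "\t".join(
                        [
                            chrom,
                            str(pos),
                            str(pos + gap_length - 1),
                            str(part),
                            "U",
                            str(gap_length),
                            "scaffold",
                            "yes",
                            "map",
                        ]
                    )
                )
                pos += gap_length
                part += 1
            length = lengths[p.piece_id]
            orient = (
                "?" if not p.orientation_known
                else ("-" if p.orientation == "reverse" else "+")
            )
            lines.append(
                "\t".join(
                    [
                        chrom,
                        str(pos),
                        str(pos + length - 1),
                        str(part),
                        "W",
                        p.piece_id,
                        "1",
                        str(length),
                        orient,
                    ]
                )
            )
            pos += length
            part += 1
    return "\n".join(lines) + "\n"


def parse_agp(text: str) -> list[Placement]:
    """Parse an AGP document written by :func:`emit_agp` back into
    placements (order_index = within-chromosome component rank)."""
    placements = []
    counters: dict[str, int] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        chrom, _beg, _end, _part, ctype = fields[:5]
        if ctype != "W":
            continue
        idx = counters.get(chrom, 0)
        counters[chrom] = idx + 1
        orient = fields[8]
        placements.append(
            Placement(
                piece_id=fields[5],
                chromosome=chrom,
                order_index=float(idx),
                orientation="reverse" if orient == "-" else "forward",
                orientation_known=orient != "?",
                supporting_markers=0,
            )
        )
    return placements
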