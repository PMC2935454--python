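"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import random

import pytest

from aviangen.snv import (
    GAP,
    LONG_READ_PLATFORM,
    SHORT_READ_PLATFORM,
    PileupColumn,
    ReadObservation,
    SNVThresholds,
)


def make_column(
    symbols_with_quals,
    consensus="A",
    left="",
    right="",
    platform=SHORT_READ_PLATFORM,
    contig="c1",
    position=0,
):
    """Build a column from (symbol, quality[, platform]) tuples."""
    obs = []
    for i, entry in enumerate(symbols_with_quals):
        sym, q = entry[0], entry[1]
        plat = entry[2] if len(entry) > 2 else platform
        flanks = (q, q) if sym == GAP else (None, None)
        obs.append(ReadObservation(sym, q, plat, f"r{i}", flanks))
    return PileupColumn(contig, position, consensus, obs, left, right)


def random_column(rng: random.Random, position: int = 0) -> PileupColumn:
    """A randomized pileup column that hugs the classifier thresholds:
    small supports, qualities around the per-allele quality-sum cutoffs,
    depths straddling the strong depth cap, occasional gaps/Ns, mixed
    platforms and homopolymer contexts."""
    consensus = rng.choice("ACGT")
    left = "".join(rng.choice([consensus, rng.choice("ACGT")]) for _ in range(3))
    right = "".join(rng.choice([consensus, rng.choice("ACGT")]) for _ in range(3))
    n_alleles = rng.randint(1, 4)
    alphabet = ["A", "C", "G", "T", GAP, "N"]
    alleles = rng.sample(alphabet, n_alleles)
    obs = []
    i = 0
    for allele in alleles:
        for _ in range(rng.randint(1, rng.choice([4, 14]))):
            q = rng.randint(8, 32)
            plat = rng.choice([LONG_READ_PLATFORM, SHORT_READ_PLATFORM])
            flanks = (rng.randint(8, 32), rng.randint(8, 32)) if allele == GAP else (None, None)
            quality = min(f for f in flanks if f is not None) if allele == GAP else q
            obs.append(ReadObservation(allele, quality, plat, f"r{i}", flanks))
            i += 1
    rng.shuffle(obs)
    return PileupColumn("c1", position, consensus, obs, left, right)


def oracle_classify(col: PileupColumn, cfg: SNVThresholds) -> str:
    """Literal re-statement of the tier criteria, kept independent of the
    implementation: explicit tallies, explicit per-criterion checks."""
    tally: dict[str, list[tuple[int, str]]] = {}
    for o in col.observations:
        if o.symbol == "N":
            continue
        q = o.quality
        if o.symbol == GAP:
            flanks = [f for f in o.flank_qualities if f is not None]
            if flanks:
                q = min(flanks)
        tally.setdefault(o.symbol, []).append((q, o.platform))
    depth = sum(len(v) for v in tally.values())

    def passes(allele, min_support, top_k, quality_sum):
        entries = tally[allele]
        if len(entries) < min_support:
            return False
        quals = sorted((q for q, _ in entries), reverse=True)
        return sum(quals[:top_k]) >= quality_sum

    def homopolymer_ok(alleles):
        if GAP not in alleles:
            return True
        base = col.consensus
        if base not in "ACGT":
            non_gap = {a: len(tally[a]) for a in tally if a in "ACGT"}
            if not non_gap:
                return True
            base = sorted(non_gap, key=lambda a: (-non_gap[a], a))[0]
        run = 1
        for ch in reversed(col.left_context):
            if ch != base:
                break
            run += 1
        for ch in col.right_context:
            if ch != base:
                break
            run += 1
        if run < cfg.homopolymer_min_run:
            return True
        return all(
            any(p == cfg.short_read_platform for _, p in tally[a]) for a in alleles
        )

    strong = [
        a
        for a in tally
        if passes(a, cfg.strong_min_support, cfg.strong_top_k, cfg.strong_quality_sum)
    ]
    if len(strong) >= 2 and depth <= cfg.strong_max_depth and homopolymer_ok(strong):
        return "strong"
    weak = [
        a
        for a in tally
        if passes(a, cfg.weak_min_support, cfg.weak_top_k, cfg.weak_quality_sum)
    ]
    if len(weak) >= 2 and homopolymer_ok(weak):
        return "weak"
    return "none"


@pytest.fixture
def thresholds() -> SNVThresholds:
    return SNVThresholds()
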