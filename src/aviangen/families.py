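"""Gene-family assignment and copy-number rate-of-change analysis.

Genes are assigned to reference families by best similarity hit passing
strict thresholds (similarity strictly above 75%, alignment covering
strictly more than 25% of the query).  Family copy numbers across species
are converted to rates of change relative to a reference species,
R_ij = (n_ij - n_ih) / T_jh copies per million years (T_jh the divergence
time between species j and the reference h), families sharing the same
cross-species rate pattern are grouped (rate pattern groups, RPGs), and
lineage-specific presence/absence reports cover e.g. bird-specific or
egg-laying-specific families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SimilarityHit:
    gene_id: str
    reference_gene: str
    reference_family: str
    percent_similarity: float  # [0, 100]
    alignment_coverage: float  # fraction of the query covered, [0, 1]

    def __post_init__(self) -> None:
        if not 0 <= self.percent_similarity <= 100:
            raise ValueError("percent_similarity outside [0,100]")
        if not 0 <= self.alignment_coverage <= 1:
            raise ValueError("alignment_coverage outside [0,1]")


@dataclass(frozen=True)
class AssignmentThresholds:
    min_similarity: float = 75.0  # strict: similarity must exceed this
    min_coverage: float = 0.25  # strict: coverage must exceed this


DEFAULT_ASSIGNMENT = AssignmentThresholds()


def assign_family(
    hits: Sequence[SimilarityHit], thresholds: AssignmentThresholds = DEFAULT_ASSIGNMENT
) -> str:
    """Family of the best hit passing the strict thresholds, or
    ``"unassigned"``.  Ties break by higher similarity, then lexicographic
    family id."""
    passing = [
        h
        for h in hits
        if h.percent_similarity > thresholds.min_similarity
        and h.alignment_coverage > thresholds.min_coverage
    ]
    if not passing:
        return UNASSIGNED
    best = min(passing, key=lambda h: (-h.percent_similarity, h.reference_family))
    return best.reference_family


def default_rate(n_ij: int, n_ih: int, t_jh: float) -> float:
    """Copy-number change per million years relative to the reference."""
    return (n_ij - n_ih) / t_jh


def rate_matrix(
    matrix: pd.DataFrame,
    divergence_times: Mapping[str, float] | None = None,
    reference: str | None = None,
    rate_fn: Callable[[int, int, float], float] = default_rate,
) -> pd.DataFrame:
    """Per-family, per-species rate of copy-number change.

    ``matrix`` is families x species (integer counts); divergence times and
    the reference species default to the frame's ``attrs`` (as produced by
    the synthetic generator).  The reference column is identically 0.
    ``rate_fn`` is pluggable — the default is the absolute copy-number
    difference per million years.
    """
    times = dict(divergence_times or matrix.attrs.get("divergence_times", {}))
    ref = reference or matrix.attrs.get("reference")
    if ref is None or ref not in matrix.columns:
        raise ValueError("reference species not given or absent from the matrix")
    missing = [c for c in matrix.columns if c != ref and c not in times]
    if missing:
        raise KeyError(f"missing divergence times for {missing}")
    bad = [c for c in matrix.columns if c != ref and times[c] <= 0]
    if bad:
        raise ValueError(f"non-positive divergence time for {bad}")
    rates = pd.DataFrame(0.0, index=matrix.index, columns=matrix.columns)
    ref_counts = matrix[ref]
    for col in matrix.columns:
        if col == ref:
            continue
        rates[col] = [
            rate_fn(int(nij), int(nih), times[col])
            for nij, nih in zip(matrix[col], ref_counts)
        ]
    rates.attrs["reference"] = ref
    return rates


def _sign_key(row: pd.Series, reference: str) -> tuple:
    return tuple(
        "=" if row[c] == 0 else ("+" if row[c] > 0 else "-")
        for c in row.index
        if c != reference
    )


def _ranking_key(row: pd.Series, reference: str) -> tuple:
    cols = [c for c in row.index if c != reference]
    return tuple(sorted(cols, key=lambda c: (-row[c], c)))


def rpg_group(rates: pd.DataFrame, mode: str = "sign") -> pd.DataFrame:
    """Group families into rate pattern groups (RPGs).

    ``mode="sign"`` keys each family by its per-species
    expanded/contracted/equal signature; ``mode="ranking"`` keys by the
    species order sorted by rate (descending, ties by species name).
    Returns a frame with family_id, pattern and group id; groups partition
    the families.
    """
    ref = rates.attrs.get("reference")
    keyfn = {"sign": _sign_key, "ranking": _ranking_key}.get(mode)
    if keyfn is None:
        raise ValueError(f"unknown RPG mode {mode!r}")
    keys = {fam: keyfn(rates.loc[fam], ref) for fam in rates.index}
    pattern_ids: dict[tuple, int] = {}
    rows = []
    for fam in rates.index:
        key = keys[fam]
        if key not in pattern_ids:
            pattern_ids[key] = len(pattern_ids)
        rows.append(
            {
                "family_id": fam,
                "pattern": "|".join(map(str, key)),
                "group": pattern_ids[key],
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "pattern", "group"])


def lineage_specific_families(
    matrix: pd.DataFrame,
    focal: Iterable[str],
    background: Iterable[str],
    presence_threshold: int = 1,
) -> tuple[list[str], list[str]]:
    """Families private to, or completely lost from, a species group.

    ``present_only``: copy number >= ``presence_threshold`` in every focal
    species and 0 in every background species.  ``absent_only``: the
    converse.  The focal and background sets must be disjoint; species not
    listed in either are ignored, so the same matrix serves bird-specific,
    turkey/chicken-specific and egg-laying (birds + platypus vs eutherians)
    reports.
    """
    focal = list(focal)
    background = list(background)
    if set(focal) & set(background):
        raise ValueError("focal and background sets overlap")
    for sp in focal + background:
        if sp not in matrix.columns:
            raise KeyError(f"species {sp} not in matrix")
    f = matrix[focal].to_numpy()
    b = matrix[background].to_numpy()
    present_only = (f >= presence_threshold).all(axis=1) & (b == 0).all(axis=1)
    absent_only = (f == 0).all(axis=1) & (b >= presence_threshold).all(axis=1)
    idx = np.asarray(matrix.index)
    return list(idx[present_only]), list(idx[absent_only])
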