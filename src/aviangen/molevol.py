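"""Lineage-acceleration (Devog) statistics and related group comparisons.

A "differentially evolved gene" (Devog) is one whose log-transformed dN/dS
(omega) between the two focal birds deviates significantly from the spread
of pairwise mammalian log-omega values for the same gene.  Because each
gene has a single avian pair value, the test is a one-sample two-sided
Student t of the mammalian log-omega sample against the avian value as the
hypothesized mean.  Benjamini-Hochberg step-up controls the FDR across
genes, and a paired t on turkey-mammal versus chicken-mammal log-omega
assigns accelerated genes to a lineage.

The module also houses the Wilcoxon rank-sum comparison used for group
contrasts (innate-immune vs other genes; Z-linked vs autosomal "fast-Z"),
chromosome-size trends of dS/dN/omega, one-sided hypergeometric GO-term
over-representation, and average-linkage clustering of GO terms under an
overlap dissimilarity d(X,Y) = 1 - |N(X) ∩ N(Y)| / min(|N(X)|, |N(Y)|)
computed on the Devog membership sets N(·).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

EXCLUDED = "excluded"
AVIAN_SPECIES = ("turkey", "chicken")


@dataclass
class PairOmega:
    dN: float
    dS: float
    omega: float


@dataclass
class GeneOmegaProfile:
    """Per-gene omega values keyed by species-pair label, with pair roles."""

    gene_id: str
    omega: dict[str, PairOmega]
    avian_pair: str
    mammal_pairs: list[str]
    avian_mammal_pairs: dict[str, list[str]] = field(default_factory=dict)
    # avian_mammal_pairs: bird species -> pair labels ordered by mammal name


@dataclass
class DevogResult:
    gene_id: str
    t_statistic: float
    p_value: float
    adjusted_p: float
    accelerated: bool
    lineage: str  # turkey | chicken | none
    lineage_p: float | None
    degenerate: bool = False


class TestOutcome(NamedTuple):
    t: float
    p: float
    degenerate: bool


class PairedOutcome(NamedTuple):
    t: float
    p: float
    direction: str
    degenerate: bool


def profiles_from_table(
    table: pd.DataFrame, avian: Sequence[str] = AVIAN_SPECIES
) -> list[GeneOmegaProfile]:
    """Build per-gene profiles from a long (gene_id, pair, dN, dS, omega)
    table; pair roles are derived from the ``"a:b"`` pair labels."""
    avian_set = set(avian)
    profiles = []
    for gene, grp in table.groupby("gene_id", sort=True):
        omega: dict[str, PairOmega] = {}
        avian_pair = None
        mammal_pairs: list[str] = []
        avian_mammal: dict[str, list[str]] = {sp: [] for sp in avian}
        for r in grp.itertuples():
            omega[r.pair] = PairOmega(dN=r.dN, dS=r.dS, omega=r.omega)
            species = set(r.pair.split(":"))
            if species <= avian_set:
                avian_pair = r.pair
            elif species & avian_set:
                (bird,) = species & avian_set
                avian_mammal[bird].append(r.pair)
            else:
                mammal_pairs.append(r.pair)
        if avian_pair is None:
            continue
        for sp in avian_mammal:
            avian_mammal[sp].sort(key=lambda lab: sorted(lab.split(":")))
        profiles.append(
            GeneOmegaProfile(
                gene_id=gene,
                omega=omega,
                avian_pair=avian_pair,
                mammal_pairs=sorted(mammal_pairs),
                avian_mammal_pairs=avian_mammal,
            )
        )
    return profiles


def safe_log_omega(omega_value: float, policy: str = "exclude") -> float | str:
    """Natural log of an omega value; omega = 0 (or an undefined ratio from
    dS = 0) cannot be log-transformed and is excluded under the default
    policy."""
    if omega_value is None or (isinstance(omega_value, float) and math.isnan(omega_value)):
        return EXCLUDED
    if omega_value < 0:
        raise ValueError("negative omega")
    if omega_value == 0:
        if policy == "exclude":
            return EXCLUDED
        raise ValueError(f"unknown zero-omega policy {policy!r}")
    return math.log(omega_value)


def devog_gene_test(profile: GeneOmegaProfile) -> TestOutcome:
    """One-sample two-sided t of the mammalian log-omega sample against the
    avian-pair log-omega as hypothesized mean (df = n_mammal_pairs - 1).

    All mammal values equal to the avian value give (t=0, p=1); equal to
    each other but different from the avian value is a degenerate outcome
    (flagged, p=0).
    """
    avian = safe_log_omega(profile.omega[profile.avian_pair].omega)
    if avian is EXCLUDED:
        raise ValueError(f"avian log-omega undefined for {profile.gene_id}")
    mammal = [
        lo
        for p in profile.mammal_pairs
        if (lo := safe_log_omega(profile.omega[p].omega)) is not EXCLUDED
    ]
    if len(mammal) < 2:
        raise ValueError(f"need >=2 mammalian log-omega values for {profile.gene_id}")
    arr = np.asarray(mammal, dtype=float)
    if np.ptp(arr) == 0:
        if arr[0] == avian:
            return TestOutcome(0.0, 1.0, False)
        return TestOutcome(math.copysign(math.inf, arr[0] - avian), 0.0, True)
    res = stats.ttest_1samp(arr, popmean=avian)
    return TestOutcome(float(res.statistic), float(res.pvalue), False)


def lineage_paired_test(
    turkey_mammal: Mapping[str, float], chicken_mammal: Mapping[str, float]
) -> PairedOutcome:
    """Paired two-sided t on per-mammal log-omega differences
    (turkey-mammal minus chicken-mammal); direction is the lineage with the
    larger mean log-omega."""
    if set(turkey_mammal) != set(chicken_mammal):
        raise ValueError("mammal species keys differ between lineages")
    keys = sorted(turkey_mammal)
    if len(keys) < 2:
        raise ValueError("need >=2 paired mammal values")
    diffs = np.array([turkey_mammal[k] - chicken_mammal[k] for k in keys])
    mean = float(diffs.mean())
    direction = "none" if mean == 0 else ("turkey" if mean > 0 else "chicken")
    if np.ptp(diffs) == 0:
        if mean == 0:
            return PairedOutcome(0.0, 1.0, "none", False)
        return PairedOutcome(math.copysign(math.inf, mean), 0.0, direction, True)
    res = stats.ttest_1samp(diffs, popmean=0.0)
    return PairedOutcome(float(res.statistic), float(res.pvalue), direction, False)


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with the
    input."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def call_devogs(
    profiles: Sequence[GeneOmegaProfile], q: float = 0.05
) -> list[DevogResult]:
    """Run the Devog scan: per-gene t test, BH adjustment across genes,
    acceleration call at adjusted p < q, and lineage assignment for
    accelerated genes via the paired turkey/chicken-versus-mammal test.

    Genes whose avian omega cannot be log-transformed (omega or dS of 0)
    are excluded before testing.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0,1]")
    tested: list[tuple[GeneOmegaProfile, TestOutcome]] = []
    for prof in profiles:
        if safe_log_omega(prof.omega[prof.avian_pair].omega) is EXCLUDED:
            continue
        try:
            outcome = devog_gene_test(prof)
        except ValueError:
            continue
        tested.append((prof, outcome))
    adjusted = adjust_bh([o.p for _, o in tested])
    results = []
    for (prof, outcome), adj in zip(tested, adjusted):
        accelerated = adj < q
        lineage = "none"
        lineage_p = None
        if accelerated and prof.avian_mammal_pairs:
            sides = {}
            for bird, labels in prof.avian_mammal_pairs.items():
                vals = {}
                for lab in labels:
                    mammal = next(s for s in lab.split(":") if s != bird)
                    lo = safe_log_omega(prof.omega[lab].omega)
                    if lo is not EXCLUDED:
                        vals[mammal] = lo
                sides[bird] = vals
            turkey = sides.get("turkey", {})
            chicken = sides.get("chicken", {})
            shared = set(turkey) & set(chicken)
            if len(shared) >= 2:
                paired = lineage_paired_test(
                    {k: turkey[k] for k in shared}, {k: chicken[k] for k in shared}
                )
                lineage = paired.direction
                lineage_p = paired.p
        results.append(
            DevogResult(
                gene_id=prof.gene_id,
                t_statistic=outcome.t,
                p_value=outcome.p,
                adjusted_p=adj,
                accelerated=accelerated,
                lineage=lineage,
                lineage_p=lineage_p,
                degenerate=outcome.degenerate,
            )
        )
    return results


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def wilcoxon_group_compare(
    group_a: Sequence[float], group_b: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two value groups.

    Midranks handle ties.  ``mode="exact"`` enumerates all label
    assignments (p is the probability of a rank-sum at least as far from
    its mean as observed); ``"approximate"`` uses the tie-corrected normal
    approximation; ``"auto"`` picks exact for n_a + n_b <= 12.
    Returns (W, p) with W the rank-sum of group A.
    """
    a = list(map(float, group_a))
    b = list(map(float, group_b))
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    n_a, n = len(a), len(a) + len(b)
    if mode == "auto":
        mode = "exact" if n <= 12 else "approximate"
    ranks = stats.rankdata(a + b)
    w_obs = float(ranks[:n_a].sum())
    if mode == "exact":
        mean_w = n_a * (n + 1) / 2.0
        dev = abs(w_obs - mean_w)
        hits = total = 0
        for combo in itertools.combinations(range(n), n_a):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean_w) >= dev - 1e-9:
                hits += 1
        return w_obs, hits / total
    if mode == "approximate":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return w_obs, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TrendResult:
    statistic: str
    medians: list[float]
    log2_lengths: list[float]
    pearson: float
    spearman: float
    slope: float


def size_trend(
    per_chromosome: Sequence[tuple[float, Sequence[float]]], statistic: str = "omega"
) -> TrendResult:
    """Per-chromosome medians of an evolutionary statistic against
    log2(chromosome length): Pearson and Spearman correlations plus the
    least-squares slope."""
    if len(per_chromosome) < 3:
        raise ValueError("need at least 3 chromosomes")
    lengths, values = zip(*per_chromosome)
    medians = [float(np.median(v)) for v in values]
    log_len = [math.log2(l) for l in lengths]
    if np.ptp(medians) == 0:
        pearson = spearman = 0.0
        slope = 0.0
    else:
        pearson = float(stats.pearsonr(log_len, medians).statistic)
        spearman = float(stats.spearmanr(log_len, medians).statistic)
        slope = float(stats.linregress(log_len, medians).slope)
    return TrendResult(
        statistic=statistic,
        medians=medians,
        log2_lengths=log_len,
        pearson=pearson,
        spearman=spearman,
        slope=slope,
    )


# ---------------------------------------------------------------------------
# GO-term enrichment and clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GOTermSet:
    term_id: str
    genes: frozenset[str]


def go_overrepresentation(
    devog_genes: set[str], background: set[str], terms: Sequence[GOTermSet]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each term among the
    Devog genes, BH-adjusted across terms.

    Returns a frame with term_id, term size, Devog overlap k, p and
    adjusted_p.
    """
    if not devog_genes <= background:
        raise ValueError("devog genes must be a subset of the background")
    M, N = len(background), len(devog_genes)
    rows = []
    for term in terms:
        if not term.genes <= background:
            raise ValueError(f"term {term.term_id} has genes outside the background")
        n = len(term.genes)
        k = len(term.genes & devog_genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append({"term_id": term.term_id, "term_size": n, "overlap": k, "p": p})
    df = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap", "p"])
    df["adjusted_p"] = adjust_bh(df["p"]) if len(df) else []
    return df


def go_dissimilarity(x: GOTermSet, y: GOTermSet) -> float:
    """Overlap dissimilarity between two terms' Devog sets:
    d = 1 - |N(X) ∩ N(Y)| / min(|N(X)|, |N(Y)|)."""
    if not x.genes or not y.genes:
        raise ValueError("both term sets must be non-empty")
    return 1.0 - len(x.genes & y.genes) / min(len(x.genes), len(y.genes))


def dissimilarity_matrix(
    terms: Sequence[GOTermSet],
    metric: Callable[[GOTermSet, GOTermSet], float] = go_dissimilarity,
) -> np.ndarray:
    n = len(terms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = metric(terms[i], terms[j])
    return d


def average_linkage_cluster(dissimilarity: np.ndarray) -> np.ndarray:
    """Agglomerative average-linkage (UPGMA) merge tree of a symmetric
    zero-diagonal dissimilarity matrix, in SciPy linkage format."""
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    if d.shape[0] < 2:
        return np.empty((0, 4))
    return linkage(squareform(d, checks=False), method="average")


def cluster_to_newick(merge_tree: np.ndarray, labels: Sequence[str]) -> str:
    """Newick rendering of a SciPy merge tree (branch lengths from merge
    heights)."""
    if len(merge_tree) == 0:
        if len(labels) == 1:
            return f"{labels[0]};"
        raise ValueError("empty merge tree for multiple items")
    root = to_tree(merge_tree)

    def quote(label: str) -> str:
        if any(ch in label for ch in ":,;()[] '"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{quote(labels[node.id])}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
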