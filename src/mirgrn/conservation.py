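"""Cross-group conservation classification and comparative statistics.

A family is *conserved* when at least one member locus is detected in every
vertebrate group analyzed, *group-specific* when detected exclusively in one
group, and *shared-subset* otherwise; families never detected anywhere are
excluded (presence here is an expression concept, not a genomic one).  The
module also enumerates Venn regions over group combinations, tests the
significance of multi-set intersections with an exact iterated-hypergeometric
test (the k-set generalization of Fisher's one-sided exact test), and
compares conserved against group-specific families by expression level and
putative target count with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

ALPHA_INTERSECTION = 0.005   # significance threshold for intersection tests


# ---------------------------------------------------------------------------
# Presence and labels


def presence_matrix(
    loci: pd.DataFrame,
    flags: pd.DataFrame,
    groups: dict[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Family x group detection matrix.

    ``loci`` has columns locus_id, species, family; ``flags`` is the boolean
    locus x species detection matrix; ``groups`` maps species -> group (each
    species to exactly one group).  presence(f, g) is true when any member
    locus of f is detected in any species of g; provenance records which
    species triggered each presence.
    """
    species_seen = set(loci["species"])
    for sp in species_seen:
        if sp not in groups:
            raise ValueError(f"species {sp!r} is not mapped to a group")
    group_names = list(dict.fromkeys(groups.values()))
    families = list(dict.fromkeys(loci["family"]))
    presence = pd.DataFrame(False, index=families, columns=group_names)
    provenance: dict[tuple[str, str], list[str]] = {}
    for _, row in loci.iterrows():
        locus, sp, fam = row["locus_id"], row["species"], row["family"]
        if not fam:
            continue
        if locus in flags.index and sp in flags.columns and bool(flags.loc[locus, sp]):
            g = groups[sp]
            presence.loc[fam, g] = True
            provenance.setdefault((fam, g), [])
            if sp not in provenance[(fam, g)]:
                provenance[(fam, g)].append(sp)
    return presence, provenance


def classify_conservation(presence: pd.DataFrame) -> dict[str, str]:
    """Label each family from its presence row; all-false rows are excluded."""
    labels: dict[str, str] = {}
    for fam, row in presence.iterrows():
        ngroups = int(row.sum())
        if ngroups == 0:
            continue
        if ngroups == len(presence.columns):
            labels[fam] = "conserved"
        elif ngroups == 1:
            labels[fam] = f"group_specific:{row.index[row][0]}"
        else:
            labels[fam] = "shared_subset"
    return labels


def venn_counts(presence: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region counts over all nonempty group combinations.

    Each family is counted in exactly one region — the one matching its exact
    presence pattern — so region counts sum to the number of families with at
    least one presence.  Output keys are alphabetically sorted group tuples;
    the result is invariant to family and group input order.
    """
    groups = sorted(presence.columns)
    if len(groups) > 8:
        raise ValueError("venn enumeration limited to 8 groups")
    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, k):
            counts[combo] = 0
    for _, row in presence.iterrows():
        pattern = tuple(sorted(g for g in presence.columns if row[g]))
        if pattern:
            counts[pattern] += 1
    return counts


# ---------------------------------------------------------------------------
# Multi-set intersection exact test


@dataclass
class IntersectionResult:
    combination: tuple[str, ...]
    set_sizes: tuple[int, ...]
    observed: int
    expected: float
    p_value: float
    significant: bool


def _intersection_pmf(n: int, sizes: list[int]) -> np.ndarray:
    """Distribution of the intersection size of k independent uniform random
    subsets of fixed sizes from a universe of n, via iterated hypergeometric
    mixing: X2 ~ HG(n, n1, n2); given X_j = m, X_{j+1} ~ HG(n, m, n_{j+1})."""
    pmf = np.zeros(n + 1)
    pmf[sizes[0]] = 1.0
    for nj in sizes[1:]:
        new = np.zeros(n + 1)
        for m in np.nonzero(pmf)[0]:
            support = np.arange(0, min(m, nj) + 1)
            new[support] += pmf[m] * hypergeom.pmf(support, n, m, nj)
        pmf = new
    return pmf


def multiset_intersection_test(
    set_sizes,
    observed: int,
    universe: int,
    *,
    alpha: float = ALPHA_INTERSECTION,
    combination: tuple[str, ...] = (),
) -> IntersectionResult:
    """Exact upper-tail test P(X >= observed) for a k-set intersection.

    The expected overlap under independence is n * prod(n_i / n).  The k=2
    case reduces to the one-sided Fisher/hypergeometric tail.
    """
    sizes = [int(s) for s in set_sizes]
    n = int(universe)
    for s in sizes:
        if s < 0 or s > n:
            raise ValueError(f"set size {s} outside universe of {n}")
    if observed < 0 or (sizes and observed > min(sizes)):
        raise ValueError("observed overlap exceeds the smallest set")
    expected = n * math.prod(s / n for s in sizes) if n > 0 else 0.0
    if observed == 0:
        p = 1.0
    else:
        pmf = _intersection_pmf(n, sizes)
        p = float(pmf[observed:].sum())
        p = min(1.0, max(0.0, p))
    return IntersectionResult(tuple(combination), tuple(sizes), observed, expected, p, p < alpha)


def intersection_tests(
    presence: pd.DataFrame,
    *,
    universe: int | None = None,
    alpha: float = ALPHA_INTERSECTION,
) -> pd.DataFrame:
    """Test every group combination of size >= 2 (SuperExactTest style).

    The observed overlap for a combination is the number of families present
    in *all* its groups (a superset count, not the exclusive Venn region).
    The universe defaults to the number of distinct families observed in at
    least one group.
    """
    detected = presence.loc[presence.any(axis=1)]
    n = universe if universe is not None else len(detected)
    groups = sorted(presence.columns)
    sizes = {g: int(detected[g].sum()) for g in groups}
    rows = []
    for k in range(2, len(groups) + 1):
        for combo in itertools.combinations(groups, k):
            obs = int(detected[list(combo)].all(axis=1).sum())
            res = multiset_intersection_test(
                [sizes[g] for g in combo], obs, n, alpha=alpha, combination=combo
            )
            rows.append({
                "combination": "&".join(combo),
                "observed": res.observed,
                "expected": round(res.expected, 4),
                "p_value": res.p_value,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)


@dataclass
class RankTestResult:
    statistic: float          # U = favorable pairs for x (ties count 1/2)
    n1: int
    n2: int
    p_value: float
    alternative: str
    ties: bool


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U via the standard partition recurrence."""
    maxu = n1 * n2
    # table[j][u]: number of ways with j observations in x so far
    table = [np.zeros(maxu + 1) for _ in range(n1 + 1)]
    table[0][0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for j in range(min(i, n1), 0, -1):
            beat = i - j      # y's ranked below this new x observation
            contrib = np.zeros(maxu + 1)
            if beat <= maxu:
                contrib[beat:] = table[j - 1][: maxu + 1 - beat]
            table[j] += contrib
    return table[n1]


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Rank-sum test on U = #(x_i > y_j) + 0.5 #(x_i = y_j).

    Exact permutation p-value when n1 + n2 <= 20 and there are no ties;
    otherwise a normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    u = float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))

    combined = np.concatenate([x, y])
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 + n2 <= 20 and not has_ties:
        dist = _exact_u_counts(n1, n2)
        total = dist.sum()
        ui = int(round(u))
        p_greater = dist[ui:].sum() / total
        p_less = dist[: ui + 1].sum() / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        sigma = math.sqrt(sigma2) if sigma2 > 0 else 0.0
        if sigma == 0:
            p = 1.0
        else:
            z_greater = (u - mu - 0.5) / sigma
            z_less = (u - mu + 0.5) / sigma
            if alternative == "greater":
                p = float(norm.sf(z_greater))
            elif alternative == "less":
                p = float(norm.cdf(z_less))
            else:
                p = float(min(1.0, 2.0 * min(norm.sf(z_greater), norm.cdf(z_less))))
    return RankTestResult(u, n1, n2, float(p), alternative, has_ties)


def compare_conserved_vs_specific(
    labels: dict[str, str],
    family_expression: dict[str, float],
    family_target_counts: dict[str, int],
    *,
    alternative: str = "greater",
) -> tuple[RankTestResult, RankTestResult]:
    """Conserved vs group-specific families: expression level and target count.

    ``family_expression`` holds the per-family summary (median TMM-CPM of
    member loci across species where detected); ``family_target_counts`` the
    number of consensus target genes.  The one-sided alternative 'greater'
    tests whether conserved families exceed group-specific ones, matching the
    reported direction (higher expression, more targets for conserved).
    """
    conserved = [f for f, lab in labels.items() if lab == "conserved"]
    specific = [f for f, lab in labels.items() if lab.startswith("group_specific")]
    if not conserved or not specific:
        raise ValueError("both label classes must be nonempty; skip this comparison")
    expr_test = wilcoxon_rank_sum(
        [family_expression[f] for f in conserved if f in family_expression],
        [family_expression[f] for f in specific if f in family_expression],
        alternative=alternative,
    )
    tgt_test = wilcoxon_rank_sum(
        [family_target_counts.get(f, 0) for f in conserved],
        [family_target_counts.get(f, 0) for f in specific],
        alternative=alternative,
    )
    return expr_test, tgt_test
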