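"""Phenotype normalizations and statistics for mite resistance assays.

Covers the enclosure-assay bookkeeping (effective-female correction,
progeny-per-female rates, trapped-mite exclusion), one-way ANOVA with
Hochberg-corrected pairwise Welch t-tests and a compact letter display,
the damage-vs-productivity regression, and the single-marker genotype-class
analysis (mode of action plus variance explained among homozygotes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("RR", "Het", "SS")


@dataclass(frozen=True)
class EnclosureAssay:
    """One leaf enclosure: released females, day counts, progeny, trapped."""

    plant_id: str
    leaf_id: str = "8"
    released: int = 40
    day1_count: float | None = None
    day6_count: float | None = None
    progeny_total: int = 0
    trapped_count: int = 0

    def __post_init__(self) -> None:
        for name in ("released", "progeny_total", "trapped_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def effective_females(assay: EnclosureAssay) -> float:
    """Number of females that entered the enclosure: the greater of the
    day-1 and day-6 counts (day counts may exceed the released number when
    extra mites were captured in tips).  Both counts missing -> NaN."""
    counts = [c for c in (assay.day1_count, assay.day6_count)
              if c is not None and not (isinstance(c, float) and math.isnan(c))]
    if not counts:
        return float("nan")
    return float(max(counts))


def progeny_per_female(assays: list[EnclosureAssay], mode: str = "per_enclosure"):
    """Progeny-per-female rate(s) for one plant.

    ``per_enclosure``: each enclosure's progeny total divided by its
    effective females (NaN, flagged for exclusion, when effective females
    is zero or missing).  ``two_leaf_sum``: the summed progeny of the
    plant's enclosures divided by the fixed total of released females
    (2 x 20 = 40 in the validation design).
    """
    if mode == "two_leaf_sum":
        total = sum(a.progeny_total for a in assays)
        divisor = sum(a.released for a in assays)
        if divisor == 0:
            raise ValueError("no released females")
        return total / divisor
    if mode != "per_enclosure":
        raise ValueError(f"unknown mode {mode!r}")
    rates = []
    for a in assays:
        eff = effective_females(a)
        rates.append(a.progeny_total / eff if eff and not math.isnan(eff) else float("nan"))
    return rates


def exclusion_rule(assay: EnclosureAssay, max_trapped: int = 10) -> bool:
    """Keep the sample unless more than ``max_trapped`` mites (25% of the 40
    released) were trapped in the pipet tip.  Returns True to keep."""
    return assay.trapped_count <= max_trapped


def hochberg_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="simes-hochberg")[1]


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    letters: dict[str, str]
    group_means: dict[str, float] = field(default_factory=dict)
    group_n: dict[str, int] = field(default_factory=dict)


def _letters_from_graph(groups: list[str], nonsig: set[frozenset], means: dict[str, float]) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Groups sharing a letter are not significantly different; letters are the
    maximal cliques of the graph, ordered by the smallest group mean they
    contain so relabeling groups permutes letters but preserves the
    partition.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for pair in nonsig:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = [tuple(sorted(c, key=lambda x: (means[x], x))) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (min(means[x] for x in c), c))
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        symbol = chr(ord("a") + i) if i < 26 else f"z{i}"
        for grp in clique:
            letters[grp].append(symbol)
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def group_compare(groups: dict[str, np.ndarray], alpha: float = 0.05,
                  log_transform: bool = False) -> GroupComparison:
    """One-way ANOVA across groups; if significant, all pairwise Welch
    t-tests with Hochberg step-up correction and a compact letter display.

    A pair where both groups have zero variance (t-test degenerate) is
    flagged and treated as not significant.  NaN observations are dropped.
    """
    clean: dict[str, np.ndarray] = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if log_transform:
            arr = np.log(arr + 1.0)
        if len(arr) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
        clean[label] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    labels = list(clean)
    means = {g: float(np.mean(v)) for g, v in clean.items()}
    ns = {g: int(len(v)) for g, v in clean.items()}

    if all(np.var(v) == 0 for v in clean.values()) and len({v[0] for v in clean.values()}) == 1:
        f_stat, p_anova = 0.0, 1.0  # all observations identical
    else:
        f_stat, p_anova = stats.f_oneway(*clean.values())
        if math.isnan(p_anova):
            f_stat, p_anova = 0.0, 1.0

    pair_rows = []
    nonsig: set[frozenset] = set()
    if p_anova < alpha:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        raw = []
        degenerate = []
        for a, b in pairs:
            deg = np.var(clean[a]) == 0 and np.var(clean[b]) == 0
            if deg:
                t, p = float("nan"), float("nan")
            else:
                t, p = stats.ttest_ind(clean[a], clean[b], equal_var=False)
            raw.append(p)
            degenerate.append(deg)
        finite = np.isfinite(raw)
        adj = np.full(len(raw), np.nan)
        if finite.any():
            adj[finite] = hochberg_adjust(np.asarray(raw)[finite])
        for (a, b), p_raw, p_adj, deg in zip(pairs, raw, adj, degenerate):
            significant = bool(np.isfinite(p_adj) and p_adj < alpha)
            if not significant:
                nonsig.add(frozenset((a, b)))
            pair_rows.append({"group_a": a, "group_b": b, "p_raw": p_raw,
                              "p_adj": p_adj, "significant": significant,
                              "degenerate": deg})
            if deg:
                logger.warning("degenerate t-test for %s vs %s (zero variance)", a, b)
    else:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                nonsig.add(frozenset((labels[i], labels[j])))

    letters = _letters_from_graph(labels, nonsig, means)
    pairwise = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "p_raw",
                                                "p_adj", "significant", "degenerate"])
    return GroupComparison(float(f_stat), float(p_anova), pairwise, letters, means, ns)


def damage_productivity_fit(scores, progeny_rates) -> tuple[float, float]:
    """OLS of progeny rate on damage score: (R-squared, slope p-value)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(progeny_rates, dtype=float)
    keep = np.isfinite(s) & np.isfinite(y)
    s, y = s[keep], y[keep]
    if len(s) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(s) == 0:
        raise ValueError("zero variance in damage scores; fit undefined")
    res = stats.linregress(s, y)
    return float(res.rvalue**2), float(res.pvalue)


@dataclass
class MarkerEffectResult:
    class_means: dict[str, float]
    class_n: dict[str, int]
    letters: dict[str, str]
    mode: str | None
    r2_homozygous: float | None
    p_homozygous: float | None
    r2_homozygous_outlier_excluded: float | None
    comparison: GroupComparison | None


def _r2_homozygous(genotypes: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Squared point-biserial correlation between the RR-vs-SS indicator and
    the damage score, among homozygotes only."""
    hom = (genotypes == "RR") | (genotypes == "SS")
    x = (genotypes[hom] == "RR").astype(float)
    y = scores[hom]
    r, p = stats.pearsonr(x, y)
    return float(r**2), float(p)


def marker_effect_analysis(
    genotypes,
    damage_scores,
    alpha: float = 0.05,
    exclude_outlier: bool = False,
) -> MarkerEffectResult:
    """Genotype-class analysis at a single marker.

    Classes are compared by ANOVA + Hochberg-corrected pairwise t-tests; the
    mode of action is *recessive* when the heterozygote is indistinguishable
    from the susceptible homozygote while the resistant homozygote differs
    from both, *dominant* in the mirrored case, and *additive* when all
    three classes differ.  Variance explained is the squared point-biserial
    correlation among the homozygous classes.  With ``exclude_outlier`` the
    single most extreme residual in the resistant homozygous class is
    dropped and the homozygous R-squared recomputed (reported separately;
    never applied automatically).
    """
    g = np.asarray(genotypes, dtype=object).astype(str)
    s = np.asarray(damage_scores, dtype=float)
    keep = np.isin(g, GENOTYPE_CLASSES) & np.isfinite(s)  # missing dropped listwise
    g, s = g[keep], s[keep]
    present = [c for c in GENOTYPE_CLASSES if (g == c).sum() >= 2]
    class_means = {c: float(s[g == c].mean()) for c in GENOTYPE_CLASSES if (g == c).any()}
    class_n = {c: int((g == c).sum()) for c in GENOTYPE_CLASSES}

    comparison = None
    letters: dict[str, str] = {}
    mode: str | None = None
    if len(present) == 3:
        comparison = group_compare({c: s[g == c] for c in present}, alpha=alpha)
        letters = comparison.letters
        sig = {
            frozenset((row["group_a"], row["group_b"])): bool(row["significant"])
            for _, row in comparison.pairwise.iterrows()
        }

        def is_sig(a: str, b: str) -> bool:
            return sig.get(frozenset((a, b)), False)

        rr_het = is_sig("RR", "Het")
        rr_ss = is_sig("RR", "SS")
        het_ss = is_sig("Het", "SS")
        if rr_het and rr_ss and not het_ss:
            mode = "recessive"
        elif het_ss and rr_ss and not rr_het:
            mode = "dominant"
        elif rr_het and rr_ss and het_ss:
            mode = "additive"
        else:
            mode = "unclassified"
    else:
        logger.warning("missing genotype class; mode undeterminable")

    r2 = p_hom = None
    if class_n["RR"] >= 2 and class_n["SS"] >= 2:
        r2, p_hom = _r2_homozygous(g, s)

    r2_excl = None
    if exclude_outlier and class_n["RR"] >= 3 and class_n["SS"] >= 2:
        rr_idx = np.flatnonzero(g == "RR")
        resid = np.abs(s[rr_idx] - s[rr_idx].mean())
        drop = rr_idx[int(np.argmax(resid))]
        mask = np.ones(len(g), dtype=bool)
        mask[drop] = False
        r2_excl, _ = _r2_homozygous(g[mask], s[mask])

    return MarkerEffectResult(class_means, class_n, letters, mode, r2, p_hom, r2_excl, comparison)
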