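"""Statistical toolkit: hypergeometric enrichment, Wilcoxon rank-sum,
Spearman and partial-Spearman correlation.

All correlations are rank-based (average ranks, then Pearson). The
hypergeometric test is upper-tail (over-representation) only. Raw
p-values are reported; a Benjamini-Hochberg column is attached to
enrichment output as extra information but never used for filtering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AnnotationSet, HierarchyAssignment, HIERARCHY_LEVELS, PROMOTER_CLASSES
from .errors import ValidationError


@dataclass
class StatResult:
    """A single statistic with its two-sided p-value and sample size.

    ``estimate`` is NaN with an explanatory ``note`` when the statistic
    is undefined (e.g. a constant vector in a correlation).
    """

    name: str
    estimate: float
    p: float
    n: int
    note: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


# ---------------------------------------------------------------------------
# rank correlations
# ---------------------------------------------------------------------------

def _align(x, y, z=None):
    """Align inputs pairwise; pandas Series align on shared identifiers."""
    series = [isinstance(v, pd.Series) for v in (x, y) + ((z,) if z is not None else ())]
    if all(series):
        idx = x.index.intersection(y.index)
        if z is not None:
            idx = idx.intersection(z.index)
        idx = idx.sort_values()
        arrs = [x.loc[idx].to_numpy(float), y.loc[idx].to_numpy(float)]
        if z is not None:
            arrs.append(z.loc[idx].to_numpy(float))
        return arrs
    arrs = [np.asarray(x, float), np.asarray(y, float)]
    if z is not None:
        arrs.append(np.asarray(z, float))
    if len({len(a) for a in arrs}) != 1:
        raise ValidationError("paired vectors must have equal length")
    return arrs


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _rho_p(rho: float, n: int, df: int) -> float:
    """Two-sided p for a (partial) rank correlation via the t approximation."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p.

    Average ranks, then Pearson. For n <= 9 the p-value is an exact
    permutation tail over all n! orderings; otherwise the large-sample
    t approximation is used. Constant input yields a NaN result with a
    reason note rather than an exception.
    """
    a, b = _align(x, y)
    n = len(a)
    if n < 3:
        raise ValidationError(f"spearman requires n >= 3, got {n}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return StatResult("spearman_rho", float("nan"), float("nan"), n,
                          note="constant vector: correlation undefined")
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    rho = _pearson(ra, rb)
    if n <= 9:
        count = 0
        total = 0
        for perm in itertools.permutations(rb):
            r = _pearson(ra, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = _rho_p(rho, n, n - 2)
    return StatResult("spearman_rho", rho, p, n)


def partial_spearman(x, y, control) -> StatResult:
    """Rank-based partial correlation of x and y given one control.

    All three vectors are average-ranked; the first-order partial
    correlation formula is applied to the rank Pearson correlations.
    Undefined (NaN with note) when the control is perfectly rank
    correlated with either variable.
    """
    a, b, c = _align(x, y, control)
    n = len(a)
    if n < 4:
        raise ValidationError(f"partial_spearman requires n >= 4, got {n}")
    if np.all(a == a[0]) or np.all(b == b[0]) or np.all(c == c[0]):
        return StatResult("partial_spearman_rho", float("nan"), float("nan"), n,
                          note="constant vector: correlation undefined")
    ra, rb, rc = sps.rankdata(a), sps.rankdata(b), sps.rankdata(c)
    r_xy, r_xz, r_yz = _pearson(ra, rb), _pearson(ra, rc), _pearson(rb, rc)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        return StatResult("partial_spearman_rho", float("nan"), float("nan"), n,
                          note="control perfectly correlated with a variable")
    rho = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    rho = float(np.clip(rho, -1.0, 1.0))
    return StatResult("partial_spearman_rho", rho, _rho_p(rho, n, n - 3), n)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b) -> StatResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when the combined sample size is <= 12 and
    there are no ties; otherwise the normal approximation with tie
    correction (no continuity correction). The reported statistic is W,
    the rank sum of the first group.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("wilcoxon_rank_sum requires nonempty groups")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    w = float(res.statistic + len(a) * (len(a) + 1) / 2.0)
    return StatResult("wilcoxon_W", w, float(min(res.pvalue, 1.0)), len(combined))


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(overlap: int, universe: int, term: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    return float(min(sps.hypergeom.sf(overlap - 1, universe, term, query), 1.0))


def hypergeom_enrich(
    query: set,
    annotations: AnnotationSet,
    universe: set | None = None,
    min_term_size: int = 6,
    p_cutoff: float | None = 1e-5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set over annotation terms.

    Terms are restricted to the universe; terms with fewer than
    ``min_term_size`` genes in the universe are ignored. Results with
    p < ``p_cutoff`` (all results when ``None``) are returned sorted
    ascending by p. Columns: term, term_size, query_size, overlap, p,
    fold (observed/expected overlap), bh_fdr.
    """
    uni = set(universe) if universe is not None else set(annotations.universe)
    offenders = sorted(set(query) - uni)
    if offenders:
        raise ValidationError(f"query genes outside universe: {offenders[:10]}")
    q = set(query)
    rows = []
    for term, genes in sorted(annotations.terms.items()):
        tg = genes & uni
        if len(tg) < min_term_size:
            continue
        k = len(tg & q)
        p = hypergeom_upper_tail(k, len(uni), len(tg), len(q))
        expected = len(tg) * len(q) / len(uni)
        rows.append({
            "term": term,
            "term_size": len(tg),
            "query_size": len(q),
            "overlap": k,
            "p": p,
            "fold": (k / expected) if expected > 0 else float("nan"),
        })
    table = pd.DataFrame(rows, columns=["term", "term_size", "query_size",
                                        "overlap", "p", "fold"])
    if len(table):
        m = len(table)
        order = table["p"].rank(method="first")
        bh = (table["p"] * m / order).to_numpy()
        # enforce monotonicity of the step-up procedure
        idx = np.argsort(order.to_numpy())
        running = np.minimum.accumulate(bh[idx][::-1])[::-1]
        out_bh = np.empty(m)
        out_bh[idx] = np.minimum(running, 1.0)
        table["bh_fdr"] = out_bh
    else:
        table["bh_fdr"] = pd.Series(dtype=float)
    if p_cutoff is not None:
        table = table[table["p"] < p_cutoff]
    return table.sort_values(["p", "term"]).reset_index(drop=True)


def top_bottom_sets(ev: pd.DataFrame, k: int = 500) -> tuple[set, set]:
    """The k highest-EV and k lowest-EV genes (ties broken by gene id)."""
    n = len(ev)
    if 2 * k > n:
        raise ValidationError(f"2k={2 * k} exceeds number of genes {n}")
    ordered = ev.assign(_gene=ev.index).sort_values(["ev", "_gene"], kind="mergesort")
    low = set(ordered.index[:k])
    high = set(ordered.index[-k:])
    return high, low


def class_level_heatmap(
    assignment: HierarchyAssignment,
    classes: dict,
    levels: tuple = HIERARCHY_LEVELS,
) -> pd.DataFrame:
    """-log10 hypergeometric enrichment p of each (hierarchy level, promoter class).

    The universe is the overlap of the assignment's gene space with the
    promoter-class map. Rows = hierarchy levels, columns = classes I-IV.
    """
    uni = set(assignment.levels) & set(classes)
    if not uni:
        raise ValidationError("assignment and promoter classes share no genes")
    mat = pd.DataFrame(index=list(levels), columns=list(PROMOTER_CLASSES), dtype=float)
    for lv in levels:
        lv_genes = assignment.genes_at(lv) & uni
        for cls in PROMOTER_CLASSES:
            cls_genes = {g for g in uni if classes[g] == cls}
            k = len(lv_genes & cls_genes)
            p = hypergeom_upper_tail(k, len(uni), len(cls_genes), len(lv_genes))
            mat.loc[lv, cls] = -math.log10(max(p, 1e-300))
    mat.index.name = "level"
    return mat
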