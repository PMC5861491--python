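"""Enrichment statistics for interface placement of mutations and ddG.

The central quantity is the odds ratio

    OR = [p1 / (1 - p1)] / [p2 / (1 - p2)]

where p1 is the fraction of mutations falling in a feature (interacting
domain, contacting residues, ...) and p2 the fraction of residues belonging
to that feature over all proteins considered. Both proportions are kept as
exact fractions until display. Exact tests (Fisher, Mann-Whitney U) come
from scipy; GO relative specificity similarity (RSS) and co-expression
correlation validate network quality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_DDG_THRESHOLD = 1.5


@dataclass
class EnrichmentInput:
    """2x2 proportions input: k_obs/n_obs mutations vs k_bg/n_bg residues."""

    k_obs: int
    n_obs: int
    k_bg: int
    n_bg: int

    def __post_init__(self) -> None:
        for k, n in ((self.k_obs, self.n_obs), (self.k_bg, self.n_bg)):
            if n <= 0:
                raise ValueError("denominators must be positive")
            if not 0 <= k <= n:
                raise ValueError("require 0 <= k <= n")


@dataclass
class EnrichmentResult:
    p1: float
    p2: float
    odds_ratio: float  # may be inf/0 when a proportion is degenerate
    degenerate: bool = False
    haldane_odds_ratio: float | None = None
    fisher_p: float | None = None


def odds_ratio(inp: EnrichmentInput, haldane: bool = False) -> EnrichmentResult:
    """Feature-enrichment odds ratio from exact (un-rounded) fractions.

    p1 or p2 at 0 or 1 makes the plain ratio degenerate (0 or inf, flagged);
    ``haldane`` additionally reports the +0.5-corrected alternative.
    """
    p1 = inp.k_obs / inp.n_obs
    p2 = inp.k_bg / inp.n_bg
    degenerate = p1 in (0.0, 1.0) or p2 in (0.0, 1.0)
    if not degenerate:
        or_ = (p1 / (1 - p1)) / (p2 / (1 - p2))
    else:
        odds1 = math.inf if p1 == 1.0 else p1 / (1 - p1)
        odds2 = math.inf if p2 == 1.0 else p2 / (1 - p2)
        if odds1 == odds2:  # inf/inf or 0/0
            or_ = math.nan
        elif odds2 == 0.0 or odds1 == math.inf:
            or_ = math.inf
        elif odds2 == math.inf or odds1 == 0.0:
            or_ = 0.0
        else:  # pragma: no cover - exhausted above
            or_ = odds1 / odds2
    result = EnrichmentResult(p1=p1, p2=p2, odds_ratio=or_, degenerate=degenerate)
    if haldane:
        a, b = inp.k_obs + 0.5, inp.n_obs - inp.k_obs + 0.5
        c, d = inp.k_bg + 0.5, inp.n_bg - inp.k_bg + 0.5
        result.haldane_odds_ratio = (a / b) / (c / d)
    return result


def fisher_exact(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Hypergeometric exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p sums all tables (same margins) whose probability does not
    exceed the observed table's; ``greater`` is the upper tail on cell a.
    """
    if min(a, b, c, d) < 0 or a + b + c + d == 0:
        raise ValueError("counts must be non-negative with positive total")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    sided: str = "two",
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact permutation distribution when both samples have at most
    ``exact_max_n`` observations and no ties span the samples; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DdgRecord:
    """One interface residue with its experimental binding ddG (kcal/mol)."""

    complex_id: str
    chain: str
    position: int
    ddg: float
    contacting: bool
    in_domain: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")


@dataclass
class DdgAnalysis:
    mean_contacting: float
    mean_noncontacting: float
    table: tuple[int, int, int, int]  # (cont>thr, noncont>thr, cont<=thr, noncont<=thr)
    fraction_contacting_high: float
    fraction_contacting_low: float
    enrichment: EnrichmentResult
    fisher_greater_p: float
    fisher_two_p: float
    utest_p: float
    threshold: float


def ddg_analysis(
    records: Sequence[DdgRecord], threshold: float = DEFAULT_DDG_THRESHOLD
) -> DdgAnalysis:
    """Hot-spot analysis: is high ddG enriched on contacting residues?

    Cross-tabulates (contacting x ddG > threshold), reports class means, the
    odds ratio of the table, Fisher exact p (one- and two-sided, sidedness
    chosen as 'contacting enriched above threshold'), and the Mann-Whitney U
    p for the ddG distributions of the two contact classes.
    """
    cont = [r.ddg for r in records if r.contacting]
    non = [r.ddg for r in records if not r.contacting]
    if len(cont) < 2 or len(non) < 2:
        raise ValueError("need at least 2 records in each contact class")
    a = sum(1 for r in records if r.contacting and r.ddg > threshold)
    b = sum(1 for r in records if not r.contacting and r.ddg > threshold)
    c = len(cont) - a
    d = len(non) - b
    high, low = a + b, c + d
    frac_high = a / high if high else math.nan
    frac_low = c / low if low else math.nan
    if high and low:
        enrich = odds_ratio(EnrichmentInput(a, high, c, low), haldane=True)
    else:
        enrich = EnrichmentResult(
            p1=frac_high, p2=frac_low, odds_ratio=math.nan, degenerate=True
        )
    _, u_p = mann_whitney_u(cont, non, sided="two")
    return DdgAnalysis(
        mean_contacting=float(np.mean(cont)),
        mean_noncontacting=float(np.mean(non)),
        table=(a, b, c, d),
        fraction_contacting_high=frac_high,
        fraction_contacting_low=frac_low,
        enrichment=enrich,
        fisher_greater_p=fisher_exact(a, b, c, d, "greater"),
        fisher_two_p=fisher_exact(a, b, c, d, "two"),
        utest_p=u_p,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# GO relative specificity similarity (RSS)
# ---------------------------------------------------------------------------

GO_ASPECT_NAMESPACE = {
    "BP": "biological_process",
    "CC": "cellular_component",
    "MF": "molecular_function",
}


@dataclass
class RssScore:
    aspect: str
    value: float
    defined: bool = True


class GoDag:
    """A GO aspect DAG with depth and ancestor caches.

    Built from an obonet graph (edges point child -> parent). Depth is the
    longest is_a path from the aspect root down to the term.
    """

    def __init__(self, graph: nx.MultiDiGraph, aspect: str = "BP") -> None:
        ns = GO_ASPECT_NAMESPACE.get(aspect, aspect)
        keep = [
            n for n, d in graph.nodes(data=True)
            if d.get("namespace", ns) == ns
        ]
        sub = graph.subgraph(keep)
        self.aspect = aspect
        self.parents: dict[str, set[str]] = {
            n: {v for _, v, k in sub.out_edges(n, keys=True) if k == "is_a"} for n in sub
        }
        roots = [n for n, ps in self.parents.items() if not ps]
        if not roots:
            raise ValueError(f"no root found for aspect {aspect!r}")
        self.root = min(roots)
        self._ancestors: dict[str, dict[str, int]] = {}
        self._depth: dict[str, int] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> dict[str, int]:
        """All ancestors (term included) with shortest up-path distance."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        dist = {term: 0}
        frontier = [term]
        while frontier:
            nxt = []
            for t in frontier:
                for p in self.parents.get(t, ()):
                    if p not in dist or dist[t] + 1 < dist[p]:
                        dist[p] = dist[t] + 1
                        nxt.append(p)
            frontier = nxt
        self._ancestors[term] = dist
        return dist

    def depth(self, term: str) -> int:
        """Longest is_a path from the root to the term."""
        if term in self._depth:
            return self._depth[term]
        parents = self.parents.get(term, set())
        d = 0 if not parents else 1 + max(self.depth(p) for p in parents)
        self._depth[term] = d
        return d


def rss_term_pair(dag: GoDag, t1: str, t2: str) -> float:
    """Depth/LCA specificity score of one GO term pair.

    rss = depth(c) / (depth(c) + d1 + d2) with c the deepest common
    ancestor and d_i the shortest up-path distance from t_i to c.
    Identical non-root terms score 1; pairs whose only common ancestor is
    the aspect root score 0.
    """
    anc1, anc2 = dag.ancestors(t1), dag.ancestors(t2)
    common = set(anc1) & set(anc2)
    if not common:
        return 0.0
    c = max(common, key=lambda t: (dag.depth(t), t))
    dc = dag.depth(c)
    if dc == 0:
        return 0.0
    return dc / (dc + anc1[c] + anc2[c])


def rss_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    dag: GoDag,
) -> RssScore:
    """Protein-pair RSS: maximum term-pair score within one GO aspect.

    Terms absent from the aspect DAG are skipped with a warning; if either
    set is empty after filtering the score is undefined (flagged).
    """
    terms_a, terms_b = list(terms_a), list(terms_b)
    ta = [t for t in terms_a if t in dag]
    tb = [t for t in terms_b if t in dag]
    for t in sorted(set(terms_a + terms_b) - set(ta) - set(tb)):
        logger.warning("GO term %s absent from %s DAG; skipped", t, dag.aspect)
    if not ta or not tb:
        return RssScore(aspect=dag.aspect, value=math.nan, defined=False)
    best = max(rss_term_pair(dag, x, y) for x in ta for y in tb)
    return RssScore(aspect=dag.aspect, value=best)


def read_annotations(stream: IO[str] | str) -> dict[str, set[str]]:
    """Read protein -> GO term sets from GAF 2.x or 2-column TSV."""
    df = pd.read_csv(stream, sep="\t", header=None, comment="!", dtype=str)
    if df.shape[1] >= 15:  # GAF 2.x: DB, DB_Object_ID, Symbol, Qualifier, GO_ID, ...
        pairs = df[[1, 4]]
    elif df.shape[1] >= 2:
        pairs = df[[0, 1]]
    else:
        raise ValueError("annotation file needs at least two columns")
    out: dict[str, set[str]] = {}
    for pid, term in pairs.itertuples(index=False):
        out.setdefault(str(pid), set()).add(str(term))
    return out


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionSummary:
    mean_correlation: float
    n_computed: int
    n_uncovered: int
    n_skipped_constant: int
    per_edge: pd.DataFrame = field(repr=False, default=None)


def coexpression(
    edges: Iterable[tuple[str, str]],
    expression: pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = True,
    min_samples: int = 3,
) -> CoexpressionSummary:
    """Per-edge expression correlation over shared samples.

    ``expression`` is genes x samples. Values are log2(x+1)-transformed
    before a Pearson correlation by default (``method='spearman'`` to rank).
    Edges with an unmeasured endpoint count as uncovered; constant vectors
    are skipped and flagged.
    """
    if expression.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    mat = np.log2(expression.astype(float) + 1.0) if log_transform else expression.astype(float)
    rows = []
    n_uncovered = n_constant = 0
    for a, b in edges:
        if a not in mat.index or b not in mat.index:
            n_uncovered += 1
            continue
        va, vb = mat.loc[a].to_numpy(), mat.loc[b].to_numpy()
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            n_constant += 1
            continue
        if method == "pearson":
            r = float(sps.pearsonr(va, vb).statistic)
        elif method == "spearman":
            r = float(sps.spearmanr(va, vb).statistic)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"protein_a": a, "protein_b": b, "r": r})
    per_edge = pd.DataFrame(rows, columns=["protein_a", "protein_b", "r"])
    mean_r = float(per_edge["r"].mean()) if len(per_edge) else math.nan
    return CoexpressionSummary(
        mean_correlation=mean_r,
        n_computed=len(per_edge),
        n_uncovered=n_uncovered,
        n_skipped_constant=n_constant,
        per_edge=per_edge,
    )
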