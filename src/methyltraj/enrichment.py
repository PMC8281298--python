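"""Genomic-feature and gene-set enrichment for trajectory signatures.

Feature enrichment tests each annotation category (gene-region group or
CpG-island relation) with a two-sided Fisher's exact test of signature
membership against the tested universe.  Gene-set enrichment corrects for the
uneven number of probes per gene: a gene's chance of containing a significant
probe grows with its probe count, so the null is a Wallenius noncentral
hypergeometric distribution whose odds come from a smoothed probability-
weight function of probe count (the missMethyl approach).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


@dataclass
class ContingencyTable:
    """2x2 counts: a = signature & category, b = signature & not category,
    c = background-only & category, d = background-only & not category."""

    a: int
    b: int
    c: int
    d: int

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else (0.0 if self.a == 0 else np.inf)
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class FeatureEnrichmentResult:
    category: str
    odds_ratio: float
    pvalue: float
    counts: ContingencyTable


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable than the
    observed one (with a small tie tolerance)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise EnrichmentError("negative counts")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("degenerate margin; p = 1")
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(np.clip(probs[probs <= p_obs * (1 + 1e-7)].sum(), 0.0, 1.0))


def feature_enrichment(signature_probes: Iterable[str], universe_probes: Iterable[str],
                       annotation: pd.DataFrame, category_field: str) -> List[FeatureEnrichmentResult]:
    """Per-category Fisher enrichment of the signature within the universe.

    The universe should be the set of tested loci (e.g. the MAD-selected
    subset); each category of ``annotation[category_field]`` gets a 2x2 table,
    a cross-product odds ratio and a two-sided exact p.
    """
    sig = set(signature_probes)
    uni = list(dict.fromkeys(universe_probes))
    if not sig or not uni:
        raise EnrichmentError("empty signature or universe")
    if not sig <= set(uni):
        raise EnrichmentError("signature must be a subset of the universe")
    cats = annotation.loc[[p for p in uni if p in annotation.index], category_field]
    results = []
    for cat in sorted(cats.unique()):
        in_cat = set(cats.index[cats == cat])
        a = len(sig & in_cat)
        b = len(sig) - a
        c = len(in_cat) - a
        d = len(cats) - len(sig) - c
        tab = ContingencyTable(a, b, c, d)
        results.append(FeatureEnrichmentResult(
            category=str(cat),
            odds_ratio=tab.odds_ratio(),
            pvalue=fisher_exact_two_sided(tab),
            counts=tab,
        ))
    return results


def map_probes_to_genes(probes: Iterable[str], annotation: pd.DataFrame) -> Dict[str, int]:
    """Gene symbols hit by the probes, with per-gene probe counts.

    A probe may annotate to several ';'-separated genes; probes with no gene
    contribute nothing.
    """
    counts: Dict[str, int] = {}
    ann = annotation["gene_symbols"]
    for p in probes:
        if p not in ann.index:
            continue
        val = ann.loc[p]
        if not isinstance(val, str) or not val:
            continue
        for g in val.split(";"):
            if g:
                counts[g] = counts.get(g, 0) + 1
    return counts


def _probability_weight(probe_counts: np.ndarray, significant: np.ndarray,
                        window: Optional[int] = None) -> np.ndarray:
    """Smoothed per-gene selection probability as a function of probe count:
    moving average of the significance indicator over probe-count-ordered
    genes."""
    n = len(probe_counts)
    if window is None:
        window = max(5, min(101, (n // 10) | 1))
    if window % 2 == 0:
        window += 1
    order = np.argsort(probe_counts, kind="stable")
    ind = significant[order].astype(float)
    kernel = np.ones(window) / window
    padded = np.concatenate([np.full(window // 2, ind[0] if n else 0.0), ind,
                             np.full(window // 2, ind[-1] if n else 0.0)])
    sm = np.convolve(padded, kernel, mode="valid")
    # the weight must be a function of the covariate: average over tied counts
    sorted_counts = probe_counts[order]
    uniq, inv = np.unique(sorted_counts, return_inverse=True)
    means = np.bincount(inv, weights=sm) / np.bincount(inv)
    sm = means[inv]
    pwf = np.empty(n)
    pwf[order] = np.clip(sm, 1e-6, 1 - 1e-6)
    return pwf


@dataclass
class GeneSetResult:
    set_id: str
    n_genes_in_set: int
    n_significant_genes: int
    odds: float
    pvalue: float
    fdr_q: float = np.nan


def go_enrichment_bias_adjusted(significant_genes: Iterable[str],
                                gene_probe_counts: Dict[str, int],
                                gene_sets: Dict[str, Sequence[str]],
                                pwf_window: Optional[int] = None) -> List[GeneSetResult]:
    """Probe-bias-adjusted gene-set enrichment.

    ``gene_probe_counts`` defines the gene universe (genes with >= 1 tested
    probe) and the bias covariate.  For each set, the tail probability of
    drawing at least the observed number of significant in-set genes follows
    a Wallenius noncentral hypergeometric whose odds parameter is the ratio
    of mean smoothed selection probabilities in- vs out-of-set, converted to
    odds form.  P-values are then BH-corrected across sets.
    """
    universe = sorted(gene_probe_counts)
    if not universe:
        raise EnrichmentError("empty gene universe")
    counts = np.array([gene_probe_counts[g] for g in universe], dtype=float)
    sig = set(significant_genes) & set(universe)
    sig_ind = np.array([g in sig for g in universe])
    n_sig = int(sig_ind.sum())

    results: List[GeneSetResult] = []
    if n_sig == 0:
        for sid, members in gene_sets.items():
            m = len(set(members) & set(universe))
            if m == 0:
                continue
            results.append(GeneSetResult(sid, m, 0, 1.0, 1.0))
        _attach_bh(results)
        return results

    pwf = _probability_weight(counts, sig_ind, window=pwf_window)
    uni_set = set(universe)
    gene_pos = {g: i for i, g in enumerate(universe)}
    for sid, members in gene_sets.items():
        in_set = sorted(set(members) & uni_set)
        m = len(in_set)
        if m == 0:
            continue
        idx = np.array([gene_pos[g] for g in in_set])
        x = int(sig_ind[idx].sum())
        p_in = pwf[idx].mean()
        mask = np.ones(len(universe), dtype=bool)
        mask[idx] = False
        p_out = pwf[mask].mean() if mask.any() else p_in
        odds = (p_in / (1 - p_in)) / (p_out / (1 - p_out))
        if abs(odds - 1.0) < 1e-12 or not mask.any():
            pval = float(stats.hypergeom.sf(x - 1, len(universe), m, n_sig))
        else:
            dist = stats.nchypergeom_wallenius(len(universe), m, n_sig, odds)
            pval = float(dist.sf(x - 1))
        results.append(GeneSetResult(sid, m, x, float(odds), float(np.clip(pval, 0, 1))))
    _attach_bh(results)
    return results


def _attach_bh(results: List[GeneSetResult]) -> None:
    if not results:
        return
    qs = bh_fdr([r.pvalue for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r, FeatureEnrichmentResult):
            rows.append({"category": r.category, "odds_ratio": r.odds_ratio,
                         "pvalue": r.pvalue, "a": r.counts.a, "b": r.counts.b,
                         "c": r.counts.c, "d": r.counts.d})
        else:
            rows.append({"set_id": r.set_id, "n_genes_in_set": r.n_genes_in_set,
                         "n_significant_genes": r.n_significant_genes,
                         "odds": r.odds, "pvalue": r.pvalue, "fdr_q": r.fdr_q})
    return pd.DataFrame(rows)


def read_gmt(path) -> Dict[str, List[str]]:
    """Read a GMT gene-set file (set id, description, tab-separated genes)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Dict[str, Sequence[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for sid, genes in gene_sets.items():
            fh.write("\t".join([sid, description, *genes]) + "\n")
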