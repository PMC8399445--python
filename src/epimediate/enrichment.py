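"""Local pathway over-representation for genes of top mediation probes.

The most significant probes (by delta-method NIE p-value) are mapped to
gene symbols through the probe annotation, and the resulting analysis
list is tested for over-representation against a reference universe — the
genes mappable from the full probe list — one pathway at a time with the
one-sided hypergeometric (upper-tail) test, BH-adjusted across retained
pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ProbeAnnotation
from .fcr import bh_select  # noqa: F401  (shared BH machinery)
from .mediation import MediationEstimate
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    pathway: str
    n_analysis: int       # analysis-list genes in the pathway
    n_reference: int      # pathway genes present in the reference universe
    expected: float       # n_reference * analysis_size / reference_size
    fold: float           # n_analysis / expected
    p: float              # hypergeometric upper tail P[X >= n_analysis]
    q: float              # BH-adjusted p over retained pathways


def top_probes(estimates: list[MediationEstimate], k: int = 100) -> list[str]:
    """The ``k`` most significant unique probes by delta-method p-value.

    Pairs are ranked by ascending p with ties broken by (p, probe id)
    lexicographically; unique probes are emitted in first-occurrence
    order until ``k`` are collected.  Deterministic under input
    permutations.
    """
    ranked = sorted(estimates, key=lambda e: (e.p_nie, e.probe_id))
    out: list[str] = []
    seen = set()
    for e in ranked:
        if e.probe_id not in seen:
            seen.add(e.probe_id)
            out.append(e.probe_id)
            if len(out) == k:
                return out
    if len(out) < k:
        log.warning("only %d unique probes available (k=%d); returning all", len(out), k)
    return out


def probes_to_genes(probes: list[str], annotation: ProbeAnnotation) -> list[str]:
    """Unique, non-empty gene symbols for the probes, first-occurrence order.

    Probes absent from the annotation or without a gene symbol are
    dropped with a logged count.
    """
    genes: list[str] = []
    seen = set()
    n_unmapped = 0
    for probe in probes:
        if probe not in annotation.table.index:
            n_unmapped += 1
            continue
        gene = annotation.gene_of(probe)
        if not gene:
            n_unmapped += 1
            continue
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
    if n_unmapped:
        log.info("%d of %d probes had no gene mapping", n_unmapped, len(probes))
    return genes


def over_representation(
    analysis_genes,
    reference_genes,
    gmt: dict[str, list[str]],
    min_ref: int = 5,
    min_analysis: int = 2,
    filter_mode: str = "either",
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of the analysis list per pathway.

    Pathway gene sets are intersected with the reference universe before
    counting.  With ``filter_mode='either'`` (default) a pathway is
    excluded when it has fewer than ``min_ref`` genes in the reference
    list OR fewer than ``min_analysis`` genes in the analysis list;
    ``'both'`` requires both bounds to fail.  Rows are sorted by p, with
    BH q-values computed over the retained pathways.
    """
    reference = set(reference_genes)
    if not reference:
        raise ValueError("empty reference gene universe")
    analysis = set(analysis_genes) & reference
    N = len(reference)
    n_draw = len(analysis)
    if filter_mode not in ("either", "both"):
        raise ValueError("filter_mode must be 'either' or 'both'")

    kept = []
    for name in gmt:
        in_ref = set(gmt[name]) & reference
        n_ref = len(in_ref)
        n_ana = len(in_ref & analysis)
        fail_ref = n_ref < min_ref
        fail_ana = n_ana < min_analysis
        excluded = (fail_ref or fail_ana) if filter_mode == "either" else (fail_ref and fail_ana)
        if excluded:
            continue
        expected = n_ref * n_draw / N
        fold = n_ana / expected if expected > 0 else 0.0
        p = float(stats.hypergeom.sf(n_ana - 1, N, n_ref, n_draw))
        kept.append((name, n_ana, n_ref, expected, fold, p))

    if not kept:
        return []
    pvals = np.array([row[5] for row in kept])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(pathway=name, n_analysis=n_ana, n_reference=n_ref,
                      expected=float(expected), fold=float(fold), p=p, q=float(qv))
        for (name, n_ana, n_ref, expected, fold, p), qv in zip(kept, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.pathway))
    return rows


ENRICHMENT_COLUMNS = (
    "pathway", "n_analysis", "n_reference", "expected", "fold_enrichment",
    "p_value", "fdr_q_value",
)


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS))
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "n_analysis": r.n_analysis,
                "n_reference": r.n_reference,
                "expected": r.expected,
                "fold_enrichment": r.fold,
                "p_value": r.p,
                "fdr_q_value": r.q,
            }
            for r in rows
        ]
    )
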