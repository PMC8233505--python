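"""Per-gene CNS gain/loss categories and differential-expression enrichment.

For one accession, every reference gene with an ortholog is classified by the
sign of its CNS count change: *gain* when more CNS sit at the gene in the
accession than in the reference, *loss* when fewer, *no_change* otherwise.
PosV elements count toward their new proximate gene and leave their old one.
Over/under-representation of differentially expressed genes within each
category is tested with exact hypergeometric tails.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .caller import CnsCall
from .stats import hypergeom_overlap_test

logger = logging.getLogger(__name__)

CATEGORIES = ("gain", "loss", "no_change")


def gene_cns_delta(
    calls: list[CnsCall] | pd.DataFrame,
    cns_gene_map: pd.Series,
    orthologs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene CNS counts and gain/loss category for one accession.

    ``cns_gene_map`` maps cns_id -> reference associated gene. The accession
    count of a gene is the number of collinear CNS retained at it plus the
    PosV CNS whose new proximate gene maps back to it through the ortholog
    table; PosV landing next to a gene without an ortholog contributes to no
    gene (logged). The universe is all reference genes with orthologs.
    """
    if isinstance(calls, pd.DataFrame):
        rows = list(calls.itertuples(index=False))
        accession = rows[0].accession if rows else ""
        statuses = [(r.cns_id, r.status, r.acc_proximate_gene or "") for r in rows]
    else:
        accession = calls[0].accession if calls else ""
        statuses = [(c.cns_id, c.status, c.acc_proximate_gene or "") for c in calls]
    acc_to_ref = dict(zip(orthologs["acc_gene_id"], orthologs["ref_gene_id"]))
    universe = list(pd.unique(orthologs["ref_gene_id"]))
    n_ref = cns_gene_map.groupby(cns_gene_map).size()
    n_acc: dict[str, int] = {}
    for cns_id, status, prox in statuses:
        if status == "collinear":
            g = cns_gene_map[cns_id]
            n_acc[g] = n_acc.get(g, 0) + 1
        elif status == "posv":
            ref_gene = acc_to_ref.get(prox)
            if ref_gene is None:
                logger.warning(
                    "PosV %s lands near %s which has no ortholog; excluded", cns_id, prox
                )
                continue
            n_acc[ref_gene] = n_acc.get(ref_gene, 0) + 1
    out = pd.DataFrame({"gene_id": universe})
    out["n_cns_ref"] = out["gene_id"].map(n_ref).fillna(0).astype(int)
    out["n_cns_acc"] = out["gene_id"].map(n_acc).fillna(0).astype(int)
    out.insert(0, "accession", accession)
    out["category"] = np.where(
        out["n_cns_acc"] > out["n_cns_ref"],
        "gain",
        np.where(out["n_cns_acc"] < out["n_cns_ref"], "loss", "no_change"),
    )
    return out


def de_enrichment_table(
    deltas: pd.DataFrame,
    de_up: set[str],
    de_down: set[str],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Over/under-representation of DE genes in each CNS-change category.

    One row per (category, direction): the overlap count n, the percent of
    the category it represents, and exact hypergeometric over- and under-
    representation probabilities (inclusive tails) against the gene universe.
    Empty categories are reported with missing statistics.
    """
    if universe is None:
        universe = set(deltas["gene_id"])
    for name, s in (("de_up", de_up), ("de_down", de_down)):
        extra = set(s) - universe
        if extra:
            raise ValueError(f"{name} contains genes outside the universe: {sorted(extra)[:5]}")
    N = len(universe)
    rows = []
    for cat in CATEGORIES:
        genes = set(deltas.loc[deltas["category"] == cat, "gene_id"]) & universe
        for direction, de in (("up", set(de_up)), ("down", set(de_down))):
            K = len(de & universe)
            n_cat = len(genes)
            if n_cat == 0:
                rows.append((cat, direction, np.nan, np.nan, np.nan, np.nan))
                continue
            x = len(genes & de)
            p_over = hypergeom_overlap_test(N, K, n_cat, x, tail="ge").p
            # under-representation: P[X <= x] = 1 - P[X > x]
            p_under = 1.0 - hypergeom_overlap_test(N, K, n_cat, x, tail="gt").p
            rows.append((cat, direction, x, 100.0 * x / n_cat, p_over, p_under))
    return pd.DataFrame(
        rows, columns=["category", "direction", "n", "percent", "p_over", "p_under"]
    )


def average_enrichment(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-accession averages of per-cell counts and percentages."""
    cat = pd.concat(tables, ignore_index=True)
    return (
        cat.groupby(["category", "direction"], sort=False)[["n", "percent"]]
        .mean()
        .reset_index()
        .rename(columns={"n": "mean_n", "percent": "mean_percent"})
    )
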