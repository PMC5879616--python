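"""Cross-species conservation of memory types through ortholog maps.

Given memory-type assignments for two species and a (possibly many-to-many)
ortholog map, every pair whose species-A gene is a *memory* gene is placed
in one of five conservation categories from the species-B side:

* ``conserved-same-type``   — the ortholog is a memory gene of the *same*
  ``[a/b]`` type;
* ``memory-different-type`` — a memory gene of a different type;
* ``non-memory`` / ``late-response`` / ``non-response`` — the ortholog's
  own category.

Classification is per *pair* (an A gene with three orthologs contributes
three records), matching how ortholog tallies are usually reported; a
per-gene rollup (memory-conserved if ANY ortholog shares the type) is
available as a secondary view.  B-side genes absent from the species-B
assignment table fall in the ``non-response`` bucket.
"""

from __future__ import annotations

import logging

import pandas as pd

from memtype.memory_classify import CATEGORY_OF_TYPE, percent

logger = logging.getLogger(__name__)

PAIR_CATEGORIES = (
    "conserved-same-type", "memory-different-type",
    "non-memory", "late-response", "non-response",
)

MEMORY_ONLY = tuple(t for t, c in CATEGORY_OF_TYPE.items() if c == "memory")


def _pair_category(type_a: str, type_b: str) -> str:
    cat_b = CATEGORY_OF_TYPE[type_b]
    if cat_b != "memory":
        return cat_b
    return "conserved-same-type" if type_a == type_b else "memory-different-type"


def classify_pairs(ortholog_map: pd.DataFrame,
                   assign_a: pd.DataFrame,
                   assign_b: pd.DataFrame) -> pd.DataFrame:
    """One conservation record per ortholog pair of a species-A memory gene.

    ``assign_a``/``assign_b`` are assignment tables with ``gene_id`` and
    ``memory_type`` columns.  Pairs whose A-side gene is not a memory gene
    (or is absent from ``assign_a``) are skipped; B-side genes without an
    assignment are treated as ``[=/=]`` (non-responding in species B).
    """
    if len(ortholog_map) == 0:
        logger.warning("classify_pairs: empty ortholog map")
        return pd.DataFrame(columns=["gene_a", "gene_b", "type_a", "type_b",
                                     "pair_category"])
    types_a = assign_a.set_index("gene_id")["memory_type"]
    types_b = assign_b.set_index("gene_id")["memory_type"]
    rows = []
    for gene_a, gene_b in ortholog_map[["gene_a", "gene_b"]].itertuples(index=False):
        type_a = types_a.get(gene_a)
        if type_a is None or CATEGORY_OF_TYPE[type_a] != "memory":
            continue
        type_b = types_b.get(gene_b, "[=/=]")
        rows.append((gene_a, gene_b, type_a, type_b,
                     _pair_category(type_a, type_b)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "type_a", "type_b",
                                       "pair_category"])


def conservation_summary(records: pd.DataFrame,
                         n_memory_a: int | None = None) -> dict:
    """Counts and percentages over the classified orthologs.

    Percentages use the total number of classified ortholog pairs as the
    denominator (1 decimal).  ``per_type_conserved`` tallies, for each
    memory type, how many pairs are conserved-same-type of that type, with
    its explicit denominator (pairs whose A-side gene has that type).
    ``memory_ortholog_pct`` restates the conserved-same-type +
    memory-different-type pairs as the share of orthologs that are memory
    genes in species B.
    """
    total = len(records)
    cat_counts = {c: 0 for c in PAIR_CATEGORIES}
    if total:
        for c, n in records["pair_category"].value_counts().items():
            cat_counts[c] = int(n)
    n_memory_orthologs = (cat_counts["conserved-same-type"]
                          + cat_counts["memory-different-type"])
    per_type = {}
    for t in MEMORY_ONLY:
        of_type = records[records["type_a"] == t] if total else records
        n_type = len(of_type)
        n_cons = int((of_type["pair_category"] == "conserved-same-type").sum()) \
            if n_type else 0
        per_type[t] = {"conserved": n_cons, "pairs": n_type,
                       "conserved_pct": percent(n_cons, n_type, 1)}
    summary = {
        "n_orthologs": total,
        "n_memory_genes_a": n_memory_a,
        "n_a_genes_with_ortholog": int(records["gene_a"].nunique()) if total else 0,
        "category_counts": cat_counts,
        "category_pct": {c: percent(cat_counts[c], total, 1)
                         for c in PAIR_CATEGORIES},
        "n_memory_orthologs": n_memory_orthologs,
        "memory_ortholog_pct": percent(n_memory_orthologs, total, 1),
        "per_type_conserved": per_type,
    }
    # among the pairs whose ortholog is a memory gene in species B: their
    # split by A-side type (the "64 of 76 were [x/y]" view) and, per type,
    # how many keep the A-side type exactly (the "conserved [x/y]" view)
    if total:
        mem = records[records["pair_category"].isin(
            ["conserved-same-type", "memory-different-type"])]
        per_type_of_memory = {}
        by_type_a = {}
        for t in MEMORY_ONLY:
            of_type = mem[mem["type_a"] == t]
            n_type = len(of_type)
            n_cons = int((of_type["pair_category"] == "conserved-same-type").sum())
            per_type_of_memory[t] = {
                "conserved": n_cons, "memory_orthologs": n_type,
                "conserved_pct": percent(n_cons, n_type, 1)}
            by_type_a[t] = {"count": n_type,
                            "pct": percent(n_type, len(mem), 1)}
        summary["per_type_conserved_of_memory"] = per_type_of_memory
        summary["memory_orthologs_by_type_a"] = by_type_a
        # keyed by the ortholog's own (species-B) type: of the memory
        # orthologs carrying type t in species B, how many match the A side
        by_type_b = {}
        for t in MEMORY_ONLY:
            of_type = mem[mem["type_b"] == t]
            n_type = len(of_type)
            n_cons = int((of_type["pair_category"] == "conserved-same-type").sum())
            by_type_b[t] = {"conserved": n_cons, "memory_orthologs": n_type,
                            "conserved_pct": percent(n_cons, n_type, 1)}
        summary["per_type_b_conserved"] = by_type_b
    return summary


def gene_rollup(records: pd.DataFrame) -> pd.DataFrame:
    """Secondary per-gene view: an A gene is memory-conserved if ANY of its
    orthologs shares its memory type."""
    if len(records) == 0:
        return pd.DataFrame(columns=["gene_a", "type_a", "n_orthologs",
                                     "memory_conserved"])
    grouped = records.groupby("gene_a", sort=True)
    return pd.DataFrame({
        "gene_a": [g for g, _ in grouped],
        "type_a": grouped["type_a"].first().to_numpy(),
        "n_orthologs": grouped.size().to_numpy(),
        "memory_conserved": (grouped["pair_category"]
                             .apply(lambda s: bool((s == "conserved-same-type").any()))
                             .to_numpy()),
    })
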