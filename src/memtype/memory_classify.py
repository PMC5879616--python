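"""Nine-way memory-type classification and its summary accounting.

Combining two direction calls — first stress vs control (D1 vs C1) and
second stress vs first (D2 vs D1) — yields a memory type written ``[a/b]``:

========  ==========================  =====================
type      condition-mean pattern      category
========  ==========================  =====================
[+/+]     C1 < D1 < D2                memory
[+/−]     C1 < D1 > D2                memory
[−/+]     C1 > D1 < D2                memory
[−/−]     C1 > D1 > D2                memory
[+/=]     C1 < D1 = D2                non-memory
[−/=]     C1 > D1 = D2                non-memory
[=/+]     C1 = D1 < D2                late-response
[=/−]     C1 = D1 > D2                late-response
[=/=]     C1 = D1 = D2                non-response
========  ==========================  =====================

*Memory* genes change again in the second stress (their second response
differs from a plain repeat of the first); *non-memory* genes respond once
and hold; *late-response* genes only respond on the second exposure.  The
nine types partition the detected-gene universe.

The module also provides the Venn overlap accounting used to relate the
memory classes to the plain per-stress up/down sets, and a one-sided
hypergeometric term-enrichment test for flat, user-supplied annotation sets
(GO/KEGG term retrieval is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
import logging

import pandas as pd
from scipy import stats

from memtype.diffexpr import bh_adjust, normalize_call
from memtype.expression_io import AnnotationSets

logger = logging.getLogger(__name__)

MEMORY_TYPES = (
    "[+/+]", "[+/-]", "[-/+]", "[-/-]",
    "[+/=]", "[-/=]", "[=/+]", "[=/-]", "[=/=]",
)

CATEGORY_OF_TYPE = {
    "[+/+]": "memory", "[+/-]": "memory", "[-/+]": "memory", "[-/-]": "memory",
    "[+/=]": "non-memory", "[-/=]": "non-memory",
    "[=/+]": "late-response", "[=/-]": "late-response",
    "[=/=]": "non-response",
}

CATEGORIES = ("memory", "non-memory", "late-response", "non-response")


def assign_memory_type(call_first: str, call_second: str) -> tuple[str, str]:
    """Map a pair of direction calls to ``(memory_type, category)``.

    ``call_first`` is the D1-vs-C1 call, ``call_second`` the D2-vs-D1 call;
    both in ``{+, -, =}`` (the typographic minus ``−`` is accepted).
    """
    a = normalize_call(call_first)
    b = normalize_call(call_second)
    memory_type = f"[{a}/{b}]"
    return memory_type, CATEGORY_OF_TYPE[memory_type]


def classify_genes(contrast_first: pd.DataFrame,
                   contrast_second: pd.DataFrame) -> pd.DataFrame:
    """Build the per-gene assignment table from two called contrast tables.

    Genes present in only one contrast are dropped from the universe with a
    warning.  Returns columns ``gene_id, call_first, call_second,
    memory_type, category``, ordered as in the first contrast.
    """
    first = contrast_first.set_index("gene_id")["call"]
    second = contrast_second.set_index("gene_id")["call"]
    common = first.index.intersection(second.index)
    dropped = len(first.index.symmetric_difference(second.index))
    if dropped:
        logger.warning(
            "classify_genes: %d gene(s) absent from one contrast, excluded", dropped)
    first = first.loc[common]
    second = second.loc[common]
    if first.isna().any() or second.isna().any():
        raise ValueError("contrast tables carry unset calls; run call_direction")
    pairs = [assign_memory_type(a, b) for a, b in zip(first, second)]
    return pd.DataFrame({
        "gene_id": common.astype(str),
        "call_first": [normalize_call(c) for c in first],
        "call_second": [normalize_call(c) for c in second],
        "memory_type": [t for t, _ in pairs],
        "category": [c for _, c in pairs],
    })


# ---------------------------------------------------------------------------
# summary (Table-1-style accounting)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float | None:
    """Percentage with round-half-away-from-zero at ``decimals`` places.

    Returns None for an undefined ratio (zero denominator) — rendered blank
    in text output.
    """
    if denominator == 0:
        return None
    raw = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Counts and derived shares of the nine memory types.

    Every percentage is paired with an explicit denominator:

    * each memory type over total memory genes (integer percent);
    * memory genes over *response* genes — genes with a non-``=`` first
      call, i.e. DEGs of the first stress (1 decimal);
    * each category over total detected genes (1 decimal).
    """

    type_counts: dict[str, int]
    category_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for t in self.type_counts:
            if t not in MEMORY_TYPES:
                raise ValueError(f"unknown memory type {t!r}")
        self.type_counts = {t: int(self.type_counts.get(t, 0)) for t in MEMORY_TYPES}
        self.category_counts = {c: 0 for c in CATEGORIES}
        for t, n in self.type_counts.items():
            self.category_counts[CATEGORY_OF_TYPE[t]] += n

    @property
    def total_detected(self) -> int:
        return sum(self.type_counts.values())

    @property
    def total_memory(self) -> int:
        return self.category_counts["memory"]

    @property
    def total_response(self) -> int:
        """Genes with a non-'=' first call (DEGs of the first stress)."""
        return self.total_memory + self.category_counts["non-memory"]

    def memory_type_shares(self) -> dict[str, float | None]:
        """Integer-percent share of each memory type among memory genes."""
        return {t: percent(self.type_counts[t], self.total_memory)
                for t in ("[+/+]", "[-/-]", "[+/-]", "[-/+]")}

    def memory_of_response_percent(self) -> float | None:
        """Memory genes as a share of first-stress response genes, 1 decimal."""
        return percent(self.total_memory, self.total_response, 1)

    def category_shares(self) -> dict[str, float | None]:
        return {c: percent(self.category_counts[c], self.total_detected, 1)
                for c in CATEGORIES}

    def ratio(self, numerator: int, denominator: int, decimals: int = 1) -> float | None:
        """Caller-specified ratio of printed counts at a chosen precision."""
        return percent(numerator, denominator, decimals)

    def to_dict(self) -> dict:
        return {
            "type_counts": dict(self.type_counts),
            "category_counts": dict(self.category_counts),
            "total_detected": self.total_detected,
            "total_memory": self.total_memory,
            "total_response": self.total_response,
            "memory_type_shares_pct": self.memory_type_shares(),
            "memory_of_response_pct": self.memory_of_response_percent(),
            "category_shares_pct": self.category_shares(),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, CATEGORY_OF_TYPE[t], n) for t, n in self.type_counts.items()]
        return pd.DataFrame(rows, columns=["memory_type", "category", "count"])


def summarize(assignments: pd.DataFrame) -> SummaryTable:
    """Tally an assignment table into a :class:`SummaryTable`.

    An empty input yields an all-zero table with undefined percentages.
    """
    if len(assignments) == 0:
        return SummaryTable({})
    counts = assignments["memory_type"].value_counts().to_dict()
    return SummaryTable(counts)


# ---------------------------------------------------------------------------
# Venn overlap accounting


def venn_sets(calls_a: pd.Series, calls_b: pd.Series, direction: str,
              with_members: bool = False) -> dict:
    """Overlap of the genes called ``direction`` in two contrasts.

    ``calls_a`` and ``calls_b`` are per-gene call vectors indexed by gene id
    over the same universe (e.g. D1-vs-C1 and D2-vs-C1 up-calls feed the
    classic two-stress Venn diagram).  Returns the six set sizes of the
    two-set Venn decomposition, plus sorted membership lists on request.
    """
    direction = normalize_call(direction)
    if direction == "=":
        raise ValueError("direction must be '+' or '-'")
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError("venn_sets: the two call vectors cover different gene universes")
    set_a = set(calls_a.index[[normalize_call(c) == direction for c in calls_a]])
    set_b = set(calls_b.index[[normalize_call(c) == direction for c in calls_b]])
    report = {
        "direction": direction,
        "size_a": len(set_a),
        "size_b": len(set_b),
        "common": len(set_a & set_b),
        "only_a": len(set_a - set_b),
        "only_b": len(set_b - set_a),
        "union": len(set_a | set_b),
    }
    if with_members:
        report["members_common"] = sorted(set_a & set_b)
        report["members_only_a"] = sorted(set_a - set_b)
        report["members_only_b"] = sorted(set_b - set_a)
    return report


def venn_from_sizes(size_a: int, size_b: int, common: int) -> dict:
    """Venn arithmetic from printed set sizes (inclusion–exclusion)."""
    if common > min(size_a, size_b):
        raise ValueError("overlap exceeds a set size")
    return {
        "size_a": size_a, "size_b": size_b, "common": common,
        "only_a": size_a - common, "only_b": size_b - common,
        "union": size_a + size_b - common,
    }


# ---------------------------------------------------------------------------
# hypergeometric term enrichment


def enrich_terms(selected: set[str], universe: set[str],
                 annotations: AnnotationSets) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of flat term sets.

    For each term with members in ``universe``, tests whether ``selected``
    (a subset of the universe, e.g. the memory genes) overlaps the term more
    than a uniform draw of ``len(selected)`` genes would.  The upper-tail
    p-value is ``P[X >= k]`` for ``X ~ Hypergeom(M=|universe|, K=|term|,
    n=|selected|)``; q-values are Benjamini–Hochberg across the tested terms.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        stray = sorted(selected - universe)[:3]
        raise ValueError(f"selected genes outside the universe, e.g. {stray}")
    restricted = annotations.restricted_to(universe)
    rows = []
    m = len(universe)
    n_sel = len(selected)
    for term, genes in restricted.sets.items():
        k = len(selected & genes)
        p = float(stats.hypergeom.sf(k - 1, m, len(genes), n_sel))
        rows.append((term, restricted.descriptions.get(term, ""), k,
                     len(genes), n_sel, m, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=[
        "term_id", "description", "overlap", "term_size",
        "selected_size", "universe_size", "p_value",
    ]).sort_values("p_value", kind="stable").reset_index(drop=True)
    result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    return result
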