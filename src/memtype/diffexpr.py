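"""Two-condition differential-expression contrasts with direction calls.

A contrast compares two conditions of the design (e.g. first dehydration D1
vs control C1, or second dehydration D2 vs D1) and emits, per gene, a
log2 fold change, a p-value, a Benjamini–Hochberg q-value, the replicate-mean
FPKM on each side, and a direction call in ``{+, −, =}`` under a three-part
DEG criterion:

1. ``q <= q_threshold``            (default 0.05, inclusive)
2. ``|log2fc| >= fc_threshold``    (default 1, inclusive)
3. an *expression floor*: the FPKM of the gene on the up-regulated side
   (stress side for ``+`` calls, baseline side for ``−`` calls) must be at
   least ``floor_fraction`` (default 20%) of the mean FPKM of all expressed
   genes in that condition.

Fold changes use a pseudocount: ``log2fc = log2((mean_b + c) / (mean_a + c))``
with ``c = 1`` by default, so genes that are off in one condition stay finite.

Count-level DE engines (Cuffdiff and kin) are not reproduced here.
Instead ``compute_contrast`` offers three interchangeable p-value sources:

``precomputed``
    ingest a Cuffdiff-style table of ``log2fc``/``p``/``q`` and only attach
    replicate-mean FPKMs (the faithful route when upstream output exists);
``pooled``
    a z-test on log2(FPKM + c) whose residual variance is pooled across all
    genes — the standard way to get usable inference from two replicates per
    condition, where any per-gene test is powerless; this is the default;
``permutation``
    an exact per-gene label-permutation test (all reassignments enumerated
    up to 10 total replicates, Monte-Carlo beyond), useful with richer
    designs and as a distribution-free check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CALLS = ("+", "-", "=")

#: Direction-call glyphs: ASCII "-" is used internally; the typographic
#: minus "−" is accepted on input for interoperability with published tables.
MINUS_ALIASES = {"−": "-", "-": "-"}

CONTRAST_COLUMNS = (
    "gene_id", "log2fc", "p_value", "q_value", "mean_fpkm_a", "mean_fpkm_b", "call",
)


@dataclass(frozen=True)
class DEGCriteria:
    """Thresholds of the three-part DEG criterion (all inclusive)."""

    q_threshold: float = 0.05
    fc_threshold: float = 1.0       # log2 units
    floor_fraction: float = 0.20    # of mean FPKM of expressed genes
    pseudocount: float = 1.0        # FPKM units, for fold changes

    def __post_init__(self) -> None:
        for name in ("q_threshold", "fc_threshold", "floor_fraction", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def normalize_call(call: str) -> str:
    call = MINUS_ALIASES.get(call, call)
    if call not in CALLS:
        raise ValueError(f"invalid direction call {call!r}; expected one of {CALLS}")
    return call


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment (monotone step-up q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design helpers


def _condition_samples(sheet: pd.DataFrame, condition: str) -> list[str]:
    samples = sheet.loc[sheet["condition"] == condition, "sample_id"].tolist()
    if not samples:
        raise ValueError(f"condition {condition!r} not present in the sample sheet")
    return samples


def condition_means(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean FPKM per gene and condition (genes × conditions)."""
    cols = {}
    for condition in sheet["condition"].unique():
        cols[condition] = matrix[_condition_samples(sheet, condition)].mean(axis=1)
    return pd.DataFrame(cols)


def expressed_mean(matrix: pd.DataFrame, sheet: pd.DataFrame, condition: str) -> float:
    """Mean FPKM of all *expressed* genes in one condition.

    A gene counts as expressed when its replicate-mean FPKM is > 0 in at
    least one condition of the whole design; the returned mean is taken over
    that fixed gene universe, in the requested condition (zeros included).
    This is the quantity the 20% expression floor is anchored to.
    """
    means = condition_means(matrix, sheet)
    if condition not in means.columns:
        raise ValueError(f"condition {condition!r} not present in the sample sheet")
    expressed = (means > 0).any(axis=1)
    if not expressed.any():
        raise ValueError("no expressed genes in the design (all-zero matrix)")
    return float(means.loc[expressed, condition].mean())


def deg_floors(matrix, sheet, cond_a, cond_b, criteria: DEGCriteria) -> tuple[float, float]:
    """Expression-floor values ``(floor_up, floor_down)`` for one contrast.

    ``floor_up`` applies to the stressed-side mean (condition B) of ``+``
    calls; ``floor_down`` to the baseline side (condition A) of ``−`` calls.
    """
    floor_up = criteria.floor_fraction * expressed_mean(matrix, sheet, cond_b)
    floor_down = criteria.floor_fraction * expressed_mean(matrix, sheet, cond_a)
    return floor_up, floor_down


# ---------------------------------------------------------------------------
# p-value engines


def _permutation_pvalues(log_a: np.ndarray, log_b: np.ndarray,
                         n_mc: int, seed) -> np.ndarray:
    """Two-sided permutation p for mean(log_b) − mean(log_a), per gene.

    Exact enumeration of every label reassignment when the contrast has at
    most 10 replicates in total, otherwise Monte-Carlo with ``n_mc`` draws.
    """
    n_a, n_b = log_a.shape[1], log_b.shape[1]
    n = n_a + n_b
    pooled = np.concatenate([log_a, log_b], axis=1)      # genes × n
    observed = log_b.mean(axis=1) - log_a.mean(axis=1)
    totals = pooled.sum(axis=1)
    eps = 1e-12

    def stat_for(a_idx: tuple[int, ...]) -> np.ndarray:
        sum_a = pooled[:, list(a_idx)].sum(axis=1)
        return (totals - sum_a) / n_b - sum_a / n_a

    if n <= 10:
        count = np.zeros(pooled.shape[0], dtype=int)
        n_perm = 0
        for a_idx in combinations(range(n), n_a):
            count += np.abs(stat_for(a_idx)) >= np.abs(observed) - eps
            n_perm += 1
        return count / n_perm
    if seed is None:
        raise ValueError("Monte-Carlo permutation requires a seed")
    rng = np.random.default_rng(seed)
    count = np.zeros(pooled.shape[0], dtype=int)
    for _ in range(n_mc):
        a_idx = tuple(rng.choice(n, size=n_a, replace=False))
        count += np.abs(stat_for(a_idx)) >= np.abs(observed) - eps
    return (1 + count) / (1 + n_mc)


def _pooled_z_pvalues(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Two-sided z-test with residual variance pooled across all genes.

    With two replicates per condition a per-gene variance estimate has one
    degree of freedom and no test based on it can reach q <= 0.05; pooling
    the within-condition residual scatter of every gene gives a variance
    estimate with thousands of degrees of freedom, so a normal reference
    distribution is appropriate.  When the pooled variance is exactly zero
    (noise-free data) the p-value degenerates to 0 where the group means
    differ and 1 where they coincide.
    """
    n_a, n_b = log_a.shape[1], log_b.shape[1]
    resid = np.concatenate(
        [log_a - log_a.mean(axis=1, keepdims=True),
         log_b - log_b.mean(axis=1, keepdims=True)], axis=1)
    df = resid.shape[0] * ((n_a - 1) + (n_b - 1))
    pooled_var = float((resid ** 2).sum()) / df
    diff = log_b.mean(axis=1) - log_a.mean(axis=1)
    if pooled_var == 0.0:
        return np.where(diff == 0.0, 1.0, 0.0)
    se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    return 2.0 * stats.norm.sf(np.abs(diff) / se)


# ---------------------------------------------------------------------------
# public operations


def compute_contrast(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    method: str = "pooled",
    seed: int | None = 20180402,
    pseudocount: float = 1.0,
    precomputed: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
) -> pd.DataFrame:
    """Per-gene contrast of condition ``cond_b`` over ``cond_a``.

    Returns a contrast table (one row per gene of the matrix, in matrix
    order) with ``log2fc``, ``p_value``, BH ``q_value``, the replicate-mean
    FPKM of each side and an unset ``call`` column; run
    :func:`call_direction` to set the calls.

    ``method`` selects the p-value engine: ``"pooled"`` (default),
    ``"permutation"``, or ``"precomputed"`` with a table of
    ``gene_id/log2fc/p_value[/q_value]`` (fold changes and p-values are taken
    verbatim from it; q is recomputed by BH when absent).
    """
    samples_a = _condition_samples(sheet, cond_a)
    samples_b = _condition_samples(sheet, cond_b)
    fpkm_a = matrix[samples_a].to_numpy(float)
    fpkm_b = matrix[samples_b].to_numpy(float)
    mean_a = fpkm_a.mean(axis=1)
    mean_b = fpkm_b.mean(axis=1)

    if method == "precomputed":
        if precomputed is None:
            raise ValueError("method='precomputed' requires a precomputed table")
        table = precomputed.set_index("gene_id").reindex(matrix.index)
        if table["log2fc"].isna().any() or table["p_value"].isna().any():
            missing = table.index[table["p_value"].isna()][:3].tolist()
            raise ValueError(f"precomputed table missing genes, e.g. {missing}")
        log2fc = table["log2fc"].to_numpy(float)
        p = table["p_value"].to_numpy(float)
        q = (table["q_value"].to_numpy(float)
             if "q_value" in table.columns and table["q_value"].notna().all()
             else bh_adjust(p))
    else:
        if min(len(samples_a), len(samples_b)) < 2:
            raise ValueError(
                f"method={method!r} needs >= 2 replicates per condition; "
                "use method='precomputed' with an external contrast table"
            )
        log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
        log_a = np.log2(fpkm_a + pseudocount)
        log_b = np.log2(fpkm_b + pseudocount)
        if method == "pooled":
            p = _pooled_z_pvalues(log_a, log_b)
        elif method == "permutation":
            p = _permutation_pvalues(log_a, log_b, n_permutations, seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        q = bh_adjust(p)

    return pd.DataFrame({
        "gene_id": matrix.index.astype(str),
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "mean_fpkm_a": mean_a,
        "mean_fpkm_b": mean_b,
        "call": pd.array([pd.NA] * len(matrix), dtype="string"),
    })


def call_direction(
    contrast: pd.DataFrame,
    criteria: DEGCriteria,
    floor_value_up: float,
    floor_value_down: float,
) -> pd.DataFrame:
    """Set the ``{+, -, =}`` call of every gene in a contrast table.

    ``+``: q <= q_threshold, log2fc >= fc_threshold and the condition-B mean
    clears ``floor_value_up``; ``-``: symmetric with the condition-A mean and
    ``floor_value_down``; everything else ``=``.  All thresholds inclusive.
    ``floor_value_*`` are :func:`deg_floors` outputs (already scaled by
    ``floor_fraction``).
    """
    if contrast["q_value"].isna().any():
        bad = contrast.loc[contrast["q_value"].isna(), "gene_id"].iloc[0]
        raise ValueError(f"q_value unset for gene {bad!r}; run BH adjustment first")
    q = contrast["q_value"].to_numpy(float)
    fc = contrast["log2fc"].to_numpy(float)
    significant = q <= criteria.q_threshold
    up = (significant & (fc >= criteria.fc_threshold)
          & (contrast["mean_fpkm_b"].to_numpy(float) >= floor_value_up))
    down = (significant & (fc <= -criteria.fc_threshold)
            & (contrast["mean_fpkm_a"].to_numpy(float) >= floor_value_down))
    out = contrast.copy()
    out["call"] = pd.array(np.where(up, "+", np.where(down, "-", "=")),
                           dtype="string")
    return out


def contrast_with_calls(matrix, sheet, cond_a, cond_b,
                        criteria: DEGCriteria | None = None,
                        **kwargs) -> pd.DataFrame:
    """Convenience wrapper: :func:`compute_contrast` then :func:`call_direction`."""
    criteria = criteria or DEGCriteria()
    contrast = compute_contrast(matrix, sheet, cond_a, cond_b,
                                pseudocount=criteria.pseudocount, **kwargs)
    floor_up, floor_down = deg_floors(matrix, sheet, cond_a, cond_b, criteria)
    return call_direction(contrast, criteria, floor_up, floor_down)
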