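"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates the repeated-stress design the classifier targets:
four conditions (naive control C1, first stress D1, recovery R1, second
stress D2) with a small number of biological replicates, expression reported
as FPKM.  Each simulated gene is planted with one of the nine memory classes
by construction of its per-condition log2 mean:

* ``[+/+]``: D1 = C1 + Δ, D2 = D1 + Δ;  ``[=/−]``: D1 = C1, D2 = D1 − Δ; …
* R1 is drawn at the C1 level (recovery restores baseline);
* replicate values are the condition mean plus Normal(0, ``noise_sd``) on
  the log2 scale, exponentiated to FPKM (log-normal replicate noise).

Baseline log2-FPKM is Normal(``baseline_log2_mean``, ``baseline_log2_sd``).
Because the DEG criterion carries a 20%-of-mean expression floor and a
pseudocount in the fold change, low-baseline genes could fail their planted
call for reasons unrelated to the classifier; the generator therefore lifts
any offending gene's whole profile (preserving its planted deltas) until the
planted class holds *by construction* under the criteria at zero noise.

Everything is a pure function of (config, seed): the same inputs reproduce
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from memtype import diffexpr
from memtype.memory_classify import CATEGORY_OF_TYPE, MEMORY_TYPES

#: default share of the non-conserved ortholog pairs per category
DEFAULT_NONCONSERVED_PROPORTIONS = {
    "memory-different-type": 0.078,
    "non-memory": 0.198,
    "late-response": 0.154,
    "non-response": 0.570,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the expression simulator.

    Defaults mirror the design the classifier was built for: two biological
    replicates of four treatments, planted per-contrast effect of 3 log2
    units (far beyond the |log2FC| >= 1 call threshold, so recovery failures
    reflect the pipeline rather than boundary effects), and replicate noise
    of 0.25 log2 units.
    """

    n_per_class: dict[str, int] | int = 50
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    delta: float = 3.0            # planted |log2 FC| per non-'=' contrast
    noise_sd: float = 0.25        # replicate noise, log2 scale
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("C1", "D1", "R1", "D2")
    seed: int = 0

    def class_counts(self) -> dict[str, int]:
        if isinstance(self.n_per_class, int):
            return {t: self.n_per_class for t in MEMORY_TYPES}
        counts = {t: int(self.n_per_class.get(t, 0)) for t in MEMORY_TYPES}
        unknown = set(self.n_per_class) - set(MEMORY_TYPES)
        if unknown:
            raise ValueError(f"unknown memory class(es) {sorted(unknown)}")
        return counts

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline_log2_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(n < 0 for n in self.class_counts().values()):
            raise ValueError("per-class gene counts must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")
        for required in ("C1", "D1", "D2"):
            if required not in self.conditions:
                raise ValueError(f"design must include condition {required!r}")


_SYMBOL_DELTA = {"+": 1.0, "-": -1.0, "=": 0.0}


def _class_symbols(memory_type: str) -> tuple[str, str]:
    return memory_type[1], memory_type[3]


def _planted_log2_means(classes: list[str], baselines: np.ndarray,
                        delta: float, conditions: tuple[str, ...]) -> pd.DataFrame:
    a = np.array([_SYMBOL_DELTA[_class_symbols(t)[0]] for t in classes]) * delta
    b = np.array([_SYMBOL_DELTA[_class_symbols(t)[1]] for t in classes]) * delta
    means = {}
    for cond in conditions:
        if cond == "D1":
            means[cond] = baselines + a
        elif cond == "D2":
            means[cond] = baselines + a + b
        else:                      # C1, R1 and any extra recovery condition
            means[cond] = baselines.copy()
    return pd.DataFrame(means)


def _lift_to_satisfy_criteria(log2_means: pd.DataFrame, classes: list[str],
                              criteria: diffexpr.DEGCriteria,
                              margin: float = 1.0,
                              max_rounds: int = 60) -> pd.DataFrame:
    """Raise gene profiles until every planted call holds at zero noise.

    The planted deltas already guarantee the sign pattern; what can fail at
    low expression is (a) the pseudocount-shrunk |log2fc| dropping below the
    threshold and (b) the 20%-of-mean expression floor.  Lifting a profile
    by a constant fixes both and never breaks a planted '=' (equal means
    stay equal), so iterating to a fixed point terminates whenever the
    planted effect exceeds the fold-change threshold asymptotically.

    ``margin`` (log2 units) is the clearance required beyond both
    thresholds, so that genes the lift touched do not sit exactly on a
    boundary where replicate noise would flip them half of the time —
    planted classes are meant to be unambiguous and recovery to measure the
    pipeline, not boundary behaviour.
    """
    log2_means = log2_means.copy()
    symbols = np.array([_class_symbols(t) for t in classes])
    fc_needed = criteria.fc_threshold + margin
    floor_scale = 2.0 ** margin
    for _ in range(max_rounds):
        fpkm = 2.0 ** log2_means
        floors = {c: criteria.floor_fraction * fpkm[c].mean() for c in fpkm.columns}
        violated = np.zeros(len(log2_means), dtype=bool)
        for (cond_a, cond_b), sym in ((("C1", "D1"), symbols[:, 0]),
                                      (("D1", "D2"), symbols[:, 1])):
            ma = fpkm[cond_a].to_numpy()
            mb = fpkm[cond_b].to_numpy()
            fc = np.log2((mb + criteria.pseudocount) / (ma + criteria.pseudocount))
            bad_up = (sym == "+") & ((fc < fc_needed)
                                     | (mb < floor_scale * floors[cond_b]))
            bad_down = (sym == "-") & ((fc > -fc_needed)
                                       | (ma < floor_scale * floors[cond_a]))
            violated |= bad_up | bad_down
        if not violated.any():
            return log2_means
        log2_means.loc[violated] += 1.0
    raise RuntimeError(
        "could not make planted classes consistent with the DEG criteria; "
        "is the planted delta at or below the fold-change threshold plus margin?")


def generate_expression(
    config: SimulationConfig,
    criteria: diffexpr.DEGCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate ``(matrix, sample_sheet, truth)`` for the planted design.

    ``truth`` holds, per gene, the planted memory class, its category, and
    the planted per-condition log2 means (after the floor-consistency lift).
    At ``noise_sd = 0`` running the full classifier on the output recovers
    the planted class of every gene exactly.
    """
    criteria = criteria or diffexpr.DEGCriteria(pseudocount=1.0)
    rng = np.random.default_rng(config.seed)
    counts = config.class_counts()
    classes = [t for t in MEMORY_TYPES for _ in range(counts[t])]
    n = len(classes)
    if n == 0:
        raise ValueError("no genes requested")
    gene_ids = [f"g{i:05d}" for i in range(n)]

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    log2_means = _planted_log2_means(classes, baselines, config.delta,
                                     config.conditions)
    log2_means = _lift_to_satisfy_criteria(log2_means, classes, criteria)

    sheet = pd.DataFrame(
        [(f"{cond}_{rep}", cond, rep)
         for cond in config.conditions
         for rep in range(1, config.n_replicates + 1)],
        columns=["sample_id", "condition", "replicate"])

    values = {}
    for cond in config.conditions:
        mean = log2_means[cond].to_numpy()
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 \
                else np.zeros(n)
            values[f"{cond}_{rep}"] = 2.0 ** (mean + noise)
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"))

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "planted_class": classes,
        "planted_category": [CATEGORY_OF_TYPE[t] for t in classes],
        **{f"log2_{c}": log2_means[c].to_numpy() for c in config.conditions},
    })
    return matrix, sheet, truth


def generate_class_table(n_per_type: dict[str, int] | int,
                         prefix: str = "b") -> pd.DataFrame:
    """Deterministic assignment-style table of genes with given types.

    Handy for building a species-B universe for ortholog simulations
    without running a full expression simulation.
    """
    if isinstance(n_per_type, int):
        n_per_type = {t: n_per_type for t in MEMORY_TYPES}
    rows = []
    i = 0
    for t in MEMORY_TYPES:
        for _ in range(int(n_per_type.get(t, 0))):
            rows.append((f"{prefix}{i:05d}", t, CATEGORY_OF_TYPE[t]))
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "memory_type", "category"])


def generate_ortholog_map(
    assign_a: pd.DataFrame,
    assign_b: pd.DataFrame,
    conservation_rate: float,
    seed: int,
    n_pairs: int | None = None,
    nonconserved_proportions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wire ortholog pairs with a known memory-conservation rate.

    Each pair links a species-A *memory* gene to a species-B gene chosen so
    that, with probability ``conservation_rate``, the B gene has the same
    memory type (``conserved-same-type``); otherwise the pair's category is
    drawn from ``nonconserved_proportions`` (defaults mirror a realistic
    split dominated by non-responding orthologs) and a matching B gene is
    picked.  Returns ``(ortholog_map, planted_records)`` where the records
    carry the planted per-pair category — the expected input/output of the
    conservation summary.
    """
    if not 0.0 <= conservation_rate <= 1.0:
        raise ValueError("conservation_rate must be within [0, 1]")
    props = dict(nonconserved_proportions or DEFAULT_NONCONSERVED_PROPORTIONS)
    if min(props.values()) < 0 or abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("nonconserved proportions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)

    memory_a = assign_a[assign_a["memory_type"].map(CATEGORY_OF_TYPE) == "memory"]
    if len(memory_a) == 0:
        raise ValueError("species A has no memory genes to pair")
    if n_pairs is None:
        n_pairs = len(memory_a)
    replace_a = n_pairs > len(memory_a)
    chosen = memory_a.iloc[rng.choice(len(memory_a), size=n_pairs,
                                      replace=replace_a)]

    b_by_type = {t: assign_b.loc[assign_b["memory_type"] == t, "gene_id"].to_numpy()
                 for t in MEMORY_TYPES}
    b_by_category: dict[str, np.ndarray] = {}
    cat_b = assign_b["memory_type"].map(CATEGORY_OF_TYPE)
    for cat in ("non-memory", "late-response", "non-response"):
        b_by_category[cat] = assign_b.loc[cat_b == cat, "gene_id"].to_numpy()

    cat_names = list(props)
    cat_p = np.array([props[c] for c in cat_names])
    rows = []
    for gene_a, type_a in chosen[["gene_id", "memory_type"]].itertuples(index=False):
        if rng.random() < conservation_rate:
            category = "conserved-same-type"
            pool = b_by_type[type_a]
        else:
            category = cat_names[rng.choice(len(cat_names), p=cat_p)]
            if category == "memory-different-type":
                pool = np.concatenate([b_by_type[t] for t in MEMORY_TYPES
                                       if CATEGORY_OF_TYPE[t] == "memory"
                                       and t != type_a])
            else:
                pool = b_by_category[category]
        if pool.size == 0:
            raise ValueError(
                f"species B has no gene available for category {category!r}")
        gene_b = pool[rng.integers(pool.size)]
        rows.append((gene_a, gene_b, type_a, category))
    records = (pd.DataFrame(rows, columns=["gene_a", "gene_b", "type_a",
                                           "planted_category"])
               .drop_duplicates(subset=["gene_a", "gene_b"])
               .reset_index(drop=True))
    pairs = records[["gene_a", "gene_b"]].copy()
    return pairs, records


def generate_ct_table(
    gene_effects: dict[str, float],
    decay: dict[int, float],
    seed: int,
    reference_gene: str = "REF1",
    n_biological: int = 3,
    n_technical: int = 3,
    d1_response_log2: float = 2.0,
    target_base_ct: float = 28.0,
    reference_ct: float = 20.0,
    biological_noise_sd: float = 0.15,
    technical_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table for the persistence design.

    ``gene_effects`` maps target gene ids to their planted memory effect in
    log2 units — the extra (or missing, if negative) second-stress response
    of trained plants relative to the untrained first-stress response; use
    0 for non-memory genes.  ``decay`` maps each replanting interval (days)
    to the retained fraction of that effect.  For every interval the table
    contains conditions ``D1_untrained_{d}d`` and ``D2_trained_{d}d`` plus a
    shared naive calibrator ``C``; the reference gene is constant across
    samples up to technical noise.  One row per well.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def emit(condition: str, expr_log2: dict[str, float]) -> None:
        for bio in range(1, n_biological + 1):
            sample = f"{condition}_b{bio}"
            for gene, expr in expr_log2.items():
                bio_shift = rng.normal(0.0, biological_noise_sd)
                ct_mean = target_base_ct - expr + bio_shift
                for _ in range(n_technical):
                    rows.append((sample, condition, bio, gene, "target",
                                 ct_mean + rng.normal(0.0, technical_noise_sd)))
            for _ in range(n_technical):
                rows.append((sample, condition, bio, reference_gene, "reference",
                             reference_ct + rng.normal(0.0, technical_noise_sd)))

    emit("C", {g: 0.0 for g in gene_effects})
    for day in sorted(decay):
        emit(f"D1_untrained_{day}d",
             {g: d1_response_log2 for g in gene_effects})
        emit(f"D2_trained_{day}d",
             {g: d1_response_log2 + eff * decay[day]
              for g, eff in gene_effects.items()})
    return pd.DataFrame(rows, columns=["sample_id", "condition",
                                       "biological_rep", "gene_id", "role", "ct"])


def boundary_contrast_fixture(criteria: diffexpr.DEGCriteria | None = None,
                              floor_value: float = 2.0) -> pd.DataFrame:
    """Hand-built contrast rows sitting exactly on every call threshold.

    Genes at log2fc = ±fc_threshold with q = q_threshold and means exactly
    at the expression floor must be called '+'/'-' (thresholds inclusive);
    companions one ulp-sized step past each threshold must be '='.
    """
    criteria = criteria or diffexpr.DEGCriteria()
    q, fc = criteria.q_threshold, criteria.fc_threshold
    rows = [
        # gene_id, log2fc, p, q, mean_a, mean_b -> expected call (comments)
        ("at_up_boundary", fc, q, q, 10.0, floor_value),          # +
        ("at_down_boundary", -fc, q, q, floor_value, 10.0),       # -
        ("q_above", fc, q, np.nextafter(q, 1), 10.0, 10.0),       # =
        ("fc_below", np.nextafter(fc, 0), q, q, 10.0, 10.0),      # =
        ("floor_up_below", fc, q, q, 10.0, np.nextafter(floor_value, 0)),   # =
        ("floor_down_below", -fc, q, q, np.nextafter(floor_value, 0), 10.0),  # =
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value",
                                        "q_value", "mean_fpkm_a", "mean_fpkm_b"])
    table["call"] = pd.array([pd.NA] * len(table), dtype="string")
    return table
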