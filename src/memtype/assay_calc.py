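"""ΔΔCt relative quantification, memory-persistence testing, and leaf
physiology indices.

qPCR quantities follow the classic ΔΔCt model with amplification efficiency
fixed at 2 (no standard-curve correction):

    ΔCt   = Ct(target) − Ct(reference)          per biological replicate
    ΔΔCt  = ΔCt − mean ΔCt(calibrator condition)
    RQ    = 2^(−ΔΔCt)

Technical replicates are averaged on the Ct scale first.  Because RQ is
log-normal by construction, biological replicates are aggregated on the
log2 scale (geometric-mean RQ, SD reported in log2 units); the calibrator
condition therefore has RQ exactly 1 by definition.

Persistence of transcriptional memory is assessed per replanting interval by
a two-sample Welch test on the per-replicate log2 RQ of trained plants in
their second stress against untrained plants in their first stress — memory
genes are expected to differ at short intervals and return to baseline as
the memory fades.

Physiology: relative water content ``RWC% = (fresh − dry)/(turgid − dry) ×
100`` and detached-leaf water-loss curves ``loss(t) = (w0 − w(t))/w0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# ΔΔCt


def relative_expression_ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression of ``target`` normalised to ``reference``.

    ``table`` is a long Ct table (columns ``sample_id, condition,
    biological_rep, gene_id, role, ct``); ``calibrator_condition`` anchors
    RQ = 1.  Returns ``(per_condition, per_replicate)``:

    * ``per_condition``: condition, n biological replicates, geometric-mean
      RQ (``rq``), log2 RQ mean and SD over biological replicates;
    * ``per_replicate``: condition, biological_rep, mean Ct of target and
      reference, ΔCt, ΔΔCt, log2 RQ, RQ.
    """
    sub = table[table["gene_id"].isin([target, reference])]
    mean_ct = (sub.groupby(["condition", "biological_rep", "gene_id"])["ct"]
               .mean().unstack("gene_id"))
    if reference not in mean_ct.columns:
        raise ValueError(f"no Ct values for reference gene {reference!r}")
    if target not in mean_ct.columns:
        raise ValueError(f"no Ct values for target gene {target!r}")
    missing_ref = mean_ct[mean_ct[reference].isna()]
    if len(missing_ref):
        cond, rep = missing_ref.index[0]
        raise ValueError(
            f"missing reference-gene Ct for condition {cond!r}, "
            f"biological replicate {rep!r}")
    mean_ct = mean_ct.dropna(subset=[target])
    dct = (mean_ct[target] - mean_ct[reference]).rename("delta_ct")
    if calibrator_condition not in dct.index.get_level_values("condition"):
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    calibrator_mean = dct.xs(calibrator_condition, level="condition").mean()
    ddct = dct - calibrator_mean
    log2_rq = -ddct

    per_replicate = mean_ct.reset_index()
    per_replicate.columns.name = None
    per_replicate = per_replicate.rename(
        columns={target: "ct_target", reference: "ct_reference"})
    per_replicate["delta_ct"] = dct.to_numpy()
    per_replicate["delta_delta_ct"] = ddct.to_numpy()
    per_replicate["log2_rq"] = log2_rq.to_numpy()
    per_replicate["rq"] = 2.0 ** per_replicate["log2_rq"]

    grouped = log2_rq.groupby(level="condition")
    per_condition = pd.DataFrame({
        "condition": grouped.mean().index,
        "n_replicates": grouped.size().to_numpy(),
        "log2_rq_mean": grouped.mean().to_numpy(),
        "log2_rq_sd": grouped.std(ddof=1).to_numpy(),
    })
    per_condition["rq"] = 2.0 ** per_condition["log2_rq_mean"]
    return per_condition, per_replicate


# ---------------------------------------------------------------------------
# persistence of the memory effect


@dataclass(frozen=True)
class PersistenceVerdict:
    interval_days: int
    gene_class: str
    verdict: str          # memory-retained | baseline | insufficient-replication
    p_value: float | None
    log2_rq_diff: float | None


def persistence_compare(
    rq_trained_d2: dict[int, np.ndarray],
    rq_untrained_d1: dict[int, np.ndarray],
    gene_class: str = "memory",
    alpha: float = 0.05,
) -> list[PersistenceVerdict]:
    """Per replanting interval, test trained-D2 vs untrained-D1 expression.

    Inputs map interval (days in soil between training and the assayed
    stress, e.g. 3/5/7) to per-biological-replicate **log2 RQ** arrays.
    A Welch two-sample t-test on log2 RQ labels the interval
    ``memory-retained`` when the trained second response differs
    significantly from the untrained first response, else ``baseline``;
    fewer than two replicates on either side yields
    ``insufficient-replication``.  Non-memory genes are expected to sit at
    ``baseline`` for every interval.
    """
    verdicts = []
    for interval in sorted(rq_trained_d2):
        trained = np.asarray(rq_trained_d2[interval], dtype=float)
        untrained = np.asarray(rq_untrained_d1[interval], dtype=float)
        if min(trained.size, untrained.size) < 2:
            verdicts.append(PersistenceVerdict(interval, gene_class,
                                               "insufficient-replication",
                                               None, None))
            continue
        diff = float(trained.mean() - untrained.mean())
        if np.allclose(trained, trained[0]) and np.allclose(untrained, untrained[0]):
            # degenerate zero-variance groups: decide on the mean difference
            p = 0.0 if diff != 0 else 1.0
        else:
            p = float(stats.ttest_ind(trained, untrained, equal_var=False).pvalue)
        verdict = "memory-retained" if p <= alpha else "baseline"
        verdicts.append(PersistenceVerdict(interval, gene_class, verdict, p, diff))
    return verdicts


# ---------------------------------------------------------------------------
# physiology


def rwc(fresh_weight: float, dry_weight: float, turgid_weight: float) -> tuple[float, bool]:
    """Relative water content, percent: ``(fresh − dry)/(turgid − dry) × 100``.

    Returns ``(rwc_percent, in_range)``; ``in_range`` is False when the
    weights violate ``dry <= fresh <= turgid`` (the value is still
    returned, flagged, for QC).  ``turgid == dry`` is a hard error.
    """
    if turgid_weight == dry_weight:
        raise ValueError("turgid weight equals dry weight: RWC undefined")
    value = (fresh_weight - dry_weight) / (turgid_weight - dry_weight) * 100.0
    in_range = dry_weight <= fresh_weight <= turgid_weight
    return value, in_range


def water_loss_curve(times, weights) -> pd.DataFrame:
    """Fraction of initial fresh weight lost at each time point.

    ``loss(t) = (w0 − w(t)) / w0`` for a detached-leaf weight series; time
    must be strictly increasing and weights positive.  The ``monotone``
    column flags whether the cumulative loss is non-decreasing up to each
    point (small rehydration artifacts show up as False).
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise ValueError("times and weights must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    loss = (w[0] - w) / w[0]
    monotone = np.r_[True, np.diff(loss) >= 0].cumprod().astype(bool)
    return pd.DataFrame({"time": t, "weight": w, "loss_fraction": loss,
                         "monotone": monotone})
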