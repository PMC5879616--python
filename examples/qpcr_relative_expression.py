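"""ΔΔCt relative expression and memory persistence from a simulated qPCR run.

Simulates Ct values for a memory gene whose trained second-stress response
carries a 3-log2 boost that persists fully for 3 and 5 days of replanting
but decays to 5% by day 7, then reads the persistence back with Welch tests
on log2 relative quantity (RQ).
"""

from memtype import generate_ct_table, persistence_compare, relative_expression_ddct

decay = {3: 1.0, 5: 1.0, 7: 0.05}
ct = generate_ct_table({"MEM1": 3.0}, decay, seed=20180402)

per_condition, per_replicate = relative_expression_ddct(
    ct, target="MEM1", reference="REF1", calibrator_condition="C")
print("relative quantity by condition (geometric mean over 3 biological reps):")
for row in per_condition.itertuples():
    print(f"  {row.condition:>16}: RQ = {row.rq:8.2f} "
          f"(log2 SD {row.log2_rq_sd:.2f})")

days = sorted(decay)
trained = {d: per_replicate.loc[per_replicate["condition"] == f"D2_trained_{d}d",
                                "log2_rq"].to_numpy() for d in days}
untrained = {d: per_replicate.loc[per_replicate["condition"]
                                  == f"D1_untrained_{d}d",
                                  "log2_rq"].to_numpy() for d in days}
print("\npersistence verdicts (trained D2 vs untrained D1):")
for verdict in persistence_compare(trained, untrained):
    print(f"  day {verdict.interval_days}: {verdict.verdict} "
          f"(p = {verdict.p_value:.4f}, "
          f"log2 RQ difference = {verdict.log2_rq_diff:+.2f})")
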