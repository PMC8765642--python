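"""Watch the VR chunk form in a single laboratory-market simulation.

The chunking learner tests, after every observed transition, whether the
pair occurred more often than its chance expectation by more than C_p
binomial standard deviations (and at least Q times).  In the laboratory
market only V->R can pass — serving the resident forces an empty trial, so
R->V never occurs.
"""

from cleanermarket import (
    EnvironmentConfig,
    LearnerParams,
    final_preference,
    preference_series,
    run_simulation,
)

res = run_simulation(
    EnvironmentConfig.lab_market(),
    LearnerParams("chunking", C_p=2.0),
    n_trials=2000,
    seed=4,
)

for ev in res.chunk_events:
    print(
        f"chunk {ev.chunk.label!r} created on trial {ev.trial_index}: "
        f"W={ev.W_at_creation} exceeded the chance threshold "
        f"{ev.threshold_at_creation:.2f}"
    )

vr_trial = next(e.trial_index for e in res.chunk_events if e.chunk.label == "VR")
before = [p for b, p in preference_series(res, 40) if b * 40 + 40 <= vr_trial]
print(f"\nvisitor preference before the VR chunk: "
      f"{sum(before) / len(before):.2f}" if before else "\n(chunk formed immediately)")
print(f"visitor preference over the last 200 trials: "
      f"{final_preference(res, 200):.2f}")
print(f"final f(VR) = {res.final_values['VR']:.2f} "
      "(the executed V-then-R sequence is worth 2 food units)")
print(f"W(R,V) = {res.final_graph.W.get(('R', 'V'), 0)} "
      "(the misleading RV chunk can never form here)")
print("\nfinal internal representation:")
print(res.final_graph.node_table().to_string(index=False))
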