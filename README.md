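# cleanermarket

An agent-based simulator of associative learning and chunking on the
cleaner-fish ephemeral-reward task (the "market problem"), for behavioural
ecologists and cognition modellers studying how advanced learning abilities
evolve.

Bluestreak cleaner wrasse (*Labroides dimidiatus*) feed on ectoparasites of
"client" fish.  When a **visitor** client (which leaves if not served
first) and a **resident** client (which waits) solicit together, serving
the visitor first yields both meals; serving the resident first loses the
visitor.  Learning this visitor-first policy is the market problem, and the
laboratory version of it has defeated a surprising range of species.

## The model

The learner's memory is a weighted directed graph over behavioural states
*N* = {*V*, *R*, *X*} (serve a visitor, serve a resident, wait at an empty
arena).  Whenever state *n*<sub>j</sub> is perceived right after
*n*<sub>i</sub>, the edge weight *W*(*n*<sub>i</sub>, *n*<sub>j</sub>)
grows by 1.  Whenever a state is chosen its node weight *U* grows by 1 and
its value *F* grows by the food obtained — but only after the state's first
*Q* = 10 occurrences (a zero prior).  Between two simultaneously present
client types the cleaner chooses by soft-max on the normalised values
*f* = *F*/*U*:

&nbsp;&nbsp;&nbsp;&nbsp;π<sub>i</sub> = 1 / (1 + e<sup>−(f(n<sub>i</sub>) − f(n<sub>j</sub>))</sup>)

Four policies share this representation:

* **linear operator** — benchmark; *f*(*i*) ← (1−α)*f*(*i*) + αφ(*i*) per
  state, with learning rate α = 0.1;
* **core** — first-order soft-max learner over *f* = *F*/*U*;
* **extended credit** — chaining: a rewarding state also credits the state
  perceived immediately before it, so delayed consequences reach the
  initial choice;
* **chunking** — an ordered pair (*n*<sub>i</sub>, *n*<sub>j</sub>) becomes
  a new decision element "*n*<sub>i</sub>*n*<sub>j</sub>" when

  &nbsp;&nbsp;&nbsp;&nbsp;*W*(*n*<sub>i</sub>, *n*<sub>j</sub>) >
  *M*·*P*(*n*<sub>i</sub>)·*P*(*n*<sub>j</sub>) + *C*<sub>p</sub>·σ̂,
  &nbsp;&nbsp; σ̂ = √( *M*·*P*<sub>i</sub>*P*<sub>j</sub>·(1 −
  *P*<sub>i</sub>*P*<sub>j</sub>) ),

  i.e. when the pair co-occurs more often than chance by more than
  *C*<sub>p</sub> binomial standard deviations (and at least *Q* times).
  The chunking-avoidance parameter *C*<sub>p</sub> ≥ 0 trades off creating
  the useful *VR* chunk against the misleading *RV* chunk.

Four environments fill a two-spot arena each trial: the basic two-choice
task (2 vs 1 food units, both ephemeral), the laboratory market (always one
visitor + one resident, empty trial interleaved), the laboratory complex
market (v+r / r+r / v+v presentations at 0.5/0.25/0.25), and the natural
market (independent per-spot draws with probabilities *P*<sub>V</sub>,
*P*<sub>R</sub>, *P*<sub>0</sub>).  The experiment layer scans
*C*<sub>p</sub> across ecological conditions, estimates each condition's
optimal *C*<sub>p</sub> by a Gaussian-peak fit of preference versus
*C*<sub>p</sub>, and regresses it on the analytic r+v pair frequency
2·*P*<sub>V</sub>·*P*<sub>R</sub>.

## Worked example

`examples/lab_market_learners.py` compares the four learners on the
laboratory market (100 replicates × 1,000 feeding trials):

```
laboratory market problem, 100 replicates x 1,000 feeding trials
learner              pref   f(V)   f(R)  f(VR)
linear_operator     0.502  1.000  1.000      -
core                0.500  0.979  0.990      -
extended_credit     0.726  1.972  0.990      -
chunking            0.730  0.000  0.968  1.971
```

Both immediate rewards are equal, so the first-order learners end
indifferent (preference 0.5, both values near 1).  The extended-credit
learner attaches the resident's delayed reward to the visitor choice —
*f*(*V*) → 2 while *f*(*R*) → 1 — and prefers visitors at the soft-max
limit 1/(1+e<sup>−1</sup>) ≈ 0.73.  The chunking learner instead creates
the *VR* element and values the executed two-step sequence at ~2 (note
*f*(*V*) itself stays 0: the chunk forms before any value attaches to *V*).
The other examples show single-run chunk-formation events, the natural
market (where chaining fails and chunking succeeds), and the optimal-
*C*<sub>p</sub> scan.

A thin CLI mirrors the library: `cleanermarket run|replicates|cpsweep|
gridsweep|report --config cfg.yaml --seed 1 --out out/` (CSV/JSON/DOT
outputs; `report` rebuilds summaries from stored CSVs without
re-simulating).

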