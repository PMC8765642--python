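# Methods

This note documents the model implemented by `cleanermarket`, the
assumptions baked into the simulated environments, the parameters that
matter, and the numerical and design choices made where the written model
leaves room.

## The representation and its update rules

The learner's internal state is a weighted directed graph over elements.
The three basic elements are behavioural states, not stimuli: `V` (serving
a visitor client), `R` (serving a resident client) and `X` (waiting at an
empty arena).  Chunks — ordered pairs of basic elements such as `VR` — may
be added during a run; chunks of chunks do not exist.  Per element the
graph stores the choice count `U`, the accumulated food value `F` and the
perceived-occurrence count `O`; per ordered element pair it stores the
transition count `W`, with `M = ΣW` the total number of recorded
transitions.  All counts are unbounded and non-decreasing: forgetting and
weight decay are deliberately outside this model's scope.

Two update rules drive everything.  (1) Transition counting: whenever an
element is perceived right after another, `W` of that ordered pair and `O`
of the new element are incremented by 1.  The perceived stream runs across
trial boundaries — the last element of one trial and the first of the next
form a pair — because that is precisely how spurious sequences (a visitor
arriving by chance after a served resident) enter the statistics.  (2)
Choice crediting: a chosen element's `U` is incremented, and `F` then
grows by the obtained food only if the post-increment `U` exceeds the
prior threshold `Q`.  With `Q = 10` (the value used throughout), `F` first
rises on the 11th serving.  This implements a zero prior on unfamiliar
states without special-casing initial values.  `U` is incremented for
every perceived serving outcome, including `X` and the waiting resident
served second; since `F(X)` is always 0 and `X` is never a decision
option, this uniform bookkeeping is behaviourally inert.

Decisions between two simultaneously present client types use binary
soft-max on the normalised values `f = F/U` (0 for never-chosen elements):
`π_i = 1/(1 + exp(−(f_i − f_j)))`.  Same-type pairs are served at random;
since the two arena spots carry no identity, this requires no tie-break
draw.  Single clients are always served; an empty arena is waited out.

## The four learners

* **Linear operator** (benchmark): per basic state,
  `f(i) ← (1−α)·f(i) + α·φ(i)` with reward input `φ` and learning rate
  `α = 0.1` by default (`α ∈ (0,1]`).  Decisions use the same soft-max.
* **Core**: the representation above, first-order only.
* **Extended credit**: one step of chaining.  When a perceived element is
  rewarding, the element perceived immediately before it also receives the
  reward in `F` — behind the receiver's own already-accumulated `Q` gate,
  without touching its `U`.  Credit extension is exactly one step back.
  `X` neither donates nor receives extended credit: its reward is zero and
  it is never a decision option, so the choice is inert but documented for
  reproducibility.
* **Chunking**: after every transition update of a pair of basic elements,
  the pair is tested (only the just-updated pair can newly pass, so this
  is equivalent to testing all pairs at O(1) cost).  A chunk is created
  when `W > M·P_i·P_j + C_p·σ̂` with `σ̂ = sqrt(M·P_i·P_j·(1−P_i·P_j))`,
  the standard deviation of the binomial co-occurrence count, subject to
  `W ≥ Q`.  The element frequencies `P(k) = O(k)/ΣO` are observed
  perceived-stream frequencies, and `M` is the transition total — this
  reading keeps both sides of the inequality on the same (pair-count)
  scale.  Chunk creation ignores reward entirely; decision-irrelevant
  chunks (`XR`, `RR`, `XX`, …) form freely and sit inert in the graph.
  Creating a chunk does not reset the constituents' `W`.

Once the `VR` chunk exists, a mixed visitor-resident pair is decided
between executing `VR` and the alternative (`R`, or `RV` if that chunk
also exists); the first element of a known chunk is never offered alone.
An executed `VR` is perceived as a single element and its full two-step
food (2 units) credits the chunk only — constituent states receive no
`U`/`F` updates during a chunk episode, avoiding double counting.

An executed `RV` is the model's maladaptive option: the resident is served
(1 unit, credited to `RV`), the visitor leaves, and the chunk's second
step extends into the next trial — the first client served there
contributes its reward to `F(RV)` instead of its own node, while being
processed normally for the environment and the transition stream.  If the
next trial is empty the pending credit lapses (the episode "ends up with
serving only R").  In the corner case where the next trial's action is
itself a chunk execution, the pending chunk takes the first constituent's
food unit and the executed chunk keeps the remainder; this situation is
rare, underdetermined by the written model, and isolated in one code block
for easy revision.

## Simulated environments

A two-spot arena is refilled each discrete trial.  Visitors leave if not
served first; residents wait and are served second within the same trial.
Regimes:

* `two_choice`: always one 2-unit and one 1-unit client, both ephemeral,
  no second approach; a forced empty trial follows each feeding trial.
* `lab_market`: always one visitor + one resident per feeding trial, each
  worth 1; forced empty trial after each feeding trial.
* `lab_complex`: feeding trials draw v+r / r+r / v+v at 0.5/0.25/0.25 by
  default; forced empty trial after each feeding trial.
* `natural`: each spot filled independently with probabilities `P_V`,
  `P_R`, `P_0` (summing to 1); no forced empties.  The two ecological
  axes are the visitor frequency `P_V/(P_V+P_R)` and the client density
  `1−P_0`; the analytic probability of a mixed pair is `2·P_V·P_R`.

`n_trials` counts *total* trials including forced empty trials, so the
standard laboratory experiment of 1,000 feeding trials runs
`n_trials = 2000`.  Natural-regime experiments default to 2,000 trials,
which gives a comparable number of feeding events at density 0.5.

What the generator emulates — and does not.  The environments reproduce
the ephemeral/enduring reward structure, the client-arrival statistics of
the two-spot arena, and the laboratory protocols' interleaved empty
trials.  They do not model client species identity, more than two
simultaneous clients, waiting costs, cheating/retaliation dynamics, or
session structure in real experiments.  Results here are statements about
the learning mechanisms under these idealised arrival statistics, not
predictions of individual fish behaviour.

## Experiment layer

Preference is the proportion of visitor-first choices among mixed
encounters (executing `VR` counts as visitor-first; serving `R` or
executing `RV` as resident-first), reported in bins of 40 trials for time
series and over the last 200 trials (laboratory runs) or last 500 trials
(sweeps) as the end-of-run summary.  Preference ≥ 0.6 counts as solving
the market problem.

The optimal `C_p` for an environment is located by scanning a `C_p` grid
(101 equally spaced values in [0, 5] at the scaled-down default; the
full-resolution 1,000-value scan is a parameter away), pooling
visitor-first/mixed-encounter counts over the replicates at each value,
and fitting `a·exp(−(x−μ)²/(2s²)) + b` by least squares.  The baseline
`b` absorbs the nonzero floor of soft-max preferences.  Numerical
safeguards, all on the scale of the data: the fit is initialised at the
empirical argmax; `s` is bounded below by three grid steps (the curve
describes the broad preference profile, not single Monte-Carlo outliers);
`a` and `b` are bounded to [0, 1]; the fitted peak is clipped to the
scanned interval and capped at 1; on non-convergence the argmax is used
and flagged.

Sampling adequacy.  A preference point backed by fewer than 20 pooled
mixed encounters is recorded as missing — a proportion estimated from a
handful of Bernoulli draws carries no information and only feeds noise
into the peak fit.  At the grid level the same threshold is applied
*analytically*: a cell whose expected encounter count
`window·reps·2·P_V·P_R` falls below it is marked undetermined
(no optimum, not successful) rather than estimated.  Because this gate
uses the analytic pair frequency, the set of assessable cells is a
deterministic property of the experimental design, not of the seed.

The ecological grid sweep (default 9×9 over visitor frequencies and
densities 0.1–0.9, 3 replicates per `C_p` value, 2,000 trials per run)
records each cell's optimal `C_p`, fitted peak preference, success flag
and analytic r+v pair frequency, and the experiment's summary statistic is
the OLS regression of optimal `C_p` on r+v pair frequency over successful
cells (slope, intercept, R², F-test p-value).

Seeding.  Every run draws all randomness from one `random.Random(seed)`.
Replicate `i` of a summary uses `base_seed + i`.  Sweep runs derive their
seeds from the `C_p` *value* (not its grid index), which makes sweep
results exactly invariant to the order in which the grid is scanned;
grid cells further hash their ecological coordinates into the seed so
cells are decorrelated.

## Known limitations

* The `RV` second-step credit rule is one defensible reading of an
  underdetermined specification; it reproduces the qualitative behaviour
  (RV worth ~1 unit in sparse environments, approaching 2 at high
  density) and is confined to one code path.
* Chunks are perceived only when executed as chosen actions; a passively
  experienced V-then-R across trials updates `W(V,R)` but is not
  re-perceived as `VR`.  This ties chunk perception to choice, which is an
  interpretation rather than a stated rule.
* Scaled-down sweep settings trade Monte-Carlo precision for runtime; the
  regression R² at the 9×9/101-value scale varies by roughly ±0.03 across
  seeds.
* No forgetting, no hierarchical chunks, no evolutionary dynamics over
  `C_p`: the simulator measures which fixed parameters would be adaptive,
  not how selection reaches them.
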