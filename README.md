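# synmix

Analysis pipeline for pairing-induced synaptic plasticity in layer 4 (L4)
of visual cortex: sweep-level quality control, per-cell LTP/LTD/NC
classification, and a Monte Carlo "input mixing" simulation that asks
whether compound (extracellular-stimulation) plasticity outcomes can arise
from random versus segregated mixing of unitary connections.

## The problem

Pairing pre- and postsynaptic activity can potentiate (LTP), depress (LTD)
or leave unchanged (NC) a synaptic connection. When a single presynaptic
neuron is driven (single-cell stimulation, SCS), outcomes across
connections are heterogeneous. When many afferents are driven at once
(extracellular stimulation, ECS), the evoked compound response sums ~18
unitary inputs — so if each input's outcome were drawn independently,
opposite-sign changes should average out and the compound response should
barely move. Yet with GABA_A inhibition blocked, ECS pairing produces
robust LTP and LTD at the compound level. This package implements the
statistical machinery for that comparison:

* **Classification.** For one experiment with pre- and post-pairing sweep
  amplitude series, the normalized change is
  `Δ_N = 100·(post_mean − pre_mean)/pre_mean`. The cell is LTP iff
  `Δ_N > +15%` *and* the pre-vs-post two-sample t-test gives `p < 0.05`;
  LTD iff `Δ_N < −15%` with `p < 0.05`; otherwise NC.
* **QC.** Recordings are excluded for access resistance above 40 MΩ or 20%
  of input resistance, Ra drift above 20%, membrane potential above
  −60 mV, or a significant linear trend (p < 0.05) in the baseline.
* **Input mixing.** A simulated compound response (SCR) is built by
  sequentially sampling unitary connections from an SCS database until
  their summed pre-pairing strength reaches 350 pA, then summing the same
  connections' post-pairing strengths; `SCR Δ_N` is the normalized change.
  A segregation parameter `S ∈ [0, 1]` biases each draw after the first to
  the first draw's outcome class with probability `S` (so
  `P(same class) = S + (1 − S)·p(class)`, linear in `S`). `S = 0` is fully
  random mixing; `S = 1` builds each SCR from one plasticity class. SCR
  Δ_N variances are compared against the observed ECS Δ_N variance with a
  two-sided F-test across an `S` grid.

Because the original per-connection data live in an external repository,
the package ships a first-class synthetic-data module that generates sweep
series and SCS databases with the published protocol structure, response
scales, group effect sizes and outcome frequencies (7/43 LTP, 18/43 LTD,
18/43 NC), so the entire pipeline is testable offline.

## Worked example

```python
import numpy as np
from synmix import (GeneratorParams, ProtocolParams, classify_recording,
                    generate_ecs_dataset, generate_scs_database,
                    sweep_segregation)
from synmix.pipeline import BICUCULLINE_COMPOSITION

protocol = ProtocolParams()           # 120 pre sweeps @0.2 Hz, 60 pairings @0.1 Hz, 120 post
recs = generate_ecs_dataset(BICUCULLINE_COMPOSITION, protocol,
                            GeneratorParams(seed=0), condition="bicuculline")
res = classify_recording(recs[0])
print(f"{recs[0].cell_id}: delta_n = {res.delta_n_pct:+.1f}%, "
      f"p = {res.p_value:.2g} -> {res.label}")
# bicuculline-LTP-00: delta_n = +44.8%, p = 2.8e-77 -> LTP

db = generate_scs_database(seed=0)    # 43 unitary connections
deltas = np.array([classify_recording(r).delta_n_pct for r in recs])
print(sweep_segregation(db, deltas, s_grid=[0.0, 0.5, 1.0], n_scr=26, seed=0))
#      s    mean  variance  ...  f_statistic  p_value  variance_lower
#    0.0 -10.632    79.994  ...        0.057    0.000            True
#    0.5  -6.433   526.876  ...        0.375    0.017            True
#    1.0 -14.109  1145.948  ...        0.816    0.614            True
```

The 26-cell disinhibited dataset relabels to 7 LTP / 9 LTD / 10 NC. The
sweep table shows the core result: with random mixing (`S = 0`) the SCR
Δ_N variance is far below the observed ECS variance (F-test p < 0.001);
only near complete segregation does the difference stop being significant.

The same stages are exposed on the command line:

```sh
synmix --seed 1 --out run1 simulate
synmix --seed 1 --out run1 classify run1/control.csv run1/bicuculline.csv
synmix --seed 1 --out run1 sweep-s run1/scs_database.csv run1/per_cell_results.csv
synmix --seed 1 --out run1 report     # full pipeline + JSON report
```

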