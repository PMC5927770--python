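# quantalysis

Quantal analysis of neuromuscular-junction (NMJ) electrophysiology, built
around the questions raised by compartmentalized presynaptic homeostatic
potentiation (PHP) at the *Drosophila* larval NMJ: when postsynaptic
glutamate-receptor function is reduced on one of two muscles innervated by
the same motor neuron, does the presynaptic compensation — more vesicles
released per action potential — stay confined to the synapses on that
muscle?

The package is for electrophysiologists and modellers who need the standard
quantal estimators as tested, composable code:

* **Miniature/evoked quantification** — threshold detection of spontaneous
  miniature events (mEPSP/mEPSC) over a running-median baseline, and
  peak-minus-baseline evoked amplitudes for single stimuli and trains.
* **Quantal content** — QC = EPSP/mEPSP (per cell, ratio of means), the
  estimate of N·p vesicles released per action potential.
* **Readily releasable pool (RRP)** — cumulative EPSC amplitude during a
  60 Hz train, ordinary least squares on the linear phase (stimuli 18–30),
  back-extrapolated to t = 0 and divided by the mean mEPSC.
* **Variance–mean (MPFA)** — across Ca²⁺ conditions (0.5/1.5/3.0/6.0 mM
  plus a theoretical origin for Ca-free saline), trial-to-trial variance
  versus mean evoked amplitude follows the binomial parabola

      variance = Q·Ī − Ī²/N,

  whose initial slope is the quantal size Q and whose curvature gives the
  number of functional release sites N; per-condition release probability
  follows as p = Ī/(N·Q).
* **PHP classification** — a condition expresses PHP when minis are
  significantly reduced, evoked amplitude is statistically unchanged, and
  QC is significantly increased (Student's t; ANOVA + Tukey for families).
* **A seeded binomial-release simulator** — Binomial(N, p(Ca)) release with
  gamma quantal sizes, pool depletion/replenishment for trains, and full
  trace synthesis (difference-of-exponentials kernels, Poisson minis,
  Gaussian noise) with ground-truth sidecars for parameter-recovery
  testing, including wild-type and muscle-specific knockdown scenarios.

The estimators follow scikit-learn conventions (`fit`, fitted attributes
with trailing underscores, `get_params`/`set_params`); module-level
functions wrap them for one-line use.

## Worked example

```python
import numpy as np
import quantalysis as q

rng = np.random.default_rng(0)
model = q.ReleaseModel(n_sites=150, q_mean=0.6, q_cv=0.3)  # ground truth
pool = q.PoolModel(pool_size=600)

Ns, Qs, rrps = [], [], []
for cell in range(6):
    points = [q.summarize_condition(
        q.draw_evoked_amplitudes(model, ca, n_sweeps=30, rng=rng), ca)
        for ca in (0.5, 1.5, 3.0, 6.0)]
    fit = q.fit_parabola(q.with_origin(points))
    train = q.simulate_train(model, pool, ca=3.0, n_stim=30, freq=60.0,
                             rng=rng)
    Ns.append(fit.n_sites_N)
    Qs.append(fit.quantal_size_Q)
    rrps.append(q.estimate_rrp(train, mean_mepsc=model.q_mean).rrp_quanta)

print(f"quantal size Q : {np.mean(Qs):.2f} +/- "
      f"{np.std(Qs, ddof=1)/np.sqrt(6):.2f} nA")
print(f"release sites N: median {np.median(Ns):.0f}")
print(f"RRP            : {np.mean(rrps):.0f} +/- "
      f"{np.std(rrps, ddof=1)/np.sqrt(6):.0f} quanta")
```

prints

```
quantal size Q : 0.64 +/- 0.09 nA
release sites N: median 170
RRP            : 541 +/- 5 quanta
```

The fitted Q slightly exceeds the true 0.6 nA because independent quantal
variability inflates the parabola's initial slope by (1 + cv²); the median
N̂ sits near the true 150 but is the noisiest of the three estimates at 30
sweeps per condition (see `docs/methods.md`); the back-extrapolated RRP
underestimates the true 600-quantum pool by design of the train method
(replenishment during the depleting phase is absorbed into the line).

A command-line interface mirrors the library
(`quantalysis simulate|detect|quantal-content|rrp|varmean|run|report`):

```bash
quantalysis simulate --template knockdown --seed 1 --out data/kd
quantalysis run --manifest data/kd/manifest.csv --out results/
```

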