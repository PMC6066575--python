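# fairplay

An evolutionary agent-based model of **juvenile fair play**: why should
young animals play "fairly" (role-reversal, self-handicapping) when play
is dangerous and adult fairness — splitting resources evenly — has no
expected-payoff advantage?

The model is a group-structured population of asexual agents carrying a
single binary *play gene*. Gene-carrying juveniles seek one play bout per
step with a group-mate, paying a per-bout mortality probability *c*; a
juvenile that accumulates at least *α* bouts matures into a **fair**
adult. Fair adults pool each step's foraging gains with the other fair
adults in their group and divide the pool evenly; selfish adults keep
what they catch. Reproduction converts accumulated resources into
offspring under three life-history constraints: a resource threshold *T*,
a parental investment fraction *P* (the offspring's endowment), and a
reproductive delay *d* between successive births.

## The core argument

Each adult forages successfully with probability *p* for a reward of mean
*R*, so expected intake is *pR* for everyone — pooling does not change
it. What pooling changes is the **variance**: a selfish forager's
per-step intake variance is

> var(R, p) = (1 − p) p R²

while the within-pool variance of a fair adult's intake is zero. Under a
reproductive delay, that matters: after reproducing, a parent must regain
roughly *P·T* resources before its next opportunity. A fair adult
accumulates steadily (*d·pR* expected over the delay); a selfish adult
needs *k* = ⌈*P·T*/*R*⌉ discrete wins inside the window, which it gets
with binomial probability P(X ≥ k), X ~ Bin(d, p) — under 0.4 across the
relevant conditions. Selection for fairness therefore peaks where the
delay just spans the replacement time, *d* ≈ *P·T*/(*pR*).

## Worked example

```bash
python examples/single_run.py
```

runs a quarter-length (6,000-step) simulation at the reference condition
(*R* = 40, *p* = 0.0875, *P* = 0.5, *d* = 15, *c* = 0.003) and prints:

```
step     0: adults  873  living gene frequency 0.057
step  1000: adults  990  living gene frequency 0.118
step  2000: adults  993  living gene frequency 0.200
step  3000: adults  984  living gene frequency 0.328
step  4000: adults  990  living gene frequency 0.435
step  5000: adults  989  living gene frequency 0.554

gene frequency among births in steps [3000, 6000): 0.507
realized juvenile play mortality: 9.9%  (per-bout cost c = 0.003)
births in measurement window: 160339
```

The play gene starts at 5% and climbs steadily even though every bout of
play carries a 0.3% death risk (about 10% cumulative mortality among
playing juveniles); full-length 25,000-step runs equilibrate near 80%.
The other examples cover the closed-form payoff analytics
(`closed_form_payoffs.py`), the learning-vs-control comparison
(`control_vs_learning.py`), and a reduced factorial sweep
(`reduced_sweep.py`).

The same machinery is scriptable from a shell:

```bash
fairplay run --seed 1 --out out/                 # one run + manifest
fairplay sweep --spec spec.json --out sweep/     # resumable factorial sweep
fairplay analytics variance 40 0.0875            # 127.75
fairplay analytics peak-delay 0.5 100 0.0875 40  # 14.29
```

## Package layout

- `fairplay.params` — parameter records, JSON config I/O, factorial sweep
  enumeration, deterministic per-run seeding
- `fairplay.population` — agents/groups state, birth, lifespan, removal
- `fairplay.engine` — the seven-phase step loop and `run_simulation`
- `fairplay.analytics` — closed-form payoff/variance/threshold quantities
- `fairplay.experiments` — replicates, controls, aggregation, summary tables
- `fairplay.cli` — the thin `fairplay` command

See `docs/methods.md` for the model description, parameter meanings,
numerical choices, and limitations.
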