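# ugadecode

Quantitative analysis of alternative UGA codon assignment during
selenoprotein synthesis.

At a selenoprotein UGA codon the ribosome either incorporates
selenocysteine (Sec) — when a charged Sec-tRNA wins the site — or
terminates translation when a release factor (RF) wins, yielding a
full-length protein P_L or a truncated protein P_S. `ugadecode` is for
researchers who measure this competition with dual-fluorescent (GPS)
reporters, where RFP reports protein synthesis and GFP reports protein
abundance, and who want to turn single-cell (RFP, GFP) clouds recorded
at several selenium concentrations into the kinetic parameters of the
decoding process.

## The model

Three mass-action equilibria,

    m·SeT = k₁·m_f·SeT_f        SeT_total = k₃·Se·T        m·RF = kF·m_f

are coupled to two resource constraints — the mRNA partition
`m_f + m·SeT + m·RF = m_total` and the tRNA pool
`T + SeT_total = T_total` — giving a closed-form steady state: the free
mRNA `m_f` is the positive root of

    k₁(1+kF)·m_f² + [(1+kF) + k₁(S − m_total)]·m_f − m_total = 0,
    S = k₃·Se·T_total/(1 + k₃·Se),

from which `P_L ∝ k₁·m_f·SeT_f` and `P_S ∝ kF·m_f` follow, and the
observables `RFP = ρ·ρ_p·m_total`, `GFP = ρ_p·(P_L + P_S)`. The package
provides

* the closed-form model with constraint-ablated variants
  (`full`, `mrna_only`, `trna_only`, `none`) and an optional
  nonsense-mediated-decay correction (`ugadecode.model`);
* a synthetic GPS data generator with the measured multiplicative noise
  structure (`ugadecode.simulate`);
* the two-stage cytometry filtering protocol (`ugadecode.gps_io`);
* a recursive log-grid divide-and-conquer estimator of
  {k₁, kF, k₃, T_total, ρ} (`ugadecode.fitting`);
* a simulate-then-fit parameter-recovery benchmark
  (`ugadecode.benchmark`).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate noiseless five-condition GPS data from a known parameter set
and refit it:

```python
import ugadecode as ug

truth = ug.KineticParameters(k1=3, kF=0.1, k3=10, T_total=500, rho=10, rho_p=100)
data = ug.simulate_multi_condition(truth, ug.default_m_grid(200), noise_sd=0.0, seed=1)
result = ug.grid_search(data, ug.FitConfig(blocks=8))
print(result.table.head(3)[["k1", "kF", "k3", "T_total", "rho", "Q2"]])
print(ug.recovery_error(result.best, truth))
```

prints

```
         k1        kF         k3     T_total        rho            Q2
0  8.505258  0.099105  20.908000   50.028646  99.104586  1.624332e+09
1  1.512473  0.099105  20.908000  281.331751  17.623564  1.624332e+09
2  1.512473  0.099105  21.673922  281.331751  17.623564  1.676915e+09
```

```
{'k1': 0.4526, 'kF': 0.0039, 'k3': 0.3203, 'T_total': 0.9998, 'rho': 0.9961}
```

Every recovery error `|log10(estimate/truth)|` is below 1, i.e. the
rank-1 solution lands within ten-fold of the generating values. The
estimate does not sit exactly on the truth because the model has an
exact scaling degeneracy — `(c·k₁, T_total/c, c·ρ)` predicts identical
GFP–RFP curves for any `c` — so the search lands somewhere on the
degenerate ridge, and the report retains the degenerate classes: ranks
1 and 2 above share one loss value but sit at different ridge positions
(`c ≈ 10` and `c ≈ 1.8`); `kF` and `k₃` are well identified.
The decoding probability at a given state is also directly available:

```python
>>> ug.uga_sec_fraction(truth, m_total=1000.0, Se=1.0)
0.9015301215293817
```

A shell pipeline is available too:

```sh
ugadecode simulate --params truth.yaml --se 0,8,40,200,1000 --n 1000 --noise 0.3 --seed 7 --out sim.tsv
ugadecode filter --in sim.tsv --grid 2000 --min-bin 30 --keep 0.004 --out filtered.tsv
ugadecode fit --data filtered.tsv --out fit.json
ugadecode benchmark recovery --trials 30 --blocks 8 --noise 0.3 --seed 1 --out report.json
```

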