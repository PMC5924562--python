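# mitodem

Temporal mitogenome diversity and demographic inference for bottlenecked
populations.

Conservation-genetic studies increasingly compare *pre-decline* museum
specimens with *post-decline* modern samples of the same population. For a
single maternally inherited, non-recombining locus (a mitogenome) this
package provides the full analysis chain for such two-layer data:

- **per-layer diversity statistics** — haplotype count h, segregating
  sites S, haplotype diversity Hd, nucleotide diversity π, mean pairwise
  differences k, Tajima's D, and Fu's *F*ₛ evaluated *exactly* through the
  Ewens sampling formula with big-integer Stirling numbers (no underflow in
  the deep tail, e.g. 36 haplotypes among 39 samples);
- **a serially sampled coalescent simulator** for piecewise-constant
  haploid demographies (constant / post-glacial expansion / recent
  bottlenecks tied to Polynesian and European settlement windows), with
  infinite-sites or Jukes–Cantor mutations and a study-shaped synthetic
  data generator (39 historical + 79 modern sequences, 16,588 bp, 2%
  missing data in historical consensus sequences);
- **ABC demographic inference** — prior-predictive reference tables,
  normalized Euclidean rejection, Beaumont-style local-linear regression
  adjustment on a logit scale (adjusted draws respect prior bounds),
  logistic-regression model choice, KDE posterior modes with 5%/95% HPD
  bounds, and pod-based type I/II scenario-choice error rates;
- **haplotype networks** — temporal sharing between layers and
  minimum-spanning networks (union of all MSTs) over Hamming distances.

The central statistics, in standard notation:

- Tajima's D = (k − S/a₁) / √(e₁S + e₂S(S−1)), negative under expansion,
  positive after a bottleneck;
- Fu's *F*ₛ = ln(S′/(1−S′)) with S′ = Σ_{j=h}^{n} |s(n,j)| θʲ / (θ)ₙ,
  θ = k — strongly negative when haplotypes are in excess (expansion);
- Hd = n(1 − Σpᵢ²)/(n−1), π = k/L_eff;
- coalescence at rate k(k−1)/(2N) per generation within each epoch of the
  size history N(t).

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

Simulate a study-shaped dataset at the European-bottleneck scenario's
posterior-mode parameters (modern N\_e ≈ 17.6, bottleneck ≈ 4.5 generations
ago, pre-bottleneck N\_e ≈ 5.7×10⁵), then summarize it:

```python
import numpy as np
from mitodem.synthetic_data import DatasetSpec, generate_dataset
from mitodem.sumstats import layer_stats
from mitodem.haplonet import collapse, temporal_shared

params = {"ne_modern": 17.6, "ne_pre_european": 5.67e5,
          "ne_pre_glaciation": 3.90e3, "t_bottleneck_eu": 4.47,
          "t_post_glaciation": 600.0, "mu": 5e-8}
ds = generate_dataset(DatasetSpec("bottleneck_eu", params=params),
                      np.random.default_rng(42))
for layer, st in layer_stats(ds.alignment).items():
    print(layer, f"n={st.n} h={st.h} S={st.S} Hd={st.Hd:.3f} "
                 f"pi={st.pi:.5f} D={st.D:.2f} Fs={st.Fs:.2f}")
shared, _ = temporal_shared(collapse(ds.alignment))
print("haplotypes shared across layers:", shared)
```

prints

```
modern n=79 h=4 S=9 Hd=0.714 pi=0.00053 D=3.17 Fs=9.19
historical n=39 h=13 S=23 Hd=0.787 pi=0.00074 D=0.15 Fs=-0.25
haplotypes shared across layers: 3
```

The four-generation bottleneck at N\_e ≈ 18 collapses 13 historical
haplotypes to 4 modern ones and drives modern Tajima's D and Fu's *F*ₛ
strongly positive (rare alleles lost) — the qualitative signature seen in
real post-decline data.

The same stages are available from the shell:

```bash
mitodem simulate --scenario bottleneck_eu --seed 1 --out sim
mitodem stats   --fasta sim.fasta --meta sim.tsv --out stats.tsv
mitodem network --fasta sim.fasta --meta sim.tsv --out-prefix net
mitodem abc build-table --scenarios bottleneck_eu,bottleneck_pol --nsims 10000 --seed 2 --out table.tsv
mitodem abc fit  --table table.tsv --fasta sim.fasta --meta sim.tsv --accept 0.01 --out fit.json
mitodem abc pods --scenarios bottleneck_eu,bottleneck_pol --n-pods 100 --seed 3 --out pods.tsv
mitodem report  --config run.json --out-dir results/   # whole pipeline + manifest
```

Observed data enter as a plain FASTA alignment plus a tab-separated
metadata table (`sample_id`, `layer`, `age_generations`); ids are joined
strictly.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the published-value targets from scratch — currently the
historical layer's Fu's *F*ₛ, evaluated exactly from the printed sample
size, haplotype count and θ = π × L through the package's Ewens-sampling
machinery — and writes them as JSON.
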